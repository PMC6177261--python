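"""Maximum-likelihood ancestral sequence reconstruction on a fixed topology.

Likelihoods are computed with Felsenstein's pruning algorithm under
LG + discrete gamma; gaps and unrecognized residues are treated as missing
data (an all-ones conditional likelihood at the tip). Marginal (empirical
Bayes) posteriors at a named internal node integrate over the discrete rate
categories weighted by each site's posterior over categories.

The "AltAll" alternative ancestor carries, at every ambiguously reconstructed
site (any non-ML state with posterior probability strictly above a threshold,
default 0.20), the second-best state instead of the ML state — a conservative
probe of reconstruction robustness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import AminoAlignment, FlatTree, PhyloTree
from .model import AMINO_ACIDS, GAP_CODE, LGGammaModel

_BL_MIN, _BL_MAX = 1e-8, 20.0
_ALPHA_MIN, _ALPHA_MAX = 0.05, 50.0


# ---------------------------------------------------------------------------
# pruning machinery


def _tip_partials(alignment: AminoAlignment, flat: FlatTree) -> dict[int, np.ndarray]:
    codes = alignment.codes()
    name_to_row = {n: i for i, n in enumerate(alignment.names)}
    leaves = flat.leaf_index()
    missing = set(leaves) - set(name_to_row)
    extra = set(name_to_row) - set(leaves)
    if missing or extra:
        raise ValueError(
            f"leaf/alignment label mismatch; tree-only: {sorted(missing)}, "
            f"alignment-only: {sorted(extra)}")
    out = {}
    for label, node_i in leaves.items():
        c = codes[name_to_row[label]]
        L = np.zeros((alignment.n_sites, 20))
        obs = c != GAP_CODE
        L[obs, c[obs]] = 1.0
        L[~obs, :] = 1.0  # gap: missing data
        out[node_i] = L
    return out


def _edge_matrices(flat: FlatTree, model: LGGammaModel, rate: float) -> list:
    mats = [None] * flat.n_nodes
    for i in range(flat.n_nodes):
        if flat.parent[i] >= 0:
            mats[i] = model.transition_matrix(flat.lengths[i] * rate)
    return mats


def _postorder_partials(flat: FlatTree, tips: dict[int, np.ndarray],
                        P: list) -> tuple[list, np.ndarray]:
    """Conditional likelihoods L[node] (n_sites, 20) with per-site log scaling."""
    n_sites = next(iter(tips.values())).shape[0]
    L: list = [None] * flat.n_nodes
    logscale = np.zeros((flat.n_nodes, n_sites))
    for i in range(flat.n_nodes):
        if flat.is_leaf[i]:
            L[i] = tips[i]
            continue
        acc = np.ones((n_sites, 20))
        sc = np.zeros(n_sites)
        for c in flat.children[i]:
            acc = acc * (L[c] @ P[c].T)
            sc = sc + logscale[c]
        m = acc.max(axis=1)
        small = m < 1e-200
        if small.any():
            m = np.where(m > 0, m, 1.0)
            acc = acc / m[:, None]
            sc = sc + np.log(m)
        else:
            pass
        L[i] = acc
        logscale[i] = sc
    return L, logscale


def _per_category_site_loglik(alignment, flat, model):
    """log site likelihood per rate category, shape (K, n_sites), plus partials."""
    tips = _tip_partials(alignment, flat)
    rates = model.category_rates
    per_cat = []
    partials = []
    for r in rates:
        P = _edge_matrices(flat, model, r)
        L, logscale = _postorder_partials(flat, tips, P)
        root_lik = L[flat.root] @ model.freqs
        per_cat.append(np.log(np.maximum(root_lik, 1e-300)) + logscale[flat.root])
        partials.append((P, L, logscale))
    return np.array(per_cat), partials


def tree_log_likelihood(alignment: AminoAlignment, tree: PhyloTree,
                        model: LGGammaModel) -> float:
    """Total log likelihood of the alignment on the tree under LG + gamma."""
    flat = tree.flatten()
    return _loglik_flat(alignment, flat, model)


def _loglik_flat(alignment: AminoAlignment, flat: FlatTree,
                 model: LGGammaModel) -> float:
    per_cat, _ = _per_category_site_loglik(alignment, flat, model)
    logw = np.log(model.category_weights)[:, None]
    m = per_cat.max(axis=0)
    site = m + np.log(np.exp(per_cat + logw - m[None, :]).sum(axis=0))
    return float(site.sum())


# ---------------------------------------------------------------------------
# parameter optimization


def optimize_parameters(alignment: AminoAlignment, tree: PhyloTree,
                        model: LGGammaModel, fit_shape: bool = True,
                        tol: float = 1e-6, max_sweeps: int = 30,
                        ) -> tuple[PhyloTree, LGGammaModel, float]:
    """Optimize branch lengths (and optionally gamma shape) by ML.

    Coordinate-wise bounded scalar searches over each branch and alpha,
    swept until the log-likelihood improves by less than ``tol``.
    Returns a new tree (ML branch lengths), a new model, and the final lnL.
    """
    tree = tree.clone()
    flat = tree.flatten()
    cur = _loglik_flat(alignment, flat, model)
    converged = False
    for _ in range(max_sweeps):
        start = cur
        for i in range(flat.n_nodes):
            if flat.parent[i] < 0:
                continue

            old = flat.lengths[i]

            def f(x, i=i):
                flat.lengths[i] = x
                return -_loglik_flat(alignment, flat, model)

            res = minimize_scalar(f, bounds=(_BL_MIN, _BL_MAX),
                                  method="bounded",
                                  options={"xatol": 1e-7})
            if -res.fun >= cur:
                flat.lengths[i] = res.x
                cur = -res.fun
            else:
                flat.lengths[i] = old
        if fit_shape:
            def g(a):
                return -_loglik_flat(alignment, flat, model.with_alpha(a))

            res = minimize_scalar(g, bounds=(_ALPHA_MIN, _ALPHA_MAX),
                                  method="bounded", options={"xatol": 1e-5})
            if -res.fun >= cur:
                model = model.with_alpha(float(res.x))
                cur = -res.fun
        if cur - start < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimization did not converge within "
                      f"{max_sweeps} sweeps; returning best-found values")
    tree.set_lengths_from(flat)
    return tree, model, cur


# ---------------------------------------------------------------------------
# marginal ancestral reconstruction


@dataclass
class AncestralPosterior:
    """Per-site marginal posterior state distribution at one internal node."""

    node_label: str
    probs: np.ndarray  # (n_sites, 20), rows sum to 1

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]

    @property
    def ml_states(self) -> np.ndarray:
        return self.probs.argmax(axis=1)

    @property
    def ml_probs(self) -> np.ndarray:
        return self.probs.max(axis=1)


def marginal_posteriors(alignment: AminoAlignment, tree: PhyloTree,
                        model: LGGammaModel, node_label: str
                        ) -> AncestralPosterior:
    """Empirical-Bayes marginal posteriors at a labeled internal node.

    Combines inside (pruning) and outside vectors per rate category; the
    categories are mixed with their site-specific posterior weights, which is
    what summing the per-category joints and normalizing per site achieves.
    """
    flat = tree.flatten()
    target = flat.internal_index().get(node_label)
    if target is None:
        raise KeyError(f"unknown internal node {node_label!r}; available: "
                       f"{sorted(flat.internal_index())}")
    per_cat, partials = _per_category_site_loglik(alignment, flat, model)
    n_sites = alignment.n_sites
    weights = model.category_weights
    joint = np.zeros((n_sites, 20))
    # overall per-site log evidence for normalization across categories
    m = per_cat.max(axis=0)
    for k, (P, L, logscale) in enumerate(partials):
        U, ulog = _outside_vector(flat, target, P, L, logscale, model)
        Jk = U * L[target]                      # (n_sites, 20)
        lognorm = ulog + logscale[target] - m   # (n_sites,)
        joint += weights[k] * Jk * np.exp(lognorm)[:, None]
    total = joint.sum(axis=1, keepdims=True)
    probs = joint / np.where(total > 0, total, 1.0)
    return AncestralPosterior(node_label=node_label, probs=probs)


def _outside_vector(flat: FlatTree, target: int, P, L, logscale, model):
    """Outside (complementary) likelihood vector at `target` for one category."""
    path = []
    i = target
    while i >= 0:
        path.append(i)
        i = flat.parent[i]
    path.reverse()  # root ... target
    n_sites = L[flat.root].shape[0]
    U = np.tile(model.freqs, (n_sites, 1))
    ulog = np.zeros(n_sites)
    for parent, child in zip(path[:-1], path[1:]):
        for sib in flat.children[parent]:
            if sib == child:
                continue
            U = U * (L[sib] @ P[sib].T)
            ulog = ulog + logscale[sib]
        U = U @ P[child]
        mx = U.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        U = U / mx[:, None]
        ulog = ulog + np.log(mx)
    return U, ulog


# ---------------------------------------------------------------------------
# ancestral sequences, AltAll, substitutions


@dataclass
class AncestralSequenceSet:
    """ML and AltAll sequences for one node, with uncertainty summaries."""

    node_label: str
    ml_sequence: str
    altall_sequence: str
    ambiguous_sites: list[int]          # 0-based site indices
    mean_posterior: float
    expected_errors: float
    altall_mean_posterior: float
    tied_sites: list[int] = field(default_factory=list)


def ancestral_sequences(posterior: AncestralPosterior,
                        alt_threshold: float = 0.20) -> AncestralSequenceSet:
    """Extract ML and AltAll sequences from a marginal posterior.

    A site is ambiguous when any non-ML state has posterior strictly above
    ``alt_threshold``; AltAll substitutes the second-best state at all such
    sites simultaneously. ML-state ties are broken in alphabetical
    amino-acid order and reported in ``tied_sites``.
    """
    probs = posterior.probs
    alpha_order = np.argsort(list(AMINO_ACIDS))  # alphabetical preference
    ml = np.empty(posterior.n_sites, dtype=int)
    second = np.empty(posterior.n_sites, dtype=int)
    tied = []
    for s in range(posterior.n_sites):
        row = probs[s]
        # stable sort on (-prob, alphabetical rank of residue)
        rank = np.argsort(alpha_order)  # residue index -> alphabetical rank
        order = sorted(range(20), key=lambda i: (-row[i], rank[i]))
        ml[s] = order[0]
        second[s] = order[1]
        if np.sum(np.isclose(row, row[order[0]], rtol=0, atol=1e-12)) > 1:
            tied.append(s)
    ml_p = probs[np.arange(posterior.n_sites), ml]
    second_p = probs[np.arange(posterior.n_sites), second]
    ambiguous = [int(s) for s in range(posterior.n_sites)
                 if second_p[s] > alt_threshold]
    alt = ml.copy()
    alt[ambiguous] = second[ambiguous]
    alt_p = probs[np.arange(posterior.n_sites), alt]
    seq = "".join(AMINO_ACIDS[i] for i in ml)
    alt_seq = "".join(AMINO_ACIDS[i] for i in alt)
    return AncestralSequenceSet(
        node_label=posterior.node_label,
        ml_sequence=seq,
        altall_sequence=alt_seq,
        ambiguous_sites=ambiguous,
        mean_posterior=float(ml_p.mean()),
        expected_errors=float((1.0 - ml_p).sum()),
        altall_mean_posterior=float(alt_p.mean()),
        tied_sites=tied,
    )


@dataclass
class Substitution:
    site: int               # 0-based alignment column
    ancestral: str
    derived: str
    diagnostic: bool | None = None

    def label(self, offset: int = 0) -> str:
        """Conventional name, ancestral lowercase / derived uppercase."""
        return f"{self.ancestral.lower()}{self.site + 1 + offset}{self.derived.upper()}"


def count_substitutions(anc_a: str, anc_b: str) -> list[Substitution]:
    """Columns at which two (ancestral) sequences differ."""
    if len(anc_a) != len(anc_b):
        raise ValueError(
            f"sequence length mismatch: {len(anc_a)} vs {len(anc_b)}")
    return [Substitution(site=i, ancestral=a, derived=b)
            for i, (a, b) in enumerate(zip(anc_a.upper(), anc_b.upper()))
            if a != b]


def flag_diagnostic(subs: list[Substitution], alignment: AminoAlignment,
                    tree: PhyloTree, clade_label: str) -> list[Substitution]:
    """Mark substitutions whose derived state is conserved across a clade.

    A substitution is phylogenetically diagnostic when every extant sequence
    descending from ``clade_label`` carries the derived state at that column
    (a gap counts as not conserved).
    """
    leaves = tree.clade_leaves(clade_label)
    seqs = [alignment.sequence(name) for name in leaves]
    out = []
    for sub in subs:
        conserved = all(s[sub.site] == sub.derived for s in seqs)
        out.append(Substitution(site=sub.site, ancestral=sub.ancestral,
                                derived=sub.derived, diagnostic=conserved))
    return out
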