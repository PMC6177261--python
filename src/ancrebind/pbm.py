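"""Protein-binding-microarray analysis: rank-based k-mer enrichment scores
(E-scores), 6-mer summaries, specificity correlations, hierarchical profile
clustering, and position-specific binding-energy (PWM energy) models.

E-scores follow the universal-PBM convention: for each k-mer, probes
containing the k-mer (on either strand) form the foreground and all other
probes the background; a Wilcoxon–Mann–Whitney statistic is computed on the
most-enriched halves of the two sets and rescaled to [-0.5, +0.5]. Being
rank-based, E-scores are invariant to any strictly monotone transformation of
the intensities, and a k-mer and its reverse complement share one score.

The energy model is additive over motif positions: a window of length L at
offset j (either strand) has energy E_j = sum_i eps[i, base], in RT units, and
contributes occupancy 1 / (1 + exp(E_j - mu)) where mu is a chemical
potential absorbing protein concentration. Predicted probe intensity is
background + beta * sum of window occupancies.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode_sequences(seqs: list[str]) -> np.ndarray:
    arr = np.zeros((len(seqs), len(seqs[0])), dtype=np.int8)
    for i, s in enumerate(seqs):
        arr[i] = [_BASE_INDEX[c] for c in s]
    return arr


# ---------------------------------------------------------------------------
# probe tables


@dataclass
class ProbeTable:
    """Probe-level PBM data: id, sequence, normalized intensity, replicate."""

    data: pd.DataFrame

    REQUIRED = ("probe_id", "sequence", "intensity", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"probe table missing columns {missing}")
        seqs = self.data["sequence"]
        if seqs.str.len().nunique() > 1:
            raise ValueError("probe sequences have unequal lengths")
        bad = ~seqs.str.fullmatch(f"[{BASES}]+")
        if bad.any():
            raise ValueError(
                f"non-ACGT probe sequences at rows {list(self.data.index[bad][:5])}")
        inten = self.data["intensity"].to_numpy(float)
        if not np.all(np.isfinite(inten)) or np.any(inten <= 0):
            raise ValueError("intensities must be finite and > 0")

    @property
    def probe_length(self) -> int:
        return len(self.data["sequence"].iloc[0])

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    def replicate(self, rep) -> "ProbeTable":
        sub = self.data[self.data["replicate"] == rep]
        if sub.empty:
            raise KeyError(f"no replicate {rep!r}; available: {self.replicates}")
        return ProbeTable(sub.reset_index(drop=True))

    def collapsed(self) -> "ProbeTable":
        """Median intensity per probe across replicates."""
        agg = (self.data.groupby(["probe_id", "sequence"], sort=False,
                                 as_index=False)["intensity"].median())
        agg["replicate"] = "pooled"
        return ProbeTable(agg)

    @classmethod
    def from_tsv(cls, path) -> "ProbeTable":
        from .io import read_tsv
        return cls(read_tsv(path, required=cls.REQUIRED))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class KmerScoreTable:
    """Reverse-complement-collapsed k-mer E-scores (and 8-mer medians)."""

    k: int
    data: pd.DataFrame  # columns: kmer, escore [, median_intensity]

    def __post_init__(self) -> None:
        s = self.data["escore"].to_numpy(float)
        if np.any(s < -0.5 - 1e-12) or np.any(s > 0.5 + 1e-12):
            raise ValueError("E-scores out of [-0.5, 0.5]")

    def score(self, kmer: str) -> float:
        row = self.data.loc[self.data["kmer"] == canonical(kmer), "escore"]
        if row.empty:
            raise KeyError(f"k-mer {kmer!r} not scored")
        return float(row.iloc[0])

    def as_series(self) -> pd.Series:
        return self.data.set_index("kmer")["escore"]

    @classmethod
    def from_tsv(cls, path) -> "KmerScoreTable":
        from .io import read_tsv
        df = read_tsv(path, required=("kmer", "escore"))
        return cls(k=len(df["kmer"].iloc[0]), data=df)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# E-scores


def _kmer_probe_map(seqs: list[str], k: int) -> dict[str, np.ndarray]:
    """Canonical k-mer -> sorted array of probe indices containing it."""
    hits: dict[str, set[int]] = {}
    for i, s in enumerate(seqs):
        for j in range(len(s) - k + 1):
            hits.setdefault(canonical(s[j:j + k]), set()).add(i)
    return {km: np.fromiter(sorted(ix), dtype=int) for km, ix in hits.items()}


def compute_escores(probes: ProbeTable, k: int = 8,
                    truncated: bool = True) -> KmerScoreTable:
    """Rank-based E-score for every k-mer present in the probe library.

    With ``truncated`` (the default), only the most-enriched half of each of
    foreground and background enters the rank comparison, as in the original
    universal-PBM scoring; ``truncated=False`` uses the full sets. Intensity
    ties are resolved by stable probe order. Probes from multiple replicates
    are collapsed to per-probe medians first.
    """
    if len(probes.data) < 2:
        raise ValueError("need at least 2 probes")
    if len(probes.replicates) > 1:
        probes = probes.collapsed()
    seqs = probes.data["sequence"].tolist()
    inten = probes.data["intensity"].to_numpy(float)
    n = len(seqs)
    kmap = _kmer_probe_map(seqs, k)
    # global descending-intensity positions (stable)
    order = np.argsort(-inten, kind="stable")
    pos = np.empty(n, dtype=int)
    pos[order] = np.arange(n)
    records = []
    for kmer, fidx in kmap.items():
        f = len(fidx)
        b = n - f
        if b == 0:
            warnings.warn(f"k-mer {kmer} present in all probes; omitted")
            continue
        fpos = np.sort(pos[fidx])                      # ascending = best first
        nf = (f + 1) // 2 if truncated else f
        nb = (b + 1) // 2 if truncated else b
        top_f = fpos[:nf]
        # for each selected foreground probe: background probes ranked above it
        above = top_f - np.searchsorted(fpos, top_f)   # fg before it excluded
        u = np.clip(nb - above, 0, nb).sum()
        escore = u / (nf * nb) - 0.5
        records.append((kmer, escore, float(np.median(inten[fidx]))))
    df = pd.DataFrame(records, columns=["kmer", "escore", "median_intensity"])
    df = df.sort_values("kmer", ignore_index=True)
    return KmerScoreTable(k=k, data=df)


def sixmer_scores(table8: KmerScoreTable) -> KmerScoreTable:
    """6-mer score = mean E-score over all scored 8-mers containing the 6-mer
    on either strand (containment counted once per 8-mer)."""
    if table8.k != 8:
        raise ValueError("expected an 8-mer table")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for kmer, score in zip(table8.data["kmer"], table8.data["escore"]):
        contained = set()
        for strand in (kmer, revcomp(kmer)):
            for j in range(3):
                contained.add(canonical(strand[j:j + 6]))
        for s6 in contained:
            sums[s6] = sums.get(s6, 0.0) + score
            counts[s6] = counts.get(s6, 0) + 1
    df = pd.DataFrame(
        {"kmer": list(sums), "escore": [sums[s] / counts[s] for s in sums]})
    df = df.sort_values("kmer", ignore_index=True)
    return KmerScoreTable(k=6, data=df)


def correlate_specificities(a: KmerScoreTable, b: KmerScoreTable) -> float:
    """Pearson correlation of two k-mer score tables on their shared universe."""
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} vs {b.k}")
    merged = a.data.merge(b.data, on="kmer", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared k-mers")
    x = merged["escore_a"].to_numpy(float)
    y = merged["escore_b"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in E-scores; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# clustering and logos


@dataclass
class ClusterResult:
    """Hierarchically clustered binding profiles of thresholded 8-mers."""

    kmers: list[str]
    construct_labels: list[str]
    matrix: np.ndarray            # (n_kmers, n_constructs) E-scores
    linkage: np.ndarray
    leaf_order: np.ndarray
    assignments: np.ndarray       # cluster id per kmer (1-based)
    logos: dict[int, pd.DataFrame] = field(default_factory=dict)
    consensus: dict[int, str] = field(default_factory=dict)

    @property
    def ordered_matrix(self) -> np.ndarray:
        return self.matrix[self.leaf_order]


def cluster_profiles(tables: list[KmerScoreTable],
                     labels: list[str] | None = None,
                     threshold: float = 0.45,
                     n_clusters: int = 2) -> ClusterResult:
    """Filter 8-mers by max-across-constructs E-score and cluster profiles.

    Agglomerative clustering with Manhattan (city-block) distance and
    complete linkage; per-cluster logos are position-frequency matrices of
    the member 8-mers aligned to the cluster's top-scoring 8-mer.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 constructs to cluster")
    labels = labels or [f"construct_{i}" for i in range(len(tables))]

    def cols(t, lab):
        d = t.data[["kmer", "escore"]].rename(columns={"escore": lab})
        if "median_intensity" in t.data.columns:
            # per-construct normalized enrichment of the 8-mer's median
            # intensity over the library-wide median; used to down-weight
            # co-occurrence artifacts when building logos
            mi = t.data["median_intensity"]
            d[f"_mi_{lab}"] = mi / mi.median()
        return d
    wide = cols(tables[0], labels[0])
    for t, lab in zip(tables[1:], labels[1:]):
        wide = wide.merge(cols(t, lab), on="kmer")
    keep = wide[labels].max(axis=1) >= threshold
    wide = wide[keep].reset_index(drop=True)
    if wide.empty:
        raise ValueError(f"no 8-mer reaches E-score {threshold} in any construct")
    mat = wide[labels].to_numpy(float)
    kmers = wide["kmer"].tolist()
    if len(kmers) == 1:
        Z = np.zeros((0, 4))
        order = np.array([0])
        assign = np.array([1])
    else:
        Z = linkage(pdist(mat, metric="cityblock"), method="complete")
        order = leaves_list(Z)
        assign = fcluster(Z, t=min(n_clusters, len(kmers)), criterion="maxclust")
    result = ClusterResult(kmers=kmers, construct_labels=labels, matrix=mat,
                           linkage=Z, leaf_order=order, assignments=assign)
    mi_cols = [c for c in wide.columns if c.startswith("_mi_")]
    if mi_cols:
        logo_weight = wide[mi_cols].max(axis=1).to_numpy() - 1.0
        logo_weight = np.clip(logo_weight, 1e-3, None)
    else:
        logo_weight = wide[labels].max(axis=1).to_numpy()
    for cid in np.unique(assign):
        members = [kmers[i] for i in np.flatnonzero(assign == cid)]
        pfm = _aligned_pfm(members, logo_weight[assign == cid])
        result.logos[int(cid)] = pfm
        result.consensus[int(cid)] = "".join(
            BASES[i] for i in pfm.to_numpy().argmax(axis=1))
    return result


def _modal_hexamer(members: list[str], weights: np.ndarray) -> str:
    """Most common (weight-summed) canonical hexamer across member 8-mers."""
    tally: dict[str, float] = {}
    for m, w in zip(members, weights):
        seen = set()
        for strand in (m, revcomp(m)):
            for j in range(len(m) - 5):
                seen.add(canonical(strand[j:j + 6]))
        for h in seen:
            tally[h] = tally.get(h, 0.0) + w
    return max(sorted(tally), key=lambda h: tally[h])


def _aligned_pfm(members: list[str], weights: np.ndarray, max_shift: int = 3
                 ) -> pd.DataFrame:
    """Weighted position-frequency matrix of 8-mers aligned to a seed.

    The seed is the strongest member containing the cluster's modal hexamer,
    oriented so the hexamer reads on the forward strand; members align by
    best shift/strand match and contribute with their profile strength as
    weight, so isolated off-motif 8-mers do not swamp the logo.
    """
    weights = np.asarray(weights, dtype=float)
    core = _modal_hexamer(members, weights)
    seed = None
    best_w = -np.inf
    for m, w in zip(members, weights):
        for cand in (m, revcomp(m)):
            if (core in cand or revcomp(core) in cand) and w > best_w:
                seed, best_w = cand, w
    if seed is None:  # no member carries the modal core on either strand
        seed = members[int(np.argmax(weights))]
    k = len(seed)
    counts = np.zeros((k, 4))
    for m, w in zip(members, weights):
        best, best_score = None, -1
        for cand in (m, revcomp(m)):
            for shift in range(-max_shift, max_shift + 1):
                score = sum(1 for i in range(k)
                            if 0 <= i + shift < k and cand[i + shift] == seed[i])
                if score > best_score:
                    best, best_score = (cand, shift), score
        cand, shift = best
        for i in range(k):
            if 0 <= i + shift < k:
                counts[i, _BASE_INDEX[cand[i + shift]]] += w
    freq = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-12)
    return pd.DataFrame(freq, columns=list(BASES))


# ---------------------------------------------------------------------------
# position-energy model


@dataclass
class EnergyModel:
    """Additive position-energy binding model (PWM energy model), RT units.

    ``eps[i, b]`` is the energy contribution of base b at motif position i,
    mean-centered per position (the gauge freedom is absorbed into ``mu``).
    """

    eps: np.ndarray               # (L, 4)
    mu: float = 0.0
    beta: float = 1.0
    background: float = 0.1
    positional_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        if self.eps.ndim != 2 or self.eps.shape[1] != 4:
            raise ValueError("eps must be (L, 4)")

    @property
    def L(self) -> int:
        return self.eps.shape[0]

    def centered(self) -> "EnergyModel":
        """Equivalent model with per-position mean energies of zero."""
        means = self.eps.mean(axis=1)
        return EnergyModel(eps=self.eps - means[:, None],
                           mu=self.mu - means.sum(),
                           beta=self.beta, background=self.background,
                           positional_weights=self.positional_weights)

    def window_energies(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Energies of all L-windows on both strands; (n, W) arrays."""
        n, plen = codes.shape
        W = plen - self.L + 1
        if W < 1:
            raise ValueError("probes shorter than motif")
        win = np.lib.stride_tricks.sliding_window_view(codes, self.L, axis=1)
        fwd = self._gather(self.eps, win)
        eps_rc = self.eps[::-1, ::-1]  # reverse positions, complement bases
        rev = self._gather(eps_rc, win)
        return fwd, rev

    @staticmethod
    def _gather(eps: np.ndarray, win: np.ndarray) -> np.ndarray:
        # win: (n, W, L) base codes; returns (n, W) summed energies
        L = eps.shape[0]
        return eps[np.arange(L)[None, None, :], win].sum(axis=2)

    def occupancy(self, codes: np.ndarray) -> np.ndarray:
        fwd, rev = self.window_energies(codes)
        occ = 1.0 / (1.0 + np.exp(fwd - self.mu))
        occ += 1.0 / (1.0 + np.exp(rev - self.mu))
        if self.positional_weights is not None:
            occ *= self.positional_weights[None, :]
            return occ.sum(axis=1)
        return occ.sum(axis=1)

    def predict(self, sequences: list[str]) -> np.ndarray:
        """Predicted probe intensities."""
        codes = encode_sequences(list(sequences))
        return self.background + self.beta * self.occupancy(codes)

    def to_json(self, path) -> None:
        obj = {"L": self.L, "eps": self.eps.tolist(), "mu": self.mu,
               "beta": self.beta, "background": self.background}
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EnergyModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(eps=np.array(obj["eps"]), mu=obj["mu"], beta=obj["beta"],
                   background=obj["background"])


def motif_energy_model(motif: str, depth: float = 4.0, mu: float = 0.0,
                       beta: float = 1.0, background: float = 0.1
                       ) -> EnergyModel:
    """Construct an energy model preferring ``motif``: the consensus base at
    each position sits ``depth`` RT below the other three (before centering)."""
    L = len(motif)
    eps = np.zeros((L, 4))
    for i, b in enumerate(motif):
        eps[i, :] = depth
        eps[i, _BASE_INDEX[b]] = 0.0
    m = EnergyModel(eps=eps, mu=mu, beta=beta, background=background)
    return m.centered()


def fit_energy_model(probes: ProbeTable, init: EnergyModel,
                     max_nfev: int = 200) -> EnergyModel:
    """Nonlinear least-squares fit of the energy model to probe intensities.

    Minimizes squared error between observed and predicted intensities over
    (background, log beta, mu, eps). A small quadratic penalty on the
    per-position mean energies pins the gauge during optimization; the
    returned model is exactly mean-centered, with the shift absorbed into mu.
    """
    if len(probes.replicates) > 1:
        probes = probes.collapsed()
    seqs = probes.data["sequence"].tolist()
    y = probes.data["intensity"].to_numpy(float)
    codes = encode_sequences(seqs)
    L = init.L
    if codes.shape[1] < L:
        raise ValueError("probes shorter than motif length")
    scale = np.median(y)

    def unpack(theta):
        bg, logbeta, mu = theta[0], theta[1], theta[2]
        eps = theta[3:].reshape(L, 4)
        return EnergyModel(eps=eps, mu=mu, beta=np.exp(logbeta), background=bg)

    def resid(theta):
        m = unpack(theta)
        r = (m.background + m.beta * m.occupancy(codes) - y) / scale
        gauge = m.eps.mean(axis=1) * 1e-2
        return np.concatenate([r, gauge])

    x0 = np.concatenate([[init.background, np.log(max(init.beta, 1e-12)),
                          init.mu], init.eps.ravel()])
    sol = least_squares(resid, x0, method="trf", max_nfev=max_nfev)
    if not sol.success:
        warnings.warn(f"energy-model fit did not converge: {sol.message}")
    return unpack(sol.x).centered()


def evaluate_r2(model: EnergyModel, heldout: ProbeTable, k: int = 8,
                normalize: bool = True) -> float:
    """R^2 of predicted vs observed k-mer median intensities on held-out data.

    Medians are taken over all probes containing each (rc-collapsed) k-mer;
    R^2 = 1 - SS_res/SS_tot. With ``normalize`` (default) observed and
    predicted intensities are each divided by their median first, so a
    replicate-wide scale difference (arrays routinely differ in overall
    signal) does not masquerade as poor sequence-level prediction.
    """
    if len(heldout.replicates) > 1:
        heldout = heldout.collapsed()
    seqs = heldout.data["sequence"].tolist()
    obs = heldout.data["intensity"].to_numpy(float)
    pred = model.predict(seqs)
    if normalize:
        obs = obs / np.median(obs)
        pred = pred / np.median(pred)
    kmap = _kmer_probe_map(seqs, k)
    o = np.array([np.median(obs[ix]) for ix in kmap.values()])
    p = np.array([np.median(pred[ix]) for ix in kmap.values()])
    ss_res = float(((o - p) ** 2).sum())
    ss_tot = float(((o - o.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def replicate_r2(probes: ProbeTable, rep_train, rep_test, k: int = 8,
                 normalize: bool = True) -> float:
    """Reproducibility ceiling: R^2 of one replicate's k-mer medians
    predicting another's, computed like ``evaluate_r2``."""
    tr = probes.replicate(rep_train)
    te = probes.replicate(rep_test)
    seqs = tr.data["sequence"].tolist()
    a = tr.data["intensity"].to_numpy(float)
    b = te.data["intensity"].to_numpy(float)
    if normalize:
        a = a / np.median(a)
        b = b / np.median(b)
    kmap = _kmer_probe_map(seqs, k)
    ma = np.array([np.median(a[ix]) for ix in kmap.values()])
    mb = np.array([np.median(b[ix]) for ix in kmap.values()])
    ss_res = float(((mb - ma) ** 2).sum())
    ss_tot = float(((mb - mb.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def energy_logo(model: EnergyModel) -> pd.DataFrame:
    """Per-position, per-base letter values for an energy logo.

    Values are the mean-centered energies divided by RT (already RT units, so
    the division is a no-op numerically); letter height is the absolute
    value, with sign giving above/below-axis placement.
    """
    centered = model.centered()
    return pd.DataFrame(centered.eps, columns=list(BASES))


def plot_energy_logo(model: EnergyModel, path) -> None:
    """Render the energy logo as a bar-per-base figure (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logo = energy_logo(model)
    fig, ax = plt.subplots(figsize=(1 + model.L, 3))
    x = np.arange(model.L)
    width = 0.2
    for i, b in enumerate(BASES):
        ax.bar(x + (i - 1.5) * width, logo[b], width=width, label=b)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("motif position")
    ax.set_ylabel("energy (RT, mean-centered)")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def all_kmers(k: int) -> list[str]:
    """All rc-collapsed canonical k-mers."""
    out = set()
    for tup in itertools.product(BASES, repeat=k):
        out.add(canonical("".join(tup)))
    return sorted(out)
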