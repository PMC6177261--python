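"""Synthetic-data generators for every input the pipeline consumes.

All generators draw from a seeded ``numpy.random.Generator`` (PCG64), so a
fixed seed gives bit-identical output on any platform. Forward models reuse
the exact evaluation code of the fitting modules: titrations call
``eval_isotherm``, sensorgrams call ``eval_association``, and PBM intensities
come from ``EnergyModel.predict`` — a single source of truth for each curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .asr import tree_log_likelihood  # noqa: F401  (re-export convenience)
from .binding import (Sensorgram, TitrationSeries, eval_association,
                      eval_dissociation, eval_isotherm)
from .containers import AminoAlignment, PhyloTree
from .model import AMINO_ACIDS, LGGammaModel
from .pbm import BASES, EnergyModel, ProbeTable, motif_energy_model


# ---------------------------------------------------------------------------
# sequence evolution


def simulate_alignment(tree: PhyloTree, model: LGGammaModel, n_sites: int,
                       seed: int) -> tuple[AminoAlignment, dict[str, str]]:
    """Evolve an alignment down the tree under LG + discrete gamma.

    The root state is drawn from the stationary frequencies; each site draws
    one rate category; states evolve along each branch via P(t * r). Returns
    the leaf alignment and the true sequences at every internal node
    (unlabeled internal nodes get generated names ``node<i>``).
    """
    rng = np.random.default_rng(seed)
    flat = tree.flatten()
    rates = model.category_rates
    cat = rng.integers(0, model.n_categories, size=n_sites)
    site_rates = rates[cat]
    states: dict[int, np.ndarray] = {}
    root = flat.root
    states[root] = rng.choice(20, size=n_sites, p=model.freqs)
    for i in reversed(range(flat.n_nodes)):  # postorder reversed = parents first
        if i == root:
            continue
        p = flat.parent[i]
        parent_states = states[p]
        child = np.empty(n_sites, dtype=int)
        for r in np.unique(site_rates):
            mask = site_rates == r
            P = model.transition_matrix(flat.lengths[i] * r)
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[i] = child
    names, rows = [], []
    internals: dict[str, str] = {}
    for i in range(flat.n_nodes):
        seq = "".join(AMINO_ACIDS[s] for s in states[i])
        if flat.is_leaf[i]:
            names.append(flat.labels[i])
            rows.append(seq)
        else:
            internals[flat.labels[i] or f"node{i}"] = seq
    return AminoAlignment(names=names, rows=rows), internals


# ---------------------------------------------------------------------------
# PBM


def random_probes(n_probes: int, probe_len: int, rng: np.random.Generator
                  ) -> list[str]:
    codes = rng.integers(0, 4, size=(n_probes, probe_len))
    return ["".join(BASES[c] for c in row) for row in codes]


def simulate_pbm(energy_model: EnergyModel, n_probes: int = 8000,
                 probe_len: int = 36, noise_sd: float = 0.2,
                 n_replicates: int = 2, replicate_scale: float = 0.6,
                 seed: int = 0) -> ProbeTable:
    """Probe library with intensities from the energy model's forward model.

    intensity = background + beta * occupancy * exp(eps_noise), with
    log-normal multiplicative noise on the specific signal (intensities are
    positive and ratio-scaled). Replicates get independent noise and a
    replicate-specific overall scale emulating unequal array signal strength.
    """
    if probe_len < energy_model.L:
        raise ValueError("probe_len must be >= motif length")
    rng = np.random.default_rng(seed)
    seqs = random_probes(n_probes, probe_len, rng)
    from .pbm import encode_sequences
    occ = energy_model.occupancy(encode_sequences(seqs))
    frames = []
    for rep in range(1, n_replicates + 1):
        noise = np.exp(rng.normal(0.0, noise_sd, size=n_probes)) \
            if noise_sd > 0 else 1.0
        scale = 1.0 if rep == 1 else replicate_scale ** (rep - 1)
        intensity = scale * (energy_model.background
                             + energy_model.beta * occ * noise)
        frames.append(pd.DataFrame({
            "probe_id": [f"probe_{i:05d}" for i in range(n_probes)],
            "sequence": seqs,
            "intensity": intensity,
            "replicate": rep,
        }))
    return ProbeTable(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# titrations and sensorgrams


def simulate_titration(b0: float, bM: float, KA: float, D: float,
                       P_grid: np.ndarray, noise_sd: float = 0.02,
                       n_reps: int = 1, motif: str = "", seed: int = 0
                       ) -> TitrationSeries:
    """F-EMSA series: quadratic isotherm plus Gaussian noise on F."""
    rng = np.random.default_rng(seed)
    P_grid = np.asarray(P_grid, dtype=float)
    P = np.tile(P_grid, n_reps)
    rep = np.repeat(np.arange(1, n_reps + 1), P_grid.size)
    F = eval_isotherm(b0, bM, KA, D, P)
    if noise_sd > 0:
        F = F + rng.normal(0.0, noise_sd, size=P.size)
    return TitrationSeries(D=D, P=P, F=F, motif=motif,
                           replicate=rep if n_reps > 1 else None)


def simulate_sensorgram(kon: float, koff: float, Rmax: float, c0_list,
                        t_assoc: float = 120.0, t_dissoc: float = 240.0,
                        dt: float = 1.0, R_RI: float = 0.0, cD: float = 0.0,
                        noise_sd: float = 0.5, seed: int = 0
                        ) -> list[Sensorgram]:
    """Association + dissociation sensorgrams at each analyte concentration.

    Association follows the 1:1 model; dissociation continues exponentially
    from the association endpoint with the same drift; RU noise is Gaussian.
    """
    rng = np.random.default_rng(seed)
    out = []
    for c0 in c0_list:
        ta = np.arange(0.0, t_assoc + dt / 2, dt)
        Ra = eval_association(ta, kon, koff, Rmax, c0, R_RI, cD)
        R_end = Ra[-1] - R_RI - cD * ta[-1]   # specific signal at end
        td = np.arange(t_assoc + dt, t_assoc + t_dissoc + dt / 2, dt)
        Rd = eval_dissociation(td, R_end, koff, t_assoc, R_RI, cD) \
            + cD * t_assoc  # keep drift continuous in absolute time
        if noise_sd > 0:
            Ra = Ra + rng.normal(0.0, noise_sd, ta.size)
            Rd = Rd + rng.normal(0.0, noise_sd, td.size)
        out.append(Sensorgram(t=ta, R=Ra, c0=c0, phase="association"))
        out.append(Sensorgram(t=td, R=Rd, c0=c0, phase="dissociation"))
    return out


# ---------------------------------------------------------------------------
# shipped demo scenario


ZEN_MOTIF = "TAATTA"   # canonical Zen motif (ZM)
BCD_MOTIF = "TAATCC"   # canonical Bicoid motif (BM)

# Demo equilibrium affinities (M^-1). Protein B gains 25-fold on BM and loses
# 10-fold on ZM relative to protein A, so the BM/ZM preference shifts 250x.
DEMO_AFFINITIES = {
    ("A", "BM"): 1.0e7,
    ("A", "ZM"): 2.5e8,
    ("B", "BM"): 2.5e8,
    ("B", "ZM"): 2.5e7,
}
DEMO_D = 2.5e-9          # labeled-DNA concentration, 2.5 nM
DEMO_NOISE_SD = 0.005    # Gaussian noise on the bound-fraction ratio
DEMO_N_REPS = 3          # triplicates, reported as mean +/- SEM


def demo_titration_grid(KA: float) -> np.ndarray:
    """Titration design for one condition: 12 points log-spaced across the
    full accessible range plus 8 points within a decade of the expected Kd,
    the way a bench titration brackets its transition."""
    Kd = 1.0 / KA
    return np.sort(np.concatenate([np.geomspace(1e-10, 1e-5, 12),
                                   np.geomspace(Kd / 10, Kd * 10, 8)]))


def demo_titrations(seed: int = 0) -> dict[tuple[str, str], TitrationSeries]:
    """Triplicate titrations for two proteins on BM and ZM probes."""
    out = {}
    for i, (key, KA) in enumerate(sorted(DEMO_AFFINITIES.items())):
        out[key] = simulate_titration(
            b0=0.02, bM=0.95, KA=KA, D=DEMO_D,
            P_grid=demo_titration_grid(KA),
            noise_sd=DEMO_NOISE_SD, n_reps=DEMO_N_REPS,
            motif=key[1], seed=seed * 13 + i)
    return out


def demo_energy_models() -> dict[str, EnergyModel]:
    """Two synthetic proteins preferring the Zen vs Bicoid hexamer."""
    # mu places consensus windows ~2 RT above the chemical potential after
    # centering, so the strongest probes partially saturate (as strong
    # binders do on a universal array) and mu is identifiable from the data
    return {
        "A": motif_energy_model(ZEN_MOTIF, depth=4.0, mu=2.0,
                                beta=10.0, background=0.5),
        "B": motif_energy_model(BCD_MOTIF, depth=4.0, mu=2.0,
                                beta=10.0, background=0.5),
    }


def demo_tree(n_zen: int = 5, n_bcd: int = 5, seed: int = 0,
              stem: float = 0.4) -> PhyloTree:
    """Two-clade tree with labeled AncZB / AncBcd nodes, emulating a
    post-duplication Zen clade and a faster-evolving Bcd clade.

    The root is AncZB (the pre-duplication ancestor); its Bcd-side child is
    AncBcd at the end of a long stem branch (rapid post-duplication
    evolution); within-clade branches are short, the Bcd clade slightly
    faster than the Zen clade.
    """
    if n_zen < 2 or n_bcd < 2:
        raise ValueError("each clade needs >= 2 taxa")
    rng = np.random.default_rng(seed)

    def caterpillar(names, scale):
        tips = [f"{n}:{rng.uniform(0.02, scale):.4f}" for n in names]
        s = f"({tips[0]},{tips[1]})"
        for t in tips[2:]:
            s = f"({s}:{rng.uniform(0.02, scale):.4f},{t})"
        return s
    zen = caterpillar([f"Zen_{i}" for i in range(n_zen)], 0.12)
    bcd = caterpillar([f"Bcd_{i}" for i in range(n_bcd)], 0.2)
    nwk = f"({zen}:0.05,{bcd}AncBcd:{stem})AncZB;"
    return PhyloTree.from_newick(nwk)
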