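"""E-score computation against a brute-force rank oracle, 6-mer averaging,
specificity correlation, profile clustering, and the position-energy model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ancrebind import simulate
from ancrebind.pbm import (EnergyModel, KmerScoreTable, ProbeTable, canonical,
                           cluster_profiles, compute_escores,
                           correlate_specificities, energy_logo,
                           evaluate_r2, fit_energy_model, motif_energy_model,
                           replicate_r2, revcomp, sixmer_scores)


def _table(seqs, intens, rep=1):
    return ProbeTable(pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(len(seqs))],
        "sequence": seqs, "intensity": intens, "replicate": rep}))


def brute_escore(seqs, intens, kmer, truncated=True):
    """Independent oracle: explicit truncated WMW pair counting."""
    kc = canonical(kmer)
    fg, bg = [], []
    for s, x in zip(seqs, intens):
        present = any(canonical(s[j:j + len(kmer)]) == kc
                      for j in range(len(s) - len(kmer) + 1))
        (fg if present else bg).append(x)
    fg = sorted(fg, reverse=True)
    bg = sorted(bg, reverse=True)
    nf = (len(fg) + 1) // 2 if truncated else len(fg)
    nb = (len(bg) + 1) // 2 if truncated else len(bg)
    top_f, top_b = fg[:nf], bg[:nb]
    u = sum(1 for x in top_f for y in top_b if x > y)
    return u / (nf * nb) - 0.5


class TestEscores:
    def test_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(42)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(12)]
        intens = rng.lognormal(0, 0.5, 12)
        table = compute_escores(_table(seqs, intens), k=3)
        for kmer, esc in zip(table.data["kmer"], table.data["escore"]):
            assert esc == pytest.approx(
                brute_escore(seqs, intens, kmer), abs=1e-12), kmer

    def test_untruncated_variant_matches_brute_force(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(15)]
        intens = rng.lognormal(0, 0.5, 15)
        table = compute_escores(_table(seqs, intens), k=4, truncated=False)
        for kmer, esc in zip(table.data["kmer"], table.data["escore"]):
            assert esc == pytest.approx(
                brute_escore(seqs, intens, kmer, truncated=False), abs=1e-12)

    def test_maximal_separation_bounds(self):
        # probes containing AAAA all rank above the rest -> E = +0.5
        seqs = ["AAAACG", "CAAAAG", "GGCCTT", "CCGGTT", "GTGTGT", "CACACC"]
        intens = [10.0, 9.0, 1.0, 0.9, 0.8, 0.7]
        t = compute_escores(_table(seqs, intens), k=4)
        assert t.score("AAAA") == pytest.approx(0.5)
        # reversed intensities -> E = -0.5
        t2 = compute_escores(_table(seqs, intens[::-1]), k=4)
        assert t2.score("AAAA") == pytest.approx(-0.5)

    def test_bounds_and_rc_collapse(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(40)]
        t = compute_escores(_table(seqs, rng.lognormal(0, 1, 40)), k=4)
        assert t.data["escore"].between(-0.5, 0.5).all()
        # a k-mer and its reverse complement share one canonical record
        assert (t.data["kmer"] == t.data["kmer"].map(canonical)).all()
        assert t.score("TTTT") == t.score("AAAA")

    def test_monotone_intensity_invariance(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(30)]
        intens = rng.lognormal(0, 0.5, 30)
        base = compute_escores(_table(seqs, intens), k=3)
        for f in (np.exp, lambda x: x ** 3, lambda x: 5 * x + 1):
            other = compute_escores(_table(seqs, f(intens)), k=3)
            # scores are rank-based, hence identical; medians rescale
            pd.testing.assert_frame_equal(base.data[["kmer", "escore"]],
                                          other.data[["kmer", "escore"]])

    def test_sequence_independent_intensities_center_near_zero(self):
        rng = np.random.default_rng(12)
        seqs = ["".join(rng.choice(list("ACGT"), 16)) for _ in range(300)]
        means = []
        for _ in range(20):
            intens = rng.lognormal(0, 0.4, 300)
            t = compute_escores(_table(seqs, intens), k=4)
            means.append(t.data["escore"].mean())
        assert abs(np.mean(means)) < 0.02

    def test_needs_two_probes(self):
        with pytest.raises(ValueError):
            compute_escores(_table(["ACGT"], [1.0]), k=2)


class TestSixmerScores:
    def test_single_containing_eightmer(self):
        df = pd.DataFrame({"kmer": ["AAAATTTC"], "escore": [0.3]})
        t6 = sixmer_scores(KmerScoreTable(k=8, data=df))
        assert t6.score("AAAATT") == pytest.approx(0.3)

    def test_constant_table_gives_constant_sixmers(self):
        kmers = ["AAAATTTC", "ACGTACGT", "CCCCGGGA"]
        t8 = KmerScoreTable(k=8, data=pd.DataFrame(
            {"kmer": [canonical(k) for k in kmers], "escore": 0.21}))
        t6 = sixmer_scores(t8)
        assert np.allclose(t6.data["escore"], 0.21)

    def test_means_match_exhaustive_containment(self):
        kmers = ["AAAATTTC", "AAAATTGG", "CAAAATTG", "ACGTACGT", "TTGCGCAA"]
        rng = np.random.default_rng(0)
        scores = rng.uniform(-0.4, 0.5, len(kmers))
        t8 = KmerScoreTable(k=8, data=pd.DataFrame(
            {"kmer": [canonical(k) for k in kmers], "escore": scores}))
        t6 = sixmer_scores(t8)
        # brute force: for every 6-mer, list 8-mers containing it either strand
        for s6, esc in zip(t6.data["kmer"], t6.data["escore"]):
            hits = []
            for km, sc in zip(t8.data["kmer"], t8.data["escore"]):
                found = any(canonical(strand[j:j + 6]) == s6
                            for strand in (km, revcomp(km)) for j in range(3))
                if found:
                    hits.append(sc)
            assert esc == pytest.approx(np.mean(hits), abs=1e-12)

    def test_averaging_commutes_with_affine_rescale(self):
        kmers = [canonical(k) for k in
                 ["AAAATTTC", "AAAATTGG", "ACGTACGT"]]
        s = np.array([0.1, 0.3, -0.2])
        t6a = sixmer_scores(KmerScoreTable(
            k=8, data=pd.DataFrame({"kmer": kmers, "escore": s})))
        t6b = sixmer_scores(KmerScoreTable(
            k=8, data=pd.DataFrame({"kmer": kmers, "escore": 0.5 * s + 0.1})))
        assert np.allclose(0.5 * t6a.data["escore"] + 0.1, t6b.data["escore"])


class TestCorrelation:
    def _t(self, scores):
        return KmerScoreTable(k=6, data=pd.DataFrame(
            {"kmer": ["AAAAAA", "AAAAAC", "AAAAAG", "AAAACC"],
             "escore": scores}))

    def test_self_correlation_is_one(self):
        a = self._t([0.1, 0.4, -0.3, 0.0])
        assert correlate_specificities(a, a) == pytest.approx(1.0)

    def test_negated_correlation_is_minus_one(self):
        a = self._t([0.1, 0.4, -0.3, 0.0])
        b = self._t([-0.1, -0.4, 0.3, 0.0])
        assert correlate_specificities(a, b) == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        a = self._t([0.1, 0.1, 0.1, 0.1])
        b = self._t([0.1, 0.4, -0.3, 0.0])
        with pytest.raises(ValueError, match="variance"):
            correlate_specificities(a, b)

    def test_shared_model_correlates_higher_than_shuffled(self):
        em = simulate.demo_energy_models()["B"]
        shuffled = EnergyModel(eps=em.eps[::-1].copy(), mu=em.mu,
                               beta=em.beta, background=em.background)
        tables = []
        for i, m in enumerate([em, em, shuffled]):
            probes = simulate.simulate_pbm(m, n_probes=1500, noise_sd=0.2,
                                           n_replicates=1, seed=20 + i)
            tables.append(sixmer_scores(compute_escores(probes, k=8)))
        r_same = correlate_specificities(tables[0], tables[1])
        r_diff = correlate_specificities(tables[0], tables[2])
        assert r_same > r_diff


class TestClustering:
    def test_identical_constructs_trivial_tree(self):
        # identical profiles across constructs: all pairwise 8-mer
        # distances collapse to the within-construct differences, and
        # identical-score 8-mers sit at distance zero
        t = KmerScoreTable(k=8, data=pd.DataFrame(
            {"kmer": [canonical(k) for k in ["AAAATTTC", "ACGTACGT"]],
             "escore": [0.5, 0.5]}))
        res = cluster_profiles([t, t], threshold=0.45, n_clusters=1)
        assert res.linkage[:, 2] == pytest.approx(0.0)
        assert np.array_equal(res.matrix[:, 0], res.matrix[:, 1])
        assert sorted(res.leaf_order) == [0, 1]

    def test_threshold_above_bound_raises(self):
        t = KmerScoreTable(k=8, data=pd.DataFrame(
            {"kmer": ["AAAATTTC"], "escore": [0.5]}))
        with pytest.raises(ValueError, match="0.51"):
            cluster_profiles([t, t], threshold=0.51)

    def test_planted_motifs_separate_into_two_clusters(self):
        ems = simulate.demo_energy_models()
        tables = []
        for i, name in enumerate(sorted(ems)):
            probes = simulate.simulate_pbm(ems[name], n_probes=3000,
                                           noise_sd=0.2, n_replicates=1,
                                           seed=30 + i)
            tables.append(compute_escores(probes, k=8))
        res = cluster_profiles(tables, labels=["A", "B"], threshold=0.45)
        cons = [res.consensus[c] for c in sorted(res.consensus)]

        def contains(c, h):
            return h in c or revcomp(h) in c
        assert any(contains(c, simulate.ZEN_MOTIF) for c in cons)
        assert any(contains(c, simulate.BCD_MOTIF) for c in cons)


class TestEnergyModel:
    def test_gauge_shift_leaves_predictions_unchanged(self):
        em = motif_energy_model("TAAT", depth=3.0, mu=1.0, beta=4.0,
                                background=0.2)
        shifted = EnergyModel(eps=em.eps + np.array([[1.0], [0], [0], [0]]),
                              mu=em.mu + 1.0, beta=em.beta,
                              background=em.background)
        seqs = ["ACGTTAATCG", "GGGGGGGGGG", "TTAATTAATT"]
        assert np.allclose(em.predict(seqs), shifted.predict(seqs))

    def test_flat_model_predicts_identically(self):
        em = EnergyModel(eps=np.zeros((4, 4)), mu=0.0, beta=2.0,
                         background=0.3)
        preds = em.predict(["ACGTACGT", "GGGGCCCC", "TTTTTTTT"])
        assert np.allclose(preds, preds[0])

    def test_centered_model_equivalent(self):
        em = EnergyModel(eps=np.arange(8.0).reshape(2, 4), mu=0.5, beta=3.0,
                         background=0.1)
        c = em.centered()
        assert np.allclose(c.eps.mean(axis=1), 0.0)
        seqs = ["ACGTAC", "TTGGCA"]
        assert np.allclose(em.predict(seqs), c.predict(seqs))

    def test_noiseless_recovery(self):
        """Fitting noiseless synthetic intensities recovers the planted
        energies to well under 0.01 RT after gauge fixing."""
        em = simulate.demo_energy_models()["B"]
        probes = simulate.simulate_pbm(em, n_probes=1500, noise_sd=0.0,
                                       n_replicates=1, seed=44)
        init = motif_energy_model("TAATCC", depth=2.0, mu=2.0, beta=5.0,
                                  background=1.0)
        fit = fit_energy_model(probes, init)
        assert np.abs(fit.eps - em.eps).max() < 1e-2
        assert evaluate_r2(fit, probes) == pytest.approx(1.0, abs=1e-9)

    def test_flat_data_yields_flat_model(self):
        flat = EnergyModel(eps=np.zeros((4, 4)), mu=-1.0, beta=1.0,
                           background=0.5)
        probes = simulate.simulate_pbm(flat, n_probes=300, noise_sd=0.0,
                                       n_replicates=1, seed=2)
        fit = fit_energy_model(probes, flat)
        seqs = probes.data["sequence"].tolist()
        assert np.allclose(fit.predict(seqs), probes.data["intensity"],
                           rtol=1e-6)
        assert np.abs(fit.eps).max() < 0.05

    def test_constant_prediction_r2_nonpositive(self):
        em = simulate.demo_energy_models()["B"]
        probes = simulate.simulate_pbm(em, n_probes=500, noise_sd=0.1,
                                       n_replicates=1, seed=6)
        const = EnergyModel(eps=np.zeros((6, 4)), mu=0.0, beta=0.0,
                            background=1.0)
        assert evaluate_r2(const, probes, normalize=False) <= 0.0


class TestEnergyLogo:
    def test_equal_energies_zero_heights(self):
        em = EnergyModel(eps=np.full((3, 4), 2.0), mu=0.0)
        logo = energy_logo(em)
        assert np.allclose(logo.to_numpy(), 0.0)

    def test_mean_centering_arithmetic(self):
        # one base 1 RT below the other three: heights 0.75 vs 0.25
        eps = np.array([[0.0, 0.0, 0.0, -1.0]])
        logo = energy_logo(EnergyModel(eps=eps, mu=0.0))
        assert logo.iloc[0]["T"] == pytest.approx(-0.75)
        assert logo.iloc[0]["A"] == pytest.approx(0.25)

    def test_planted_motif_logo_shows_cc(self):
        em = simulate.demo_energy_models()["B"]  # TAATCC
        logo = energy_logo(em)
        # C is the favorable (most negative) base at positions 5 and 6
        assert logo.iloc[4].idxmin() == "C"
        assert logo.iloc[5].idxmin() == "C"


def test_replicate_scale_preserves_escores():
    """A replicate-wide intensity scale factor leaves E-scores (ranks)
    essentially unchanged."""
    em = simulate.demo_energy_models()["A"]
    probes = simulate.simulate_pbm(em, n_probes=1200, noise_sd=0.0,
                                   n_replicates=2, replicate_scale=2.0,
                                   seed=77)
    t1 = compute_escores(probes.replicate(1), k=8)
    t2 = compute_escores(probes.replicate(2), k=8)
    pd.testing.assert_frame_equal(t1.data[["kmer", "escore"]],
                                  t2.data[["kmer", "escore"]])
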