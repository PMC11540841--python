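"""Weir-Cockerham theta, AMOVA and the FST dendrogram."""

import numpy as np
import pandas as pd
import pytest

import lanternpop as lp
from lanternpop.differentiation import (
    genotype_distance_matrix, FstMatrix, _amova_components,
)
from conftest import make_gm, make_meta


def wc_theta_textbook(dos_by_pop):
    """Independent per-locus a/b/c computation, written long-hand from the
    standard two-allele estimator (loop style, no vectorisation)."""
    r = len(dos_by_pop)
    L = dos_by_pop[0].shape[1]
    num = den = 0.0
    for l in range(L):
        cols = [d[:, l][~np.isnan(d[:, l])] for d in dos_by_pop]
        if any(len(c) == 0 for c in cols):
            continue
        n_i = np.array([len(c) for c in cols], float)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        for allele in (0, 1):  # both alleles, summed
            if allele == 0:
                p_i = np.array([(2 * (c == 0).sum() + (c == 1).sum())
                                / (2 * len(c)) for c in cols])
            else:
                p_i = np.array([(2 * (c == 2).sum() + (c == 1).sum())
                                / (2 * len(c)) for c in cols])
            h_i = np.array([(c == 1).mean() for c in cols])
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                       - s2 * (r - 1) / r
                                       - hbar * (2 * nbar - 1) / (4 * nbar))
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


class TestWeirCockerham:
    def test_fixed_opposite_samples_give_one(self, two_pop_fixed):
        gm, meta = two_pop_fixed
        theta = lp.weir_cockerham_fst(gm, meta, by="site", pairwise=False)
        assert theta == pytest.approx(1.0)

    def test_matches_textbook_computation(self):
        rng = np.random.default_rng(8)
        d1 = rng.integers(0, 3, (6, 4)).astype(float)
        d2 = rng.integers(0, 3, (5, 4)).astype(float)
        d2[0, 1] = np.nan
        gm = make_gm(np.vstack([np.nan_to_num(d1, nan=-1),
                                np.nan_to_num(d2, nan=-1)]).astype(int))
        labels = np.array(["a"] * 6 + ["b"] * 5)
        got = lp.weir_cockerham_theta(gm.calls, labels)
        want = wc_theta_textbook([d1, d2])
        assert got == pytest.approx(want, abs=1e-12)

    def test_null_split_is_near_zero(self):
        rng = np.random.default_rng(1)
        gm = make_gm(rng.binomial(2, 0.4, (60, 30)))
        meta = make_meta(gm, ["s1"] * 30 + ["s2"] * 30, ["g"] * 60)
        res = lp.weir_cockerham_fst(gm, meta, by="site", n_perm=199, seed=0)
        assert abs(res.fst[0, 1]) < 0.02
        assert res.p_values[0, 1] > 0.05

    def test_invariant_to_allele_relabeling_and_sample_order(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, (20, 5))
        labels = np.array(["a"] * 10 + ["b"] * 10)
        gm = make_gm(dos)
        t1 = lp.weir_cockerham_theta(gm.calls, labels)
        gm_flipped = make_gm(2 - dos)
        t2 = lp.weir_cockerham_theta(gm_flipped.calls, labels)
        perm = rng.permutation(20)
        t3 = lp.weir_cockerham_theta(gm.calls[perm], labels[perm])
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert t1 == pytest.approx(t3, abs=1e-12)

    def test_permutation_flags_true_structure(self, two_pop_fixed):
        gm, meta = two_pop_fixed
        res = lp.weir_cockerham_fst(gm, meta, by="site", n_perm=499, seed=3)
        assert res.p_values[0, 1] < 0.05


def brute_force_flat_amova(D2, labels):
    """Sums of squares straight from the definition (loop style)."""
    N = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(D2[i, j] for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    for g in groups:
        rows = [i for i in range(N) if labels[i] == g]
        ss_within += sum(D2[i, j] for i in rows for j in rows if i < j
                         ) / len(rows)
    ss_among = ss_total - ss_within
    k = len(groups)
    ms_among = ss_among / (k - 1)
    ms_within = ss_within / (N - k)
    sizes = [labels.count(g) for g in groups]
    n0 = (N - sum(s * s for s in sizes) / N) / (k - 1)
    sig_w = ms_within
    sig_a = (ms_among - ms_within) / n0
    return sig_a, sig_w


class TestAmova:
    def test_identical_individuals_have_zero_components(self):
        gm = make_gm(np.ones((6, 4), dtype=int))
        meta = make_meta(gm, ["s1"] * 3 + ["s2"] * 3, ["g"] * 6)
        res = lp.amova(gm, meta, by="site", n_perm=0)
        assert res.components["among_samples"] == pytest.approx(0.0)
        assert res.components["within_samples"] == pytest.approx(0.0)

    def test_maximally_distinct_samples(self, two_pop_fixed):
        gm, meta = two_pop_fixed
        res = lp.amova(gm, meta, by="site", n_perm=0)
        assert res.percentages["among_samples"] == pytest.approx(100.0)

    def test_six_individual_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, (6, 5))
        gm = make_gm(dos)
        labels = ["s1", "s1", "s2", "s2", "s3", "s3"]
        meta = make_meta(gm, labels, ["g"] * 6)
        res = lp.amova(gm, meta, by="site", n_perm=0)
        D2 = genotype_distance_matrix(gm)
        sig_a, sig_w = brute_force_flat_amova(D2, labels)
        assert res.components["among_samples"] == pytest.approx(sig_a, abs=1e-12)
        assert res.components["within_samples"] == pytest.approx(sig_w, abs=1e-12)

    def test_flat_percentage_equals_fst(self):
        rng = np.random.default_rng(7)
        gm = make_gm(rng.integers(0, 3, (24, 8)))
        meta = make_meta(gm, ["s1"] * 8 + ["s2"] * 8 + ["s3"] * 8,
                         ["g"] * 24)
        res = lp.amova(gm, meta, by="site", n_perm=0)
        assert res.percentages["among_samples"] == pytest.approx(
            100 * res.f_statistics["FST"], abs=1e-9)

    def test_hierarchical_components_track_generator(self):
        """FCT/FSC follow the configured two-level divergences.

        The genotype-distance AMOVA ratio runs somewhat above the
        allele-level divergence parameter (genotypic distances undercount
        within-sample variation relative to random allele pairing), so the
        check is a band around the configured values rather than equality.
        """
        fct_vals, fsc_vals = [], []
        for seed in range(15):
            cfg = lp.SimulationConfig(
                seed=seed,
                groups=[
                    lp.GroupConfig("G1", [("a", 25), ("b", 25)], (1, 0, 0),
                                   fst_to_ancestral=0.10),
                    lp.GroupConfig("G2", [("c", 25), ("d", 25)], (1, 0, 0),
                                   fst_to_ancestral=0.10),
                ],
                n_background_loci=60, fst_within_group=0.02,
            )
            gm, meta, _ = lp.simulate_dataset(cfg)
            res = lp.amova(gm, meta, by="site", groups="group", n_perm=0)
            fct_vals.append(res.f_statistics["FCT"])
            fsc_vals.append(res.f_statistics["FSC"])
        assert 0.07 < np.mean(fct_vals) < 0.17
        assert 0.005 < np.mean(fsc_vals) < 0.06
        # the hierarchy is ordered correctly: groups >> sites within groups
        assert np.mean(fct_vals) > 2 * np.mean(fsc_vals)

    def test_single_sample_group_degenerates_gracefully(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.integers(0, 3, (9, 5)))
        meta = make_meta(gm, ["s1"] * 3 + ["s2"] * 3 + ["s3"] * 3,
                         ["g1"] * 3 + ["g1"] * 3 + ["g2"] * 3)
        res = lp.amova(gm, meta, by="site", groups="group", n_perm=49, seed=0)
        assert np.isnan(res.p_values["FCT"])  # one-sample group flagged


class TestDendrogram:
    def _fst(self, mat, names):
        m = np.asarray(mat, float)
        return FstMatrix(names, m, np.full_like(m, np.nan), 0)

    def test_identical_pair_joined_first(self):
        fst = self._fst([[0, 0.0, 0.3], [0.0, 0, 0.3], [0.3, 0.3, 0]],
                        ["a", "b", "c"])
        newick, order = lp.fst_dendrogram(fst)
        assert "(a:0,b:0)" in newick.replace(" ", "")
        assert set(order) == {"a", "b", "c"}

    def test_ultrametric_distances_reconstructed(self):
        # exact UPGMA fixed point: heights 0.1 and 0.4
        d = np.array([
            [0.0, 0.2, 0.8, 0.8],
            [0.2, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.0, 0.2],
            [0.8, 0.8, 0.2, 0.0],
        ])
        fst = self._fst(d, list("abcd"))
        newick, _ = lp.fst_dendrogram(fst)
        assert newick.count("(") == 3
        assert ":0.3" in newick  # leaf branch under the root join at h=0.4

    def test_preset_recovers_three_habitat_clades(self, small_preset):
        gm, meta, _ = small_preset
        fst = lp.weir_cockerham_fst(gm, meta, by="site", n_perm=0)
        newick, order = lp.fst_dendrogram(fst)
        grp = meta.group_of_site()
        labels = [grp[s] for s in order]
        # leaf order groups habitats contiguously
        changes = sum(a != b for a, b in zip(labels, labels[1:]))
        assert changes == 2

    def test_missing_entries_error(self):
        m = np.array([[0, np.nan], [np.nan, 0]])
        fst = self._fst(m, ["a", "b"])
        with pytest.raises(ValueError):
            lp.fst_dendrogram(fst)
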