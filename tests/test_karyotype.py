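"""Karyotype classification, frequency signature, haplogroup maps, migrants."""

import numpy as np
import pandas as pd
import pytest

import lanternpop as lp
from lanternpop.karyotype import (ClassificationRejected,
                                  assignment_memberships)
from lanternpop.simulate import migrant_study_preset
from conftest import make_gm, make_meta


@pytest.fixture(scope="module")
def classified():
    gm, meta, truth = lp.simulate_dataset(
        lp.paper_like_preset(seed=7, scale=0.5))
    pca = lp.pca_genotypes(gm, n_axes=3)
    drivers = sorted(truth.driver_loci())
    calls = lp.classify_karyotypes(pca, gm, drivers, metadata=meta)
    return gm, meta, truth, pca, calls


class TestClassification:
    def test_matches_truth_with_perfect_data(self, classified):
        gm, meta, truth, pca, calls = classified
        truth_s = pd.Series(truth.karyotype)
        assigned = calls.labels[calls.labels != "unassigned"]
        acc = (assigned == truth_s.loc[assigned.index]).mean()
        assert acc > 0.995
        assert (calls.labels == "unassigned").mean() < 0.02

    def test_mediterranean_all_bb(self, classified):
        gm, meta, truth, pca, calls = classified
        grp = meta.group_of().loc[calls.labels.index]
        med = calls.labels[(grp == "Mediterranean").to_numpy()]
        assert (med[med != "unassigned"] == "BB").all()

    def test_middle_cluster_is_heterokaryotype(self, classified):
        gm, _, truth, _, calls = classified
        diag = [l for l, c in truth.locus_class.items()
                if c == "inversion-diagnostic"]
        het = (gm.subset(loci=diag).dosage() == 1).mean(axis=1)
        het_s = pd.Series(het, index=gm.individuals)
        ab = het_s[(calls.labels == "AB").to_numpy()].mean()
        aa = het_s[(calls.labels == "AA").to_numpy()].mean()
        assert ab > 0.99 and aa < 0.01

    def test_rejects_structureless_data(self):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.binomial(2, 0.4, (60, 30)))
        pca = lp.pca_genotypes(gm, n_axes=2)
        with pytest.raises(ClassificationRejected):
            lp.classify_karyotypes(pca, gm, gm.loci[:5], mode="pc1")

    def test_invariant_to_pc1_sign_flip(self, classified):
        gm, meta, truth, pca, calls = classified
        import copy
        pca2 = copy.deepcopy(pca)
        pca2.scores["PC1"] *= -1
        calls2 = lp.classify_karyotypes(pca2, gm, calls.driver_loci,
                                        metadata=meta)
        assert (calls.labels == calls2.labels).all()

    def test_driver_score_fallback_mode(self, classified):
        gm, meta, truth, _, calls_pc1 = classified
        calls2 = lp.classify_karyotypes(None, gm, calls_pc1.driver_loci,
                                        metadata=meta, mode="driver-score")
        agree = (calls_pc1.labels == calls2.labels).mean()
        assert agree > 0.98


class TestFrequencyTable:
    def test_diagnostic_signature_exact(self, classified):
        gm, meta, truth, pca, calls = classified
        diag = [l for l, c in truth.locus_class.items()
                if c == "inversion-diagnostic"]
        kft = lp.karyotype_frequency_table(gm, calls, loci=diag,
                                           metadata=meta)
        tot = kft.table["Total"]
        assert np.allclose(tot["AA"], 1.0, atol=1e-9)
        assert np.allclose(tot["AB"], 0.5, atol=1e-9)
        assert np.allclose(tot["BB"], 0.0, atol=1e-9)
        assert kft.diagnostic.all()

    def test_background_locus_not_diagnostic(self, classified):
        gm, meta, truth, pca, calls = classified
        kft = lp.karyotype_frequency_table(
            gm, calls, loci=[l for l in gm.loci if l.startswith("bg")][:10],
            metadata=meta)
        assert not kft.diagnostic.any()

    def test_partial_locus_tracks_arrangement_frequencies(self, classified):
        gm, meta, truth, pca, calls = classified
        partial = [l for l, c in truth.locus_class.items()
                   if c == "inversion-partial"]
        kft = lp.karyotype_frequency_table(gm, calls, loci=partial,
                                           metadata=meta)
        inv_loci = [l for l in gm.loci if l.startswith("inv")]
        qA = dict(zip(inv_loci, truth.arrangement_freqs["A"]))
        tot = kft.table["Total"]
        n = gm.n_individuals
        for loc in partial:
            se = 3 * np.sqrt(qA[loc] * (1 - qA[loc]) / n) + 0.03
            assert tot.loc[loc, "AA"] == pytest.approx(qA[loc], abs=se)
            assert tot.loc[loc, "AB"] == pytest.approx(qA[loc] / 2, abs=se)
            assert tot.loc[loc, "BB"] == pytest.approx(0.0, abs=0.05)

    def test_empty_class_reported_missing(self, classified):
        gm, meta, truth, pca, calls = classified
        kft = lp.karyotype_frequency_table(
            gm, calls, loci=calls.driver_loci, metadata=meta,
            groups=["Mediterranean"])
        assert kft.table[("Mediterranean", "AA")].isna().all()


class TestHaplogroupFrequencies:
    def test_proportions_sum_to_one(self, classified):
        gm, meta, truth, pca, calls = classified
        t = lp.haplogroup_frequencies_by_sample(calls, meta)
        assert np.allclose(t.sum(axis=1), 1.0)

    def test_fjords_near_configured_proportions(self, classified):
        gm, meta, truth, pca, calls = classified
        t = lp.haplogroup_frequencies_by_sample(calls, meta, by="group")
        fj = t.loc["Fjords"]
        n_fj = (meta.group_of() == "Fjords").sum()
        for kt, expect in zip(("AA", "AB", "BB"), (0.185, 0.537, 0.278)):
            se = np.sqrt(expect * (1 - expect) / n_fj)
            assert fj[kt] == pytest.approx(expect, abs=3 * se + 0.01)

    def test_single_individual_site_one_hot(self):
        gm, meta, truth = lp.simulate_dataset(lp.SimulationConfig(
            seed=0,
            groups=[lp.GroupConfig("G", [("solo", 1), ("many", 30)],
                                   (0.25, 0.5, 0.25))],
            n_background_loci=5, n_inversion_loci=6, n_diagnostic_loci=6,
        ))
        calls = lp.classify_karyotypes(None, gm, truth.driver_loci(),
                                       metadata=meta, mode="driver-score")
        t = lp.haplogroup_frequencies_by_sample(calls, meta)
        assert sorted(t.loc["solo"]) == [0.0, 0.0, 1.0]


class TestMigrants:
    def test_planted_migrants_exactly_flagged(self):
        hits = 0
        for seed in range(10):
            gm, meta, truth = lp.simulate_dataset(migrant_study_preset(seed))
            mem = assignment_memberships(gm, meta, by="group")
            mig = lp.detect_migrants(mem, meta, q_threshold=0.7)
            hits += set(mig["individual"]) == set(truth.migrants)
        assert hits >= 9

    def test_no_migrants_no_flags(self):
        cfg = migrant_study_preset(3)
        cfg.migrants = []
        gm, meta, truth = lp.simulate_dataset(cfg)
        mem = assignment_memberships(gm, meta, by="group")
        mig = lp.detect_migrants(mem, meta, q_threshold=0.7)
        assert len(mig) <= 1  # at most a borderline resident

    def test_threshold_validation(self):
        mem = pd.DataFrame({"a": [0.9], "b": [0.1]}, index=["x"])
        meta = lp.SampleMetadata(pd.DataFrame(
            {"site": ["s"], "group": ["a"]}, index=["x"]))
        with pytest.raises(ValueError):
            lp.detect_migrants(mem, meta, q_threshold=1.5)
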