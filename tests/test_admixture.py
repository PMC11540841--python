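"""Admixture Gibbs sampler, K selection and run alignment."""

import numpy as np
import pandas as pd
import pytest

import lanternpop as lp
from lanternpop.admixture import AdmixtureRun, g_similarity
from conftest import make_gm, make_meta


def _fixed_two_pop(n=20, L=30):
    calls = np.zeros((n, L, 2), dtype=np.int8)
    calls[n // 2:] = 1
    from lanternpop.genotypes import GenotypeMatrix
    return GenotypeMatrix([f"i{k}" for k in range(n)],
                          [f"l{j}" for j in range(L)], calls,
                          [("A", "B")] * L)


class TestSampler:
    def test_k1_closed_form(self):
        gm = _fixed_two_pop()
        run = lp.run_admixture(gm, K=1, burn_in=200, n_iter=800, seed=0)
        assert np.allclose(run.Q.to_numpy(), 1.0)
        # pooled allele frequency is 0.5 everywhere; per-copy log-likelihood
        analytic = gm.n_individuals * gm.n_loci * 2 * np.log(0.5)
        assert run.log_prob == pytest.approx(analytic, rel=0.03)

    def test_k2_separates_fixed_populations(self):
        gm = _fixed_two_pop()
        run = lp.run_admixture(gm, K=2, burn_in=200, n_iter=800, seed=1)
        cl = run.Q.to_numpy().argmax(axis=1)
        assert len(set(cl[:10])) == 1 and len(set(cl[10:])) == 1
        assert cl[0] != cl[-1]
        assert run.Q.to_numpy().max(axis=1).min() > 0.9

    def test_q_rows_on_simplex(self):
        gm = _fixed_two_pop(12, 10)
        run = lp.run_admixture(gm, K=3, burn_in=100, n_iter=400, seed=2)
        assert np.allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
        assert (run.P >= 0).all() and (run.P <= 1).all()

    def test_k_bounds_validated(self):
        gm = _fixed_two_pop(6, 5)
        with pytest.raises(ValueError):
            lp.run_admixture(gm, K=0)
        with pytest.raises(ValueError):
            lp.run_admixture(gm, K=7)

    def test_missing_calls_tolerated(self):
        gm = _fixed_two_pop(16, 20)
        calls = gm.calls.copy()
        calls[0, :5] = -1
        gm2 = type(gm)(gm.individuals, gm.loci, calls, gm.locus_alleles)
        run = lp.run_admixture(gm2, K=2, burn_in=100, n_iter=400, seed=0)
        assert np.isfinite(run.log_prob)


def _stub_runs(ls_by_k, n_runs=2):
    runs = []
    for K, ls in ls_by_k.items():
        for v in ls:
            r = AdmixtureRun(
                K=K, Q=pd.DataFrame(np.ones((2, K)) / K, index=["a", "b"]),
                P=np.zeros((K, 1)), log_prob=v,
                log_likelihood_trace=np.array([v]),
                alpha_trace=np.array([1.0]), burn_in=0, n_iter=1, seed=0)
            runs.append(r)
    return runs


class TestEvanno:
    def test_stated_arithmetic(self):
        runs = _stub_runs({1: [-100.5, -99.5], 2: [-50.5, -49.5],
                           3: [-45.5, -44.5], 4: [-44.5, -43.5]})
        ev = lp.evanno_delta_k(runs)
        sd = np.std([-50.5, -49.5], ddof=1)
        assert ev.table.loc[2, "delta_K"] == pytest.approx(
            abs(-45 - 2 * (-50) + (-100)) / sd)
        assert ev.best_k == 2

    def test_equal_means_give_zero(self):
        runs = _stub_runs({1: [-10, -11], 2: [-10, -11], 3: [-10, -11]})
        ev = lp.evanno_delta_k(runs)
        assert ev.table.loc[2, "delta_K"] == pytest.approx(0.0)

    def test_zero_sd_flagged(self):
        runs = _stub_runs({1: [-100, -100], 2: [-50, -50], 3: [-45, -45]})
        ev = lp.evanno_delta_k(runs)
        assert np.isnan(ev.table.loc[2, "delta_K"])

    def test_requires_consecutive_ks(self):
        runs = _stub_runs({1: [-1, -2], 3: [-1, -2], 5: [-1, -2]})
        with pytest.raises(ValueError):
            lp.evanno_delta_k(runs)

    def test_two_population_simulation_selects_k2(self):
        hits = 0
        for seed in range(5):
            cfg = lp.SimulationConfig(
                seed=seed,
                groups=[lp.GroupConfig("P1", [("a", 25)], (1, 0, 0),
                                       fst_to_ancestral=0.12),
                        lp.GroupConfig("P2", [("b", 25)], (1, 0, 0),
                                       fst_to_ancestral=0.12)],
                n_background_loci=60, ancestral_freq_range=(0.1, 0.9))
            gm, meta, _ = lp.simulate_dataset(cfg)
            runs = lp.run_replicates(gm, range(1, 4), n_runs=2, seed=seed,
                                     burn_in=200, n_iter=800)
            hits += lp.evanno_delta_k(runs).best_k == 2
        assert hits >= 4


def _q_run(q, K, lp_=0.0):
    return AdmixtureRun(
        K=K, Q=q, P=np.zeros((K, 1)), log_prob=lp_,
        log_likelihood_trace=np.array([lp_]), alpha_trace=np.array([1.0]),
        burn_in=0, n_iter=1, seed=0)


class TestPuechmaille:
    def _runs_from_labels(self, labels, K, n_runs=3, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        runs = []
        inds = [f"i{k}" for k in range(len(labels))]
        for _ in range(n_runs):
            q = np.full((len(labels), K), noise)
            for i, lab in enumerate(labels):
                q[i, lab] = 1.0
            q /= q.sum(axis=1, keepdims=True)
            perm = rng.permutation(K)
            runs.append(_q_run(
                pd.DataFrame(q[:, perm], index=inds), K))
        return runs, pd.Series([f"s{lab}" for lab in labels],
                               index=inds)

    def test_three_separated_samples(self):
        labels = [0] * 10 + [1] * 10 + [2] * 10
        runs, sample_of = self._runs_from_labels(labels, K=4)
        pm = lp.puechmaille_statistics(runs, sample_of)
        assert (pm.med_med_k, pm.med_mean_k, pm.max_med_k, pm.max_mean_k
                ) == (3, 3, 3, 3)

    def test_single_panmictic_sample(self):
        rng = np.random.default_rng(1)
        q = rng.dirichlet(np.ones(4) * 50, size=12)
        runs = [_q_run(pd.DataFrame(q, index=[f"i{k}" for k in range(12)]), 4)
                for _ in range(3)]
        sample_of = pd.Series(["s0"] * 12, index=[f"i{k}" for k in range(12)])
        pm = lp.puechmaille_statistics(runs, sample_of)
        assert pm.max_mean_k == 1 and pm.med_med_k == 1

    def test_threshold_validated(self):
        labels = [0] * 4
        runs, sample_of = self._runs_from_labels(labels, K=2)
        with pytest.raises(ValueError):
            lp.puechmaille_statistics(runs, sample_of, threshold=1.2)

    def test_label_permutation_invariance(self):
        labels = [0] * 8 + [1] * 8
        runs, sample_of = self._runs_from_labels(labels, K=3, seed=5)
        pm1 = lp.puechmaille_statistics(runs, sample_of)
        permuted = []
        for r in runs:
            q = r.Q.to_numpy()[:, [2, 0, 1]]
            permuted.append(_q_run(pd.DataFrame(q, index=r.Q.index), 3))
        pm2 = lp.puechmaille_statistics(permuted, sample_of)
        assert (pm1.med_med_k, pm1.max_mean_k) == (pm2.med_med_k,
                                                   pm2.max_mean_k)


class TestAlignment:
    def test_relabeled_identical_runs_align_perfectly(self):
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(3), size=20)
        inds = [f"i{k}" for k in range(20)]
        r1 = _q_run(pd.DataFrame(q, index=inds), 3, lp_=-10)
        r2 = _q_run(pd.DataFrame(q[:, [1, 2, 0]], index=inds), 3, lp_=-11)
        avg, perms, g = lp.align_and_average_runs([r1, r2])
        assert g == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(avg.to_numpy(), q)
        assert perms[1] == (2, 0, 1)  # inverse of the applied relabeling

    def test_label_swap_with_noise_averages_close(self):
        rng = np.random.default_rng(1)
        q = rng.dirichlet(np.ones(2), size=15)
        eps = rng.normal(0, 0.005, q.shape)
        q2 = np.clip(q[:, ::-1] + eps, 1e-6, None)
        q2 /= q2.sum(axis=1, keepdims=True)
        inds = [f"i{k}" for k in range(15)]
        r1 = _q_run(pd.DataFrame(q, index=inds), 2, lp_=-1)
        r2 = _q_run(pd.DataFrame(q2, index=inds), 2, lp_=-2)
        avg, _, g = lp.align_and_average_runs([r1, r2])
        assert np.abs(avg.to_numpy() - q).max() < 0.02

    def test_noise_runs_align_near_random_baseline(self):
        rng = np.random.default_rng(2)
        inds = [f"i{k}" for k in range(200)]
        runs = [_q_run(pd.DataFrame(rng.dirichlet(np.ones(2), size=200),
                                    index=inds), 2, lp_=-k)
                for k in range(2)]
        _, _, g = lp.align_and_average_runs(runs)
        # empirical null for K=2 Dirichlet(1,1) rows: G concentrates well
        # below the perfect-alignment value of 1
        assert 0.3 < g < 0.9

    def test_inconsistent_individuals_error(self):
        r1 = _q_run(pd.DataFrame(np.ones((2, 2)) / 2, index=["a", "b"]), 2)
        r2 = _q_run(pd.DataFrame(np.ones((2, 2)) / 2, index=["a", "c"]), 2)
        with pytest.raises(ValueError):
            lp.align_and_average_runs([r1, r2])

    def test_hungarian_path_matches_exhaustive(self):
        rng = np.random.default_rng(3)
        q = rng.dirichlet(np.ones(4), size=30)
        perm = (2, 0, 3, 1)
        inds = [f"i{k}" for k in range(30)]
        r1 = _q_run(pd.DataFrame(q, index=inds), 4, lp_=-1)
        r2 = _q_run(pd.DataFrame(q[:, perm], index=inds), 4, lp_=-2)
        _, perms_ex, _ = lp.align_and_average_runs([r1, r2],
                                                   exhaustive_max_k=8)
        _, perms_hu, _ = lp.align_and_average_runs([r1, r2],
                                                   exhaustive_max_k=1)
        assert perms_ex[1] == perms_hu[1]
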