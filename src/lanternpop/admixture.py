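"""Model-based admixture clustering with a Gibbs sampler, replicate-run
management, K selection (Evanno's delta-K and Puechmaille's four
statistics), and label-aligned averaging of replicate runs.

The model is the classical admixture model: individual i draws each of its
two allele copies at locus l from cluster k with probability Q[i, k], and
the copy is the B allele with probability P[k, l].  Priors: Q_i ~
Dirichlet(alpha, ..., alpha) with alpha itself given a uniform prior and
updated by a Metropolis step; P[k, l] ~ Beta(1, 1) independently per
cluster and locus (independent-frequencies model).  The sampler alternates
(Z | Q, P), (P | Z), (Q | Z, alpha) and (alpha | Q).

The model-choice score L(K) is the usual estimator of the log marginal
likelihood: mean of the log-likelihood trace minus half its variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotypes import GenotypeMatrix

__all__ = [
    "AdmixtureRun",
    "EvannoTable",
    "PuechmailleResult",
    "run_admixture",
    "run_replicates",
    "evanno_delta_k",
    "puechmaille_statistics",
    "align_and_average_runs",
    "g_similarity",
]


@dataclass
class AdmixtureRun:
    """One MCMC run of the admixture model at a fixed K."""

    K: int
    Q: pd.DataFrame  # individuals x K, posterior means, rows on the simplex
    P: np.ndarray  # (K, L) posterior mean B-allele frequencies
    log_prob: float  # L(K): mean - var/2 of the post-burn-in logL trace
    log_likelihood_trace: np.ndarray
    alpha_trace: np.ndarray
    burn_in: int
    n_iter: int
    seed: int


def run_admixture(
    gm: GenotypeMatrix,
    K: int,
    burn_in: int = 5_000,
    n_iter: int = 20_000,
    alpha_init: float = 1.0,
    alpha_proposal_sd: float = 0.1,
    alpha_max: float = 10.0,
    thin: int = 5,
    seed: int = 0,
) -> AdmixtureRun:
    """Gibbs sampling of the admixture model for one K.

    ``n_iter`` counts total sweeps including ``burn_in``; the trace is
    thinned by ``thin``.  Missing calls contribute nothing to the
    likelihood and are ignored in all updates.
    """
    n, L = gm.n_individuals, gm.n_loci
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K cannot exceed the number of individuals")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    x = gm.calls.astype(np.int8)  # (n, L, 2), -1 missing
    valid = x >= 0
    n_valid = int(valid.sum())

    P = rng.uniform(0.1, 0.9, size=(K, L))
    Q = rng.dirichlet(np.full(K, alpha_init), size=n)
    alpha = float(alpha_init)

    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L))
    ll_trace: list[float] = []
    alpha_trace: list[float] = []
    n_kept = 0

    is_one = (x == 1)[..., None]  # (n, L, 2, 1)
    is_missing = (x < 0)[..., None]
    has_missing = bool(is_missing.any())
    P = P.astype(np.float32)
    Q = Q.astype(np.float32)
    for it in range(n_iter):
        # emission probability of each copy under each cluster
        pk = P.T[None, :, None, :]  # (1, L, 1, K)
        emit = np.where(is_one, pk, np.float32(1.0) - pk)
        if has_missing:
            emit = np.where(is_missing, np.float32(1.0), emit)
        w = emit * Q[:, None, None, :]  # (n, L, 2, K)
        keep = it >= burn_in and (it - burn_in) % thin == 0
        if keep:
            # log-likelihood of the data under current (Q, P)
            s = w.sum(axis=-1, dtype=np.float64)
            ll = float(np.log(s[valid]).sum())
        # sample Z by an exponential race (equivalent to Gumbel-max)
        e = rng.standard_exponential(w.shape, dtype=np.float32)
        np.maximum(e, np.float32(1e-30), out=e)
        Z = np.argmax(w / e, axis=-1)  # (n, L, 2)
        # P update: counts of alleles per (k, l)
        lidx = np.broadcast_to(np.arange(L)[None, :, None], Z.shape)
        flat = ((Z * L + lidx) * 2 + np.maximum(x, 0))[valid]
        cnt = np.bincount(flat.ravel(), minlength=K * L * 2).reshape(K, L, 2)
        P = rng.beta(1.0 + cnt[:, :, 1], 1.0 + cnt[:, :, 0]
                     ).astype(np.float32)
        # Q update: counts of copies per (i, k)
        iidx = np.broadcast_to(np.arange(n)[:, None, None], Z.shape)
        flat_q = (iidx * K + Z)[valid]
        m = np.bincount(flat_q.ravel(), minlength=n * K).reshape(n, K)
        gam = rng.standard_gamma(alpha + m)
        Q = (gam / gam.sum(axis=1, keepdims=True)).astype(np.float32)
        # alpha Metropolis update
        if K > 1:
            prop = alpha + rng.normal(0.0, alpha_proposal_sd)
            if 0 < prop < alpha_max:
                logq = float(np.log(np.maximum(Q, np.float32(1e-30))).sum())
                def dir_const(a: float) -> float:
                    return n * (gammaln(K * a) - K * gammaln(a))
                log_ratio = (dir_const(prop) - dir_const(alpha)
                             + (prop - alpha) * logq)
                if np.log(rng.random()) < log_ratio:
                    alpha = prop
        if keep:
            Q_sum += Q
            P_sum += P
            ll_trace.append(ll)
            alpha_trace.append(alpha)
            n_kept += 1

    Qm = Q_sum / n_kept
    Qm /= Qm.sum(axis=1, keepdims=True)
    ll_arr = np.array(ll_trace)
    log_prob = float(ll_arr.mean() - ll_arr.var(ddof=0) / 2.0)
    return AdmixtureRun(
        K=K,
        Q=pd.DataFrame(Qm, index=gm.individuals,
                       columns=[f"cluster{k + 1}" for k in range(K)]),
        P=P_sum / n_kept,
        log_prob=log_prob,
        log_likelihood_trace=ll_arr,
        alpha_trace=np.array(alpha_trace),
        burn_in=burn_in,
        n_iter=n_iter,
        seed=seed,
    )


def run_replicates(
    gm: GenotypeMatrix,
    k_values: range | list[int],
    n_runs: int = 5,
    seed: int = 0,
    **kwargs,
) -> list[AdmixtureRun]:
    """Run ``n_runs`` replicate chains for each K in ``k_values``."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in ss.spawn(len(list(k_values)) * n_runs)]
    runs = []
    i = 0
    for K in k_values:
        for _ in range(n_runs):
            runs.append(run_admixture(gm, K, seed=seeds[i], **kwargs))
            i += 1
    return runs


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------


@dataclass
class EvannoTable:
    """Per-K summary of L(K) and the second-order delta-K statistic."""

    table: pd.DataFrame  # index K; mean_L, sd_L, L_prime, L_doubleprime, delta_K
    best_k: int | None


def evanno_delta_k(runs: list[AdmixtureRun]) -> EvannoTable:
    """Evanno's delta-K over replicate runs grouped by K.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L(K));
    defined for interior K only; K with SD = 0 get NaN (flagged).
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.log_prob)
    ks = sorted(by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("need >= 2 runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean[k] - mean[k - 1] if k - 1 in mean else np.nan
        if k - 1 in mean and k + 1 in mean:
            lpp = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = lpp / sd[k] if sd[k] > 0 else np.nan
        else:
            lpp, dk = np.nan, np.nan
        rows.append((k, mean[k], sd[k], lp, lpp, dk))
    table = pd.DataFrame(
        rows, columns=["K", "mean_L", "sd_L", "L_prime", "L_doubleprime",
                       "delta_K"]
    ).set_index("K")
    dk = table["delta_K"].dropna()
    best = int(dk.idxmax()) if not dk.empty else None
    return EvannoTable(table=table, best_k=best)


@dataclass
class PuechmailleResult:
    """The four subsample-aware K-selection statistics."""

    threshold: float
    per_run: pd.DataFrame  # run index -> mean_count, median_count
    med_med_k: int
    med_mean_k: int
    max_med_k: int
    max_mean_k: int


def puechmaille_statistics(
    runs: list[AdmixtureRun],
    sample_of: pd.Series,
    threshold: float = 0.5,
) -> PuechmailleResult:
    """MedMedK / MedMeanK / MaxMedK / MaxMeanK over replicate runs.

    For each run, per predefined sample compute the mean and the median
    membership to every cluster; a cluster counts if at least one sample's
    mean (resp. median) membership reaches ``threshold``.  Max* take the
    maximum count over runs, Med* the median.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rows = []
    for idx, r in enumerate(runs):
        q = r.Q
        lab = sample_of.loc[q.index]
        mean_m = q.groupby(lab.to_numpy()).mean()
        med_m = q.groupby(lab.to_numpy()).median()
        mean_count = int(((mean_m >= threshold).any(axis=0)).sum())
        med_count = int(((med_m >= threshold).any(axis=0)).sum())
        rows.append((idx, r.K, max(mean_count, 1), max(med_count, 1)))
    per_run = pd.DataFrame(
        rows, columns=["run", "K", "mean_count", "median_count"]
    ).set_index("run")
    return PuechmailleResult(
        threshold=threshold,
        per_run=per_run,
        med_med_k=int(round(per_run["median_count"].median())),
        med_mean_k=int(round(per_run["mean_count"].median())),
        max_med_k=int(per_run["median_count"].max()),
        max_mean_k=int(per_run["mean_count"].max()),
    )


# ---------------------------------------------------------------------------
# Label alignment and averaging (CLUMPP-style)
# ---------------------------------------------------------------------------


def g_similarity(qa: np.ndarray, qb: np.ndarray) -> float:
    """Pairwise similarity G = 1 - ||Qa - Qb||_F / sqrt(2 n)."""
    n = qa.shape[0]
    return float(1.0 - np.linalg.norm(qa - qb) / np.sqrt(2.0 * n))


def _best_permutation(qref: np.ndarray, qb: np.ndarray,
                      exhaustive_max_k: int = 8) -> tuple[int, ...]:
    K = qref.shape[1]
    if K <= exhaustive_max_k:
        best, best_g = None, -np.inf
        for perm in iter_permutations(range(K)):
            g = g_similarity(qref, qb[:, perm])
            if g > best_g:
                best, best_g = perm, g
        return best
    cost = -(qref.T @ qb)  # maximise column correlations
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return tuple(perm)


def align_and_average_runs(
    runs: list[AdmixtureRun],
    exhaustive_max_k: int = 8,
) -> tuple[pd.DataFrame, list[tuple[int, ...]], float]:
    """Align replicate runs at one K and average their Q matrices.

    The reference is the run with the highest L(K); every other run's
    clusters are permuted to maximise G similarity to the reference
    (exhaustive search for K <= ``exhaustive_max_k``, Hungarian assignment
    above).  Returns (averaged Q, permutations per run, mean pairwise G of
    the aligned runs).
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs")
    ks = {r.K for r in runs}
    if len(ks) != 1:
        raise ValueError("runs must share one K")
    inds = list(runs[0].Q.index)
    for r in runs[1:]:
        if list(r.Q.index) != inds:
            raise ValueError("runs must cover identical individuals")
    K = runs[0].K
    ref_i = int(np.argmax([r.log_prob for r in runs]))
    qref = runs[ref_i].Q.to_numpy()
    perms: list[tuple[int, ...]] = []
    aligned = []
    for r in runs:
        qb = r.Q.to_numpy()
        perm = (tuple(range(K)) if r is runs[ref_i]
                else _best_permutation(qref, qb, exhaustive_max_k))
        perms.append(perm)
        aligned.append(qb[:, perm])
    avg = np.mean(aligned, axis=0)
    avg /= avg.sum(axis=1, keepdims=True)
    gs = [g_similarity(aligned[i], aligned[j])
          for i in range(len(aligned)) for j in range(i + 1, len(aligned))]
    q_avg = pd.DataFrame(avg, index=inds, columns=runs[0].Q.columns)
    return q_avg, perms, float(np.mean(gs))
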