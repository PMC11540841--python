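"""PCA on genotype dosages, driver-locus identification from loadings, and
discriminant analysis of principal components (DAPC).

PCA operates on the B-allele dosage matrix with missing entries replaced by
the locus mean dosage and columns centered but not variance-scaled.  Axes
are oriented so the largest-magnitude loading on each axis is positive,
which makes scores reproducible across runs and platforms.

DAPC reduces the dosage matrix to ``n_pcs`` principal components and then
fits a canonical discriminant analysis on group labels; the number of PCs
is chosen by stratified cross-validation when not given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit

from .genotypes import GenotypeMatrix

__all__ = [
    "PcaResult",
    "DapcResult",
    "pca_genotypes",
    "driver_loci_from_loadings",
    "dapc_fit",
    "pc1_stripe_count",
]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a genotype PCA."""

    scores: pd.DataFrame  # individuals x axes
    loadings: pd.DataFrame  # loci x axes
    explained_variance_ratio: np.ndarray
    dropped_loci: list[str] = field(default_factory=list)


def _impute_center(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and center columns; returns (X, keep)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(dos, axis=0)
    keep = ~np.isnan(col_mean)
    X = dos[:, keep].copy()
    mu = col_mean[keep]
    inds = np.where(np.isnan(X))
    X[inds] = mu[inds[1]]
    X -= mu
    return X, keep


def pca_genotypes(gm: GenotypeMatrix, n_axes: int | None = None) -> PcaResult:
    """PCA of the mean-imputed, centered (unscaled) dosage matrix."""
    if gm.n_individuals < 2:
        raise ValueError("need at least two individuals")
    dos = gm.dosage()
    X, keep = _impute_center(dos)
    dropped = [l for l, k in zip(gm.loci, keep) if not k]
    loci = [l for l, k in zip(gm.loci, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("no typed loci")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    eigvals = s**2 / (n - 1)
    total_var = X.var(axis=0, ddof=1).sum()
    k = min(n_axes or len(s), len(s))
    # deterministic orientation: largest-|loading| positive on each axis
    for a in range(k):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U[:, :k] * s[:k]
    axes = [f"PC{a + 1}" for a in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=gm.individuals, columns=axes),
        loadings=pd.DataFrame(Vt[:k].T, index=loci, columns=axes),
        explained_variance_ratio=eigvals[:k] / total_var,
        dropped_loci=dropped,
    )


def driver_loci_from_loadings(
    pca: PcaResult,
    axis: int = 1,
    method: str = "gap",
    min_ratio: float = 2.0,
    max_block_frac: float = 0.25,
    n_sd: float = 3.0,
) -> pd.DataFrame:
    """Identify the loci driving an axis from their squared loadings.

    ``method='gap'`` (default) sorts squared loadings in decreasing order
    and cuts at the largest consecutive ratio within the top
    ``max_block_frac`` of loci (a driving block is a minority of the
    panel); if that ratio is below ``min_ratio`` no locus is reported (no
    block-like signal).  ``method='mean_sd'`` selects loci whose squared
    loading exceeds mean + ``n_sd`` * SD of all squared loadings on the
    axis.

    Returns a DataFrame (locus, loading, squared_loading) ranked by
    decreasing squared loading; empty when nothing passes.
    """
    col = f"PC{axis}"
    if col not in pca.loadings.columns:
        raise ValueError(f"axis {axis} not computed")
    lo = pca.loadings[col]
    sq = (lo**2).sort_values(ascending=False)
    if method == "mean_sd":
        thr = sq.mean() + n_sd * sq.std(ddof=1)
        sel = sq[sq > thr]
    elif method == "gap":
        vals = sq.to_numpy()
        L = len(vals)
        upper = max(1, min(int(L * max_block_frac), L - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = vals[:upper] / vals[1:upper + 1]
        ratios = np.where(np.isfinite(ratios), ratios, np.inf)
        cut = int(np.argmax(ratios))
        if ratios[cut] < min_ratio:
            sel = sq.iloc[:0]
        else:
            sel = sq.iloc[:cut + 1]
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame({
        "locus": sel.index,
        "loading": lo[sel.index].to_numpy(),
        "squared_loading": sel.to_numpy(),
    }).reset_index(drop=True)


@dataclass
class DapcResult:
    """DAPC coordinates, centroids and the cross-validation table."""

    n_pcs: int
    n_da: int
    coordinates: pd.DataFrame  # individuals x discriminant axes
    centroids: pd.DataFrame  # groups x discriminant axes
    assignment_success: float  # on the training data
    posterior: pd.DataFrame  # individuals x groups
    xval_table: pd.DataFrame  # n_pcs -> mean assignment success


def dapc_fit(
    gm: GenotypeMatrix,
    grouping: pd.Series,
    n_pcs: int | None = None,
    n_da: int | None = None,
    xval_reps: int = 30,
    xval_grid: list[int] | None = None,
    seed: int = 0,
) -> DapcResult:
    """Discriminant analysis of principal components with cross-validation.

    ``grouping`` maps individual -> label.  When ``n_pcs`` is None a grid of
    PC counts is scored by stratified 90/10 cross-validation (``xval_reps``
    splits) and the count with the highest mean held-out assignment success
    is retained (ties -> fewer PCs).
    """
    labels = grouping.loc[gm.individuals]
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two groups")
    dos = gm.dosage()
    X, _ = _impute_center(dos)
    n, L = X.shape
    max_da = len(classes) - 1
    n_da = min(n_da or max_da, max_da)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pcs_all = U * s  # scores on all PCs
    rank = int((s > 1e-10 * s[0]).sum())
    cap = min(rank, n - len(classes))
    y = labels.to_numpy()
    xval_rows = []
    if n_pcs is None:
        if xval_grid is None:
            hi = max(cap, 1)
            xval_grid = sorted({max(1, round(hi * f))
                                for f in (0.1, 0.2, 0.3, 0.5, 0.7, 0.9)})
        xval_grid = [g for g in xval_grid if 1 <= g <= cap] or [min(2, cap)]
        counts = pd.Series(y).value_counts()
        can_stratify = (counts >= 2).all() and n >= 10 * 1
        best = None
        for g in xval_grid:
            scores = []
            if can_stratify:
                sss = StratifiedShuffleSplit(
                    n_splits=xval_reps, test_size=0.1, random_state=seed)
                splits = sss.split(pcs_all[:, :g], y)
            else:  # tiny data: plain shuffle splits
                rng = np.random.default_rng(seed)
                splits = []
                for _ in range(xval_reps):
                    perm = rng.permutation(n)
                    k = max(1, n // 10)
                    splits.append((perm[k:], perm[:k]))
            for tr, te in splits:
                if len(pd.unique(y[tr])) < 2:
                    continue
                lda = LinearDiscriminantAnalysis(n_components=None)
                lda.fit(pcs_all[tr][:, :g], y[tr])
                scores.append(float((lda.predict(pcs_all[te][:, :g]) == y[te]
                                     ).mean()))
            m = float(np.mean(scores)) if scores else 0.0
            xval_rows.append((g, m))
            if best is None or m > best[1] + 1e-12:
                best = (g, m)
        n_pcs = best[0]
    n_pcs = min(n_pcs, cap) if cap >= 1 else 1
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    Z = pcs_all[:, :n_pcs]
    lda.fit(Z, y)
    coords = lda.transform(Z)[:, :n_da]
    axes = [f"LD{a + 1}" for a in range(coords.shape[1])]
    coord_df = pd.DataFrame(coords, index=gm.individuals, columns=axes)
    centroids = coord_df.groupby(labels.to_numpy()).mean()
    post = pd.DataFrame(lda.predict_proba(Z), index=gm.individuals,
                        columns=lda.classes_)
    success = float((lda.predict(Z) == y).mean())
    return DapcResult(
        n_pcs=int(n_pcs),
        n_da=int(coords.shape[1]),
        coordinates=coord_df,
        centroids=centroids,
        assignment_success=success,
        posterior=post,
        xval_table=pd.DataFrame(xval_rows,
                                columns=["n_pcs", "mean_success"]),
    )


# ---------------------------------------------------------------------------
# Stripe counting (1-D gap statistic)
# ---------------------------------------------------------------------------


def _kmeans_1d(x: np.ndarray, k: int, n_init: int = 10,
               rng: np.random.Generator | None = None
               ) -> tuple[np.ndarray, float]:
    """Small 1-D k-means; returns (centers sorted, within-cluster SS)."""
    rng = rng or np.random.default_rng(0)
    best = None
    qs = np.linspace(0, 1, k + 2)[1:-1]
    inits = [np.quantile(x, qs)]
    for _ in range(n_init - 1):
        inits.append(np.sort(rng.choice(x, size=k, replace=False)))
    for c in inits:
        c = c.astype(float).copy()
        for _ in range(100):
            d = np.abs(x[:, None] - c[None, :])
            lab = d.argmin(axis=1)
            new = np.array([
                x[lab == j].mean() if (lab == j).any() else c[j]
                for j in range(k)
            ])
            if np.allclose(new, c):
                break
            c = new
        wss = float(((x - c[lab]) ** 2).sum())
        if best is None or wss < best[1]:
            best = (np.sort(c), wss)
    return best


def pc1_stripe_count(
    scores: pd.Series | np.ndarray,
    k_max: int = 6,
    n_ref: int = 50,
    seed: int = 0,
) -> int:
    """Estimate the number of 1-D clusters ("stripes") by the gap statistic.

    Compares log within-cluster dispersion of k-means on the scores with
    its expectation under ``n_ref`` uniform reference draws on the score
    range; returns the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    rng = np.random.default_rng(seed)
    lo, hi = x.min(), x.max()
    gaps, sks = [], []
    for k in range(1, k_max + 1):
        _, wss = _kmeans_1d(x, k, rng=rng)
        ref = []
        for _ in range(n_ref):
            xr = rng.uniform(lo, hi, size=x.size)
            ref.append(np.log(max(_kmeans_1d(xr, k, n_init=3, rng=rng)[1],
                                  1e-12)))
        ref = np.array(ref)
        gaps.append(ref.mean() - np.log(max(wss, 1e-12)))
        sks.append(ref.std(ddof=1) * np.sqrt(1 + 1 / n_ref))
    gaps = np.array(gaps)
    k_best = int(np.argmax(gaps)) + 1
    # collapse to the smallest k statistically indistinguishable from the max
    for k in range(1, k_best + 1):
        if gaps[k - 1] >= gaps[k_best - 1] - sks[k_best - 1]:
            return k
    return k_best
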