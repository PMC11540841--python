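"""Per-sample diversity summaries, exact Hardy-Weinberg tests, genotype
accumulation curves and among-group comparisons.

Heterozygosity conventions: per locus within a sample, Ho is the fraction of
typed individuals that are heterozygous; He = 1 - p^2 - q^2 from sample
allele frequencies; uHe applies the small-sample correction 2n/(2n-1); FIS =
(He - Ho)/He, computed per polymorphic locus and averaged (GenAlEx
convention, unbiased He not used in the ratio).  Sample-level values are
mean +/- SE over loci with SE = sd / sqrt(number of loci used).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, SampleMetadata

__all__ = [
    "DiversityStats",
    "HweResult",
    "per_sample_diversity",
    "hwe_exact_test",
    "hwe_tests_per_sample",
    "genotype_accumulation_curve",
    "kruskal_wallis_groups",
]


@dataclass
class DiversityStats:
    """Sample-level diversity table (one row per sample)."""

    table: pd.DataFrame  # index=sample; columns below

    COLUMNS = (
        "n", "polymorphic_pct",
        "ho_mean", "ho_se", "uhe_mean", "uhe_se", "fis_mean", "fis_se",
        "n_loci_used",
    )

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["ho_mean"].between(0, 1)).all()
                and (t["uhe_mean"].between(0, 1)).all()):
            raise ValueError("heterozygosities must be in [0, 1]")
        if not t["polymorphic_pct"].between(0, 100).all():
            raise ValueError("polymorphic_pct must be in [0, 100]")


def _se(x: np.ndarray) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def per_sample_diversity(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    by: str = "site",
) -> DiversityStats:
    """Compute Ho, uHe and FIS per sample (``by`` = 'site' or 'group').

    Loci untyped in a sample are skipped for that sample; FIS averages only
    over loci polymorphic in the sample (He > 0).
    """
    metadata.check_against(gm)
    labels = metadata.table.loc[gm.individuals, by]
    dos = gm.dosage()
    rows = {}
    for sample in pd.unique(labels):
        sel = (labels == sample).to_numpy()
        d = dos[sel]
        n_typed = np.sum(~np.isnan(d), axis=0).astype(float)
        used = n_typed > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(d, axis=0) / (2 * n_typed)  # B-allele freq
            ho = np.nansum(d == 1, axis=0) / n_typed
            he = 2 * p * (1 - p)
            uhe = np.where(n_typed > 0.5,
                           2 * n_typed / (2 * n_typed - 1) * he, np.nan)
            fis = np.where(he > 0, (he - ho) / he, np.nan)
        poly = used & (p > 0) & (p < 1)
        ho_u, uhe_u = ho[used], uhe[used]
        fis_u = fis[poly]
        rows[sample] = {
            "n": int(sel.sum()),
            "polymorphic_pct": 100.0 * poly.sum() / max(used.sum(), 1),
            "ho_mean": float(np.nanmean(ho_u)) if used.any() else np.nan,
            "ho_se": _se(ho_u),
            "uhe_mean": float(np.nanmean(uhe_u)) if used.any() else np.nan,
            "uhe_se": _se(uhe_u),
            "fis_mean": float(np.nanmean(fis_u)) if poly.any() else np.nan,
            "fis_se": _se(fis_u),
            "n_loci_used": int(used.sum()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[list(DiversityStats.COLUMNS)]
    return DiversityStats(table)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


@dataclass
class HweResult:
    """Exact-test outcome for one (sample, locus) genotype count triple."""

    p_value: float
    direction: str  # "deficit", "excess" or "monomorphic"
    counts: tuple[int, int, int]


def _log_prob_het(n_ab: int, n_a: int, n: int) -> float:
    """Log P(n_AB | allele counts) under Hardy-Weinberg (Levene/Haldane)."""
    n_b = 2 * n - n_a
    n_aa = (n_a - n_ab) // 2
    n_bb = (n_b - n_ab) // 2
    return (
        lgamma(n + 1) - lgamma(n_aa + 1) - lgamma(n_ab + 1) - lgamma(n_bb + 1)
        + n_ab * log(2.0)
        + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n + 1)
    )


def hwe_exact_test(counts: Sequence[int]) -> HweResult:
    """Two-sided exact Hardy-Weinberg test for one biallelic locus.

    ``counts`` = (nAA, nAB, nBB).  The null distribution of the heterozygote
    count conditional on the allele counts is enumerated fully and the
    p-value sums the probabilities of all outcomes no more probable than the
    observed one.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb < 1:
        raise ValueError("counts must be non-negative with at least one genotype")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return HweResult(1.0, "monomorphic", (n_aa, n_ab, n_bb))
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = np.array([_log_prob_het(h, n_a, n) for h in hets])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_ab)[0][0]]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    p = min(p, 1.0)
    pq = (n_a / (2 * n)) * (n_b / (2 * n))
    he = 2 * pq
    ho = n_ab / n
    direction = "deficit" if ho < he else "excess"
    return HweResult(p, direction, (n_aa, n_ab, n_bb))


def hwe_tests_per_sample(
    gm: GenotypeMatrix, metadata: SampleMetadata, by: str = "site"
) -> pd.DataFrame:
    """Exact HWE test for every (sample, locus); long-format DataFrame."""
    metadata.check_against(gm)
    labels = metadata.table.loc[gm.individuals, by]
    dos = gm.dosage()
    out = []
    for sample in pd.unique(labels):
        sel = (labels == sample).to_numpy()
        d = dos[sel]
        for j, locus in enumerate(gm.loci):
            col = d[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            counts = (int((col == 0).sum()), int((col == 1).sum()),
                      int((col == 2).sum()))
            r = hwe_exact_test(counts)
            out.append((sample, locus, r.p_value, r.direction, *counts))
    return pd.DataFrame(
        out, columns=["sample", "locus", "p", "direction", "nAA", "nAB", "nBB"]
    )


# ---------------------------------------------------------------------------
# Genotype accumulation curve
# ---------------------------------------------------------------------------


def genotype_accumulation_curve(
    gm: GenotypeMatrix,
    max_loci: int | None = None,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Distinct multilocus genotypes vs number of loci subsampled.

    For each subset size 1..max_loci (default n_loci - 1), draw ``reps``
    random locus subsets without replacement and count distinct multilocus
    genotype strings (a missing call is its own symbol).  Returns a long
    DataFrame with columns ``n_loci, rep, n_mlg``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    L = gm.n_loci
    max_loci = min(max_loci or L - 1, L)
    # encode genotypes as small ints: 0,1,2 dosage, 3 missing
    d = gm.dosage()
    enc = np.where(np.isnan(d), 3, d).astype(np.int8)
    rows = []
    for k in range(1, max_loci + 1):
        for r in range(reps):
            cols = rng.choice(L, size=k, replace=False)
            sub = enc[:, cols]
            n_mlg = len({sub[i].tobytes() for i in range(sub.shape[0])})
            rows.append((k, r, n_mlg))
    return pd.DataFrame(rows, columns=["n_loci", "rep", "n_mlg"])


def kruskal_wallis_groups(
    values: Sequence[float], grouping: Sequence[str]
) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum test of a per-sample statistic across groups."""
    s = pd.Series(values, index=None)
    g = pd.Series(grouping)
    if s.size != g.size:
        raise ValueError("values and grouping must align")
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    chunks = [s[(g == lev).to_numpy()].to_numpy() for lev in levels]
    if any(len(c) == 0 for c in chunks):
        raise ValueError("every group must be nonempty")
    if all(np.ptp(np.concatenate(chunks)) == 0 for _ in (0,)):
        return 0.0, 1.0
    h, p = stats.kruskal(*chunks)
    return float(h), float(p)
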