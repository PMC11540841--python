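"""Weir-Cockerham F-statistics, flat and hierarchical AMOVA, and the
FST dendrogram.

The multi-locus Weir-Cockerham estimator theta is the ratio of summed
variance components sum(a) / sum(a+b+c), with per-locus, per-allele
components a (among populations), b (among individuals within populations)
and c (within individuals).  Negative per-locus components are retained in
the ratio, following the original estimator.

AMOVA partitions the variance of squared inter-individual genetic distances
(per locus: number of differing alleles, 0/1/2, summed over loci typed in
both individuals and rescaled for missingness) across a one- or two-level
sampling hierarchy, with method-of-moments variance components and
permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genotypes import GenotypeMatrix, SampleMetadata

__all__ = [
    "FstMatrix",
    "AmovaResult",
    "weir_cockerham_theta",
    "weir_cockerham_fst",
    "amova",
    "genotype_distance_matrix",
    "fst_dendrogram",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(genos: list[np.ndarray]) -> tuple[float, float, float]:
    """Per-locus WC variance components summed over alleles.

    ``genos``: one integer array of allele pairs ``(n_i, 2)`` per population
    (missing individuals already removed), alleles coded as small ints.
    """
    r = len(genos)
    n_i = np.array([g.shape[0] for g in genos], dtype=float)
    if (n_i < 1).any() or r < 2:
        return np.nan, np.nan, np.nan
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = np.unique(np.concatenate([g.ravel() for g in genos]))
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = np.array([(g == al).mean() for g in genos])
        # frequency of heterozygotes carrying exactly one copy of al
        h_i = np.array([((g == al).sum(axis=1) == 1).mean() for g in genos])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = ((n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar))
        hbar = (n_i * h_i).sum() / (r * nbar)
        if nbar <= 1:
            return np.nan, np.nan, np.nan
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _wc_biallelic_components(
    dos: np.ndarray, pop: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-locus WC components for biallelic dosage data.

    ``dos``: (n, L) B-allele counts with NaN missing.  Returns per-locus
    (a, b, c) arrays (NaN where a locus is untyped in some population or has
    mean sample size <= 1); components are summed over the two alleles.
    """
    pops = pd.unique(pop)
    r = len(pops)
    n_i = np.stack([np.sum(~np.isnan(dos[pop == p]), axis=0) for p in pops])
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nansum(dos[pop == p], axis=0) for p in pops]) / (
            2 * n_i)
        h_i = np.stack([np.nansum(dos[pop == p] == 1, axis=0) for p in pops]
                       ) / n_i
        nbar = n_i.mean(axis=0)
        nc = (r * nbar - (n_i.astype(float) ** 2).sum(axis=0) / (r * nbar)
              ) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
            / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = (n_i < 1).any(axis=0) | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return 2 * a, 2 * b, 2 * c


def weir_cockerham_theta(
    calls: np.ndarray, pop: np.ndarray
) -> float:
    """Multi-locus WC theta from a ``(n, L, 2)`` call array and labels.

    Loci untyped in any population are skipped.  Alleles may be multiallelic
    (any non-negative integer codes; -1 = missing); biallelic data take a
    vectorised path.
    """
    if calls.max() <= 1:
        d = calls.sum(axis=2).astype(float)
        d[calls[:, :, 0] < 0] = np.nan
        a, b, c = _wc_biallelic_components(d, np.asarray(pop))
        den = np.nansum(a + b + c)
        if den == 0 or not np.isfinite(den):
            return np.nan
        return float(np.nansum(a) / den)
    pops = pd.unique(pop)
    num = den = 0.0
    L = calls.shape[1]
    for l in range(L):
        genos = []
        skip = False
        for pp in pops:
            g = calls[pop == pp, l, :]
            g = g[g[:, 0] >= 0]
            if g.shape[0] < 1:
                skip = True
                break
            genos.append(g)
        if skip:
            continue
        a, b, c = _wc_components(genos)
        if np.isnan(a):
            continue
        num += a
        den += a + b + c
    if den == 0:
        return np.nan
    return num / den


@dataclass
class FstMatrix:
    """Pairwise FST estimates with permutation p-values."""

    samples: list[str]
    fst: np.ndarray  # symmetric, diag 0
    p_values: np.ndarray  # symmetric, diag NaN
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        """Lower triangle = estimates, upper triangle = p-values."""
        out = pd.DataFrame(np.nan, index=self.samples, columns=self.samples)
        k = len(self.samples)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out.iat[i, j] = self.fst[i, j]
                elif i < j:
                    out.iat[i, j] = self.p_values[i, j]
        return out


def weir_cockerham_fst(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    by: str = "site",
    pairwise: bool = True,
    n_perm: int = 10_000,
    seed: int = 0,
) -> FstMatrix | float:
    """Pairwise (or global) multi-locus WC theta with permutation tests.

    The permutation null reassigns individuals at random between the two
    samples of a pair; p = (#permuted theta >= observed + 1)/(n_perm + 1).
    With ``pairwise=False`` returns the single multi-population theta.
    """
    metadata.check_against(gm)
    labels = metadata.table.loc[gm.individuals, by].to_numpy()
    if not pairwise:
        return float(weir_cockerham_theta(gm.calls, labels))
    samples = list(pd.unique(labels))
    k = len(samples)
    fst = np.zeros((k, k))
    pv = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(k), 2):
        sel = (labels == samples[i]) | (labels == samples[j])
        sub = gm.calls[sel]
        lab = labels[sel]
        theta = weir_cockerham_theta(sub, lab)
        fst[i, j] = fst[j, i] = theta
        if n_perm > 0:
            count = 0
            lab_p = lab.copy()
            for _ in range(n_perm):
                rng.shuffle(lab_p)
                if weir_cockerham_theta(sub, lab_p) >= theta:
                    count += 1
            pv[i, j] = pv[j, i] = (count + 1) / (n_perm + 1)
    return FstMatrix(samples, fst, pv, n_perm)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------


def genotype_distance_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Squared inter-individual distances: allele differences summed over
    loci typed in both individuals, rescaled by total/typed loci."""
    dos = gm.dosage()
    n, L = dos.shape
    D2 = np.zeros((n, n))
    valid = ~np.isnan(dos)
    dosz = np.where(valid, dos, 0.0)
    for i in range(n):
        both = valid[i] & valid
        diff = np.abs(dosz[i] - dosz) * both
        raw = diff.sum(axis=1)
        typed = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            D2[i] = np.where(typed > 0, raw * (L / typed), 0.0)
    np.fill_diagonal(D2, 0.0)
    return (D2 + D2.T) / 2


@dataclass
class AmovaResult:
    """Variance components, percentages and F-statistics of an AMOVA."""

    hierarchical: bool
    components: dict[str, float]  # sigma2 per level
    percentages: dict[str, float]
    f_statistics: dict[str, float]  # FST (+ FSC, FCT when hierarchical)
    df: dict[str, int] = field(default_factory=dict)
    sums_of_squares: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lev in self.components:
            rows.append({
                "level": lev,
                "df": self.df.get(lev, np.nan),
                "sum_of_squares": self.sums_of_squares.get(lev, np.nan),
                "sigma2": self.components[lev],
                "pct_variation": self.percentages[lev],
            })
        return pd.DataFrame(rows)


def _ss_within_partition(D2: np.ndarray, parts: list[np.ndarray]) -> float:
    ss = 0.0
    for rows in parts:
        if len(rows) < 1:
            continue
        sub = D2[np.ix_(rows, rows)]
        ss += sub.sum() / (2 * len(rows))
    return ss


def _amova_components(
    D2: np.ndarray,
    sample_labels: np.ndarray,
    group_labels: np.ndarray | None,
) -> tuple[dict, dict, dict, dict, dict]:
    N = D2.shape[0]
    samples = pd.unique(sample_labels)
    S = len(samples)
    idx_of = {s: np.where(sample_labels == s)[0] for s in samples}
    n_s = {s: len(idx_of[s]) for s in samples}
    ss_total = D2.sum() / (2 * N)
    ss_wp = _ss_within_partition(D2, [idx_of[s] for s in samples])
    if group_labels is None:
        df_ap, df_wp = S - 1, N - S
        ss_ap = ss_total - ss_wp
        ms_ap = ss_ap / df_ap
        ms_wp = ss_wp / df_wp
        n0 = (N - sum(v**2 for v in n_s.values()) / N) / (S - 1)
        sig_w = ms_wp
        sig_a = (ms_ap - ms_wp) / n0
        total = sig_a + sig_w
        comps = {"among_samples": sig_a, "within_samples": sig_w}
        with np.errstate(invalid="ignore", divide="ignore"):
            pcts = {k: 100 * v / total for k, v in comps.items()}
            fstats = {"FST": sig_a / total}
        df = {"among_samples": df_ap, "within_samples": df_wp}
        ss = {"among_samples": ss_ap, "within_samples": ss_wp}
        return comps, pcts, fstats, df, ss
    groups = pd.unique(group_labels)
    G = len(groups)
    gidx = {g: np.where(group_labels == g)[0] for g in groups}
    N_g = {g: len(gidx[g]) for g in groups}
    group_of_sample = {}
    for s in samples:
        gl = pd.unique(group_labels[idx_of[s]])
        if len(gl) != 1:
            raise ValueError(f"sample {s!r} spans multiple groups")
        group_of_sample[s] = gl[0]
    ss_wg = _ss_within_partition(D2, [gidx[g] for g in groups])
    ss_ag = ss_total - ss_wg
    ss_ap_wg = ss_wg - ss_wp
    df_ag, df_ap, df_wp = G - 1, S - G, N - S
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap_wg / df_ap if df_ap > 0 else np.nan
    ms_wp = ss_wp / df_wp
    sum_n2_over_Ng = sum(
        sum(n_s[s] ** 2 for s in samples if group_of_sample[s] == g) / N_g[g]
        for g in groups
    )
    sum_n2_over_N = sum(n_s[s] ** 2 for s in samples) / N
    sum_Ng2_over_N = sum(v**2 for v in N_g.values()) / N
    n1 = (N - sum_n2_over_Ng) / (S - G) if S > G else np.nan
    n2 = (sum_n2_over_Ng - sum_n2_over_N) / (G - 1)
    n3 = (N - sum_Ng2_over_N) / (G - 1)
    sig_c = ms_wp
    sig_b = (ms_ap - sig_c) / n1 if S > G else 0.0
    sig_a = (ms_ag - sig_c - n2 * sig_b) / n3
    total = sig_a + sig_b + sig_c
    comps = {
        "among_groups": sig_a,
        "among_samples_within_groups": sig_b,
        "within_samples": sig_c,
    }
    with np.errstate(invalid="ignore", divide="ignore"):
        pcts = {k: 100 * v / total for k, v in comps.items()}
        fstats = {
            "FCT": sig_a / total,
            "FSC": sig_b / (sig_b + sig_c),
            "FST": (sig_a + sig_b) / total,
        }
    df = {"among_groups": df_ag,
          "among_samples_within_groups": df_ap,
          "within_samples": df_wp}
    ss = {"among_groups": ss_ag,
          "among_samples_within_groups": ss_ap_wg,
          "within_samples": ss_wp}
    return comps, pcts, fstats, df, ss


def amova(
    gm: GenotypeMatrix | None,
    metadata: SampleMetadata,
    by: str = "site",
    groups: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    distance_matrix: np.ndarray | None = None,
    individuals: list[str] | None = None,
) -> AmovaResult:
    """Flat or hierarchical AMOVA on genotype distances.

    ``by`` names the metadata column defining samples; ``groups`` (e.g.
    ``'group'``) adds the upper hierarchy level.  Permutation schemes:
    individuals among samples for the flat FST / FSC, whole samples among
    groups for FCT.  A precomputed squared-distance matrix (with matching
    ``individuals`` order) may be supplied instead of ``gm``.
    """
    if distance_matrix is not None:
        D2 = distance_matrix
        inds = individuals if individuals is not None else list(
            metadata.individuals)
    else:
        if gm is None:
            raise ValueError("need gm or distance_matrix")
        D2 = genotype_distance_matrix(gm)
        inds = gm.individuals
    sample_labels = metadata.table.loc[inds, by].to_numpy()
    group_labels = (metadata.table.loc[inds, groups].to_numpy()
                    if groups else None)
    comps, pcts, fstats, df, ss = _amova_components(
        D2, sample_labels, group_labels)
    res = AmovaResult(
        hierarchical=groups is not None,
        components=comps, percentages=pcts, f_statistics=fstats,
        df=df, sums_of_squares=ss, n_perm=n_perm,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        if group_labels is None:
            count = 0
            lab = sample_labels.copy()
            obs = fstats["FST"]
            for _ in range(n_perm):
                rng.shuffle(lab)
                f = _amova_components(D2, lab, None)[2]["FST"]
                count += f >= obs
            res.p_values["FST"] = (count + 1) / (n_perm + 1)
        else:
            # FSC: permute individuals among samples within groups
            count_sc = 0
            obs_sc = fstats["FSC"]
            lab = sample_labels.copy()
            for _ in range(n_perm):
                lab_p = lab.copy()
                for g in pd.unique(group_labels):
                    rows = np.where(group_labels == g)[0]
                    lab_p[rows] = lab_p[rng.permutation(rows)]
                f = _amova_components(D2, lab_p, group_labels)[2]["FSC"]
                count_sc += f >= obs_sc
            res.p_values["FSC"] = (count_sc + 1) / (n_perm + 1)
            # FCT: permute whole samples among groups
            samples = pd.unique(sample_labels)
            g_of_s = {
                s: group_labels[sample_labels == s][0] for s in samples
            }
            gr_sizes = pd.Series(list(g_of_s.values())).value_counts()
            if (gr_sizes < 2).any():
                res.p_values["FCT"] = np.nan  # degenerate permutation scheme
            else:
                count_ct = 0
                obs_ct = fstats["FCT"]
                svals = list(g_of_s.values())
                for _ in range(n_perm):
                    perm = rng.permutation(svals)
                    new_g_of_s = dict(zip(samples, perm))
                    glab = np.array([new_g_of_s[s] for s in sample_labels])
                    f = _amova_components(D2, sample_labels, glab)[2]["FCT"]
                    count_ct += f >= obs_ct
                res.p_values["FCT"] = (count_ct + 1) / (n_perm + 1)
    return res


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"


def fst_dendrogram(
    fst_matrix: FstMatrix, method: str = "average"
) -> tuple[str, list[str]]:
    """UPGMA tree on pairwise FST distances (negatives clamped to 0).

    Returns (newick string, leaf order for heatmap plotting).  ``method``
    may be any scipy linkage method; 'average' is UPGMA.
    """
    d = np.clip(fst_matrix.fst.copy(), 0.0, None)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValueError("FST matrix has missing entries")
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, fst_matrix.samples) + ";"
    order = [fst_matrix.samples[i] for i in hierarchy.leaves_list(Z)]
    return newick, order
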