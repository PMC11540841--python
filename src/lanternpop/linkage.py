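"""Pairwise linkage-disequilibrium tests, multilocus index of association,
Benjamini-Hochberg FDR control, and LD-pruning.

The pairwise test is Fisher's exact test on the joint genotype contingency
table of two loci (up to 3x3 for biallelic SNPs).  2x2 tables are evaluated
exactly; larger tables use a seeded Monte-Carlo evaluation of the exact
conditional null (scipy's permutation method), so the smallest attainable
p-value is 1/(draws+1).

The index of association IA and its locus-count-standardised form rbar_d
measure multilocus disequilibrium: per locus the distance between two
individuals is the number of differing alleles (0/1/2); IA compares the
variance of the summed distances with the sum of per-locus variances, and
significance comes from permuting genotypes independently within each locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeMatrix, SampleMetadata

__all__ = [
    "LdMatrix",
    "IaResult",
    "pairwise_ld_fisher",
    "index_of_association",
    "bh_fdr",
    "ld_prune",
]


@dataclass
class LdMatrix:
    """Symmetric matrix of pairwise LD p-values (NaN on the diagonal)."""

    loci: list[str]
    p_values: np.ndarray  # (L, L), symmetric, diag NaN
    method: str

    def __post_init__(self) -> None:
        L = len(self.loci)
        if self.p_values.shape != (L, L):
            raise ValueError("p-value matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_values, index=self.loci, columns=self.loci)

    def pair_series(self) -> pd.Series:
        """Upper-triangle p-values indexed by (locus_i, locus_j)."""
        idx, vals = [], []
        for i, j in combinations(range(len(self.loci)), 2):
            idx.append((self.loci[i], self.loci[j]))
            vals.append(self.p_values[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))


@dataclass
class IaResult:
    """Index of association and rbar_d with permutation p-values."""

    ia: float
    rbar_d: float
    p_ia: float
    p_rbar_d: float
    n_perm: int
    pairwise_rbar_d_range: tuple[float, float]


def _sample_margin_tables(table: np.ndarray, draws: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Sample tables from the fixed-margin null, returning sum(lgamma(x+1)).

    Rows are drawn sequentially: the first rows from the multivariate
    hypergeometric over the remaining column margins, cell by cell; the
    last row is determined.  Under this scheme each table appears with its
    conditional (Fisher) probability.
    """
    from scipy.special import gammaln

    r, c = table.shape
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    remaining_cols = np.tile(cols, (draws, 1)).astype(np.int64)
    stat = np.zeros(draws)
    for i in range(r - 1):
        left = np.full(draws, rows[i], dtype=np.int64)
        remaining_total = remaining_cols.sum(axis=1)
        for j in range(c - 1):
            ngood = remaining_cols[:, j].copy()
            nbad = remaining_total - ngood
            x = rng.hypergeometric(ngood, nbad, left)
            stat += gammaln(x + 1)
            remaining_cols[:, j] -= x
            remaining_total -= ngood  # colour j leaves the pool for this row
            left -= x
        stat += gammaln(left + 1)
        remaining_cols[:, c - 1] -= left
    stat += gammaln(remaining_cols + 1).sum(axis=1)
    return stat


def _fisher_p(table: np.ndarray, mc_draws: int, rng: np.random.Generator
              ) -> float:
    """Fisher exact p for an r x c genotype table (exact 2x2, MC otherwise).

    The Monte-Carlo path samples from the exact conditional null, so the
    smallest attainable p-value is 1/(mc_draws + 1).
    """
    from scipy.special import gammaln

    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table).pvalue)
    # P(table) is proportional to 1/prod(x_ij!): less probable tables have
    # larger sum(lgamma(x+1))
    obs = float(gammaln(table + 1).sum())
    stat = _sample_margin_tables(table, mc_draws, rng)
    count = int((stat >= obs - 1e-9).sum())
    return (count + 1) / (mc_draws + 1)


def pairwise_ld_fisher(
    gm: GenotypeMatrix,
    metadata: SampleMetadata | None = None,
    scope: str = "pooled",
    mc_draws: int = 100_000,
    seed: int = 0,
) -> LdMatrix | dict[str, LdMatrix]:
    """Fisher exact LD test on the joint genotype table of each locus pair.

    ``scope='pooled'`` tests over all individuals and returns one
    :class:`LdMatrix`; ``scope='per-sample'`` returns a dict of matrices
    keyed by site (requires metadata).  Individuals with either call missing
    are excluded pairwise.  Pairs with fewer than 2 informative individuals
    get a missing (NaN) p-value.
    """
    if gm.n_loci < 2:
        raise ValueError("need at least two loci")
    if scope == "per-sample":
        if metadata is None:
            raise ValueError("per-sample scope requires metadata")
        out = {}
        site = metadata.site_of()
        for k, s in enumerate(pd.unique(site.loc[gm.individuals])):
            sub = gm.subset(
                individuals=[i for i in gm.individuals if site[i] == s]
            )
            out[s] = pairwise_ld_fisher(
                sub, scope="pooled", mc_draws=mc_draws, seed=seed + k
            )
        return out
    rng = np.random.default_rng(seed)
    d = gm.dosage()
    L = gm.n_loci
    P = np.full((L, L), np.nan)
    for i, j in combinations(range(L), 2):
        x, y = d[:, i], d[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            continue
        tab = np.zeros((3, 3), dtype=int)
        np.add.at(tab, (x[ok].astype(int), y[ok].astype(int)), 1)
        p = _fisher_p(tab, mc_draws, rng)
        P[i, j] = P[j, i] = p
    return LdMatrix(list(gm.loci), P, method="fisher-genotypic")


# ---------------------------------------------------------------------------
# Index of association
# ---------------------------------------------------------------------------


def _ia_statistics(dos: np.ndarray) -> tuple[float, float]:
    """IA and rbar_d from a dosage matrix (NaN = missing, pairwise deletion)."""
    n, L = dos.shape
    npair = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    # per-locus pairwise distances |d_i - d_j| in {0,1,2}
    D = np.empty((npair, L))
    for l in range(L):
        col = dos[:, l]
        dl = np.abs(col[iu[0]] - col[iu[1]])
        D[:, l] = dl
    # pairwise deletion: missing distances contribute 0 to sums but are
    # excluded from per-locus variances
    valid = ~np.isnan(D)
    Dz = np.where(valid, D, 0.0)
    total = Dz.sum(axis=1)
    var_o = np.var(total, ddof=1)
    var_l = np.array([
        np.var(D[valid[:, l], l], ddof=1) if valid[:, l].sum() > 1 else 0.0
        for l in range(L)
    ])
    var_e = var_l.sum()
    if var_e == 0:
        raise ValueError("all loci monomorphic: IA undefined")
    ia = var_o / var_e - 1.0
    denom = 0.0
    for j in range(L):
        for k in range(j + 1, L):
            denom += np.sqrt(var_l[j] * var_l[k])
    rbar = (var_o - var_e) / (2.0 * denom) if denom > 0 else np.nan
    return float(ia), float(rbar)


def index_of_association(
    gm: GenotypeMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> IaResult:
    """Multilocus index of association with a within-locus permutation null.

    The permutation null shuffles genotypes independently within each locus,
    destroying between-locus association while preserving per-locus allele
    and missingness structure; p = (#permuted >= observed + 1)/(n_perm + 1).
    """
    if gm.n_loci < 2 or gm.n_individuals < 3:
        raise ValueError("need >= 2 loci and >= 3 individuals")
    dos = gm.dosage()
    ia_obs, rbar_obs = _ia_statistics(dos)
    rng = np.random.default_rng(seed)
    count_ia = count_r = 0
    for _ in range(n_perm):
        perm = dos.copy()
        for l in range(perm.shape[1]):
            rng.shuffle(perm[:, l])
        ia_p, r_p = _ia_statistics(perm)
        count_ia += ia_p >= ia_obs
        count_r += r_p >= rbar_obs
    p_ia = (count_ia + 1) / (n_perm + 1)
    p_r = (count_r + 1) / (n_perm + 1)
    # per-pair rbar_d range across locus pairs
    pair_vals = []
    L = gm.n_loci
    for j, k in combinations(range(L), 2):
        try:
            _, r = _ia_statistics(dos[:, [j, k]])
            if np.isfinite(r):
                pair_vals.append(r)
        except ValueError:
            continue
    rng_range = ((float(np.min(pair_vals)), float(np.max(pair_vals)))
                 if pair_vals else (np.nan, np.nan))
    return IaResult(ia_obs, rbar_obs, float(p_ia), float(p_r), n_perm,
                    rng_range)


# ---------------------------------------------------------------------------
# FDR and LD pruning
# ---------------------------------------------------------------------------


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR: returns (q_values, significant).

    Accepts any sequence/Series; NaNs are passed through unadjusted and
    never significant.
    """
    p = pd.Series(p_values, dtype=float)
    if p.empty:
        return p.copy(), p.astype(bool)
    ok = p.notna()
    q = pd.Series(np.nan, index=p.index)
    sig = pd.Series(False, index=p.index)
    if ok.any():
        rej, qv, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        q[ok] = qv
        sig[ok] = rej
    return q, sig


def ld_prune(
    gm: GenotypeMatrix,
    ld_matrix: LdMatrix,
    p_threshold: float = 1e-4,
) -> tuple[list[str], pd.DataFrame]:
    """Keep one locus per connected component of the significant-LD graph.

    Edges join locus pairs whose BH-FDR-corrected LD p-value is below
    ``p_threshold``.  Within each component the retained locus is the one
    with least missing data, then highest minor-allele frequency, then
    lexicographically smallest ID.  Returns (retained loci in input order,
    component table).
    """
    import networkx as nx

    if ld_matrix.loci != list(gm.loci):
        raise ValueError("LD matrix loci do not match genotype matrix")
    pairs = ld_matrix.pair_series()
    q, _ = bh_fdr(pairs)
    G = nx.Graph()
    G.add_nodes_from(gm.loci)
    for (a, b), qv in q.items():
        if np.isfinite(qv) and qv < p_threshold:
            G.add_edge(a, b)
    miss = gm.missing_mask().mean(axis=0)
    counts = gm.allele_counts().astype(float)
    tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(tot > 0, counts.min(axis=1) / tot, 0.0)
    rank = {
        l: (miss[i], -maf[i], l) for i, l in enumerate(gm.loci)
    }
    keep: set[str] = set()
    rows = []
    for comp_id, comp in enumerate(sorted(nx.connected_components(G),
                                          key=lambda c: sorted(c)[0])):
        best = min(comp, key=lambda l: rank[l])
        keep.add(best)
        for l in sorted(comp):
            rows.append((comp_id, l, l == best))
    retained = [l for l in gm.loci if l in keep]
    table = pd.DataFrame(rows, columns=["component", "locus", "retained"])
    return retained, table
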