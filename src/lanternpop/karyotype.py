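"""Karyotype (haplogroup) classification for a putative chromosomal
inversion, the per-karyotype allele-frequency table, haplogroup frequencies
per sample, and migrant flagging.

An inversion suppresses recombination between its two arrangements, so the
genotype PCA of a panel containing loci inside the block shows three
parallel clusters: the two homokaryotypes (AA, BB) flanking the
heterokaryotypes (AB).  Classification runs 1-D k-means (k=3) on PC1 scores
and validates the middle cluster as the one with the highest mean
heterozygosity at the driver loci; at perfectly diagnostic loci the
A-allele frequency per karyotype is the (1, 0.5, 0) signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleMetadata
from .ordination import PcaResult, _kmeans_1d

__all__ = [
    "KaryotypeCalls",
    "KaryotypeFrequencyTable",
    "ClassificationRejected",
    "classify_karyotypes",
    "karyotype_frequency_table",
    "haplogroup_frequencies_by_sample",
    "detect_migrants",
]


class ClassificationRejected(RuntimeError):
    """Raised when the three-cluster karyotype model does not fit."""


@dataclass
class KaryotypeCalls:
    """Per-individual karyotype assignment for the structural variant."""

    labels: pd.Series  # individual -> AA/AB/BB/unassigned
    driver_loci: list[str]
    quality: pd.Series  # per-individual distance margin to cluster boundary
    mode: str  # "pc1" or "driver-score"
    orientation: dict[str, int] = field(default_factory=dict)
    # orientation maps driver locus -> allele index (0/1) that is the
    # "A" (arrangement-A) allele at that locus


@dataclass
class KaryotypeFrequencyTable:
    """A-allele frequency per (locus, karyotype), overall and per group."""

    table: pd.DataFrame  # rows=locus; MultiIndex columns (scope, karyotype)
    diagnostic: pd.Series  # locus -> bool (fits 1/0.5/0 within tol)
    tol: float


def _mean_het(gm: GenotypeMatrix, loci: list[str], rows: np.ndarray
              ) -> float:
    sub = gm.subset(loci=loci)
    d = sub.dosage()[rows]
    with np.errstate(invalid="ignore"):
        return float(np.nanmean(d == 1))


def _score_clusters(
    score: np.ndarray,
    gm: GenotypeMatrix,
    driver_loci: list[str],
    unassigned_margin: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """k=3 1-D k-means on a score; returns (labels 0/1/2 by center order,
    centers, margin series).  Label 1 is the middle cluster."""
    rng = np.random.default_rng(seed)
    centers, _ = _kmeans_1d(score, 3, n_init=50, rng=rng)
    d = np.abs(score[:, None] - centers[None, :])
    lab = d.argmin(axis=1)
    if len(np.unique(lab)) < 3:
        raise ClassificationRejected("k-means degenerated to <3 clusters")
    # margin to the nearest k-means boundary, in units of center spacing
    bounds = (centers[:-1] + centers[1:]) / 2
    dist_to_bound = np.min(np.abs(score[:, None] - bounds[None, :]), axis=1)
    spacing = np.min(np.diff(centers))
    margin = dist_to_bound / spacing
    unas = margin < unassigned_margin
    lab = lab.astype(object)
    lab[unas] = -1
    return lab, centers, pd.Series(margin)


def classify_karyotypes(
    pca: PcaResult | None,
    gm: GenotypeMatrix,
    driver_loci: list[str],
    metadata: SampleMetadata | None = None,
    mode: str = "auto",
    unassigned_margin: float = 0.05,
    het_margin: float = 0.15,
    seed: int = 0,
) -> KaryotypeCalls:
    """Assign AA / AB / BB karyotypes from the three-cluster PCA pattern.

    ``mode='pc1'`` clusters the first PC of the full panel; ``mode='driver-score'``
    clusters the mean oriented dosage over the driver loci (robust when
    background structure dominates PC1); ``'auto'`` tries PC1 first and
    falls back.  The middle cluster must exceed both flanks' mean
    driver-locus heterozygosity by at least ``het_margin``, otherwise
    classification is rejected.  Individuals
    within ``unassigned_margin`` x (cluster spacing) of a k-means boundary
    are left unassigned.

    The flanking cluster whose homokaryotypes are most frequent among
    Ocean-group individuals (when habitat metadata exist) is labeled AA;
    without habitat labels the cluster where locus 1's lexicographically
    first allele is fixed is AA.
    """
    if gm.n_individuals < 3:
        raise ValueError("need at least three individuals")
    if not driver_loci:
        raise ValueError("driver loci required")
    sub = gm.subset(loci=driver_loci)
    dos_drv = sub.dosage()

    def try_mode(m: str):
        if m == "pc1":
            if pca is None:
                raise ClassificationRejected("no PCA provided")
            score = pca.scores["PC1"].loc[gm.individuals].to_numpy()
        elif m == "driver-score":
            # orient each driver locus by correlation with total dosage
            centered = dos_drv - np.nanmean(dos_drv, axis=0)
            ref = np.nansum(centered, axis=1)
            sgn = np.array([
                1.0 if np.nansum(centered[:, j] * ref) >= 0 else -1.0
                for j in range(centered.shape[1])
            ])
            score = np.nanmean(centered * sgn, axis=1)
        else:
            raise ValueError(f"unknown mode {m!r}")
        lab, centers, margin = _score_clusters(
            score, gm, driver_loci, unassigned_margin, seed)
        het = np.nanmean(dos_drv == 1, axis=1)
        mean_het = [np.nanmean(het[np.asarray(lab == k, bool)])
                    for k in range(3)]
        flank_max = max(mean_het[0], mean_het[2])
        if np.nanargmax(mean_het) != 1 or mean_het[1] - flank_max < het_margin:
            raise ClassificationRejected(
                f"middle cluster lacks a clear driver-heterozygosity excess "
                f"(mean het by cluster: {np.round(mean_het, 3)})"
            )
        return lab, margin

    if mode == "auto":
        try:
            lab, margin = try_mode("pc1")
            used = "pc1"
        except ClassificationRejected:
            lab, margin = try_mode("driver-score")
            used = "driver-score"
    else:
        lab, margin = try_mode(mode)
        used = mode

    # decide which flank is AA
    lab = np.asarray(lab)
    flank_rows = {k: np.asarray(lab == k, bool) for k in (0, 2)}
    a_flank = None
    if metadata is not None and "group" in metadata.table.columns:
        grp = metadata.table.loc[gm.individuals, "group"].to_numpy()
        ocean_like = pd.Series(grp).str.lower().str.contains("ocean")
        if ocean_like.any():
            counts = {k: int((flank_rows[k] & ocean_like.to_numpy()).sum())
                      for k in (0, 2)}
            a_flank = max(counts, key=counts.get)
    if a_flank is None:
        # without habitat labels: the flank where locus 1's first allele is
        # (near-)fixed is AA
        j = 0
        freq0 = {
            k: np.nanmean(dos_drv[flank_rows[k], j] == 0) for k in (0, 2)
        }
        a_flank = max(freq0, key=freq0.get)
    name_of = {a_flank: "AA", 1: "AB", (2 if a_flank == 0 else 0): "BB"}
    labels = pd.Series(
        [name_of.get(x, "unassigned") if x != -1 else "unassigned"
         for x in lab],
        index=gm.individuals,
    )
    # orientation: allele fixed (majority) in the AA cluster is the A allele
    aa_rows = (labels == "AA").to_numpy()
    orientation = {}
    for j, locus in enumerate(driver_loci):
        col = dos_drv[aa_rows, j]
        col = col[~np.isnan(col)]
        # dosage counts B-allele copies: A allele is index 0 when AA cluster
        # is rich in dosage 0
        orientation[locus] = 0 if (col.size == 0 or col.mean() < 1.0) else 1
    return KaryotypeCalls(
        labels=labels,
        driver_loci=list(driver_loci),
        quality=pd.Series(np.asarray(margin), index=gm.individuals),
        mode=used,
        orientation=orientation,
    )


def karyotype_frequency_table(
    gm: GenotypeMatrix,
    calls: KaryotypeCalls,
    loci: list[str] | None = None,
    metadata: SampleMetadata | None = None,
    groups: list[str] | None = None,
    tol: float = 0.02,
) -> KaryotypeFrequencyTable:
    """A-allele frequency per karyotype per locus, per group and total.

    A locus is flagged diagnostic when its total-column frequencies fit the
    (1, 0.5, 0) signature within ``tol``.  Empty karyotype classes yield
    missing frequencies.
    """
    loci = loci or calls.driver_loci
    sub = gm.subset(loci=loci)
    dos = sub.dosage()
    lab = calls.labels.loc[gm.individuals]
    scopes: dict[str, np.ndarray] = {}
    if metadata is not None:
        grp = metadata.table.loc[gm.individuals, "group"]
        for g in (groups or [g for g in pd.unique(grp) if pd.notna(g)]):
            scopes[g] = (grp == g).to_numpy()
    scopes["Total"] = np.ones(gm.n_individuals, bool)
    cols = {}
    for scope, rows in scopes.items():
        for kt in ("AA", "AB", "BB"):
            sel = rows & (lab == kt).to_numpy()
            if sel.sum() == 0:
                cols[(scope, kt)] = np.full(len(loci), np.nan)
                continue
            vals = []
            for j, locus in enumerate(loci):
                col = dos[sel, j]
                col = col[~np.isnan(col)]
                if col.size == 0:
                    vals.append(np.nan)
                    continue
                fB = col.mean() / 2  # B-allele frequency
                a_idx = calls.orientation.get(locus, 0)
                vals.append(1 - fB if a_idx == 0 else fB)
            cols[(scope, kt)] = np.array(vals)
    table = pd.DataFrame(cols, index=loci)
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["scope", "karyotype"])
    tot = table["Total"]
    diag = (
        (tot["AA"] - 1).abs().le(tol)
        & (tot["AB"] - 0.5).abs().le(tol)
        & tot["BB"].abs().le(tol)
    ).fillna(False)
    return KaryotypeFrequencyTable(table=table, diagnostic=diag, tol=tol)


def haplogroup_frequencies_by_sample(
    calls: KaryotypeCalls, metadata: SampleMetadata, by: str = "site"
) -> pd.DataFrame:
    """Karyotype proportions per sample over assigned individuals."""
    lab = calls.labels
    keep = lab != "unassigned"
    df = pd.DataFrame({
        "karyotype": lab[keep],
        "sample": metadata.table.loc[lab.index[keep], by].to_numpy(),
    })
    out = (
        df.groupby("sample")["karyotype"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["AA", "AB", "BB"], fill_value=0.0)
    )
    return out


def assignment_memberships(
    gm: GenotypeMatrix,
    metadata: SampleMetadata,
    by: str = "group",
    leave_one_out: bool = True,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Genetic-assignment memberships: P(individual | group frequencies).

    Classical assignment test: each group's allele frequencies are estimated
    from its members (with a ``pseudocount`` added per allele, and the focal
    individual excluded from its home group when ``leave_one_out``); the
    membership of an individual in a group is its genotype likelihood under
    Hardy-Weinberg at those frequencies, normalised across groups.  Returns
    an individuals x groups DataFrame of memberships summing to 1.
    """
    labels = metadata.table.loc[gm.individuals, by]
    groups = [g for g in pd.unique(labels) if pd.notna(g)]
    dos = gm.dosage()  # B-allele counts
    nB = {}
    nT = {}
    for g in groups:
        sel = (labels == g).to_numpy()
        nB[g] = np.nansum(dos[sel], axis=0)
        nT[g] = 2 * np.sum(~np.isnan(dos[sel]), axis=0).astype(float)
    loglik = np.zeros((gm.n_individuals, len(groups)))
    for k, g in enumerate(groups):
        for i in range(gm.n_individuals):
            b, t = nB[g].copy(), nT[g].copy()
            if leave_one_out and labels.iloc[i] == g:
                row = dos[i]
                typed = ~np.isnan(row)
                b[typed] -= row[typed]
                t[typed] -= 2
            p = (b + pseudocount) / (t + 2 * pseudocount)
            row = dos[i]
            typed = ~np.isnan(row)
            d = row[typed]
            pt = p[typed]
            ll = np.where(
                d == 1, np.log(2 * pt * (1 - pt)),
                np.where(d == 2, 2 * np.log(pt), 2 * np.log(1 - pt)),
            )
            loglik[i, k] = ll.sum()
    loglik -= loglik.max(axis=1, keepdims=True)
    w = np.exp(loglik)
    w /= w.sum(axis=1, keepdims=True)
    return pd.DataFrame(w, index=gm.individuals, columns=groups)


def detect_migrants(
    memberships: pd.DataFrame,
    metadata: SampleMetadata,
    q_threshold: float = 0.7,
    calls: KaryotypeCalls | None = None,
) -> pd.DataFrame:
    """Flag individuals strongly assigned to a non-home habitat cluster.

    ``memberships``: individuals x clusters DataFrame whose columns are
    habitat-group names (e.g. DAPC posteriors or aligned admixture Q with
    clusters mapped to groups).  An individual is flagged when its
    membership in some cluster other than its home group exceeds
    ``q_threshold``.
    """
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    home = metadata.table.loc[memberships.index, "group"]
    rows = []
    for ind in memberships.index:
        q = memberships.loc[ind]
        best = q.idxmax()
        if best != home[ind] and q[best] > q_threshold:
            rows.append({
                "individual": ind,
                "home_site": metadata.table.loc[ind, "site"],
                "home_group": home[ind],
                "assigned_cluster": best,
                "membership": float(q[best]),
                "karyotype": (calls.labels[ind] if calls is not None
                              else None),
            })
    return pd.DataFrame(
        rows, columns=["individual", "home_site", "home_group",
                       "assigned_cluster", "membership", "karyotype"]
    )
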