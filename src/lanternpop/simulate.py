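"""Synthetic genotype datasets with hierarchical structure and an inversion.

The generator emulates a marine SNP-panel survey: individuals sampled from
sites nested in habitat groups, background loci differentiated under a
Balding-Nichols (beta-binomial) model, and a block of loci inside a
non-recombining chromosomal inversion.  Every individual carries a true
karyotype (AA / AB / BB, two arrangement copies); loci inside the block are
either perfectly diagnostic (allele A fixed on arrangement A, allele B fixed
on arrangement B) or partially diagnostic with stated per-arrangement allele
frequencies.  A :class:`TruthRecord` carries the ground truth so every
downstream stage can be tested against it.

Randomness is driven by a single seed expanded into one stream per stage
(ancestral frequencies, group frequencies, site frequencies, karyotypes,
haplotypes, genotypes, missingness, migrants), so e.g. adding loci does not
perturb which karyotype an individual receives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleMetadata, MISSING

__all__ = [
    "GroupConfig",
    "MigrantSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_dataset",
    "paper_like_preset",
]


@dataclass
class GroupConfig:
    """One habitat group: its sites, sample sizes and genetic parameters."""

    name: str
    sites: list[tuple[str, int]]  # (site name, individuals)
    karyotype_freqs: tuple[float, float, float]  # (fAA, fAB, fBB)
    fst_to_ancestral: float = 0.05  # Balding-Nichols divergence of the group
    maf_shrink: float = 1.0  # multiply ancestral minor-allele freq (diversity loss)


@dataclass
class MigrantSpec:
    """Plant ``count`` individuals with ``source_group`` genetics at ``site``."""

    source_group: str
    site: str
    count: int


@dataclass
class SimulationConfig:
    """Full description of a simulated survey.

    ``fst_within_group`` is the Balding-Nichols divergence of each site from
    its group's allele frequencies; ``fst_to_ancestral`` on each group sets
    between-group differentiation (pairwise FST between groups is roughly
    the combination of the two groups' divergences).
    """

    seed: int = 0
    groups: list[GroupConfig] = field(default_factory=list)
    n_background_loci: int = 100
    n_inversion_loci: int = 0
    n_diagnostic_loci: int = 0  # perfectly diagnostic subset of the block
    fst_within_group: float = 0.005
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    partial_arrA_freq_range: tuple[float, float] = (0.55, 1.0)
    partial_arrB_freq_range: tuple[float, float] = (0.0, 0.03)
    missing_rate: float = 0.0
    migrants: list[MigrantSpec] = field(default_factory=list)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for g in self.groups:
            s = sum(g.karyotype_freqs)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"karyotype frequencies of group {g.name!r} sum to {s}, not 1"
                )
            if not 0 <= g.fst_to_ancestral < 1:
                raise ValueError("fst_to_ancestral must be in [0, 1)")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.n_diagnostic_loci > self.n_inversion_loci:
            raise ValueError("n_diagnostic_loci cannot exceed n_inversion_loci")
        if min(self.n_background_loci, self.n_inversion_loci) < 0:
            raise ValueError("locus counts must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["groups"] = [GroupConfig(**g) if isinstance(g, dict) else g
                       for g in d.get("groups", [])]
        for g in d["groups"]:
            g.sites = [tuple(s) for s in g.sites]
            g.karyotype_freqs = tuple(g.karyotype_freqs)
        d["migrants"] = [MigrantSpec(**m) for m in d.get("migrants", [])]
        for k in ("ancestral_freq_range", "partial_arrA_freq_range",
                  "partial_arrB_freq_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated dataset."""

    karyotype: dict[str, str]  # individual -> AA/AB/BB
    locus_class: dict[str, str]  # background | inversion-diagnostic | inversion-partial
    group_allele_freqs: dict[str, list[float]]  # group -> B-allele freq per locus
    arrangement_freqs: dict[str, list[float]]  # "A"/"B" -> A-allele freq per inversion locus
    migrants: list[str] = field(default_factory=list)  # planted individual IDs

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    def driver_loci(self) -> list[str]:
        return [
            l for l, c in self.locus_class.items() if c.startswith("inversion")
        ]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float
                     ) -> np.ndarray:
    """Draw descendant allele frequencies from Balding-Nichols beta."""
    if fst <= 0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))


def _shrink_minor(p: np.ndarray, factor: float) -> np.ndarray:
    """Multiply the minor-allele frequency by ``factor`` (diversity loss)."""
    minor = np.minimum(p, 1 - p) * factor
    return np.where(p <= 0.5, minor, 1 - minor)


KARYOTYPES = ("AA", "AB", "BB")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleMetadata, TruthRecord]:
    """Simulate genotypes, metadata and ground truth from a config.

    Background loci: ancestral frequency per locus, then group frequency by
    Balding-Nichols at the group's ``fst_to_ancestral`` (with optional
    minor-allele shrinkage), then site frequency at ``fst_within_group``;
    genotypes are Hardy-Weinberg draws within site.  Inversion loci: the
    individual's karyotype is drawn from its group's (fAA, fAB, fBB), then
    each arrangement copy receives alleles from the arrangement's haplotype
    frequency profile.  Missing calls are masked uniformly at random.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (r_anc, r_group, r_site, r_karyo, r_hap, r_geno, r_miss, r_mig
     ) = [np.random.default_rng(s) for s in ss.spawn(8)]

    Lb, Li = config.n_background_loci, config.n_inversion_loci
    L = Lb + Li
    bg_loci = [f"bg_{j + 1:04d}" for j in range(Lb)]
    inv_loci = [f"inv_{j + 1:03d}" for j in range(Li)]
    loci = bg_loci + inv_loci

    # --- individuals / metadata -------------------------------------------
    inds: list[str] = []
    site_col: list[str] = []
    group_col: list[str] = []
    for g in config.groups:
        for site, n in g.sites:
            for k in range(n):
                inds.append(f"{site}_{k + 1:04d}")
                site_col.append(site)
                group_col.append(g.name)
    n_ind = len(inds)
    meta = SampleMetadata(
        pd.DataFrame({"site": site_col, "group": group_col},
                     index=pd.Index(inds))
    )

    # --- background allele frequencies ------------------------------------
    lo, hi = config.ancestral_freq_range
    p_anc = r_anc.uniform(lo, hi, size=Lb)
    group_freqs: dict[str, np.ndarray] = {}
    site_freqs: dict[str, np.ndarray] = {}
    for g in config.groups:
        pg = _balding_nichols(r_group, p_anc, g.fst_to_ancestral)
        pg = _shrink_minor(pg, g.maf_shrink)
        group_freqs[g.name] = pg
        for site, _n in g.sites:
            site_freqs[site] = np.clip(
                _balding_nichols(r_site, pg, config.fst_within_group),
                1e-6, 1 - 1e-6,
            )

    # --- inversion haplotype profiles -------------------------------------
    # A-allele frequency on each arrangement, per inversion locus
    qA = np.ones(Li)
    qB = np.zeros(Li)
    n_partial = Li - config.n_diagnostic_loci
    if n_partial > 0:
        qA[config.n_diagnostic_loci:] = r_hap.uniform(
            *config.partial_arrA_freq_range, size=n_partial)
        qB[config.n_diagnostic_loci:] = r_hap.uniform(
            *config.partial_arrB_freq_range, size=n_partial)

    # --- per-individual draws ---------------------------------------------
    calls = np.full((n_ind, L, 2), MISSING, dtype=np.int8)
    karyo: dict[str, str] = {}
    kf = {g.name: np.asarray(g.karyotype_freqs, float) /
          sum(g.karyotype_freqs) for g in config.groups}
    # karyotypes drawn per individual in a dedicated stream
    karyo_draws = {
        ind: KARYOTYPES[r_karyo.choice(3, p=kf[grp])]
        for ind, grp in zip(inds, group_col)
    }
    # background genotypes: HWE within site; store B-allele (index 1) counts
    for i, ind in enumerate(inds):
        p_site = site_freqs[site_col[i]]
        dos = r_geno.binomial(2, p_site)  # count of B allele at bg loci
        calls[i, :Lb, 0] = dos == 2
        calls[i, :Lb, 1] = dos >= 1
        kt = karyo_draws[ind]
        karyo[ind] = kt
        if Li:
            n_arr_a = {"AA": 2, "AB": 1, "BB": 0}[kt]
            # each copy: allele A (=0) with prob q of its arrangement
            copy_q = np.empty((2, Li))
            copy_q[0] = qA if n_arr_a >= 1 else qB
            copy_q[1] = qA if n_arr_a == 2 else qB
            hap = (r_geno.random((2, Li)) >= copy_q).astype(np.int8)  # 1 = B allele
            hap = np.sort(hap, axis=0)  # unordered pair
            calls[i, Lb:, 0] = hap[0]
            calls[i, Lb:, 1] = hap[1]

    # --- migrants ----------------------------------------------------------
    migrant_ids: list[str] = []
    gf = {g.name: g for g in config.groups}
    for spec in config.migrants:
        rows = [i for i, s in enumerate(site_col) if s == spec.site]
        if len(rows) < spec.count:
            raise ValueError(f"site {spec.site!r} too small for migrant spec")
        chosen = r_mig.choice(rows, size=spec.count, replace=False)
        src = gf[spec.source_group]
        p_src = group_freqs[spec.source_group]
        for i in chosen:
            dos = r_mig.binomial(2, p_src)
            calls[i, :Lb, 0] = (dos == 2)
            calls[i, :Lb, 1] = (dos >= 1)
            kt = KARYOTYPES[r_mig.choice(3, p=kf[spec.source_group])]
            karyo[inds[i]] = kt
            if Li:
                n_arr_a = {"AA": 2, "AB": 1, "BB": 0}[kt]
                copy_q = np.empty((2, Li))
                copy_q[0] = qA if n_arr_a >= 1 else qB
                copy_q[1] = qA if n_arr_a == 2 else qB
                hap = (r_mig.random((2, Li)) >= copy_q).astype(np.int8)
                hap = np.sort(hap, axis=0)
                calls[i, Lb:, 0] = hap[0]
                calls[i, Lb:, 1] = hap[1]
            migrant_ids.append(inds[i])

    # --- missingness --------------------------------------------------------
    if config.missing_rate > 0:
        mask = r_miss.random((n_ind, L)) < config.missing_rate
        calls[mask] = MISSING

    gm = GenotypeMatrix(
        individuals=inds,
        loci=loci,
        calls=calls,
        locus_alleles=[("A", "B")] * L,
    )
    locus_class = {l: "background" for l in bg_loci}
    for j, l in enumerate(inv_loci):
        locus_class[l] = ("inversion-diagnostic"
                          if j < config.n_diagnostic_loci
                          else "inversion-partial")
    truth = TruthRecord(
        karyotype=karyo,
        locus_class=locus_class,
        group_allele_freqs={k: list(v) for k, v in group_freqs.items()},
        arrangement_freqs={"A": list(qA), "B": list(qB)},
        migrants=migrant_ids,
    )
    return gm, meta, truth


# ---------------------------------------------------------------------------
# Paper-like preset
# ---------------------------------------------------------------------------

# 16 sites in three habitats with retained sample sizes from the survey's
# summary table; coordinates are decimal degrees.
_PRESET_SITES = {
    "Ocean": [
        ("BaffinBay", 43, 65.93, -58.12, 2021),
        ("Labrador", 37, 61.43, -60.65, 2022),
        ("NorwegianSea", 36, 63.65, 4.10, 2020),
        ("SIceland", 87, 62.19, -18.42, 2020),
        ("Atlantic59N", 189, 59.58, -15.68, 2020),
        ("BayOfBiscay", 81, 46.71, -8.69, 2020),
        ("NPortugal", 97, 41.53, -12.92, 2020),
    ],
    "Fjords": [
        ("Osterfjorden", 156, 60.62, 5.52, 2018),
        ("Korsfjorden", 25, 60.16, 5.09, 2017),
        ("Bjornafjorden", 210, 60.12, 5.62, 2018),
        ("Hardangerfjorden", 40, 60.03, 5.93, 2018),
        ("Boknafjorden", 89, 59.20, 5.61, 2018),
    ],
    "Mediterranean": [
        ("Alboran", 24, 36.00, -3.96, 2020),
        ("Balears", 51, 38.50, 2.50, 2020),
        ("IonianSea", 63, 38.09, 22.74, 2019),
        ("AegeanSea", 60, 37.60, 23.26, 2019),
    ],
}

# Karyotype (arrangement) frequencies per habitat.  The Fjord class
# frequencies follow near-Mendelian proportions; the Ocean AA fraction is
# 0.567 with the remainder split between AB and BB in Hardy-Weinberg ratio
# (arrangement frequency 0.753); the Mediterranean is fixed for BB.
_PRESET_KARYO = {
    "Ocean": (0.567, 0.372, 0.061),
    "Fjords": (0.185, 0.537, 0.278),
    "Mediterranean": (0.0, 0.0, 1.0),
}

# Balding-Nichols divergence of each habitat from the ancestral pool plus
# Mediterranean minor-allele shrinkage (halves its background heterozygosity
# relative to the other habitats).
_PRESET_FST = {"Ocean": 0.045, "Fjords": 0.075, "Mediterranean": 0.06}
_PRESET_SHRINK = {"Ocean": 1.0, "Fjords": 1.0, "Mediterranean": 0.45}


def paper_like_preset(
    seed: int = 0,
    scale: float = 1.0,
    n_per_site: int | None = None,
    missing_rate: float = 0.0,
    migrants: Sequence[MigrantSpec] = (),
) -> SimulationConfig:
    """Survey-scale preset: 16 sites in 3 habitats, 109 + 12 loci.

    ``scale`` multiplies every site's sample size (min 2); ``n_per_site``
    overrides all sizes with a constant.  The inversion block has 12 loci of
    which 5 are perfectly diagnostic.
    """
    groups = []
    for name, sites in _PRESET_SITES.items():
        rows = []
        for site, n, *_ in sites:
            m = n_per_site if n_per_site is not None else max(2, round(n * scale))
            rows.append((site, m))
        groups.append(
            GroupConfig(
                name=name,
                sites=rows,
                karyotype_freqs=_PRESET_KARYO[name],
                fst_to_ancestral=_PRESET_FST[name],
                maf_shrink=_PRESET_SHRINK[name],
            )
        )
    return SimulationConfig(
        seed=seed,
        groups=groups,
        n_background_loci=109,
        n_inversion_loci=12,
        n_diagnostic_loci=5,
        fst_within_group=0.004,
        ancestral_freq_range=(0.05, 0.30),
        partial_arrA_freq_range=(0.70, 1.0),
        missing_rate=missing_rate,
        migrants=list(migrants),
    )


def migrant_study_preset(seed: int = 0, scale: float = 0.25) -> SimulationConfig:
    """Two-habitat (Ocean + Fjords) preset for migrant-detection studies.

    Background-only panel of 84 loci (the size of an LD-pruned panel) with
    group divergences set so pairwise Ocean-Fjords FST lands mid-range of
    the survey's observed between-habitat values (~0.15), and five Ocean
    individuals planted in fjord sites (two in Osterfjorden, one each in
    Bjornafjorden, Boknafjorden and Korsfjorden).
    """
    spec = [
        MigrantSpec("Ocean", "Bjornafjorden", 1),
        MigrantSpec("Ocean", "Boknafjorden", 1),
        MigrantSpec("Ocean", "Korsfjorden", 1),
        MigrantSpec("Ocean", "Osterfjorden", 2),
    ]
    fst = {"Ocean": 0.14, "Fjords": 0.20}
    groups = []
    for name in ("Ocean", "Fjords"):
        rows = [(s[0], max(4, round(s[1] * scale)))
                for s in _PRESET_SITES[name]]
        groups.append(GroupConfig(name, rows, (1.0, 0.0, 0.0),
                                  fst_to_ancestral=fst[name]))
    return SimulationConfig(
        seed=seed,
        groups=groups,
        n_background_loci=84,
        fst_within_group=0.004,
        ancestral_freq_range=(0.05, 0.30),
        migrants=spec,
    )


def preset_metadata(meta: SampleMetadata) -> SampleMetadata:
    """Attach preset coordinates/years to simulated metadata (in place copy)."""
    coords = {s[0]: s[2:] for sites in _PRESET_SITES.values() for s in sites}
    t = meta.table.copy()
    for site, (lat, lon, year) in coords.items():
        sel = t["site"] == site
        t.loc[sel, ["latitude", "longitude", "year"]] = (lat, lon, year)
    return SampleMetadata(t)
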