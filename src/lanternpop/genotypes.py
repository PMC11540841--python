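"""Core genotype data model, Genepop/table I/O, and marker/individual QC.

The central container is :class:`GenotypeMatrix`: diploid, biallelic calls
for a panel of SNP loci scored on a set of individuals.  Calls are stored as
unordered allele pairs (index 0/1 into the locus's two allele codes, -1 for
missing); a derived *dosage* view (count of the B allele, NaN when missing)
feeds PCA, F-statistics and AMOVA.  Sample metadata (site, habitat group,
coordinates, year) live in a :class:`SampleMetadata` table keyed by
individual ID.

Positions in files are 1-based inclusive; internal coordinates are 0-based.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SampleMetadata",
    "VariantRecord",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "write_metadata",
    "apply_locus_and_individual_qc",
    "filter_candidate_snps",
    "read_variant_table",
]

MISSING = -1


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class GenotypeValidationError(ValueError):
    """Raised when parsed genotype content violates the data model."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid biallelic calls with missing values.

    Parameters
    ----------
    individuals
        Ordered unique individual IDs (length ``n``).
    loci
        Ordered unique locus IDs (length ``L``).
    calls
        ``(n, L, 2)`` int8 array; entries are 0 (A allele), 1 (B allele) or
        -1 (missing).  Both entries of a call are missing together.
    locus_alleles
        Per-locus pair of allele code strings ``(A, B)``.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    locus_alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci"
            )
        if len(set(self.individuals)) != n:
            raise GenotypeValidationError("duplicate individual IDs")
        if len(set(self.loci)) != L:
            raise GenotypeValidationError("duplicate locus IDs")
        if len(self.locus_alleles) != L:
            raise GenotypeValidationError("locus_alleles length mismatch")
        bad = ~np.isin(self.calls, (-1, 0, 1))
        if bad.any():
            raise GenotypeValidationError("calls must be in {-1, 0, 1}")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise GenotypeValidationError("half-missing calls are not allowed")

    # ---- basic properties -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask, True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def dosage(self) -> np.ndarray:
        """``(n, L)`` float array counting B alleles (0/1/2), NaN if missing."""
        d = self.calls.sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    def subset(
        self,
        individuals: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given IDs (order preserved)."""
        ind = list(individuals) if individuals is not None else self.individuals
        loc = list(loci) if loci is not None else self.loci
        irow = {x: i for i, x in enumerate(self.individuals)}
        icol = {x: i for i, x in enumerate(self.loci)}
        try:
            ri = [irow[x] for x in ind]
            ci = [icol[x] for x in loc]
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown ID {e.args[0]!r}") from e
        return GenotypeMatrix(
            individuals=list(ind),
            loci=list(loc),
            calls=self.calls[np.ix_(ri, ci)],
            locus_alleles=[self.locus_alleles[i] for i in ci],
        )

    def allele_counts(self) -> np.ndarray:
        """Per-locus counts of (A, B) alleles over non-missing calls: ``(L, 2)``."""
        out = np.zeros((self.n_loci, 2), dtype=int)
        for a in (0, 1):
            out[:, a] = (self.calls == a).sum(axis=(0, 2))
        return out


@dataclass
class SampleMetadata:
    """Per-individual sampling metadata.

    Wraps a DataFrame indexed by individual ID with columns
    ``site, group, latitude, longitude, year, depth`` (the last four may be
    NaN).  Habitat group must be a function of site.
    """

    table: pd.DataFrame

    COLUMNS = ("site", "group", "latitude", "longitude", "year", "depth")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for c in self.COLUMNS:
            if c not in t.columns:
                t[c] = np.nan
        self.table = t[list(self.COLUMNS)]
        if self.table.index.has_duplicates:
            raise GenotypeValidationError("duplicate individual IDs in metadata")
        by_site = self.table.groupby("site")["group"].nunique()
        if (by_site > 1).any():
            bad = by_site[by_site > 1].index.tolist()
            raise GenotypeValidationError(
                f"habitat group must be a function of site; conflicting: {bad}"
            )

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)

    def site_of(self) -> pd.Series:
        return self.table["site"]

    def group_of(self) -> pd.Series:
        return self.table["group"]

    def sites(self) -> list[str]:
        return list(pd.unique(self.table["site"]))

    def groups(self) -> list[str]:
        return list(pd.unique(self.table["group"]))

    def group_of_site(self) -> dict[str, str]:
        return dict(
            self.table.drop_duplicates("site").set_index("site")["group"]
        )

    def subset(self, individuals: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(individuals)].copy())

    def check_against(self, gm: GenotypeMatrix) -> None:
        missing = set(gm.individuals) - set(self.table.index)
        if missing:
            raise GenotypeValidationError(
                f"{len(missing)} individuals lack metadata, e.g. {sorted(missing)[:3]}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One called variant site from the pool-seq discovery stage."""

    contig: str
    position: int  # 1-based
    qual: float
    coverages: tuple[float, ...]  # per-pool depth
    variant_class: str  # "SNP" or "indel"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if any(c < 0 for c in self.coverages):
            raise ValueError("coverages must be >= 0")
        if self.variant_class not in ("SNP", "indel"):
            raise ValueError("variant_class must be 'SNP' or 'indel'")


@dataclass
class QCReport:
    """Record of what the QC filters removed and why."""

    loci_dropped_missing: list[str] = field(default_factory=list)
    loci_dropped_fixed: list[str] = field(default_factory=list)
    individuals_dropped: list[str] = field(default_factory=list)
    max_locus_missing: float = 0.25
    max_major_allele_freq: float = 0.95
    max_ind_missing: float = 0.25
    n_loci_before: int = 0
    n_loci_after: int = 0
    n_individuals_before: int = 0
    n_individuals_after: int = 0

    def validate(self) -> None:
        if (
            len(self.loci_dropped_missing)
            + len(self.loci_dropped_fixed)
            + self.n_loci_after
            != self.n_loci_before
        ):
            raise GenotypeValidationError("locus QC bookkeeping inconsistent")
        if (
            len(self.individuals_dropped) + self.n_individuals_after
            != self.n_individuals_before
        ):
            raise GenotypeValidationError("individual QC bookkeeping inconsistent")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    def summary(self) -> str:
        return (
            f"loci: {self.n_loci_before} -> {self.n_loci_after} "
            f"({len(self.loci_dropped_missing)} missingness, "
            f"{len(self.loci_dropped_fixed)} near-fixed); "
            f"individuals: {self.n_individuals_before} -> "
            f"{self.n_individuals_after} "
            f"({len(self.individuals_dropped)} dropped)"
        )


class EmptyResultError(ValueError):
    """Raised when a filter removes everything."""


# ---------------------------------------------------------------------------
# Genepop / table I/O
# ---------------------------------------------------------------------------


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    format: str = "genepop",
    metadata: SampleMetadata | None = None,
    title: str = "lanternpop export",
) -> None:
    """Write a GenotypeMatrix as a Genepop file or a tab-separated table.

    Genepop: one POP block per site (metadata required; without metadata all
    individuals form one POP).  Allele 1 = A allele, allele 2 = B allele,
    00/000 = missing.  Table format: rows = individuals, columns = loci,
    calls written as ``A/B`` using the locus allele codes, ``./.`` missing.
    """
    path = Path(path)
    if format == "genepop":
        lines = [title]
        lines.extend(gm.loci)
        if metadata is not None:
            metadata.check_against(gm)
            site = metadata.site_of()
            order = sorted(set(site[i] for i in gm.individuals), key=str)
            blocks = [
                [i for i in gm.individuals if site[i] == s] for s in order
            ]
        else:
            blocks = [list(gm.individuals)]
        idx = {x: i for i, x in enumerate(gm.individuals)}
        for block in blocks:
            lines.append("POP")
            for ind in block:
                row = gm.calls[idx[ind]]
                fields = []
                for j in range(gm.n_loci):
                    a, b = row[j]
                    if a == MISSING:
                        fields.append("0000")
                    else:
                        fields.append(f"{a + 1:02d}{b + 1:02d}")
                lines.append(f"{ind} ,  " + " ".join(fields))
        path.write_text("\n".join(lines) + "\n")
    elif format == "table":
        dos = gm.calls
        rows = {}
        for i, ind in enumerate(gm.individuals):
            vals = []
            for j in range(gm.n_loci):
                a, b = dos[i, j]
                if a == MISSING:
                    vals.append("./.")
                else:
                    al = gm.locus_alleles[j]
                    vals.append(f"{al[a]}/{al[b]}")
            rows[ind] = vals
        df = pd.DataFrame.from_dict(rows, orient="index", columns=gm.loci)
        df.index.name = "individual"
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def _parse_genepop(path: Path) -> tuple[GenotypeMatrix, SampleMetadata]:
    text = path.read_text().splitlines()
    if not text:
        raise GenotypeParseError(f"{path}: empty file")
    # header line is a title; loci follow until the first POP
    loci: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().upper() != "POP":
        line = text[i].strip()
        if line:
            # loci may be comma-separated on one line
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        i += 1
    if i == len(text):
        raise GenotypeParseError(f"{path}: no POP block found")
    inds: list[str] = []
    sites: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    pop_no = 0
    while i < len(text):
        if text[i].strip().upper() == "POP":
            pop_no += 1
            i += 1
            continue
        line = text[i].strip()
        i += 1
        if not line:
            continue
        if "," not in line:
            raise GenotypeParseError(f"{path}:{i}: expected 'id , genotypes'")
        name, geno = line.split(",", 1)
        name = name.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeParseError(
                f"{path}:{i}: {len(tokens)} genotype fields for {len(loci)} loci"
            )
        row = []
        for tok in tokens:
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise GenotypeParseError(
                    f"{path}:{i}: malformed genotype field {tok!r}"
                )
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) != (b == 0):
                raise GenotypeParseError(
                    f"{path}:{i}: half-missing genotype {tok!r}"
                )
            if a > 2 or b > 2:
                raise GenotypeValidationError(
                    f"{path}:{i}: allele code > 2 in {tok!r}; only biallelic "
                    "loci are supported"
                )
            row.append((MISSING, MISSING) if a == 0 else (a - 1, b - 1))
        inds.append(name)
        sites.append(f"POP{pop_no}")
        calls.append(row)
    arr = np.array(calls, dtype=np.int8)
    arr.sort(axis=2)  # canonical unordered pair (missing already equal)
    gm = GenotypeMatrix(
        individuals=inds,
        loci=loci,
        calls=arr,
        locus_alleles=[("1", "2")] * len(loci),
    )
    meta = SampleMetadata(
        pd.DataFrame({"site": sites, "group": sites}, index=pd.Index(inds))
    )
    return gm, meta


def _parse_table(path: Path) -> tuple[GenotypeMatrix, SampleMetadata]:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    loci = list(df.columns)
    inds = [str(x) for x in df.index]
    n, L = len(inds), len(loci)
    calls = np.full((n, L, 2), MISSING, dtype=np.int8)
    alleles: list[tuple[str, str]] = []
    missing_codes = {"./.", "00", "000", "NA", "", "nan", "0000"}
    for j, loc in enumerate(loci):
        col = df[loc].astype(str).str.strip()
        seen: list[str] = []
        parsed: list[tuple[str, str] | None] = []
        for i, v in enumerate(col):
            if v in missing_codes:
                parsed.append(None)
                continue
            if "/" in v:
                parts = v.split("/")
            elif len(v) == 2:
                parts = [v[0], v[1]]
            else:
                raise GenotypeParseError(
                    f"{path}: row {inds[i]!r} locus {loc!r}: bad call {v!r}"
                )
            if len(parts) != 2:
                raise GenotypeValidationError(
                    f"{path}: row {inds[i]!r} locus {loc!r}: non-diploid "
                    f"call {v!r}"
                )
            for p in parts:
                if p not in seen:
                    seen.append(p)
            parsed.append((parts[0], parts[1]))
        if len(seen) > 2:
            raise GenotypeValidationError(
                f"{path}: locus {loc!r} has >2 alleles: {seen}"
            )
        seen_sorted = sorted(seen) if seen else ["A", "B"]
        if len(seen_sorted) == 1:
            seen_sorted.append(seen_sorted[0] + "_alt")
        code = {a: k for k, a in enumerate(seen_sorted)}
        for i, pr in enumerate(parsed):
            if pr is None:
                continue
            a, b = sorted((code[pr[0]], code[pr[1]]))
            calls[i, j] = (a, b)
        alleles.append((seen_sorted[0], seen_sorted[1]))
    gm = GenotypeMatrix(inds, loci, calls, alleles)
    meta = SampleMetadata(
        pd.DataFrame({"site": "all", "group": "all"}, index=pd.Index(inds))
    )
    return gm, meta


def read_genotypes(
    path: str | Path, format: str = "genepop"
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Read genotypes from a Genepop file or a tab-separated call table.

    For Genepop input, POP blocks become sites ``POP1..POPk`` (attach real
    site/group names afterwards via :func:`read_metadata`).  For table input
    all individuals are placed in a single placeholder site.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genepop":
        return _parse_genepop(path)
    if format == "table":
        return _parse_table(path)
    raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the tab-separated sidecar metadata table (index = individual)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    t = meta.table.copy()
    t.index.name = "individual"
    t.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def apply_locus_and_individual_qc(
    gm: GenotypeMatrix,
    metadata: SampleMetadata | None = None,
    max_locus_missing: float = 0.25,
    max_major_allele_freq: float = 0.95,
    max_ind_missing: float = 0.25,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop poorly scored loci and individuals.

    Order of operations: (1) loci with missing fraction >= ``max_locus_missing``;
    (2) loci whose major-allele frequency is >= ``max_major_allele_freq`` in
    *every* sample (near-fixed panel-wide); (3) individuals with missing
    fraction strictly > ``max_ind_missing`` over the retained loci.  The
    locus rule is inclusive (>=) while the individual rule is strict (>),
    mirroring the two acceptance phrasings used when the panel was curated.

    When ``metadata`` is None all individuals form a single sample for the
    near-fixation rule.
    """
    for t in (max_locus_missing, max_major_allele_freq, max_ind_missing):
        if not 0 < t <= 1:
            raise ValueError("thresholds must be in (0, 1]")
    report = QCReport(
        max_locus_missing=max_locus_missing,
        max_major_allele_freq=max_major_allele_freq,
        max_ind_missing=max_ind_missing,
        n_loci_before=gm.n_loci,
        n_individuals_before=gm.n_individuals,
    )
    miss = gm.missing_mask()
    frac_missing = miss.mean(axis=0)
    drop_miss = frac_missing >= max_locus_missing
    report.loci_dropped_missing = [
        l for l, d in zip(gm.loci, drop_miss) if d
    ]

    if metadata is not None:
        metadata.check_against(gm)
        site = metadata.site_of()
        groups_idx = [
            [gm.individuals.index(i) for i in gm.individuals if site[i] == s]
            for s in sorted(set(site[i] for i in gm.individuals), key=str)
        ]
    else:
        groups_idx = [list(range(gm.n_individuals))]
    near_fixed = np.ones(gm.n_loci, dtype=bool)
    for rows in groups_idx:
        sub = gm.calls[rows]
        nA = (sub == 0).sum(axis=(0, 2)).astype(float)
        nB = (sub == 1).sum(axis=(0, 2)).astype(float)
        tot = nA + nB
        with np.errstate(invalid="ignore", divide="ignore"):
            major = np.where(tot > 0, np.maximum(nA, nB) / tot, 1.0)
        near_fixed &= major >= max_major_allele_freq
    near_fixed &= ~drop_miss  # count each locus once
    report.loci_dropped_fixed = [l for l, d in zip(gm.loci, near_fixed) if d]

    keep_loci = [
        l
        for l, d1, d2 in zip(gm.loci, drop_miss, near_fixed)
        if not (d1 or d2)
    ]
    gm2 = gm.subset(loci=keep_loci)
    if gm2.n_loci == 0:
        raise EmptyResultError("all loci removed by QC")

    ind_missing = gm2.missing_mask().mean(axis=1)
    keep_ind = [
        i for i, f in zip(gm2.individuals, ind_missing) if f <= max_ind_missing
    ]
    report.individuals_dropped = [
        i for i, f in zip(gm2.individuals, ind_missing) if f > max_ind_missing
    ]
    gm3 = gm2.subset(individuals=keep_ind)
    if gm3.n_individuals == 0:
        raise EmptyResultError("all individuals removed by QC")

    report.n_loci_after = gm3.n_loci
    report.n_individuals_after = gm3.n_individuals
    report.validate()
    return gm3, report


# ---------------------------------------------------------------------------
# Candidate-SNP filtering (pool-seq discovery stage)
# ---------------------------------------------------------------------------


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a minimal VCF-style variant table.

    Tab-separated with header ``CHROM POS QUAL DP TYPE``; ``DP`` is a
    comma-separated list of per-pool depths, ``TYPE`` is ``SNP`` or ``indel``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    recs = []
    for _, row in df.iterrows():
        recs.append(
            VariantRecord(
                contig=str(row["CHROM"]),
                position=int(row["POS"]),
                qual=float(row["QUAL"]),
                coverages=tuple(float(x) for x in str(row["DP"]).split(",")),
                variant_class=str(row["TYPE"]),
            )
        )
    return recs


def filter_candidate_snps(
    records: Sequence[VariantRecord],
    qual_min: float = 600.0,
    cov_min: float = 10.0,
    cov_max: float = 50.0,
    min_spacing_bp: int = 200,
    one_per_contig: bool = True,
) -> list[VariantRecord]:
    """Apply the candidate-SNP design filters to called variants.

    Retains SNPs with QUAL strictly greater than ``qual_min``, every pool
    coverage within ``[cov_min, cov_max]``, and distance at least
    ``min_spacing_bp`` to *any* other variant (SNP or indel) on the same
    contig.  If ``one_per_contig``, a single SNP is kept per contig: highest
    QUAL, ties broken by lowest position.
    """
    by_contig: dict[str, list[VariantRecord]] = {}
    for r in sorted(records, key=lambda r: (r.contig, r.position)):
        by_contig.setdefault(r.contig, []).append(r)
    retained: list[VariantRecord] = []
    for contig, recs in by_contig.items():
        pos = np.array([r.position for r in recs])
        keep_here: list[VariantRecord] = []
        for k, r in enumerate(recs):
            if r.variant_class != "SNP":
                continue
            if not (r.qual > qual_min):
                continue
            if any(c < cov_min or c > cov_max for c in r.coverages):
                continue
            d = np.abs(pos - r.position)
            d[k] = min_spacing_bp  # ignore self
            if (d < min_spacing_bp).any():
                continue
            keep_here.append(r)
        if one_per_contig and keep_here:
            keep_here = [
                max(keep_here, key=lambda r: (r.qual, -r.position))
            ]
        retained.extend(keep_here)
    retained.sort(key=lambda r: (r.contig, r.position))
    return retained
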