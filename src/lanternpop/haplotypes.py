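"""Multilocus haplotype reconstruction by EM and haplotype-level
differentiation.

For a small set of tightly linked biallelic loci (a non-recombining
inversion block), population haplotype frequencies are estimated by the
classical multinomial EM: each individual's unordered multilocus genotype
is a sum over the phases compatible with it, and the E-step weighs phases
by the product of current haplotype frequencies (x2 for heterozygous
pairs).  Per-individual phases are the maximum-posterior pair.  Missing
calls are handled by enumerating all allele completions, giving
posterior-weighted rather than imputed phases.

Haplotype-level differentiation treats each individual's phase pair as a
genotype at one multi-allelic super-locus and reuses the Weir-Cockerham and
AMOVA machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleMetadata, MISSING
from .differentiation import FstMatrix, AmovaResult, amova, weir_cockerham_theta

__all__ = [
    "HaplotypeSet",
    "em_phase_haplotypes",
    "haplotype_differentiation",
    "haplotype_fst_pairwise",
]


@dataclass
class HaplotypeSet:
    """Estimated haplotype frequencies and per-individual best phases."""

    loci: list[str]
    haplotypes: list[str]  # allele strings over the loci, e.g. "ABBAB"
    frequencies: np.ndarray  # aligned with ``haplotypes``, sums to 1
    phases: pd.DataFrame  # individual -> hap1, hap2, posterior
    log_likelihood: float

    def frequency_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "haplotype": self.haplotypes,
            "frequency": self.frequencies,
        }).sort_values("frequency", ascending=False, ignore_index=True)


def _hap_string(bits: tuple[int, ...], alleles: list[tuple[str, str]]) -> str:
    return "".join(alleles[j][b] for j, b in enumerate(bits))


def _compatible_pairs(geno: np.ndarray) -> list[tuple[int, int]]:
    """All unordered haplotype pairs compatible with one genotype row.

    ``geno``: (L, 2) allele pairs with -1 missing.  Haplotypes are encoded
    as integers (bit j = allele at locus j).
    """
    L = geno.shape[0]
    per_locus: list[list[tuple[int, int]]] = []
    for j in range(L):
        a, b = geno[j]
        if a == MISSING:
            per_locus.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif a == b:
            per_locus.append([(a, a)])
        else:
            per_locus.append([(0, 1), (1, 0)])
    pairs = set()
    for combo in product(*per_locus):
        h1 = h2 = 0
        for j, (x, y) in enumerate(combo):
            h1 |= x << j
            h2 |= y << j
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


def em_phase_haplotypes(
    gm: GenotypeMatrix,
    loci: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    restarts: int = 10,
    seed: int = 0,
    prune_rare: bool = True,
) -> HaplotypeSet:
    """EM estimation of haplotype frequencies from unphased genotypes.

    The likelihood is multinomial over the 2^L haplotype space; convergence
    when the largest frequency change drops below ``tol``; the best of
    ``restarts`` random initialisations (plus one uniform) by final
    log-likelihood is returned.  Haplotypes with estimated frequency below
    1/(4n) are pruned and the EM re-run once to stabilise the count of
    observed haplotypes.
    """
    sub = gm.subset(loci=loci) if loci is not None else gm
    L = sub.n_loci
    if L < 1 or L > 16:
        raise ValueError("haplotype EM supports 1..16 loci")
    counts = sub.allele_counts()
    if (counts.min(axis=1) == counts.sum(axis=1)).any():
        pass  # monomorphic loci are allowed but uninformative
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("locus with no typed calls")
    poly = (counts > 0).all(axis=1)
    if not poly.any():
        raise ValueError("no polymorphic locus among the selected loci")
    pair_lists = [_compatible_pairs(sub.calls[i]) for i in
                  range(sub.n_individuals)]
    H = 1 << L
    rng = np.random.default_rng(seed)

    def run_em(f0: np.ndarray, allowed: np.ndarray) -> tuple[np.ndarray, float]:
        f = f0.copy()
        f[~allowed] = 0.0
        f /= f.sum()
        ll = -np.inf
        for _ in range(max_iter):
            new = np.zeros(H)
            ll_new = 0.0
            for pl in pair_lists:
                ws, idx = [], []
                for h1, h2 in pl:
                    w = f[h1] * f[h2] * (2.0 if h1 != h2 else 1.0)
                    if w > 0:
                        ws.append(w)
                        idx.append((h1, h2))
                tot = sum(ws)
                if tot <= 0:
                    continue
                ll_new += np.log(tot)
                for w, (h1, h2) in zip(ws, idx):
                    new[h1] += w / tot
                    new[h2] += w / tot
            s = new.sum()
            if s <= 0:
                break
            new /= s
            if np.max(np.abs(new - f)) < tol:
                f = new
                ll = ll_new
                break
            f = new
            ll = ll_new
        return f, ll

    allowed = np.zeros(H, bool)
    for pl in pair_lists:
        for h1, h2 in pl:
            allowed[h1] = allowed[h2] = True
    # uniform plus random initialisations restricted to allowed haplotypes
    inits = [np.full(H, 1.0 / H)]
    for _ in range(restarts):
        v = np.zeros(H)
        v[allowed] = rng.dirichlet(np.ones(int(allowed.sum())))
        inits.append(v + 1e-12)
    best_f, best_ll = None, -np.inf
    for f0 in inits:
        f, ll = run_em(f0, allowed)
        if ll > best_ll:
            best_f, best_ll = f, ll
    f = best_f
    if prune_rare:
        floor = 1.0 / (4 * sub.n_individuals)
        keep = f >= floor
        if keep.sum() >= 1 and keep.sum() < allowed.sum():
            f2, ll2 = run_em(np.where(keep, f, 0.0) + 1e-15 * keep, keep)
            if np.isfinite(ll2):
                f, best_ll = f2, ll2
    # best phases
    rows = []
    for ind, pl in zip(sub.individuals, pair_lists):
        ws = np.array([
            f[h1] * f[h2] * (2.0 if h1 != h2 else 1.0) for h1, h2 in pl
        ])
        tot = ws.sum()
        if tot <= 0:
            rows.append((ind, None, None, np.nan))
            continue
        k = int(ws.argmax())
        rows.append((ind, pl[k][0], pl[k][1], float(ws[k] / tot)))
    hap_ids = np.where(f > 0)[0]
    bits = [tuple((h >> j) & 1 for j in range(L)) for h in hap_ids]
    strings = {int(h): _hap_string(b, sub.locus_alleles)
               for h, b in zip(hap_ids, bits)}
    phases = pd.DataFrame(
        rows, columns=["individual", "hap1", "hap2", "posterior"]
    ).set_index("individual")
    for c in ("hap1", "hap2"):
        phases[c] = phases[c].map(
            lambda h: strings.get(int(h)) if pd.notna(h) else None)
    return HaplotypeSet(
        loci=list(sub.loci),
        haplotypes=[strings[int(h)] for h in hap_ids],
        frequencies=f[hap_ids] / f[hap_ids].sum(),
        phases=phases,
        log_likelihood=float(best_ll),
    )


# ---------------------------------------------------------------------------
# Haplotype-level differentiation
# ---------------------------------------------------------------------------


def _super_locus(hapset: HaplotypeSet) -> tuple[np.ndarray, list[str]]:
    """Encode phase pairs as a (n, 1, 2) multi-allelic call array."""
    cats = {h: k for k, h in enumerate(hapset.haplotypes)}
    inds, rows = [], []
    for ind, row in hapset.phases.iterrows():
        if row["hap1"] is None or row["hap2"] is None:
            continue
        inds.append(ind)
        rows.append((cats[row["hap1"]], cats[row["hap2"]]))
    calls = np.array(rows, dtype=np.int16).reshape(-1, 1, 2)
    return calls, inds


def haplotype_fst_pairwise(
    hapset: HaplotypeSet,
    metadata: SampleMetadata,
    by: str = "site",
    n_perm: int = 10_000,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise WC theta treating phase pairs as one multi-allelic locus."""
    from itertools import combinations

    calls, inds = _super_locus(hapset)
    labels = metadata.table.loc[inds, by].to_numpy()
    samples = list(pd.unique(labels))
    k = len(samples)
    fst = np.zeros((k, k))
    pv = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(k), 2):
        sel = (labels == samples[i]) | (labels == samples[j])
        sub, lab = calls[sel], labels[sel]
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


def haplotype_differentiation(
    hapset: HaplotypeSet,
    metadata: SampleMetadata,
    by: str = "site",
    groups: str | None = "group",
    n_perm: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA on the haplotype super-locus (allele-identity distance).

    The squared distance between two individuals is the number of
    non-shared haplotypes in their phase pairs (0, 1 or 2).
    """
    calls, inds = _super_locus(hapset)
    n = len(inds)
    D2 = np.zeros((n, n))
    for i in range(n):
        a = calls[i, 0]
        for j in range(i + 1, n):
            b = calls[j, 0]
            # count of allele differences between unordered pairs
            best = min(
                int(a[0] != b[0]) + int(a[1] != b[1]),
                int(a[0] != b[1]) + int(a[1] != b[0]),
            )
            D2[i, j] = D2[j, i] = best
    meta_sub = metadata.subset(inds)
    return amova(
        None, meta_sub, by=by, groups=groups, n_perm=n_perm, seed=seed,
        distance_matrix=D2, individuals=inds,
    )
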