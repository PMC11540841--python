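import numpy as np
import pandas as pd
import pytest

from lanternpop.genotypes import GenotypeMatrix, SampleMetadata


def make_gm(dosages, loci=None, individuals=None, alleles=None):
    """Build a GenotypeMatrix from a dosage array (B-allele counts, -1=missing)."""
    d = np.asarray(dosages)
    n, L = d.shape
    individuals = individuals or [f"ind{i + 1}" for i in range(n)]
    loci = loci or [f"loc{j + 1}" for j in range(L)]
    calls = np.full((n, L, 2), -1, dtype=np.int8)
    calls[:, :, 0] = (d == 2)
    calls[:, :, 1] = (d >= 1)
    calls[d < 0] = -1
    return GenotypeMatrix(individuals, loci, calls,
                          alleles or [("A", "B")] * L)


def make_meta(gm, sites, groups=None):
    sites = list(sites)
    groups = list(groups) if groups is not None else sites
    return SampleMetadata(
        pd.DataFrame({"site": sites, "group": groups},
                     index=pd.Index(gm.individuals))
    )


@pytest.fixture
def two_pop_fixed():
    """Two samples fixed for opposite alleles at 3 loci."""
    d = np.array([[0, 0, 0]] * 4 + [[2, 2, 2]] * 4)
    gm = make_gm(d)
    meta = make_meta(gm, ["s1"] * 4 + ["s2"] * 4, ["g"] * 8)
    return gm, meta


@pytest.fixture(scope="session")
def small_preset():
    """Desk-scale survey preset with a little missing data (session cache)."""
    import lanternpop as lp

    cfg = lp.paper_like_preset(seed=42, scale=0.25, missing_rate=0.02)
    gm, meta, truth = lp.simulate_dataset(cfg)
    return gm, meta, truth


@pytest.fixture(scope="session")
def full_preset():
    """Survey-scale preset (~1288 individuals), no missing data."""
    import lanternpop as lp

    gm, meta, truth = lp.simulate_dataset(lp.paper_like_preset(seed=7))
    return gm, meta, truth
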