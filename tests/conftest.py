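import numpy as np
import pandas as pd
import pytest

from hillpop.containers import GeneIntervals, GenotypeMatrix, PopulationMap
from hillpop.simulate import (
    DivergenceModel,
    PedigreePlan,
    default_cohort,
    simulate_cohort,
    simulate_frequencies,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced two-species cohort reused by read-only tests."""
    return default_cohort(seed=7, n_autosomes=2, sites_per_autosome=600)


@pytest.fixture
def one_pop_model():
    """Single panmictic population, no drift anywhere."""
    return DivergenceModel(
        tree={"sp": ["popA"]},
        f_species={"sp": 0.0},
        f_population={"popA": 0.0},
    )


def make_matrix(dosages, chrom="chr1", positions=None, samples=None, **annotations):
    """Build a GenotypeMatrix from a plain dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
        }
    )
    for k, v in annotations.items():
        sites[k] = v
    return GenotypeMatrix(
        dosages=dosages,
        samples=samples or [f"s{i + 1}" for i in range(n_samples)],
        sites=sites,
    )


def panmictic_cohort(
    n_samples,
    n_sites,
    seed,
    maf_range=(0.05, 0.5),
    f=0.01,
    plan=None,
    missing_rate=0.0,
):
    """One-population cohort used by kinship and QC calibration tests."""
    model = DivergenceModel(
        tree={"sp": ["popA"]}, f_species={"sp": 0.0}, f_population={"popA": f},
        ancestral_maf_range=maf_range,
    )
    freqs = simulate_frequencies(model, n_sites, 1, seed=seed)
    return simulate_cohort(
        freqs,
        pop_sizes={"popA": n_samples},
        model=model,
        plan=plan or PedigreePlan(),
        missing_rate=missing_rate,
        seed=seed + 1,
    )
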