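import numpy as np
import pandas as pd
import pytest

from endogwas import SimConfig, simulate_cohort
from endogwas.synthetic_data import CohortData


@pytest.fixture(scope="session")
def continuous_cohort() -> CohortData:
    """Mid-size cohort with one planted variant, continuous trait."""
    return simulate_cohort(
        SimConfig(
            n_individuals=1500,
            n_variants=120,
            n_blocks=12,
            causal_spec=[(30, 0.10)],
            phenotype_mode="continuous",
            seed=101,
        )
    )


@pytest.fixture(scope="session")
def bis_cohort() -> CohortData:
    """Small bounded-trait cohort mirroring a clinical study design."""
    return simulate_cohort(
        SimConfig(
            n_individuals=324,
            n_variants=200,
            n_blocks=20,
            causal_spec=[(50, 0.101)],
            phenotype_mode="bis_like",
            seed=55,
        )
    )


def make_cohort(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    chrom: str = "1",
    sex: np.ndarray | None = None,
    ref: str = "A",
    alt: str = "G",
) -> CohortData:
    """Hand-built cohort around an explicit dosage matrix."""
    n, m = dosages.shape
    f = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": 1000 * (np.arange(m) + 1),
            "ref": [ref] * m,
            "alt": [alt] * m,
            "maf": np.minimum(f, 1 - f),
            "info_r2": np.ones(m),
            "call_rate": 1.0 - np.mean(np.isnan(dosages), axis=0),
        }
    )
    return CohortData(
        dosages=np.asarray(dosages, dtype=float),
        variants=variants,
        phenotype=np.asarray(phenotype, dtype=float),
        covariates=covariates if covariates is not None else pd.DataFrame(index=range(n)),
        sex=sex if sex is not None else np.array(["female"] * n, dtype=object),
    )
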