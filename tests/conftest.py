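import warnings

import numpy as np
import pandas as pd
import pytest

from pathprs.io_formats import GenotypeMatrix, VariantMeta
from pathprs.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def study_scale_sim():
    """One study-scale simulated cohort (556 samples, default conditions),
    shared across tests that only read it."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimulationConfig(n_samples=556, seed=2026))


@pytest.fixture(scope="session")
def large_intermediate_sim():
    """A 4000-sample intermediate-only cohort with the default planted
    biomarker effects, for recovery checks."""
    cfg = SimulationConfig(n_samples=4000, stage_mode="intermediate_only", seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg)


def toy_matrix(dosages, r2=None, samples=None):
    """Small GenotypeMatrix helper: dosages is samples x variants."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    samples = samples or [f"S{i}" for i in range(n)]
    r2 = r2 if r2 is not None else [np.nan] * m
    variants = [
        VariantMeta(f"v{j}", "1", 100 + j, "A", "G", imputation_r2=r2[j])
        for j in range(m)
    ]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def toy_weights(rows):
    """rows: list of (variant_id, effect, other, beta, gene, pathway)."""
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "effect_allele",
            "other_allele",
            "effect_weight",
            "gene_label",
            "pathway",
        ],
    ).assign(chrom="1", pos=1)
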