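"""Shared fixtures: a small, fast synthetic study and the default-size one.

The small study shrinks every dimension of the design (genome, gene and
region numbers, planted class sizes) while keeping the same structure, so
unit tests run in milliseconds. Recovery-oriented checks use the
default-size study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glymem import CountMatrix, SyntheticConfig, simulate_study
from glymem.simulate import nb_counts

#: fixed seed for every seeded fixture in the suite
SEED = 1


def small_config(seed: int = SEED, **overrides) -> SyntheticConfig:
    params = dict(
        n_chroms=2,
        chrom_length=1_000_000,
        n_tads_per_chrom=25,
        n_genes=400,
        n_regions=300,
        deg_class_sizes={
            "shared_deg_up": 30, "shared_deg_down": 20,
            "hg_unique_deg_up": 10, "hg_unique_deg_down": 5,
            "memory_unique_deg_up": 8, "memory_unique_deg_down": 5,
        },
        dar_class_sizes={
            "dar_hg_up": 20, "dar_hg_down": 6,
            "dar_memory_up": 10, "dar_sf_restored": 20,
        },
        n_chance_comarked=5,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def default_study():
    """The full-size study at the default design (used for recovery checks)."""
    return simulate_study(SyntheticConfig(seed=SEED))


def nb_matrix(n_features: int, lfc: np.ndarray, mu: np.ndarray,
              dispersion: float, n_reps: int, rng: np.random.Generator,
              conditions=("control", "treated")) -> CountMatrix:
    """Two-group NB count matrix with per-feature planted log2FC in group 2."""
    cols = {}
    cond_of = {}
    for cond, l in zip(conditions, (np.zeros(n_features), lfc)):
        for r in range(1, n_reps + 1):
            name = f"{cond}_r{r}"
            cols[name] = nb_counts(mu * 2.0 ** l, dispersion, rng)
            cond_of[name] = cond
    counts = pd.DataFrame(cols, index=[f"f{i:04d}" for i in range(n_features)])
    return CountMatrix(counts, pd.Series(cond_of))
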