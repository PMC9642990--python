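import numpy as np
import pytest

import twinlca as t


@pytest.fixture(scope="session")
def default_cohort_small():
    """Five-class cohort at reduced size, with its hidden truth."""
    cfg = t.default_config(n_pairs=300, seed=42)
    cohort, truth = t.generate_cohort(cfg, return_truth=True)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def compact_cohort():
    """Two-class compact cohort used by the fast end-to-end checks."""
    cfg = t.compact_two_class_config(n_pairs=365, seed=7)
    cohort, truth = t.generate_cohort(cfg, return_truth=True)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def fitted_compact(compact_cohort):
    cfg, cohort, _ = compact_cohort
    fit = t.LatentClassModel(cohort, cfg.indicator_specs, 2).fit(
        n_starts=5, seed=0, tol=1e-8
    )
    return cfg, cohort, fit


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
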