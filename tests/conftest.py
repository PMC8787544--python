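import numpy as np
import pytest

import vfarch
from vfarch.archetypes import FitOptions, decompose_matrix, fit_archetypes
from vfarch.pipeline import td_matrix
from vfarch.synthetic import simulate_mixture
from vfarch.vf_core import ON_RELIABILITY_POLICY, reliability_pass


@pytest.fixture(scope="session")
def lib():
    return vfarch.make_pattern_library()


@pytest.fixture(scope="session")
def mixture600(lib):
    """600 fields mixed from 6 well-separated patterns, sigma = 1 dB."""
    X, W_true, P = simulate_mixture(lib, n=600, noise_sigma=1.0, seed=0)
    return X, W_true, P


@pytest.fixture(scope="session")
def model6(mixture600):
    X, _, _ = mixture600
    return fit_archetypes(X, 6, FitOptions(n_restarts=5, seed=0))


@pytest.fixture(scope="session")
def on_cohort(lib):
    """Default synthetic optic-neuritis cohort, reliability-filtered."""
    records, truth = vfarch.simulate_on_cohort(lib, vfarch.CohortConfig(seed=0))
    records = [r for r in records if reliability_pass(r, ON_RELIABILITY_POLICY)]
    return records, truth


@pytest.fixture(scope="session")
def on_X(on_cohort):
    records, _ = on_cohort
    return td_matrix(records)


@pytest.fixture(scope="session")
def on_model16(on_X):
    """The 16-archetype model fitted to the full synthetic cohort."""
    return fit_archetypes(on_X, 16, FitOptions(n_restarts=5, seed=0))


@pytest.fixture(scope="session")
def on_baseline(on_cohort, on_X, on_model16):
    """Baseline (first day-0 test per eye) weights and global indices."""
    records, _ = on_cohort
    seen = set()
    idx = []
    for i, r in enumerate(records):
        if r.visit_day == 0 and r.eye_id not in seen:
            seen.add(r.eye_id)
            idx.append(i)
    W = decompose_matrix(on_X[idx], on_model16)
    md = np.array([records[i].md for i in idx], dtype=float)
    recs = [records[i] for i in idx]
    return recs, W, md
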