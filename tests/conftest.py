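import numpy as np
import pytest

from neurovasc.paradigm import canonical_hrf, default_paradigms
from neurovasc.synthetic import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf(0.1)


@pytest.fixture(scope="session")
def paradigms():
    return default_paradigms()


@pytest.fixture(scope="session")
def tiny_study():
    """Small hypercapnia study (2 subjects x 2 scans) for fast unit tests."""
    cfg = StudyConfig(n_subjects=2, n_scans_per_subject=2)
    return simulate_study(cfg, master_seed=7)


def detrend_quadratic(y):
    """Project out an order-2 polynomial, as the preprocessing stage does."""
    y = np.asarray(y, dtype=float)
    tau = np.linspace(-1.0, 1.0, y.size)
    basis = np.column_stack([np.ones_like(tau), tau, tau**2])
    q, _ = np.linalg.qr(basis)
    return y - q @ (q.T @ y)
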