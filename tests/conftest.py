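from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import settings

from carecascade.synthetic import CohortConfig, LabTest, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """200-participant cohort shared by read-only tests."""
    cfg = CohortConfig(n_participants=200, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_lab_stream(rng, anchor: date, n_max: int = 8) -> list[LabTest]:
    """Random dated viral-load stream spanning day -400..+400 around anchor."""
    n = int(rng.integers(0, n_max + 1))
    days = rng.integers(-400, 401, size=n)
    vls = rng.choice([0, 40, 150, 199, 200, 250, 5000, 100_000], size=n)
    tests = [LabTest("PX", anchor + timedelta(days=int(d)), int(v))
             for d, v in zip(days, vls)]
    return sorted(tests, key=lambda t: t.test_date)


def newton_logit_mle(X: np.ndarray, y: np.ndarray, tol: float = 1e-12,
                     max_iter: int = 200) -> np.ndarray:
    """Independent Newton-Raphson maximizer of the logistic log-likelihood."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p)
        w = p * (1.0 - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
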