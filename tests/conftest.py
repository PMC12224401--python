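import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from foodenv.config import CityConfig, OutcomeTruth


@pytest.fixture
def small_config() -> CityConfig:
    """A compact three-city configuration for fast end-to-end runs."""
    return CityConfig(
        n_neighbourhoods=120,
        city_weights=(80, 25, 15),
        n_participants=400,
        n_survey_neighbourhoods=60,
        seed=11,
    )


def simulate_ri_logistic(
    rng: np.random.Generator,
    n_obs: int,
    n_groups: int,
    beta: tuple[float, float],
    sigma_u: float,
) -> pd.DataFrame:
    """Direct draw from the two-level logistic model (intercept + one slope)."""
    g = rng.integers(0, n_groups, size=n_obs)
    x = rng.normal(size=n_obs)
    u = rng.normal(0.0, sigma_u, size=n_groups)
    eta = beta[0] + beta[1] * x + u[g]
    y = (rng.random(n_obs) < expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "x": x, "g": g})


def brute_force_loglik(df: pd.DataFrame, beta: np.ndarray, sigma: float,
                       n_points: int = 20001, half_width: float = 10.0) -> float:
    """Marginal log-likelihood by dense trapezoid integration over u ~ N(0,1).

    Independent oracle: per-group likelihood integrated on a fixed fine grid,
    no quadrature adaptation, no shared code with the fitted path.
    """
    u = np.linspace(-half_width, half_width, n_points)
    log_phi = -0.5 * u**2 - 0.5 * np.log(2 * np.pi)
    total = 0.0
    for _, sub in df.groupby("g"):
        eta = beta[0] + beta[1] * sub["x"].to_numpy()
        lin = eta[:, None] + sigma * u[None, :]
        ll_u = (sub["y"].to_numpy()[:, None] * lin - np.logaddexp(0.0, lin)).sum(axis=0)
        total += np.log(np.trapezoid(np.exp(ll_u + log_phi), u))
    return total
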