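"""Two-level random-intercept logistic regression, fitted by maximum
marginal likelihood with adaptive Gauss–Hermite quadrature (AGHQ).

The model for individual *i* in neighbourhood *j*::

    logit P(y_ij = 1) = x_ij' beta + sigma_u * u_j,   u_j ~ Normal(0, 1)

so the random intercept has SD ``sigma_u`` on the log-odds scale.  The
marginal likelihood integrates the Bernoulli-logit likelihood of each
group over its random effect; the integral is evaluated by Gauss–Hermite
quadrature recentred at each group's conditional mode and rescaled by the
curvature there (adaptive), which keeps a modest node count (default 15)
accurate even for large groups.  One node reduces to the Laplace
approximation; ``sigma_u`` fixed at 0 reduces exactly to ordinary logistic
regression.

Estimation is by quasi-Newton (BFGS) on (beta, log sigma_u); standard
errors are Wald, from the numerically differentiated Hessian of the
marginal log-likelihood.  This estimator is implemented here rather than
delegated because the mixed logistic is the analysis core; an established
mixed-model routine serves as a cross-check in the test suite only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp

from .survey import LOW_EDUCATION

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
#: below this fitted sigma_u the optimum is treated as the boundary and the
#: model is refitted with the variance pinned at zero
_BOUNDARY_SIGMA = 1e-4


class ConstantColumnError(ValueError):
    pass


def standardize(
    df: pd.DataFrame, columns: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """z-score columns in place (population SD, ddof=0); returns (df, params).

    The (mean, sd) pair per column is persisted so fitted coefficients can
    be mapped back to the raw scale.  A constant column raises
    :class:`ConstantColumnError` naming it.
    """
    out = df.copy()
    params: dict[str, tuple[float, float]] = {}
    for c in columns:
        x = out[c].to_numpy(float)
        m, s = float(x.mean()), float(x.std(ddof=0))
        if s == 0:
            raise ConstantColumnError(f"column {c!r} is constant; cannot z-score")
        out[c] = (x - m) / s
        params[c] = (m, s)
    return out, params


@dataclass
class ModelSpec:
    """Specification of one random-intercept logistic fit."""

    outcome: str
    exposure: str | None
    covariates: list[str] = field(default_factory=list)
    group: str = "neighbourhood_id"
    quadrature_nodes: int = 15
    max_iter: int = 200
    tolerance: float = 1e-8
    #: fix sigma_u at this value instead of estimating it (0 => plain logistic)
    fix_sigma_u: float | None = None

    def fixed_terms(self) -> list[str]:
        terms = ["intercept"]
        if self.exposure:
            terms.append(self.exposure)
        terms.extend(self.covariates)
        return terms


@dataclass
class ModelFit:
    """A fitted model: coefficients, Wald SEs, variance, AIC, OR table."""

    spec: ModelSpec
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    sigma_u: float
    sigma_u_se: float | None
    log_likelihood: float
    aic: float
    converged: bool
    boundary: bool
    n_obs: int
    n_groups: int
    n_iter: int

    @property
    def or_table(self) -> pd.DataFrame:
        rows = []
        for term, b in self.coefficients.items():
            if term == "intercept":
                continue
            se = self.standard_errors[term]
            rows.append({
                "term": term,
                "or": np.exp(b),
                "ci_low": np.exp(b - 1.96 * se),
                "ci_high": np.exp(b + 1.96 * se),
                "coef": b,
                "se": se,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "exposure": self.spec.exposure,
            "covariates": list(self.spec.covariates),
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "sigma_u": self.sigma_u,
            "sigma_u_se": self.sigma_u_se,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


class _MarginalLikelihood:
    """AGHQ marginal log-likelihood of the two-level Bernoulli-logit model.

    Data are sorted by group once; per-group sums use ``np.add.reduceat``.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray, nodes: int):
        order = np.argsort(groups, kind="stable")
        self.y = np.asarray(y, float)[order]
        self.X = np.asarray(X, float)[order]
        g = np.asarray(groups)[order]
        _, self.starts = np.unique(g, return_index=True)
        self.gidx = np.repeat(np.arange(len(self.starts)),
                              np.diff(np.append(self.starts, len(g))))
        self.n_groups = len(self.starts)
        self.z, self.w = hermgauss(nodes)         # e^{-z^2} weights
        self.logw = np.log(self.w)
        self._mode_cache = np.zeros(self.n_groups)

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts)

    def _cond_logjoint(self, eta0: np.ndarray, sigma: float, u: np.ndarray) -> np.ndarray:
        """log f(y_j | u_j) + log phi(u_j) per group, u on the N(0,1) scale."""
        eta = eta0 + sigma * u[self.gidx]
        ll = self.y * eta - np.logaddexp(0.0, eta)
        return self._group_sum(ll) - 0.5 * u * u - _LOG_SQRT_2PI

    def _modes(self, eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Conditional mode and curvature of the log-joint per group (Newton)."""
        u = self._mode_cache.copy()
        for _ in range(50):
            eta = eta0 + sigma * u[self.gidx]
            p = expit(eta)
            grad = sigma * self._group_sum(self.y - p) - u
            hess = -(sigma * sigma * self._group_sum(p * (1.0 - p)) + 1.0)
            step = grad / hess
            # dampen huge steps for stability far from the mode
            step = np.clip(step, -5.0, 5.0)
            u = u - step
            if np.max(np.abs(grad)) < 1e-11:
                break
        eta = eta0 + sigma * u[self.gidx]
        p = expit(eta)
        hess = -(sigma * sigma * self._group_sum(p * (1.0 - p)) + 1.0)
        self._mode_cache = u
        return u, hess

    def plain_loglik(self, beta: np.ndarray) -> float:
        eta = self.X @ beta
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        if sigma < 1e-10:
            return self.plain_loglik(beta)
        eta0 = self.X @ beta
        u_hat, hess = self._modes(eta0, sigma)
        tau = 1.0 / np.sqrt(-hess)
        # integral over u: substitute u = u_hat + sqrt(2) tau z
        terms = np.empty((self.n_groups, len(self.z)))
        for k, (zk, lwk) in enumerate(zip(self.z, self.logw)):
            uk = u_hat + np.sqrt(2.0) * tau * zk
            terms[:, k] = lwk + zk * zk + self._cond_logjoint(eta0, sigma, uk)
        per_group = logsumexp(terms, axis=1) + 0.5 * np.log(2.0) + np.log(tau)
        return float(per_group.sum())


def _plain_logistic_irls(y: np.ndarray, X: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Ordinary logistic regression by IRLS; used for initial values."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = np.clip(p * (1 - p), 1e-10, None)
        try:
            delta = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    return beta


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at x."""
    n = len(x)
    H = np.empty((n, n))
    h = step * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_ri_logistic(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Fit the random-intercept logistic model.

    ``data`` must contain the outcome (binary 0/1), every fixed-effect
    column (numeric, already encoded/z-scored) and the grouping column,
    with no missing values in model columns.  Non-convergence returns a fit
    flagged ``converged=False``; a vanishing variance is refitted at the
    sigma_u = 0 boundary and flagged ``boundary=True``.
    """
    terms = spec.fixed_terms()
    cols = [t for t in terms if t != "intercept"] + [spec.outcome, spec.group]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing model columns: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("missing values in model columns")
    y = data[spec.outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    X = np.column_stack(
        [np.ones(len(data))]
        + [data[t].to_numpy(float) for t in terms if t != "intercept"]
    )
    groups = data[spec.group].to_numpy()
    if len(np.unique(groups)) < 2 and spec.fix_sigma_u is None:
        raise ValueError("need >= 2 groups to estimate a random intercept")

    ml = _MarginalLikelihood(y, X, groups, spec.quadrature_nodes)
    p_fix = X.shape[1]
    k_params = p_fix + 1  # fixed effects (incl. intercept) + variance parameter
    beta0 = _plain_logistic_irls(y, X)

    if spec.fix_sigma_u is not None:
        sigma = float(spec.fix_sigma_u)

        def nll_fixed(b):
            return -ml.loglik(b, sigma)

        res = optimize.minimize(
            nll_fixed, beta0, method="BFGS",
            options={"gtol": spec.tolerance ** 0.5, "maxiter": spec.max_iter},
        )
        beta = res.x
        ll = -res.fun
        H = _numeric_hessian(nll_fixed, beta)
        cov = _safe_inv(H)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return ModelFit(
            spec=spec,
            coefficients=dict(zip(terms, beta)),
            standard_errors=dict(zip(terms, ses)),
            sigma_u=sigma, sigma_u_se=None,
            log_likelihood=ll,
            aic=2.0 * k_params - 2.0 * ll,
            converged=bool(res.success), boundary=(sigma == 0.0),
            n_obs=len(y), n_groups=ml.n_groups, n_iter=int(res.nit),
        )

    # free fit over (beta, log sigma_u); deterministic start log(0.5)
    x0 = np.append(beta0, np.log(0.5))

    def nll(params):
        return -ml.loglik(params[:-1], np.exp(params[-1]))

    res = optimize.minimize(
        nll, x0, method="BFGS",
        options={"gtol": spec.tolerance ** 0.5, "maxiter": spec.max_iter},
    )
    sigma = float(np.exp(res.x[-1]))

    if sigma < _BOUNDARY_SIGMA:
        # variance vanished: report the boundary fit (= plain logistic)
        fit = fit_ri_logistic(
            data,
            ModelSpec(**{**spec.__dict__, "fix_sigma_u": 0.0}),
        )
        fit.boundary = True
        return fit

    beta = res.x[:-1]
    ll = -res.fun
    H = _numeric_hessian(nll, res.x)
    cov = _safe_inv(H)
    ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    sigma_se = float(ses[-1] * sigma)  # delta method from log scale
    if not res.success:
        logger.warning("fit_ri_logistic: optimizer did not converge (%s)", res.message)
    return ModelFit(
        spec=spec,
        coefficients=dict(zip(terms, beta)),
        standard_errors=dict(zip(terms, ses[:-1])),
        sigma_u=sigma, sigma_u_se=sigma_se,
        log_likelihood=ll,
        aic=2.0 * k_params - 2.0 * ll,
        converged=bool(res.success), boundary=False,
        n_obs=len(y), n_groups=ml.n_groups, n_iter=int(res.nit),
    )


def _safe_inv(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; using pseudo-inverse for SEs")
        return np.linalg.pinv(H)


# -- analytic frame & progressive models -------------------------------------

MODEL2_COVARIATES = ["z_age", "male", "low_education"]
MODEL3_COVARIATES = MODEL2_COVARIATES + ["z_popdens", "z_sei"]


def prepare_analytic(
    participants: pd.DataFrame,
    metrics: pd.DataFrame,
    density_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Merge analytic participants with neighbourhood metrics and encode.

    Adds ``male`` and ``low_education`` indicators and z-scores (within the
    analytic sample) age, population density, SEI and every requested
    density column as ``z_<name>``.
    """
    if density_columns is None:
        density_columns = [c for c in metrics.columns if c.startswith("density_")]
    cols = ["id", "popdens", "sei"] + density_columns
    df = participants.merge(
        metrics[cols], left_on="neighbourhood_id", right_on="id",
        how="inner", suffixes=("", "_nb"),
    )
    df["male"] = (df["gender"] == "male").astype(float)
    df["low_education"] = df["education"].isin(LOW_EDUCATION).astype(float)
    to_z = ["age", "popdens", "sei"] + density_columns
    for c in to_z:
        df[f"z_{c}"] = df[c]
    df, _ = standardize(df, [f"z_{c}" for c in to_z])
    return df


def progressive_fit(
    analytic: pd.DataFrame,
    exposure: str,
    outcome: str = "non_daily",
    group: str = "neighbourhood_id",
    quadrature_nodes: int = 15,
) -> dict[str, ModelFit]:
    """Fit the Model 1→3 adjustment sequence for one exposure.

    Model 1 is the unadjusted single-exposure model; Model 2 adds the
    individual-level confounders (age, gender, education); Model 3 adds the
    area-level confounders (population density, SEI).  All three are fitted
    on the identical analytic sample.
    """
    z_exp = f"z_{exposure}" if f"z_{exposure}" in analytic.columns else exposure
    fits: dict[str, ModelFit] = {}
    for name, covs in (
        ("model1", []),
        ("model2", MODEL2_COVARIATES),
        ("model3", MODEL3_COVARIATES),
    ):
        spec = ModelSpec(
            outcome=outcome, exposure=z_exp, covariates=list(covs),
            group=group, quadrature_nodes=quadrature_nodes,
        )
        try:
            fits[name] = fit_ri_logistic(analytic, spec)
        except Exception as exc:
            logger.warning("progressive_fit: %s for %s failed: %s", name, exposure, exc)
    return fits


def exposure_or_table(
    analytic: pd.DataFrame,
    exposures: list[str],
    **kwargs,
) -> tuple[pd.DataFrame, dict[str, dict[str, ModelFit]]]:
    """OR (95% CI) of the exposure term, rows = exposures, columns = models."""
    all_fits: dict[str, dict[str, ModelFit]] = {}
    rows = []
    for expo in exposures:
        fits = progressive_fit(analytic, expo, **kwargs)
        all_fits[expo] = fits
        row: dict[str, object] = {"exposure": expo}
        for name in ("model1", "model2", "model3"):
            fit = fits.get(name)
            if fit is None:
                row[name] = "not converged"
                continue
            tab = fit.or_table
            line = tab[tab["term"] == fit.spec.exposure].iloc[0]
            row[name] = f"{line['or']:.2f} ({line['ci_low']:.2f}, {line['ci_high']:.2f})"
            row[f"{name}_or"] = line["or"]
            row[f"{name}_ci_low"] = line["ci_low"]
            row[f"{name}_ci_high"] = line["ci_high"]
        rows.append(row)
    return pd.DataFrame(rows), all_fits


def compare_aic(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """AIC per fit with Δ-AIC vs the best; requires identical samples."""
    n_set = {f.n_obs for f in fits.values()}
    if len(n_set) > 1:
        raise ValueError("AIC comparison requires fits on identical data")
    df = pd.DataFrame(
        [{"model": k, "aic": f.aic, "log_likelihood": f.log_likelihood,
          "k": len(f.coefficients) + 1, "converged": f.converged}
         for k, f in fits.items()]
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df


def save_fits_json(fits: dict[str, dict[str, ModelFit]], path) -> None:
    doc = {
        expo: {name: fit.to_dict() for name, fit in models.items()}
        for expo, models in fits.items()
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
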