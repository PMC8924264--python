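"""Binomial GLM for coiling success versus support diameter and tendril length.

Fits ``success ~ diameter + length`` by maximum likelihood with
iteratively reweighted least squares (IRLS, i.e. Newton scoring with a
step-halving safeguard so the log-likelihood never decreases), reporting
coefficients on the logit scale with Wald standard errors, z and p values.
Complete separation is detected and flagged instead of fabricating finite
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import NotConvergedError, ValidationError

__all__ = ["GLMFit", "fit_logistic", "predict_success", "validate_success_dataset"]

MAX_ITER = 100
TOL = 1e-8
#: |linear predictor| beyond which fitted probabilities are numerically 0/1;
#: reaching it across all observations signals complete separation.
SEPARATION_ETA = 30.0


def validate_success_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check a (diameter_mm, length_mm, success) table's invariants."""
    for col in ("diameter_mm", "length_mm", "success"):
        if col not in df.columns:
            raise ValidationError(f"success table is missing column {col!r}")
    if len(df) < 1:
        raise ValidationError("success table is empty")
    if not df[["diameter_mm", "length_mm"]].gt(0).all().all():
        raise ValidationError("diameters and lengths must be positive")
    if not df["success"].isin([0, 1]).all():
        raise ValidationError("success must be 0/1")
    return df


@dataclass(frozen=True)
class GLMFit:
    """Result of a logistic fit.

    ``coefficients`` are on the logit scale in the order of ``names``
    (intercept first). ``separation`` marks complete or quasi-complete
    separation; in that case ``converged`` is False and the coefficient
    values are not maximum-likelihood estimates.
    """

    names: Tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    converged: bool
    separation: bool
    n_iterations: int
    log_likelihood: float
    n_obs: int
    ll_trace: Tuple[float, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def wald_ci(self, name: str, level: float = 0.95) -> Tuple[float, float]:
        i = self.names.index(name)
        half = norm.ppf(0.5 + level / 2) * self.standard_errors[i]
        return (
            float(self.coefficients[i] - half),
            float(self.coefficients[i] + half),
        )

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coefficients": [float(v) for v in self.coefficients],
            "standard_errors": [float(v) for v in self.standard_errors],
            "z_values": [float(v) for v in self.z_values],
            "p_values": [float(v) for v in self.p_values],
            "converged": self.converged,
            "separation": self.separation,
            "n_iterations": self.n_iterations,
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
        }


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: y*eta - log(1 + e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    data: pd.DataFrame,
    response: str = "success",
    predictors: Sequence[str] = ("diameter_mm", "length_mm"),
    interaction: bool = False,
) -> GLMFit:
    """Maximum-likelihood logistic regression via IRLS.

    Convergence when ``max |delta beta| < 1e-8`` or after 100 iterations.
    Complete separation is reported via the ``separation`` flag.

    Raises
    ------
    ValidationError
        For fewer than 3 rows or a constant (rank-deficient) predictor.
    """
    if len(data) < 3:
        raise ValidationError(f"need at least 3 observations, got {len(data)}")
    y = np.asarray(data[response], dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError(f"response {response!r} must be 0/1")
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for p in predictors:
        col = np.asarray(data[p], dtype=float)
        if np.ptp(col) == 0:
            raise ValidationError(
                f"predictor {p!r} is constant: design matrix is rank-deficient"
            )
        cols.append(col)
        names.append(p)
    if interaction and len(predictors) == 2:
        cols.append(cols[1] * cols[2])
        names.append(f"{predictors[0]}:{predictors[1]}")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValidationError("design matrix is rank-deficient")

    beta = np.zeros(x.shape[1])
    eta = x @ beta
    ll = _log_likelihood(y, eta)
    ll_trace = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        xtw = x.T * w
        try:
            delta = np.linalg.solve(xtw @ x, x.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(30):  # step halving: keep the log-likelihood ascending
            beta_new = beta + step * delta
            ll_new = _log_likelihood(y, x @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, eta, ll = beta_new, x @ beta_new, ll_new
        ll_trace.append(ll)
        if np.max(np.abs(step * delta)) < TOL:
            converged = True
            break

    # separation: fitted probabilities numerically 0/1 on every observation,
    # perfectly matching the response (the MLE is at infinity).
    margins = np.where(y == 1, eta, -eta)
    separation = bool(np.all(margins > SEPARATION_ETA / 2) and not converged) or bool(
        np.min(margins) > SEPARATION_ETA
    )
    if separation:
        converged = False

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (x.T * w) @ x
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(x.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return GLMFit(
        names=tuple(names),
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=p,
        converged=converged,
        separation=separation,
        n_iterations=n_iter,
        log_likelihood=ll,
        n_obs=len(y),
        ll_trace=tuple(ll_trace),
    )


def predict_success(fit: GLMFit, diameter: float, length: float) -> float:
    """Predicted coiling-success probability at (diameter, length) in mm."""
    if not fit.converged:
        raise NotConvergedError(
            "cannot predict from a non-converged fit"
            + (" (complete separation)" if fit.separation else "")
        )
    values = {"intercept": 1.0, "diameter_mm": diameter, "length_mm": length}
    eta = 0.0
    for name, b in zip(fit.names, fit.coefficients):
        if name in values:
            eta += b * values[name]
        elif ":" in name:
            a, b2 = name.split(":")
            eta += b * values[a] * values[b2]
        else:
            raise ValidationError(f"cannot evaluate predictor {name!r}")
    return float(expit(eta))
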