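"""Weighted logistic dose-response fit by iteratively reweighted least squares.

The probability that a stimulus of rise time tau (ms) and zero-to-peak
amplitude dG (mT/m) elicits stimulation is modelled as

    P(S=1) = logistic(b0 + b1*tau + b2*dG + sum_n [b_(1+2n)*phi'_n
                                                   + b_(2+2n)*phi'_n*tau])

where phi'_n = phi_n - phibar_n is a mean-centered subject covariate (age,
sex, z-offset) and every covariate enters both as a main effect and as an
interaction with rise time.  The z-offset covariate is centered at 0 by
convention, so fitted curves at z=0 refer to isocenter.  Observations carry
non-negative fitting weights (see :mod:`pnskit.observations`).

The maximizer of the weighted Bernoulli log-likelihood is found by Newton
scoring (IRLS) with step-halving; standard errors come from the inverse
weighted Fisher information and p-values from two-sided Wald z-tests.  An
optional ridge penalty stabilizes separable data sets.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .observations import BinaryObservation

__all__ = [
    "COVARIATE_NAMES",
    "CovariateSpec",
    "LogisticModelFit",
    "center_covariates",
    "fit_weighted_logistic",
    "fit_pns_model",
    "predict_probability",
]

COVARIATE_NAMES = ("age", "sex", "z_offset")

_ATTR = {"age": "age_years", "sex": "sex_code", "z_offset": "z_offset_cm"}

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CovariateSpec:
    """Which subject covariates enter the model and where they are centered.

    Centers are population means of the covariate (z-offset is pinned at 0 so
    that the baseline curve refers to isocenter).  Sex is coded F=0, M=1.
    """

    names: tuple[str, ...] = ()
    centers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n in self.names:
            if n not in COVARIATE_NAMES:
                raise ValueError(f"unknown covariate {n!r}; choose from {COVARIATE_NAMES}")
            c = self.centers.get(n)
            if c is None or not math.isfinite(c):
                raise ValueError(f"covariate {n!r} needs a finite center")
        if "z_offset" in self.names and self.centers["z_offset"] != 0.0:
            raise ValueError("the z_offset center is fixed at 0 by convention")

    @classmethod
    def from_observations(
        cls, observations: Sequence[BinaryObservation], names: Sequence[str]
    ) -> "CovariateSpec":
        """Centers from the data: per-subject covariate means, z-offset at 0."""
        names = tuple(names)
        centers: dict[str, float] = {}
        for n in names:
            if n == "z_offset":
                centers[n] = 0.0
                continue
            attr = _ATTR[n]
            per_subject: dict[str, float] = {}
            for o in observations:
                v = getattr(o, attr)
                if v is None:
                    raise ValueError(f"subject {o.subject_id}: missing covariate {n!r}")
                per_subject[o.subject_id] = float(v)
            centers[n] = float(np.mean(list(per_subject.values())))
        return cls(names=names, centers=centers)

    @property
    def column_names(self) -> tuple[str, ...]:
        cols = ["intercept", "rise_time", "amplitude"]
        for n in self.names:
            cols += [n, f"{n}:rise_time"]
        return tuple(cols)


def center_covariates(
    observations: Sequence[BinaryObservation], spec: CovariateSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the regression design: (X, responses, weights).

    Rows are ``[1, tau, dG, phi'_1, phi'_1*tau, ..., phi'_N, phi'_N*tau]``.
    """
    n = len(observations)
    p = 3 + 2 * len(spec.names)
    X = np.empty((n, p))
    s = np.empty(n)
    w = np.empty(n)
    for i, o in enumerate(observations):
        X[i, 0] = 1.0
        X[i, 1] = o.rise_time_ms
        X[i, 2] = o.amplitude_mTm
        for j, name in enumerate(spec.names):
            v = getattr(o, _ATTR[name])
            if v is None:
                raise ValueError(f"subject {o.subject_id}: missing covariate {name!r}")
            centered = float(v) - spec.centers[name]
            X[i, 3 + 2 * j] = centered
            X[i, 4 + 2 * j] = centered * o.rise_time_ms
        s[i] = o.response
        w[i] = o.weight
    return X, s, w


@dataclass
class LogisticModelFit:
    """Fitted weighted logistic model with Wald inference."""

    coef: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    column_names: tuple[str, ...]
    spec: CovariateSpec
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    max_score: float
    ridge: float = 0.0
    axis: str | None = None

    @property
    def z_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    def linear_predictor(
        self, rise_time_ms: float, amplitude_mTm: float,
        covariates: Mapping[str, float] | None = None,
    ) -> float:
        covariates = covariates or {}
        eta = self.coef[0] + self.coef[1] * rise_time_ms + self.coef[2] * amplitude_mTm
        for j, name in enumerate(self.spec.names):
            if name not in covariates:
                raise ValueError(f"covariate {name!r} required by this fit was not supplied")
            centered = float(covariates[name]) - self.spec.centers[name]
            eta += self.coef[3 + 2 * j] * centered
            eta += self.coef[4 + 2 * j] * centered * rise_time_ms
        return float(eta)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coef,
                "std_error": self.se,
                "z": self.z_values,
                "p_value": self.p_values,
            },
            index=list(self.column_names),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": dict(zip(self.column_names, self.coef.tolist())),
                "std_errors": dict(zip(self.column_names, self.se.tolist())),
                "p_values": dict(zip(self.column_names, self.p_values.tolist())),
                "covariates": list(self.spec.names),
                "centers": {k: float(v) for k, v in self.spec.centers.items()},
                "loglik": self.loglik,
                "n_obs": self.n_obs,
                "converged": self.converged,
                "n_iter": self.n_iter,
                "ridge": self.ridge,
                "axis": self.axis,
            },
            indent=2,
        )


def _weighted_loglik(eta: np.ndarray, s: np.ndarray, w: np.ndarray) -> float:
    # w * [s*eta - log(1 + e^eta)], numerically stable for large |eta|
    return float(np.sum(w * (s * eta - np.logaddexp(0.0, eta))))


def fit_weighted_logistic(
    X: np.ndarray,
    responses: np.ndarray,
    weights: np.ndarray,
    *,
    spec: CovariateSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
    axis: str | None = None,
) -> LogisticModelFit:
    """Maximize the weighted Bernoulli log-likelihood by IRLS.

    Convergence is declared when the largest absolute component of the
    (penalized) score vector falls below ``tol``.  With ``ridge > 0`` the
    objective gains ``-ridge/2 * ||beta_slopes||^2`` (the intercept is never
    penalized), which keeps separable data sets bounded; the default is an
    unpenalized fit.
    """
    X = np.asarray(X, dtype=float)
    s = np.asarray(responses, dtype=float)
    w = np.asarray(weights, dtype=float)
    if X.ndim != 2 or X.shape[0] != s.shape[0] or s.shape[0] != w.shape[0]:
        raise ValueError("X, responses and weights must have matching first dimensions")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    active = w > 0
    if not (np.any(s[active] == 1) and np.any(s[active] == 0)):
        raise ValueError("need both stimulated and non-stimulated observations with positive weight")

    n, p = X.shape
    beta = np.zeros(p)
    eta = X @ beta
    pen = np.full(p, ridge)
    pen[0] = 0.0  # intercept unpenalized

    def objective(b: np.ndarray, e: np.ndarray) -> float:
        return _weighted_loglik(e, s, w) - 0.5 * float(pen @ (b * b))

    obj = objective(beta, eta)
    converged = False
    it = 0
    max_score = math.inf
    for it in range(1, max_iter + 1):
        prob = expit(eta)
        score = X.T @ (w * (s - prob)) - pen * beta
        max_score = float(np.max(np.abs(score)))
        if max_score < tol:
            converged = True
            break
        info = (X * (w * prob * (1.0 - prob))[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break  # singular information: separation or collinear design
        # step-halving line search on the penalized log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            cand_eta = X @ cand
            cand_obj = objective(cand, cand_eta)
            if cand_obj >= obj - 1e-12:
                beta, eta, obj = cand, cand_eta, cand_obj
                break
            t /= 2.0
        else:
            break  # no ascent possible within machine precision
    else:
        it = max_iter

    prob = expit(eta)
    # complete separation: every active fitted probability saturates, so the
    # unpenalized likelihood has no interior maximum and the score-based stop
    # fired on a diverging path
    if ridge == 0 and bool(
        np.all((prob[active] < 1e-8) | (prob[active] > 1.0 - 1e-8))
    ):
        converged = False
        logger.warning(
            "complete separation detected (all fitted probabilities saturated "
            "after %d iterations); refit with ridge > 0 for a finite optimum",
            it,
        )
    info = (X * (w * prob * (1.0 - prob))[:, None]).T @ X + np.diag(pen)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * norm.sf(np.abs(zvals))

    spec = spec or CovariateSpec()
    names = spec.column_names
    if len(names) != p:
        names = tuple(f"x{i}" for i in range(p))
    return LogisticModelFit(
        coef=beta,
        se=se,
        p_values=pvals,
        column_names=names,
        spec=spec,
        loglik=_weighted_loglik(eta, s, w),
        n_obs=n,
        converged=converged,
        n_iter=it,
        max_score=max_score,
        ridge=ridge,
        axis=axis,
    )


def fit_pns_model(
    observations: Sequence[BinaryObservation],
    covariates: Sequence[str] = (),
    *,
    spec: CovariateSpec | None = None,
    axis: str | None = None,
    **options,
) -> LogisticModelFit:
    """Convenience wrapper: build the centered design and run the IRLS fit."""
    if spec is None:
        spec = CovariateSpec.from_observations(observations, covariates)
    X, s, w = center_covariates(observations, spec)
    return fit_weighted_logistic(X, s, w, spec=spec, axis=axis, **options)


def predict_probability(
    fit: LogisticModelFit,
    rise_time_ms: float,
    amplitude_mTm: float,
    covariates: Mapping[str, float] | None = None,
) -> float:
    """Stimulation probability at a stimulus/covariate combination."""
    if not fit.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    return float(expit(fit.linear_predictor(rise_time_ms, amplitude_mTm, covariates)))
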