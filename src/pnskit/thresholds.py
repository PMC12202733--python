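"""Threshold curves derived from fitted logistic coefficients.

Setting the linear predictor of the dose-response model to zero (the 50%
stimulation contour) and solving for amplitude gives a straight line in rise
time,

    dG(tau) = dGmin + tau * SRmin,

whose intercept dGmin (mT/m) is the rheobase-like minimum stimulating
amplitude and whose slope SRmin (mT/m/ms) is the highest slew rate that can
be sustained indefinitely without stimulation.  With centered covariates:

    dGmin = -b0/b2 - sum_n (b_(1+2n)/b2) * phi'_n
    SRmin = -b1/b2 - sum_n (b_(2+2n)/b2) * phi'_n

This module also differentiates the curve with respect to the z-offset
covariate (threshold sensitivity to subject displacement along the bore, in
mT/m per cm) and provides simple per-subject straight-line threshold fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort import HardwareEnvelope, ThresholdMeasurement, hardware_max_amplitude
from .logistic import LogisticModelFit

__all__ = [
    "ThresholdCurve",
    "SubjectLinearFit",
    "threshold_curve",
    "threshold_at",
    "z_sensitivity",
    "per_subject_linear_fit",
]

#: Rise time (ms) at which z-offset sensitivity is reported by default.
DEFAULT_TAU_REF = 0.3


@dataclass(frozen=True)
class ThresholdCurve:
    """Population 50%-stimulation line dG(tau) = dGmin + tau * SRmin."""

    dGmin_mTm: float
    SRmin_mTm_per_ms: float
    covariates: Mapping[str, float]
    axis: str | None = None
    fit: LogisticModelFit | None = None

    def __call__(self, rise_time_ms: float) -> float:
        return threshold_at(self, rise_time_ms)


def threshold_curve(
    fit: LogisticModelFit,
    covariates: Mapping[str, float] | None = None,
    *,
    axis: str | None = None,
) -> ThresholdCurve:
    """Derive the 50% threshold line for a covariate context.

    ``covariates`` maps each fitted covariate name to the raw value at which
    the curve is evaluated; omitted covariates default to their center (i.e.
    the population mean, or isocenter for z-offset).
    """
    if not fit.converged:
        raise ValueError("threshold curve requires a converged fit")
    covariates = dict(covariates or {})
    b = fit.coef
    b2 = b[2]
    if b2 == 0:
        raise ZeroDivisionError("amplitude coefficient is zero: degenerate model")
    if b2 < 0:
        warnings.warn(
            "amplitude coefficient is negative: stimulation probability decreases "
            "with amplitude, which is nonphysical", stacklevel=2,
        )
    dgmin = -b[0] / b2
    srmin = -b[1] / b2
    for j, name in enumerate(fit.spec.names):
        phi = covariates.get(name, fit.spec.centers[name])
        centered = float(phi) - fit.spec.centers[name]
        covariates[name] = float(phi)
        dgmin -= (b[3 + 2 * j] / b2) * centered
        srmin -= (b[4 + 2 * j] / b2) * centered
    return ThresholdCurve(
        dGmin_mTm=float(dgmin),
        SRmin_mTm_per_ms=float(srmin),
        covariates=covariates,
        axis=axis if axis is not None else fit.axis,
        fit=fit,
    )


def threshold_at(curve: ThresholdCurve, rise_time_ms: float) -> float:
    """Threshold amplitude (mT/m) at a rise time; the tau->0 limit is dGmin."""
    if rise_time_ms <= 0:
        raise ValueError(f"rise time must be positive, got {rise_time_ms}")
    return curve.dGmin_mTm + rise_time_ms * curve.SRmin_mTm_per_ms


def z_sensitivity(
    fit: LogisticModelFit,
    tau_ref: float = DEFAULT_TAU_REF,
    covariates: Mapping[str, float] | None = None,
) -> float:
    """Threshold change per cm of displacement toward the feet, at tau_ref.

    d(threshold)/d(z) = -b_z/b2 - (b_ztau/b2)*tau_ref; positive values mean
    the threshold rises as the subject moves toward the foot end.  The other
    covariates do not enter (the curve is linear in each phi'_n), so
    ``covariates`` is accepted only for interface symmetry.
    """
    if "z_offset" not in fit.spec.names:
        raise ValueError("fit does not include the z_offset covariate")
    j = fit.spec.names.index("z_offset")
    b = fit.coef
    b2 = b[2]
    if b2 == 0:
        raise ZeroDivisionError("amplitude coefficient is zero: degenerate model")
    return float(-b[3 + 2 * j] / b2 - (b[4 + 2 * j] / b2) * tau_ref)


@dataclass(frozen=True)
class SubjectLinearFit:
    """Ordinary least-squares line through one subject's (tau, threshold) points."""

    subject_id: str
    axis: str
    slope_mTm_per_ms: float | None
    intercept_mTm: float | None
    n_points: int
    censor_rule: str
    fitted: bool

    def __call__(self, rise_time_ms: float) -> float:
        if not self.fitted:
            raise ValueError(f"subject {self.subject_id}: no usable fit")
        return self.intercept_mTm + self.slope_mTm_per_ms * rise_time_ms


def per_subject_linear_fit(
    measurements: Sequence[ThresholdMeasurement],
    *,
    env: HardwareEnvelope | None = None,
    censor_rule: str = "cap_plus_one",
) -> SubjectLinearFit:
    """OLS of threshold amplitude on rise time for one subject and axis.

    Censored (no-stimulation) points are either substituted by the hardware
    cap + 1 mT/m (``cap_plus_one``, a conservative lower-bound convention) or
    dropped (``omit``).  Fewer than two usable points yields an unfitted
    result rather than an error.
    """
    if censor_rule not in ("cap_plus_one", "omit"):
        raise ValueError(f"unknown censor_rule {censor_rule!r}")
    ids = {m.subject_id for m in measurements}
    axes = {m.axis for m in measurements}
    if len(ids) != 1 or len(axes) != 1:
        raise ValueError("per-subject fit expects measurements from one subject and one axis")
    env = env or HardwareEnvelope()

    taus, amps = [], []
    for m in measurements:
        if m.status == "threshold":
            taus.append(m.rise_time_ms)
            amps.append(m.amplitude_mTm)
        elif m.status == "no_pns" and censor_rule == "cap_plus_one":
            taus.append(m.rise_time_ms)
            amps.append(hardware_max_amplitude(m.rise_time_ms, env) + 1.0)

    sid, axis = ids.pop(), axes.pop()
    if len(taus) < 2 or len(set(taus)) < 2:
        return SubjectLinearFit(sid, axis, None, None, len(taus), censor_rule, fitted=False)
    slope, intercept = np.polyfit(np.asarray(taus), np.asarray(amps), 1)
    return SubjectLinearFit(
        subject_id=sid,
        axis=axis,
        slope_mTm_per_ms=float(slope),
        intercept_mTm=float(intercept),
        n_points=len(taus),
        censor_rule=censor_rule,
        fitted=True,
    )
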