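"""End-to-end drivers: cohort tables -> weighted fits -> threshold curves.

Thin composition layer used by the analysis scripts, the acceptance script
and the recovery tests; every step lives in its own module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cohort import (
    HardwareEnvelope,
    ProtocolConfig,
    SubjectRecord,
    ThresholdMeasurement,
)
from .logistic import LogisticModelFit, fit_pns_model
from .observations import compute_cell_weights, expand_measurements
from .simulate import CohortSimConfig, simulate_cohort
from .thresholds import ThresholdCurve, threshold_curve, z_sensitivity

__all__ = ["AxisResult", "fit_axis", "population_analysis", "recover_population_curve"]


@dataclass(frozen=True)
class AxisResult:
    axis: str
    fit: LogisticModelFit
    curve: ThresholdCurve


def fit_axis(
    subjects: Sequence[SubjectRecord],
    measurements: Sequence[ThresholdMeasurement],
    axis: str,
    covariates: Sequence[str] = (),
    *,
    curve_at: Mapping[str, float] | None = None,
    protocol: ProtocolConfig | None = None,
    env: HardwareEnvelope | None = None,
    censored_handling: str = "omit",
    weighting: str = "cell_fraction",
    **fit_options,
) -> AxisResult:
    """Fit one gradient axis and derive its population threshold curve.

    The curve is evaluated at ``curve_at`` covariate values (defaults: the
    population means, isocenter for z-offset).
    """
    per_axis = [m for m in measurements if m.axis == axis and m.tested]
    if not per_axis:
        raise ValueError(f"no tested measurements for axis {axis!r}")
    obs = expand_measurements(
        per_axis, protocol, env,
        subjects=subjects, censored_handling=censored_handling,
    )
    obs = compute_cell_weights(obs, measurements=per_axis, scheme=weighting)
    fit = fit_pns_model(obs, covariates, axis=axis, **fit_options)
    curve = threshold_curve(fit, curve_at, axis=axis)
    return AxisResult(axis=axis, fit=fit, curve=curve)


def population_analysis(
    subjects: Sequence[SubjectRecord],
    measurements: Sequence[ThresholdMeasurement],
    axes: Sequence[str] = ("x", "y", "z"),
    covariates: Sequence[str] = (),
    **kwargs,
) -> dict[str, AxisResult]:
    """Per-axis fits and threshold curves for a cohort."""
    return {ax: fit_axis(subjects, measurements, ax, covariates, **kwargs) for ax in axes}


def recover_population_curve(
    config: CohortSimConfig,
    *,
    covariates: Sequence[str] = ("z_offset",),
    axis: str | None = None,
    **fit_options,
) -> dict:
    """Simulate a cohort and push it through the full pipeline.

    Returns the recovered intercept/slope of the population threshold line at
    isocenter and, when the z-offset covariate is fitted, the recovered
    threshold-vs-displacement sensitivity, together with the generating truth.
    """
    axis = axis or config.axes[0]
    subjects, measurements, _truth = simulate_cohort(config)
    result = fit_axis(
        subjects,
        measurements,
        axis,
        covariates,
        protocol=config.protocol,
        env=config.envelope,
        **fit_options,
    )
    out = {
        "fit": result.fit,
        "curve": result.curve,
        "dgmin_true": config.dgmin_mean,
        "dgmin_est": result.curve.dGmin_mTm,
        "srmin_true": config.srmin_mean,
        "srmin_est": result.curve.SRmin_mTm_per_ms,
    }
    if "z_offset" in covariates:
        out["z_effect_true"] = config.z_effect
        out["z_effect_est"] = z_sensitivity(result.fit)
    return out
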