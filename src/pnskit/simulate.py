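"""Synthetic cohorts with the structure the threshold analysis assumes.

Each simulated subject carries a latent straight-line threshold curve
a_i + b_i * tau, with population variability on both intercept and slope and
linear covariate effects (age, sex, z-offset) on the intercept.  The exact
amplitude-titration protocol is then replayed against the latent threshold:
a coarse sweep in 20 mT/m steps up to the hardware-reachable cap, followed by
a 2 mT/m refinement ascending from the bottom of the bracketing interval.
In deterministic mode a presentation stimulates iff its amplitude reaches the
latent threshold, so the recorded threshold over-states the latent one by
less than one fine step; a logistic response mode adds trial-to-trial
response noise with slope ``kappa`` (per mT/m).

The generator emits tables in the cohort fixture format, so everything
downstream (expansion, weighting, fitting, curve derivation) can be exercised
end to end and scored against the known truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (
    HardwareEnvelope,
    ProtocolConfig,
    SubjectRecord,
    ThresholdMeasurement,
    hardware_max_amplitude,
    write_cohort,
)

__all__ = [
    "CohortSimConfig",
    "LatentSubject",
    "sample_population",
    "latent_threshold",
    "simulate_titration",
    "simulate_cohort",
    "generate_cohort_tables",
]


@dataclass(frozen=True)
class CohortSimConfig:
    """Population, protocol and response-model parameters for the generator.

    Defaults describe a cohort like the measured ones: a 60 mT/m mean
    rheobase-like intercept with 12 mT/m between-subject SD, a 150 mT/m/ms
    mean slope so thresholds span roughly 75-135 mT/m over 0.1-0.5 ms rise
    times, a middle-aged cohort (52 +- 17 years) with thresholds rising
    0.5 mT/m per year of age, no sex effect, and a 20 mT/m per cm z-offset
    effect.
    """

    n_subjects: int = 30
    seed: int = 0
    dgmin_mean: float = 60.0      # mT/m
    dgmin_sd: float = 12.0        # mT/m
    srmin_mean: float = 150.0     # mT/m/ms
    srmin_sd: float = 30.0        # mT/m/ms
    age_mean: float = 52.0        # years
    age_sd: float = 17.0          # years
    age_effect: float = 0.5       # mT/m per year (on the intercept)
    sex_effect: float = 0.0       # mT/m (M minus F)
    z_effect: float = 20.0        # mT/m per cm toward the feet
    axes: tuple[str, ...] = ("x",)
    rise_times: tuple[float, ...] = (0.1, 0.22, 0.3, 0.5)
    z_offsets: tuple[float, ...] = (0.0,)
    response_model: str = "deterministic"   # or "logistic"
    kappa: float = 1.0            # per mT/m; logistic response slope
    refine: str = "ascending"     # fine-scan direction
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    envelope: HardwareEnvelope = field(default_factory=HardwareEnvelope)
    site: str = "berkeley"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dgmin_sd < 0 or self.srmin_sd < 0 or self.age_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.response_model not in ("deterministic", "logistic"):
            raise ValueError(f"unknown response model {self.response_model!r}")
        if self.response_model == "logistic" and self.kappa <= 0:
            raise ValueError("kappa must be positive for the logistic response model")
        if self.refine not in ("ascending", "descending"):
            raise ValueError(f"unknown refinement direction {self.refine!r}")


@dataclass(frozen=True)
class LatentSubject:
    """One simulated subject: covariates plus latent threshold-line parameters."""

    subject_id: str
    age_years: int
    sex_code: int          # F=0, M=1
    a_mTm: float           # latent intercept (threshold at tau -> 0)
    b_mTm_per_ms: float    # latent slope


def _truncated_normal_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to (0, inf) by redraw."""
    if sd == 0:
        if mean <= 0:
            raise ValueError("degenerate distribution with non-positive mean")
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError("truncated normal failed to produce a positive draw")


def sample_population(
    config: CohortSimConfig, rng: np.random.Generator | None = None
) -> list[LatentSubject]:
    """Draw the latent cohort; deterministic given the config seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    subjects = []
    for i in range(config.n_subjects):
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 100))
        sex = int(rng.integers(0, 2))
        a_mean = (
            config.dgmin_mean
            + config.age_effect * (age - config.age_mean)
            + config.sex_effect * sex
        )
        a = _truncated_normal_positive(rng, a_mean, config.dgmin_sd)
        b = _truncated_normal_positive(rng, config.srmin_mean, config.srmin_sd)
        subjects.append(
            LatentSubject(
                subject_id=f"S{i + 1:03d}",
                age_years=age,
                sex_code=sex,
                a_mTm=a,
                b_mTm_per_ms=b,
            )
        )
    return subjects


def latent_threshold(
    subject: LatentSubject, rise_time_ms: float, z_offset_cm: float, config: CohortSimConfig
) -> float:
    """True stimulation threshold of a subject at (tau, z): a + b*tau + z_effect*z."""
    if rise_time_ms <= 0:
        raise ValueError("rise time must be positive")
    return subject.a_mTm + subject.b_mTm_per_ms * rise_time_ms + config.z_effect * z_offset_cm


def _coarse_levels(cap: float, coarse: float) -> list[float]:
    """Coarse probe amplitudes: multiples of the coarse step up to and
    including the reachable cap."""
    levels = [coarse * k for k in range(1, int(np.floor(cap / coarse + 1e-9)) + 1)]
    if not levels or levels[-1] < cap - 1e-9:
        levels.append(cap)
    return levels


def simulate_titration(
    latent_mTm: float,
    rise_time_ms: float,
    protocol: ProtocolConfig | None = None,
    env: HardwareEnvelope | None = None,
    *,
    response_model: str = "deterministic",
    kappa: float = 1.0,
    refine: str = "ascending",
    rng: np.random.Generator | None = None,
) -> tuple[str, float | None]:
    """Replay the titration protocol against a latent threshold.

    Returns ``("threshold", recorded)`` or ``("no_pns", None)``.  The coarse
    sweep ascends in coarse steps (the reachable cap is always probed last);
    the fine scan then walks the bracketing interval in fine steps, by
    default ascending from its bottom, and records the first stimulating
    amplitude.  In deterministic mode this guarantees
    ``0 <= recorded - latent < fine_step`` and censoring exactly when the
    latent threshold exceeds the cap.
    """
    if latent_mTm <= 0:
        raise ValueError("latent threshold must be positive")
    protocol = protocol or ProtocolConfig()
    env = env or HardwareEnvelope()
    cap = hardware_max_amplitude(rise_time_ms, env)

    if response_model == "deterministic":
        def stimulates(g: float) -> bool:
            return g >= latent_mTm - 1e-12
    elif response_model == "logistic":
        if rng is None:
            raise ValueError("logistic response model needs an rng")

        def stimulates(g: float) -> bool:
            return bool(rng.random() < expit(kappa * (g - latent_mTm)))
    else:
        raise ValueError(f"unknown response model {response_model!r}")

    first = None
    for level in _coarse_levels(cap, protocol.coarse_step):
        if stimulates(level):
            first = level
            break
    if first is None:
        return "no_pns", None

    n_fine = int(round(protocol.coarse_step / protocol.fine_step))
    grid = [first - protocol.coarse_step + k * protocol.fine_step for k in range(1, n_fine + 1)]
    grid = [g for g in grid if g > 0]
    if refine == "ascending":
        for g in grid:
            if stimulates(g):
                return "threshold", g
        return "threshold", first  # noisy responses never re-fired: keep the bracket top
    # descending: walk down from the stimulating level to the last firing amplitude
    recorded = first
    for g in reversed(grid[:-1]):
        if not stimulates(g):
            break
        recorded = g
    return "threshold", recorded


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[SubjectRecord], list[ThresholdMeasurement], pd.DataFrame]:
    """Generate a full cohort: subject records, measurements, latent truth table."""
    rng = np.random.default_rng(config.seed)
    latents = sample_population(config, rng)
    subjects = [
        SubjectRecord(
            subject_id=s.subject_id,
            site=config.site,
            sex="M" if s.sex_code == 1 else "F",
            age_years=s.age_years,
        )
        for s in latents
    ]
    measurements: list[ThresholdMeasurement] = []
    truth_rows = []
    for s in latents:
        for axis in config.axes:
            for z in config.z_offsets:
                for tau in config.rise_times:
                    t_star = latent_threshold(s, tau, z, config)
                    status, recorded = simulate_titration(
                        t_star,
                        tau,
                        config.protocol,
                        config.envelope,
                        response_model=config.response_model,
                        kappa=config.kappa,
                        refine=config.refine,
                        rng=rng,
                    )
                    measurements.append(
                        ThresholdMeasurement(
                            subject_id=s.subject_id,
                            axis=axis,
                            rise_time_ms=tau,
                            status=status,
                            amplitude_mTm=recorded,
                            z_offset_cm=z,
                        )
                    )
                    truth_rows.append(
                        {
                            "subject_id": s.subject_id,
                            "axis": axis,
                            "z_offset_cm": z,
                            "rise_time_ms": tau,
                            "latent_mTm": t_star,
                            "a_mTm": s.a_mTm,
                            "b_mTm_per_ms": s.b_mTm_per_ms,
                            "status": status,
                            "recorded_mTm": recorded,
                        }
                    )
    return subjects, measurements, pd.DataFrame(truth_rows)


def _config_dict(config: CohortSimConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def generate_cohort_tables(
    config: CohortSimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write subjects.csv / measurements.csv / manifest.json for a cohort.

    Byte-identical outputs for identical configs (the manifest embeds the
    config hash and the latent truth table for recovery scoring).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, measurements, truth = simulate_cohort(config)
    paths = {
        "subjects": out_dir / "subjects.csv",
        "measurements": out_dir / "measurements.csv",
        "manifest": out_dir / "manifest.json",
    }
    write_cohort(subjects, measurements, paths["subjects"], paths["measurements"])
    cfg = _config_dict(config)
    manifest = {
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "latent_truth": truth.to_dict(orient="records"),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
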