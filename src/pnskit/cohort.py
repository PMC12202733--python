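"""Cohort I/O: censored PNS threshold tables, hardware envelope, protocol.

A stimulation-threshold study records, for every subject, gradient axis and
ramp rise time, the lowest zero-to-peak gradient amplitude (mT/m) at which the
subject reported peripheral nerve stimulation.  Subjects who felt nothing up
to the highest amplitude the hardware can reach at that rise time are
right-censored (``no_pns``); axes that were skipped are ``not_tested``.

This module reads and validates those tables from a pair of CSV files
(subjects + measurements), writes them back losslessly, and encodes the
gradient hardware envelope and titration protocol that the rest of the
pipeline needs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SITES",
    "AXES",
    "RISE_TIME_GRIDS",
    "SubjectRecord",
    "ThresholdMeasurement",
    "HardwareEnvelope",
    "ProtocolConfig",
    "CohortError",
    "hardware_max_amplitude",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
]

SITES = ("berkeley", "erlangen")
AXES = ("x", "y", "z")
STATUSES = ("threshold", "no_pns", "not_tested")

#: Rise-time grids (ms) used at each measurement site.  The in-scanner grid
#: uses 0.22 ms instead of 0.2 ms to skip a mechanical resonance of the coil.
RISE_TIME_GRIDS: dict[str, tuple[float, ...]] = {
    "berkeley": (0.1, 0.22, 0.3, 0.5),
    "erlangen": (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
}


class CohortError(ValueError):
    """Raised on malformed or physically inconsistent cohort tables."""


@dataclass(frozen=True)
class SubjectRecord:
    """One volunteer: identity and the covariates recorded for them."""

    subject_id: str
    site: str
    sex: str                      # "M" or "F"
    age_years: int
    height_cm: float | None = None
    weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise CohortError(f"unknown site {self.site!r}")
        if self.sex not in ("M", "F"):
            raise CohortError(f"subject {self.subject_id}: sex must be M or F")
        if not (18 <= self.age_years <= 100):
            raise CohortError(f"subject {self.subject_id}: age {self.age_years} outside [18, 100]")
        for name, val in (("height_cm", self.height_cm), ("weight_kg", self.weight_kg)):
            if val is not None and val <= 0:
                raise CohortError(f"subject {self.subject_id}: {name} must be positive, got {val}")

    @property
    def sex_code(self) -> int:
        """Numeric coding used in regression designs: F=0, M=1."""
        return 1 if self.sex == "M" else 0


@dataclass(frozen=True)
class ThresholdMeasurement:
    """One subject x axis x rise-time x z-offset cell of a threshold table.

    ``amplitude_mTm`` is the recorded onset threshold (zero-to-peak) and is
    present iff ``status == "threshold"``.  ``z_offset_cm`` is the subject
    displacement along the bore toward the feet.
    """

    subject_id: str
    axis: str
    rise_time_ms: float
    status: str
    amplitude_mTm: float | None = None
    z_offset_cm: float = 0.0
    location: str = ""

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise CohortError(f"subject {self.subject_id}: axis must be one of {AXES}")
        if self.status not in STATUSES:
            raise CohortError(f"subject {self.subject_id}: bad status {self.status!r}")
        if self.rise_time_ms <= 0:
            raise CohortError(f"subject {self.subject_id}: rise time must be positive")
        if self.status == "threshold":
            if self.amplitude_mTm is None or self.amplitude_mTm <= 0:
                raise CohortError(
                    f"subject {self.subject_id} ({self.axis}, {self.rise_time_ms} ms): "
                    "threshold rows need a positive amplitude"
                )
        elif self.amplitude_mTm is not None:
            raise CohortError(
                f"subject {self.subject_id} ({self.axis}, {self.rise_time_ms} ms): "
                f"status {self.status} must not carry an amplitude"
            )

    @property
    def tested(self) -> bool:
        return self.status != "not_tested"


@dataclass(frozen=True)
class HardwareEnvelope:
    """Gradient system limits: slew rate, amplitude cap, nominal EPI limit."""

    slew_max: float = 900.0   # mT/m/ms
    g_max: float = 200.0      # mT/m
    g_nom: float = 85.0       # mT/m, thermal/amplifier limit for EPI readouts

    def __post_init__(self) -> None:
        if min(self.slew_max, self.g_max, self.g_nom) <= 0:
            raise CohortError("envelope limits must be strictly positive")
        if self.g_nom > self.g_max:
            raise CohortError("g_nom cannot exceed g_max")


@dataclass(frozen=True)
class ProtocolConfig:
    """Amplitude titration protocol: coarse sweep then fine refinement.

    The stimulus train itself (128 alternating bipolar trapezoids, 500 us
    plateau) is metadata: thresholds are zero-to-peak amplitudes throughout,
    and the fact that a polarity switch delivers an excursion of 2*dG over
    2*tau is never applied as a multiplier.
    """

    coarse_step: float = 20.0  # mT/m
    fine_step: float = 2.0     # mT/m
    n_pulses: int = 128
    plateau_us: float = 500.0

    def __post_init__(self) -> None:
        if self.coarse_step <= 0 or self.fine_step <= 0:
            raise CohortError("protocol steps must be positive")
        ratio = self.coarse_step / self.fine_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise CohortError("fine_step must divide coarse_step")


def hardware_max_amplitude(rise_time_ms: float, env: HardwareEnvelope | None = None) -> float:
    """Highest amplitude reachable at a given rise time: min(Gmax, slew * tau)."""
    if rise_time_ms <= 0:
        raise ValueError(f"rise time must be positive, got {rise_time_ms}")
    env = env or HardwareEnvelope()
    return min(env.g_max, env.slew_max * rise_time_ms)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

SUBJECT_COLUMNS = ["subject_id", "site", "sex", "age_years", "height_cm", "weight_kg"]
MEASUREMENT_COLUMNS = [
    "subject_id", "axis", "z_offset_cm", "rise_time_ms", "status", "amplitude_mTm", "location",
]


def _parse_optional_float(raw: str, *, where: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise CohortError(f"{where}: cannot parse {raw!r} as a number") from None


def read_cohort(
    subjects_path: str | Path,
    measurements_path: str | Path,
    *,
    envelope: HardwareEnvelope | None = None,
    cap_tolerance: float = 0.0,
    rise_time_grid: Sequence[float] | None = None,
) -> tuple[list[SubjectRecord], list[ThresholdMeasurement]]:
    """Read and validate a cohort from its subjects/measurements CSV pair.

    Parameters
    ----------
    envelope
        When given, every threshold amplitude is checked against
        ``hardware_max_amplitude`` for its rise time, allowing
        ``cap_tolerance`` mT/m of slack (recorded thresholds can sit one
        refinement step above the nominal slew-limited cap).  Pass ``None``
        for tables collected on rigs whose reachable amplitudes differ from
        the nominal envelope.
    rise_time_grid
        When given, rise times must belong to this grid; defaults to the
        site's standard grid (looked up per subject's site).
    """
    subjects: list[SubjectRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(subjects_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != SUBJECT_COLUMNS:
            raise CohortError(
                f"{subjects_path}: expected header {','.join(SUBJECT_COLUMNS)}"
            )
        for i, row in enumerate(reader, start=2):
            where = f"{subjects_path}:{i}"
            try:
                age = int(row["age_years"])
            except ValueError:
                raise CohortError(f"{where}: bad age {row['age_years']!r}") from None
            rec = SubjectRecord(
                subject_id=row["subject_id"].strip(),
                site=row["site"].strip(),
                sex=row["sex"].strip(),
                age_years=age,
                height_cm=_parse_optional_float(row["height_cm"], where=where),
                weight_kg=_parse_optional_float(row["weight_kg"], where=where),
            )
            key = (rec.site, rec.subject_id)
            if key in seen:
                raise CohortError(f"{where}: duplicate subject {rec.subject_id!r} at {rec.site}")
            seen.add(key)
            subjects.append(rec)

    site_by_id = {s.subject_id: s.site for s in subjects}

    measurements: list[ThresholdMeasurement] = []
    with open(measurements_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != MEASUREMENT_COLUMNS:
            raise CohortError(
                f"{measurements_path}: expected header {','.join(MEASUREMENT_COLUMNS)}"
            )
        for i, row in enumerate(reader, start=2):
            where = f"{measurements_path}:{i}"
            sid = row["subject_id"].strip()
            if sid not in site_by_id:
                raise CohortError(f"{where}: unknown subject {sid!r}")
            tau = _parse_optional_float(row["rise_time_ms"], where=where)
            if tau is None:
                raise CohortError(f"{where}: missing rise time")
            grid = rise_time_grid
            if grid is None:
                grid = RISE_TIME_GRIDS.get(site_by_id[sid])
            if grid is not None and not any(math.isclose(tau, g) for g in grid):
                raise CohortError(
                    f"{where}: rise time {tau} ms not on the site grid {tuple(grid)}"
                )
            m = ThresholdMeasurement(
                subject_id=sid,
                axis=row["axis"].strip(),
                rise_time_ms=tau,
                status=row["status"].strip(),
                amplitude_mTm=_parse_optional_float(row["amplitude_mTm"], where=where),
                z_offset_cm=_parse_optional_float(row["z_offset_cm"], where=where) or 0.0,
                location=row["location"].strip(),
            )
            if envelope is not None and m.status == "threshold":
                cap = hardware_max_amplitude(m.rise_time_ms, envelope)
                if m.amplitude_mTm > cap + cap_tolerance + 1e-9:
                    raise CohortError(
                        f"{where}: amplitude {m.amplitude_mTm} mT/m exceeds the "
                        f"hardware cap {cap:g} mT/m at tau={m.rise_time_ms} ms"
                    )
            measurements.append(m)
    return subjects, measurements


def write_cohort(
    subjects: Iterable[SubjectRecord],
    measurements: Iterable[ThresholdMeasurement],
    subjects_path: str | Path,
    measurements_path: str | Path,
) -> None:
    """Write a cohort to CSV; ``read_cohort`` round-trips it exactly."""

    def fmt(x: float | None) -> str:
        if x is None:
            return ""
        return repr(int(x)) if float(x).is_integer() else repr(float(x))

    with open(subjects_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SUBJECT_COLUMNS)
        for s in subjects:
            w.writerow([s.subject_id, s.site, s.sex, s.age_years,
                        fmt(s.height_cm), fmt(s.weight_kg)])
    with open(measurements_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MEASUREMENT_COLUMNS)
        for m in measurements:
            w.writerow([m.subject_id, m.axis, fmt(m.z_offset_cm), repr(float(m.rise_time_ms)),
                        m.status, fmt(m.amplitude_mTm), m.location])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    n = len(values)
    if n == 0:
        return None, None
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def summarize_cohort(subjects: Sequence[SubjectRecord]) -> dict:
    """Cohort demographics: n, sex split, mean/SD of age, height and weight.

    Means are taken over recorded (non-missing) values only; each field's
    count is reported alongside so partially missing metadata is explicit.
    """
    if not subjects:
        raise CohortError("cannot summarize an empty cohort")
    ages = [float(s.age_years) for s in subjects]
    heights = [s.height_cm for s in subjects if s.height_cm is not None]
    weights = [s.weight_kg for s in subjects if s.weight_kg is not None]
    age_mean, age_sd = _mean_sd(ages)
    h_mean, h_sd = _mean_sd(heights)
    w_mean, w_sd = _mean_sd(weights)
    return {
        "n": len(subjects),
        "n_male": sum(1 for s in subjects if s.sex == "M"),
        "n_female": sum(1 for s in subjects if s.sex == "F"),
        "age_mean": age_mean, "age_sd": age_sd, "age_n": len(ages),
        "height_mean": h_mean, "height_sd": h_sd, "height_n": len(heights),
        "weight_mean": w_mean, "weight_sd": w_sd, "weight_n": len(weights),
    }
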