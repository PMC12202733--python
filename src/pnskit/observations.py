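"""Expansion of censored threshold measurements into weighted binary rows.

The logistic dose-response model is fit to binary stimulated/not-stimulated
observations, not to thresholds directly.  The titration protocol guarantees
two facts per recorded threshold g: the subject stimulated at g, and did not
stimulate one fine step below it.  Each threshold row therefore expands into
a supra-threshold (g, S=1) and a sub-threshold (g - fine_step, S=0)
observation.

Subjects who never stimulated at a rise time (``no_pns``) only bound their
threshold from below, and how they enter the fit is a genuine modelling
choice exposed as ``censored_handling``:

* ``"omit"`` (default) — censored cells contribute nothing.  Because the
  paired construction pins the fitted 50% contour to the observed threshold
  cluster, adding censored mass at the top of the amplitude range instead
  drives the amplitude coefficient negative; omission keeps the fit physical
  and, in simulation, recovers generating population curves accurately.
* ``"zero_at_cap"`` — one S=0 observation at the highest reachable amplitude
  min(Gmax, slew*tau).  Faithful to "did not stimulate at the cap" but
  nonphysical in combination with the paired construction (see above).
* ``"cap_plus_one"`` — a conservative pseudo-threshold one mT/m above the
  cap, expanded into the same sub/supra pair as a measured threshold and
  flagged ``censored``.

Each (axis, rise time, z-offset) cell is weighted by the fraction of tested
subjects who genuinely stimulated in that cell, applied uniformly to all of
the cell's observations.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import (
    HardwareEnvelope,
    ProtocolConfig,
    SubjectRecord,
    ThresholdMeasurement,
    hardware_max_amplitude,
)

__all__ = ["BinaryObservation", "CENSORED_HANDLING_MODES", "expand_measurements",
           "compute_cell_weights", "observations_frame"]

logger = logging.getLogger(__name__)

CENSORED_HANDLING_MODES = ("omit", "zero_at_cap", "cap_plus_one")


@dataclass(frozen=True)
class BinaryObservation:
    """One weighted Bernoulli row for the dose-response regression."""

    rise_time_ms: float
    amplitude_mTm: float
    response: int                   # 1 = stimulated at this amplitude
    subject_id: str
    axis: str
    z_offset_cm: float = 0.0
    age_years: float | None = None
    sex_code: int | None = None     # F=0, M=1
    weight: float = 1.0
    censored: bool = False          # row derives from a no-stimulation cell

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValueError("response must be 0 or 1")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.amplitude_mTm <= 0:
            raise ValueError("amplitude must be positive")


def expand_measurements(
    measurements: Iterable[ThresholdMeasurement],
    protocol: ProtocolConfig | None = None,
    env: HardwareEnvelope | None = None,
    *,
    subjects: Sequence[SubjectRecord] | Mapping[str, SubjectRecord] | None = None,
    censored_handling: str = "omit",
) -> list[BinaryObservation]:
    """Expand threshold/censored measurements into binary observations.

    ``subjects`` (optional) attaches age and sex covariates to each row;
    ``not_tested`` measurements never contribute.
    """
    if censored_handling not in CENSORED_HANDLING_MODES:
        raise ValueError(
            f"censored_handling must be one of {CENSORED_HANDLING_MODES}, "
            f"got {censored_handling!r}"
        )
    protocol = protocol or ProtocolConfig()
    env = env or HardwareEnvelope()
    by_id: Mapping[str, SubjectRecord]
    if subjects is None:
        by_id = {}
    elif isinstance(subjects, Mapping):
        by_id = subjects
    else:
        by_id = {s.subject_id: s for s in subjects}

    out: list[BinaryObservation] = []
    for m in measurements:
        if m.status == "not_tested":
            continue
        subj = by_id.get(m.subject_id)
        common = dict(
            rise_time_ms=m.rise_time_ms,
            subject_id=m.subject_id,
            axis=m.axis,
            z_offset_cm=m.z_offset_cm,
            age_years=None if subj is None else float(subj.age_years),
            sex_code=None if subj is None else subj.sex_code,
        )

        def pair(g: float, censored: bool) -> None:
            out.append(BinaryObservation(amplitude_mTm=g, response=1,
                                         censored=censored, **common))
            below = g - protocol.fine_step
            if below > 0:
                out.append(BinaryObservation(amplitude_mTm=below, response=0,
                                             censored=censored, **common))

        if m.status == "threshold":
            pair(m.amplitude_mTm, censored=False)
            continue
        cap = hardware_max_amplitude(m.rise_time_ms, env)
        if censored_handling == "zero_at_cap":
            out.append(BinaryObservation(amplitude_mTm=cap, response=0,
                                         censored=True, **common))
        elif censored_handling == "cap_plus_one":
            pair(cap + 1.0, censored=True)
    return out


def compute_cell_weights(
    observations: Sequence[BinaryObservation],
    *,
    measurements: Sequence[ThresholdMeasurement] | None = None,
    scheme: str = "cell_fraction",
) -> list[BinaryObservation]:
    """Assign fitting weights per (axis, rise time, z-offset) cell.

    ``cell_fraction`` weights every observation in a cell by the fraction of
    that cell's tested subjects who genuinely stimulated; ``uniform`` sets
    all weights to 1.  Cells where nobody stimulated get weight 0 and thus
    drop out of the fit; a warning is logged for them.  Weights depend only
    on cell membership, so they are invariant to observation order and
    subject relabeling.

    Pass the source ``measurements`` so the tested count includes subjects
    whose censored rows were omitted from the expansion; without them the
    counts are reconstructed from the observations (exact for the
    ``zero_at_cap`` and ``cap_plus_one`` expansions, where every tested
    subject keeps at least one row).
    """
    if scheme == "uniform":
        return [replace(o, weight=1.0) for o in observations]
    if scheme != "cell_fraction":
        raise ValueError(f"unknown weighting scheme {scheme!r}")

    tested: dict[tuple, set[str]] = defaultdict(set)
    stimulated: dict[tuple, set[str]] = defaultdict(set)
    if measurements is not None:
        for m in measurements:
            if not m.tested:
                continue
            cell = (m.axis, m.rise_time_ms, m.z_offset_cm)
            tested[cell].add(m.subject_id)
            if m.status == "threshold":
                stimulated[cell].add(m.subject_id)
    for o in observations:
        cell = (o.axis, o.rise_time_ms, o.z_offset_cm)
        tested[cell].add(o.subject_id)
        if o.response == 1 and not o.censored:
            stimulated[cell].add(o.subject_id)

    out = []
    warned: set[tuple] = set()
    for o in observations:
        cell = (o.axis, o.rise_time_ms, o.z_offset_cm)
        frac = len(stimulated[cell]) / len(tested[cell])
        if frac == 0.0 and cell not in warned:
            warned.add(cell)
            logger.warning(
                "cell axis=%s tau=%g ms z=%g cm: no subject stimulated; weight 0",
                *cell,
            )
        out.append(replace(o, weight=frac))
    return out


def observations_frame(observations: Sequence[BinaryObservation]) -> pd.DataFrame:
    """Tabular export of expanded observations (one row per Bernoulli trial)."""
    return pd.DataFrame(
        {
            "axis": [o.axis for o in observations],
            "rise_time_ms": [o.rise_time_ms for o in observations],
            "amplitude_mTm": [o.amplitude_mTm for o in observations],
            "response": [o.response for o in observations],
            "weight": [o.weight for o in observations],
            "subject_id": [o.subject_id for o in observations],
            "age_years": [o.age_years for o in observations],
            "sex_code": [o.sex_code for o in observations],
            "z_offset_cm": [o.z_offset_cm for o in observations],
            "censored": [o.censored for o in observations],
        }
    )
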