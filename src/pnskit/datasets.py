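"""Bundled study cohorts.

Two measured cohorts ship with the package as plain CSV pairs:

* ``berkeley_isocenter`` — 29 volunteers characterized in the scanner with the
  glabella at isocenter; rise times 0.1/0.22/0.3/0.5 ms; thresholds capped by
  the in-scanner envelope (900 mT/m/ms slew, 200 mT/m amplitude).
* ``erlangen`` — 32 volunteers characterized earlier on the factory test rig
  (coil outside the scanner); rise times 0.1–0.8 ms in 0.1-ms steps.  A few
  recorded thresholds sit just above the nominal slew-limited cap (e.g.
  91 mT/m at 0.1 ms, 195 at 0.2 ms), so this loader validates amplitudes
  against the 200 mT/m amplitude limit only.

The in-scanner table contains a single threshold one refinement step above
the nominal cap (92 mT/m at 0.1 ms), so its loader validates against the
envelope with a one-fine-step (2 mT/m) tolerance.
"""

from __future__ import annotations

from importlib import resources

from .cohort import (
    HardwareEnvelope,
    SubjectRecord,
    ThresholdMeasurement,
    read_cohort,
)

__all__ = ["berkeley_isocenter", "erlangen", "SCANNER_ENVELOPE"]

#: In-scanner gradient envelope of the head coil the cohorts were measured on.
SCANNER_ENVELOPE = HardwareEnvelope(slew_max=900.0, g_max=200.0, g_nom=85.0)


def _data_path(name: str):
    return resources.files("pnskit.data").joinpath(name)


def berkeley_isocenter() -> tuple[list[SubjectRecord], list[ThresholdMeasurement]]:
    """In-scanner cohort (29 subjects, isocenter), envelope-validated."""
    with resources.as_file(_data_path("berkeley_iso_subjects.csv")) as sp, \
            resources.as_file(_data_path("berkeley_iso_measurements.csv")) as mp:
        return read_cohort(sp, mp, envelope=SCANNER_ENVELOPE, cap_tolerance=2.0)


def erlangen() -> tuple[list[SubjectRecord], list[ThresholdMeasurement]]:
    """Factory-rig cohort (32 subjects); amplitude-limit validation only."""
    with resources.as_file(_data_path("erlangen_subjects.csv")) as sp, \
            resources.as_file(_data_path("erlangen_measurements.csv")) as mp:
        return read_cohort(sp, mp, envelope=None)
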