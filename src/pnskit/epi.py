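"""EPI echo-spacing feasibility over gradient amplitude and rise time.

For a trapezoidal EPI readout with no ramp sampling, one echo spacing is two
ramps plus the flat top that carries the full k-space traversal:

    ESP(G, tau) = 2*tau + A/G        [ms]

where A is the gradient-time area (mT/m * ms) required to cover the k-space
width 1/r for isotropic in-plane resolution r, gammabar*A = 1/r.  Operating
on the slew-limited locus tau = G/SRmax makes ESP a convex function of G with
an unconstrained minimizer G* = sqrt(A*SRmax/2) — the "corner point" beyond
which more amplitude no longer shortens the echo spacing.  Amplitude limits
(the 200 mT/m hardware cap or the 85 mT/m nominal thermal limit) clip G*;
PNS threshold curves clip the feasible region from above in amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import HardwareEnvelope
from .thresholds import ThresholdCurve, threshold_at

__all__ = [
    "EpiConfig",
    "EchoSpacingPoint",
    "SlewInfeasibleError",
    "readout_area",
    "echo_spacing",
    "corner_point",
    "pns_feasible_region",
]

#: Proton gyromagnetic ratio over 2*pi, MHz per tesla.
GAMMA_BAR_MHZ_PER_T = 42.577


class SlewInfeasibleError(ValueError):
    """The requested (G, tau) pair violates the slew-rate limit."""


@dataclass(frozen=True)
class EpiConfig:
    """Readout resolution and hardware context for echo-spacing calculations."""

    resolution_mm: float
    envelope: HardwareEnvelope = field(default_factory=HardwareEnvelope)
    gamma_bar_MHz_per_T: float = GAMMA_BAR_MHZ_PER_T

    def __post_init__(self) -> None:
        if self.resolution_mm <= 0:
            raise ValueError("resolution must be positive")
        if self.gamma_bar_MHz_per_T <= 0:
            raise ValueError("gyromagnetic ratio must be positive")

    @property
    def area_mTm_ms(self) -> float:
        return readout_area(self.resolution_mm, self.gamma_bar_MHz_per_T)


@dataclass(frozen=True)
class EchoSpacingPoint:
    """One (G, tau) operating point with its echo spacing and feasibility flags."""

    amplitude_mTm: float
    rise_time_ms: float
    esp_ms: float
    slew_feasible: bool
    amplitude_feasible: bool
    pns_feasible: bool | None = None


def readout_area(resolution_mm: float, gamma_bar_MHz_per_T: float = GAMMA_BAR_MHZ_PER_T) -> float:
    """Gradient-time area (mT/m * ms) whose k-space width equals 1/r.

    gammabar [MHz/T] * A [mT/m*ms] = gammabar*A [cycles/mm * 1e-3], and the
    full k-width for resolution r mm is 1/r cycles/mm, so
    A = 1e3 / (r * gammabar).
    """
    if resolution_mm <= 0:
        raise ValueError("resolution must be positive")
    return 1e3 / (resolution_mm * gamma_bar_MHz_per_T)


def echo_spacing(amplitude_mTm: float, rise_time_ms: float, config: EpiConfig) -> float:
    """ESP = 2*tau + A/G (ms) for a slew- and amplitude-feasible point."""
    env = config.envelope
    if amplitude_mTm <= 0:
        raise ValueError("amplitude must be positive")
    if amplitude_mTm > env.g_max:
        raise ValueError(
            f"amplitude {amplitude_mTm} mT/m exceeds the {env.g_max} mT/m hardware cap"
        )
    if rise_time_ms < amplitude_mTm / env.slew_max - 1e-12:
        raise SlewInfeasibleError(
            f"rise time {rise_time_ms} ms cannot reach {amplitude_mTm} mT/m "
            f"at {env.slew_max} mT/m/ms"
        )
    return 2.0 * rise_time_ms + config.area_mTm_ms / amplitude_mTm


def corner_point(config: EpiConfig, amplitude_limit: float | None = None) -> EchoSpacingPoint:
    """Minimum-ESP operating point on the slew-limited locus tau = G/SRmax.

    ESP(G) = 2G/SR + A/G is convex with minimizer G* = sqrt(A*SR/2); an
    amplitude limit (e.g. the nominal EPI limit G_nom) clips G* and the echo
    spacing is re-evaluated at the clipped amplitude.
    """
    env = config.envelope
    a = config.area_mTm_ms
    g_star = float(np.sqrt(a * env.slew_max / 2.0))
    limit = env.g_max if amplitude_limit is None else min(amplitude_limit, env.g_max)
    g = min(g_star, limit)
    tau = g / env.slew_max
    return EchoSpacingPoint(
        amplitude_mTm=g,
        rise_time_ms=tau,
        esp_ms=echo_spacing(g, tau, config),
        slew_feasible=True,
        amplitude_feasible=True,
    )


def pns_feasible_region(
    curve: ThresholdCurve,
    config: EpiConfig,
    amplitudes_mTm: Sequence[float],
    rise_times_ms: Sequence[float],
) -> tuple[pd.DataFrame, dict]:
    """Grid of operating points with hardware and PNS feasibility flags.

    A point is PNS-feasible when its amplitude stays at or below the
    population threshold curve at its rise time.  The summary reports the
    minimum echo spacing over fully feasible points and whether the PNS
    constraint forces it above the unconstrained hardware corner.
    """
    env = config.envelope
    rows = []
    for tau in rise_times_ms:
        for g in amplitudes_mTm:
            slew_ok = g <= env.slew_max * tau + 1e-12
            amp_ok = 0 < g <= env.g_max
            pns_ok = g <= threshold_at(curve, tau)
            esp = 2.0 * tau + config.area_mTm_ms / g if (slew_ok and amp_ok) else np.nan
            rows.append(
                {
                    "G_mTm": g,
                    "tau_ms": tau,
                    "esp_ms": esp,
                    "slew_ok": slew_ok,
                    "amp_ok": amp_ok,
                    "pns_ok": pns_ok,
                }
            )
    grid = pd.DataFrame(rows)
    feasible = grid[grid.slew_ok & grid.amp_ok & grid.pns_ok]
    corner = corner_point(config)
    summary = {
        "min_feasible_esp_ms": float(feasible.esp_ms.min()) if len(feasible) else None,
        "hardware_corner_esp_ms": corner.esp_ms,
        "pns_limited": bool(
            len(feasible) == 0 or feasible.esp_ms.min() > corner.esp_ms + 1e-9
        ),
    }
    return grid, summary
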