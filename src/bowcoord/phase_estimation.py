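"""Continuous relative phase from the analytic signal.

The relative phase of bow inclination versus bow velocity is estimated
from the Hilbert transforms of bow velocity and bow angular velocity
(both naturally zero-centered).  For the figure-of-eight pattern the
velocity phase is halved before subtraction, to compensate for the 2:1
frequency relation, and the resulting relative phase is doubled for
comparability with the circular patterns.  A constant offset equal to the
nearest integer multiple of the 90-degree quadrature step is subtracted
so that the result is referenced to zero; relative phase is positive for
a phase lead of inclination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

#: quadrature step used for the constant-offset subtraction
OFFSET_STEP_DEG = 90.0


@dataclass
class ContinuousPhase:
    """Unwrapped instantaneous phase of one channel, in degrees."""

    time: np.ndarray
    phase_deg: np.ndarray

    @property
    def total_cycles(self) -> float:
        return abs(self.phase_deg[-1] - self.phase_deg[0]) / 360.0


@dataclass
class RelativePhaseSeries:
    """Continuous relative phase after constant-offset subtraction."""

    time: np.ndarray
    delta_phi_deg: np.ndarray
    pattern: str
    subtracted_offset_deg: float = 0.0


def continuous_phase(x: np.ndarray, sample_rate_hz: float) -> ContinuousPhase:
    """Unwrapped instantaneous phase of a quasi-sinusoidal signal."""
    x = np.asarray(x, dtype=float)
    if not np.any(x != 0.0):
        raise ValueError("phase of an all-zero signal is undefined")
    analytic = _signal.hilbert(x)
    phase = np.degrees(np.unwrap(np.angle(analytic)))
    t = np.arange(len(x)) / sample_rate_hz
    return ContinuousPhase(time=t, phase_deg=phase)


def subtract_nominal_offset(delta_deg: np.ndarray) -> tuple[np.ndarray, float]:
    """Reference a relative-phase signal to zero.

    Subtracts the integer multiple of :data:`OFFSET_STEP_DEG` closest to
    the central-segment median of the signal.  Idempotent as long as the
    referenced signal stays within +-45 degrees of zero.
    """
    delta_deg = np.asarray(delta_deg, dtype=float)
    n = len(delta_deg)
    trim = n // 10
    central = delta_deg[trim: n - trim] if n - 2 * trim > 0 else delta_deg
    offset = OFFSET_STEP_DEG * np.round(np.median(central) / OFFSET_STEP_DEG)
    return delta_deg - offset, float(offset)


def relative_phase(
    vel_phase: ContinuousPhase,
    angvel_phase: ContinuousPhase,
    pattern: str,
) -> RelativePhaseSeries:
    """Continuous relative phase of angular velocity versus velocity.

    For Fo8 the velocity phase is divided by two before subtraction and
    the difference is doubled afterwards; the constant-offset subtraction
    acts on the doubled signal, which removes the half-phase branch
    ambiguity introduced by the division.
    """
    if pattern not in ("CW", "ACW", "Fo8"):
        raise ValueError(f"unknown pattern {pattern!r}")
    if len(vel_phase.time) != len(angvel_phase.time) or not np.allclose(
        vel_phase.time, angvel_phase.time
    ):
        raise ValueError("phase signals must share one time grid")
    if pattern == "Fo8":
        delta = 2.0 * (angvel_phase.phase_deg - vel_phase.phase_deg / 2.0)
    else:
        delta = angvel_phase.phase_deg - vel_phase.phase_deg
    delta, offset = subtract_nominal_offset(delta)
    return RelativePhaseSeries(
        time=vel_phase.time.copy(),
        delta_phi_deg=delta,
        pattern=pattern,
        subtracted_offset_deg=offset,
    )


def phase_at(series: RelativePhaseSeries, t: float | np.ndarray) -> float | np.ndarray:
    """Linear interpolation of the relative phase at time(s) ``t``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < series.time[0]) or np.any(t_arr > series.time[-1]):
        raise ValueError("t outside the support of the series")
    out = np.interp(t_arr, series.time, series.delta_phi_deg)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out
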