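"""Zero-phase filtering and differentiation of bowing channels.

Defaults: velocity low-pass 2nd-order Butterworth at 30 Hz, angular
velocity low-pass at 30 Hz, crossing-band width low-pass at 48 Hz, all
applied forward and backward (zero phase lag, doubled effective order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification."""

    order: int = 2
    cutoff_hz: float = 30.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")


#: pipeline defaults; the inclination entry mirrors the angular-velocity
#: cutoff and stands in for the stricter upstream smoothing of the raw
#: orientation data that our inputs have already received
DEFAULT_FILTERS: dict[str, FilterSpec] = {
    "velocity": FilterSpec(order=2, cutoff_hz=30.0),
    "angular_velocity": FilterSpec(order=2, cutoff_hz=30.0),
    "band_halfwidth": FilterSpec(order=2, cutoff_hz=48.0),
    "inclination": FilterSpec(order=2, cutoff_hz=30.0),
}


def zero_phase_lowpass(
    x: np.ndarray, spec: FilterSpec, sample_rate_hz: float
) -> np.ndarray:
    """Forward-backward Butterworth low-pass (zero phase lag).

    Raises if the input contains non-finite values (naming the first
    offending index) or if the cutoff reaches the Nyquist frequency.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite value in input at index {bad[0]}")
    nyquist = sample_rate_hz / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist ({nyquist} Hz)"
        )
    if len(x) <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=sample_rate_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, x)


def butterworth_magnitude(
    spec: FilterSpec, freq_hz: float, sample_rate_hz: float
) -> float:
    """Single-pass magnitude response of the filter at ``freq_hz``."""
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=sample_rate_hz,
                        output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=sample_rate_hz)
    return float(np.abs(h[0]))


def differentiate(
    x: np.ndarray,
    sample_rate_hz: float,
    spec: FilterSpec | None = None,
) -> np.ndarray:
    """Central-difference derivative followed by a zero-phase low-pass.

    The default post-filter is the 2nd-order 30 Hz specification used for
    angular velocity.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    deriv = np.gradient(x, 1.0 / sample_rate_hz)
    if spec is None:
        spec = DEFAULT_FILTERS["angular_velocity"]
    return zero_phase_lowpass(deriv, spec, sample_rate_hz)
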