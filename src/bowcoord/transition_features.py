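"""Bow-change detection and per-transition feature extraction.

Bow changes are zero crossings of the (filtered) bow-velocity signal with
sub-sample timing by linear interpolation.  For every bow change the
module extracts both relative-phase estimates (Hilbert-based and
time-domain), both normalized-range estimates (amplitude-based and
time-domain), the inclination offset and context indices.

Time-domain estimators, assuming a sinusoidal inclination:

* relative phase  = 360 * (t_bc - t_c) / T, positive when the crossing of
  the band center precedes the bow change;
* normalized range = sin(pi * dt / T), where dt is the time the bow
  spends inside the crossing band during the transition.

T is the full velocity cycle between the two same-direction bow changes
bracketing the event.  Features that cannot be computed are emitted as
NaN together with a reason code, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phase_estimation import continuous_phase, phase_at, relative_phase
from .preprocessing import DEFAULT_FILTERS, differentiate, zero_phase_lowpass
from .synthetic_data import BowingTimeSeries

#: notes per quarter-note beat; one beat is discarded at each selection end
DEFAULT_NOTES_PER_BEAT = 4

DOWN_TO_UP = "down_to_up"
UP_TO_DOWN = "up_to_down"


@dataclass(frozen=True)
class BowChangeEvent:
    """One reversal of bowing direction."""

    index: int
    t_bc: float
    direction: str
    bar: int | None = None
    beat: int | None = None
    sub_beat: int | None = None
    string_pair: str | None = None


# ---------------------------------------------------------------------- #
# event detection


def detect_bow_changes(
    velocity: np.ndarray, sample_rate_hz: float
) -> list[BowChangeEvent]:
    """Zero crossings of the velocity signal, with sub-sample timing.

    A sample that is exactly zero yields an event at that sample's time.
    Directions follow the down-bow-positive convention: a positive-to-
    negative crossing ends a down bow (``down_to_up``).
    """
    v = np.asarray(velocity, dtype=float)
    t = np.arange(len(v)) / sample_rate_hz
    events: list[tuple[float, str]] = []

    sign = np.sign(v)
    # exact zeros: event at the sample; direction from surrounding signs
    zero_idx = np.flatnonzero(sign == 0)
    for i in zero_idx:
        before = sign[:i][sign[:i] != 0]
        after = sign[i + 1:][sign[i + 1:] != 0]
        if before.size == 0 and after.size == 0:
            continue
        if before.size and after.size and before[-1] == after[0]:
            continue  # touch without reversal
        if before.size:
            direction = DOWN_TO_UP if before[-1] > 0 else UP_TO_DOWN
        else:
            # zero at the segment edge: the reversal into the first stroke
            direction = UP_TO_DOWN if after[0] > 0 else DOWN_TO_UP
        events.append((t[i], direction))

    # strict sign changes between adjacent non-zero samples
    nz = np.flatnonzero(sign != 0)
    vi, ti = v[nz], t[nz]
    flips = np.flatnonzero(np.sign(vi[:-1]) != np.sign(vi[1:]))
    for j in flips:
        if nz[j + 1] - nz[j] > 1:
            continue  # separated by exact zeros, handled above
        t_cross = ti[j] + (ti[j + 1] - ti[j]) * (-vi[j]) / (vi[j + 1] - vi[j])
        direction = DOWN_TO_UP if vi[j] > 0 else UP_TO_DOWN
        events.append((t_cross, direction))

    events.sort(key=lambda e: e[0])
    return [
        BowChangeEvent(index=i, t_bc=tc, direction=d)
        for i, (tc, d) in enumerate(events)
    ]


def trim_selection(
    events: list[BowChangeEvent], notes_per_beat: int = DEFAULT_NOTES_PER_BEAT
) -> list[BowChangeEvent]:
    """Discard the first and last beat (``notes_per_beat`` events each)."""
    if len(events) < 2 * notes_per_beat + 1:
        raise ValueError(
            f"need more than {2 * notes_per_beat} events to trim a beat at "
            f"each end, got {len(events)}"
        )
    return list(events[notes_per_beat:-notes_per_beat])


# ---------------------------------------------------------------------- #
# sub-sample helpers


def _level_crossing_times(
    x: np.ndarray, t: np.ndarray, level: float
) -> np.ndarray:
    """All times at which ``x`` crosses ``level`` (linear interpolation)."""
    d = x - level
    out = list(t[np.flatnonzero(d == 0)])
    s = np.sign(d)
    nz = np.flatnonzero(s != 0)
    di, ti = d[nz], t[nz]
    flips = np.flatnonzero(np.sign(di[:-1]) != np.sign(di[1:]))
    for j in flips:
        if nz[j + 1] - nz[j] > 1:
            continue
        out.append(ti[j] + (ti[j + 1] - ti[j]) * (-di[j]) / (di[j + 1] - di[j]))
    return np.sort(np.asarray(out))


def _refined_extremum(x: np.ndarray, i: int) -> float:
    """Quadratic-vertex refinement of a sample-level extremum value."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(y1)
    return float(y1 - (y0 - y2) ** 2 / (8.0 * denom))


# ---------------------------------------------------------------------- #
# per-event features


def cycle_duration(events: list[BowChangeEvent], i: int) -> float:
    """Full velocity cycle bracketing event ``i``.

    Time between the same-direction bow changes immediately before and
    after the event; at segment edges the nearest available full cycle is
    used instead.
    """
    if len(events) < 3:
        raise ValueError("need at least 3 events to estimate a cycle duration")
    if 0 < i < len(events) - 1:
        return events[i + 1].t_bc - events[i - 1].t_bc
    if i == 0:
        return events[2].t_bc - events[0].t_bc
    return events[i].t_bc - events[i - 2].t_bc


def crossing_center_time(
    inclination: np.ndarray,
    time: np.ndarray,
    band_center: float,
    event: BowChangeEvent,
    cycle_duration_s: float,
    boundary_offsets: tuple[float, ...] = (0.0,),
) -> tuple[float, float]:
    """Sub-sample time of the boundary crossing belonging to a transition.

    Returns ``(t_center, boundary_level)`` where the boundary level is the
    inclination value crossed.  The crossing nearest the bow change is
    used; if no crossing falls within one cycle the feature is missing
    (``(nan, nan)``).
    """
    best_t, best_level = np.nan, np.nan
    best_dist = np.inf
    for offset in boundary_offsets:
        level = band_center + offset
        crossings = _level_crossing_times(inclination, time, level)
        if crossings.size == 0:
            continue
        k = np.argmin(np.abs(crossings - event.t_bc))
        dist = abs(crossings[k] - event.t_bc)
        if dist < best_dist:
            best_dist = dist
            best_t, best_level = float(crossings[k]), float(level)
    if not np.isfinite(best_t) or best_dist > cycle_duration_s:
        return np.nan, np.nan
    return best_t, best_level


def time_domain_phase(t_bc: float, t_center: float, cycle_duration_s: float) -> float:
    """Relative phase from the bow-change / center-crossing time offset."""
    if cycle_duration_s <= 0:
        raise ValueError("cycle_duration must be positive")
    return 360.0 * (t_bc - t_center) / cycle_duration_s


def transition_duration(
    inclination: np.ndarray,
    time: np.ndarray,
    lower_edge: float,
    upper_edge: float,
    t_center: float,
    cycle_duration_s: float,
) -> float:
    """Time spent inside the crossing band during one transition.

    Band entry is the last crossing of either band edge before
    ``t_center``; exit is the first one after.  Missing (NaN) when the
    band is not fully traversed (e.g. wider than the inclination extent).
    """
    if not np.isfinite(t_center):
        return np.nan
    crossings = np.concatenate(
        [
            _level_crossing_times(inclination, time, lower_edge),
            _level_crossing_times(inclination, time, upper_edge),
        ]
    )
    before = crossings[crossings < t_center]
    after = crossings[crossings > t_center]
    if before.size == 0 or after.size == 0:
        return np.nan
    duration = float(np.min(after) - np.max(before))
    if duration > cycle_duration_s:
        return np.nan
    return duration


def time_domain_range(transition_duration_s: float, cycle_duration_s: float) -> float:
    """Normalized range from the transition duration, sinusoidal model."""
    if cycle_duration_s <= 0:
        raise ValueError("cycle_duration must be positive")
    if not np.isfinite(transition_duration_s):
        return np.nan
    if transition_duration_s < 0:
        raise ValueError("transition duration must be non-negative")
    if transition_duration_s > cycle_duration_s / 2.0:
        raise ValueError(
            "transition duration exceeds half a cycle; inconsistent with the "
            "sinusoidal model"
        )
    return float(np.sin(np.pi * transition_duration_s / cycle_duration_s))


def peak_to_peak_extent(
    inclination: np.ndarray, time: np.ndarray, event: BowChangeEvent
) -> float:
    """Absolute difference of the inclination peaks flanking a bow change."""
    x = np.asarray(inclination, dtype=float)
    d = np.diff(x)
    s = np.sign(d)
    s_nz = np.where(s == 0, 1, s)
    ext_idx = np.flatnonzero(s_nz[:-1] != s_nz[1:]) + 1
    if ext_idx.size == 0:
        return np.nan
    ext_t = time[ext_idx]
    before = ext_idx[ext_t < event.t_bc]
    after = ext_idx[ext_t > event.t_bc]
    if before.size == 0 or after.size == 0:
        return np.nan
    peak_before = _refined_extremum(x, before[-1])
    peak_after = _refined_extremum(x, after[0])
    return abs(peak_after - peak_before)


def amplitude_normalized_range(
    band_width_at_t_center: float, peak_to_peak_extent_deg: float
) -> float:
    """Ratio of the full band width to the peak-to-peak inclination extent."""
    if not np.isfinite(peak_to_peak_extent_deg) or peak_to_peak_extent_deg == 0:
        raise ValueError("peak-to-peak extent must be finite and non-zero")
    return float(band_width_at_t_center / peak_to_peak_extent_deg)


def inclination_offset(
    theta_at_bc: float, theta_at_prev_bc: float, reference_deg: float
) -> float:
    """Mean inclination at two successive bow changes, re the crossing center."""
    return 0.5 * (theta_at_bc + theta_at_prev_bc) - reference_deg


# ---------------------------------------------------------------------- #
# orchestrator

FEATURE_COLUMNS = [
    "delta_phi_hilbert_deg",
    "delta_phi_time_deg",
    "r_amp",
    "r_time",
    "theta_offset_deg",
    "band_width_deg",
    "transition_duration_s",
    "cycle_duration_s",
    "peak_to_peak_extent_deg",
]


def extract_features(
    series: BowingTimeSeries,
    *,
    trim: bool = True,
    notes_per_beat: int = DEFAULT_NOTES_PER_BEAT,
    filters: dict | None = None,
) -> pd.DataFrame:
    """Full per-transition feature table for one bowing sequence.

    Applies the default zero-phase filters, detects and (optionally)
    trims bow changes, estimates the continuous relative phase, and
    computes every per-event feature.  One row per retained bow change;
    uncomputable features are NaN with a reason in the ``flags`` column.
    """
    fs = series.sample_rate_hz
    specs = dict(DEFAULT_FILTERS)
    if filters:
        specs.update(filters)

    v = zero_phase_lowpass(series.velocity, specs["velocity"], fs)
    theta = zero_phase_lowpass(series.inclination, specs["inclination"], fs)
    w = np.clip(
        zero_phase_lowpass(series.band_halfwidth, specs["band_halfwidth"], fs),
        0.0,
        None,
    )
    angvel = differentiate(theta, fs, specs["angular_velocity"])
    t = series.time

    pattern = series.metadata.get("pattern", "CW")
    boundary_offsets = series.boundary_offsets_deg
    n_transitions = 4 if pattern == "Fo8" else 2

    all_events = detect_bow_changes(v, fs)
    if trim:
        retained = trim_selection(all_events, notes_per_beat)
    else:
        retained = all_events

    rel = relative_phase(
        continuous_phase(v, fs), continuous_phase(angvel, fs), pattern
    )

    theta_of = lambda tt: float(np.interp(tt, t, theta))  # noqa: E731
    w_of = lambda tt: float(np.interp(tt, t, w))  # noqa: E731

    rows = []
    for ev in retained:
        i = ev.index
        flags: list[str] = []
        T = cycle_duration(all_events, i)

        try:
            dphi_h = phase_at(rel, ev.t_bc)
        except ValueError:
            dphi_h = np.nan
            flags.append("hilbert_phase_outside_support")

        t_center, boundary_level = crossing_center_time(
            theta, t, series.band_center, ev, T, boundary_offsets
        )
        if np.isfinite(t_center):
            dphi_t = time_domain_phase(ev.t_bc, t_center, T)
            w_at_tc = w_of(t_center)
            dt = transition_duration(
                theta, t, boundary_level - w_at_tc, boundary_level + w_at_tc,
                t_center, T,
            )
            if not np.isfinite(dt):
                flags.append("band_not_traversed")
        else:
            dphi_t, dt, w_at_tc = np.nan, np.nan, np.nan
            flags.append("no_center_crossing_within_cycle")

        try:
            r_time = time_domain_range(dt, T)
        except ValueError:
            r_time = np.nan
            flags.append("transition_longer_than_half_cycle")

        extent = peak_to_peak_extent(theta, t, ev)
        if not np.isfinite(extent):
            flags.append("no_flanking_extrema")

        if pattern == "Fo8":
            r_amp = np.nan
            flags.append("r_amp_undefined_for_Fo8")
        elif np.isfinite(extent) and extent > 0 and np.isfinite(w_at_tc):
            r_amp = amplitude_normalized_range(2.0 * w_at_tc, extent)
        else:
            r_amp = np.nan
            if "no_flanking_extrema" not in flags:
                flags.append("r_amp_inputs_missing")

        if i > 0:
            prev = all_events[i - 1]
            ref = series.band_center
            if pattern == "Fo8":
                _, prev_level = crossing_center_time(
                    theta, t, series.band_center, prev, T, boundary_offsets
                )
                if np.isfinite(prev_level) and np.isfinite(boundary_level):
                    ref = 0.5 * (prev_level + boundary_level)
                else:
                    ref = np.nan
            theta_off = (
                inclination_offset(theta_of(ev.t_bc), theta_of(prev.t_bc), ref)
                if np.isfinite(ref)
                else np.nan
            )
            if not np.isfinite(theta_off):
                flags.append("offset_reference_missing")
        else:
            theta_off = np.nan
            flags.append("no_preceding_event")

        rows.append(
            {
                "event_index": i,
                "t_bc": ev.t_bc,
                "direction": ev.direction,
                "transition_id": i % n_transitions,
                "delta_phi_hilbert_deg": dphi_h,
                "delta_phi_time_deg": dphi_t,
                "r_amp": r_amp,
                "r_time": r_time,
                "theta_offset_deg": theta_off,
                "t_center": t_center,
                "band_width_deg": 2.0 * w_at_tc if np.isfinite(w_at_tc) else np.nan,
                "transition_duration_s": dt,
                "cycle_duration_s": T,
                "peak_to_peak_extent_deg": extent,
                "flags": ";".join(flags),
            }
        )

    df = pd.DataFrame(rows)
    for key in ("pattern", "tempo_bpm", "dynamic_level", "string_combination",
                "participant", "condition"):
        if key in series.metadata:
            df[key] = series.metadata[key]
    return df
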