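"""Forward simulator for bowing-channel time series.

Generates quasi-sinusoidal bow velocity and bow inclination with a
configurable phase lead of inclination, a string-crossing band of
configurable normalized width, constant total bow force, per-half-cycle
phase jitter, baseline drift of the inclination and additive channel noise.

Sign conventions (fixed once, here): down-bow is positive velocity,
inclination increases toward the higher-pitched string, and the crossing
band is centered at 0 degrees by default.

For the circular patterns (CW, ACW) velocity and inclination share one
frequency; for the figure-of-eight (Fo8) the inclination period is twice
the velocity period and there are two crossing boundaries, symmetric about
the band center, placed so that a configured phase of zero aligns every
bow change with a boundary crossing.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage, signal

PATTERNS = ("CW", "ACW", "Fo8")
INCL_SHAPES = ("sinusoidal", "triangular_rounded")

#: sixteenth notes per quarter-note beat
NOTES_PER_BEAT = 4
#: sixteenth notes per notated bar of the experimental patterns
NOTES_PER_BAR = 12
#: bars per protocol sequence
BARS_PER_SEQUENCE = 6


def note_rate_hz(tempo_bpm: float) -> float:
    """Note events per second for sixteenth notes at a quarter-note tempo."""
    return NOTES_PER_BEAT * tempo_bpm / 60.0


def movement_frequency_hz(tempo_bpm: float, pattern: str = "CW") -> float:
    """Frequency of one full velocity cycle (two strokes) at ``tempo_bpm``.

    For the circular patterns this is also the inclination frequency; for
    Fo8 the inclination runs at half this frequency.
    """
    f = note_rate_hz(tempo_bpm) / 2.0
    return f


def printed_note_rate(tempo_bpm: float) -> float:
    """Note rate rounded to one decimal, the convention used in print."""
    return round(note_rate_hz(tempo_bpm), 1)


def printed_movement_frequency(tempo_bpm: float) -> float:
    """Half the one-decimal note rate (the printed-table convention)."""
    return printed_note_rate(tempo_bpm) / 2.0


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters needed to synthesize one performance sequence."""

    pattern: str = "CW"
    tempo_bpm: float = 92.0
    sample_rate_hz: float = 240.0
    n_bars: int = BARS_PER_SEQUENCE
    delta_phi_deg: float = 0.0
    r_norm: float = 0.32
    velocity_amp: float = 0.5
    incl_peak_to_peak_deg: float = 30.0
    incl_offset_deg: float = 0.0
    force_total_n: float = 0.8
    incl_shape: str = "sinusoidal"
    #: Gaussian smoothing of the triangular shape, as a fraction of the
    #: inclination period (sigma of the kernel).
    incl_smooth_frac: float = 0.05
    #: if set, the band half-width is force_total_n * band_width_per_newton
    #: instead of being derived from r_norm (dynamic-level presets)
    band_width_per_newton: float | None = None
    velocity_noise_sd: float = 0.0
    inclination_noise_sd: float = 0.0
    force_noise_sd: float = 0.0
    band_noise_sd: float = 0.0
    cycle_jitter_sd_deg: float = 0.0
    offset_jitter_sd_deg: float = 0.0
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if self.incl_shape not in INCL_SHAPES:
            raise ValueError(f"unknown incl_shape {self.incl_shape!r}")
        if not 0.0 <= self.r_norm < 1.0:
            raise ValueError(f"r_norm must be in [0, 1), got {self.r_norm}")
        if self.n_bars < 1:
            raise ValueError("n_bars must be >= 1")
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        f_max = self.velocity_frequency_hz
        if self.sample_rate_hz <= 2.0 * f_max:
            raise ValueError(
                f"sample_rate_hz={self.sample_rate_hz} must exceed twice the "
                f"velocity frequency ({f_max:.3g} Hz)"
            )

    # ------------------------------------------------------------------ #
    @property
    def note_rate_hz(self) -> float:
        return note_rate_hz(self.tempo_bpm)

    @property
    def velocity_frequency_hz(self) -> float:
        return self.note_rate_hz / 2.0

    @property
    def inclination_frequency_hz(self) -> float:
        f = self.velocity_frequency_hz
        return f / 2.0 if self.pattern == "Fo8" else f

    @property
    def n_notes(self) -> int:
        return self.n_bars * NOTES_PER_BAR

    @property
    def duration_s(self) -> float:
        return self.n_notes / self.note_rate_hz

    @property
    def band_halfwidth_deg(self) -> float:
        """Half-width of the crossing band implied by the configuration."""
        if self.band_width_per_newton is not None:
            return self.band_width_per_newton * self.force_total_n
        return self.r_norm * self.incl_peak_to_peak_deg / 2.0

    # ------------------------------------------------------------------ #
    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        return cls(**yaml.safe_load(_io.StringIO(text)))


@dataclass
class BowingTimeSeries:
    """Sampled bowing channels on a uniform time grid."""

    time: np.ndarray
    velocity: np.ndarray
    inclination: np.ndarray
    force_total: np.ndarray
    band_halfwidth: np.ndarray
    band_center: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("velocity", "inclination", "force_total", "band_halfwidth"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from time grid")
        if n >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time must be strictly increasing with a constant step")
        if np.any(self.band_halfwidth < 0):
            raise ValueError("band_halfwidth must be non-negative everywhere")

    @property
    def sample_rate_hz(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def boundary_offsets_deg(self) -> tuple[float, ...]:
        """Crossing-boundary levels relative to the band center."""
        return tuple(self.metadata.get("boundary_offsets_deg", (0.0,)))


# ---------------------------------------------------------------------- #
# waveforms

_SHAPE_GRID = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)


def _unit_waveform_table(shape: str, smooth_frac: float) -> np.ndarray:
    """One period of the unit inclination waveform, sine-aligned.

    The waveform has a rising zero at phase 0 and its maximum at pi/2, like
    sin.  ``triangular_rounded`` is a triangle wave convolved with a
    periodic Gaussian kernel of sigma ``smooth_frac`` periods.
    """
    if shape == "sinusoidal":
        return np.sin(_SHAPE_GRID)
    tri = signal.sawtooth(_SHAPE_GRID + np.pi / 2.0, width=0.5)
    if smooth_frac <= 0:
        return tri
    sigma = smooth_frac * len(_SHAPE_GRID)
    return ndimage.gaussian_filter1d(tri, sigma=sigma, mode="wrap")


def _eval_waveform(table: np.ndarray, phase: np.ndarray | float) -> np.ndarray:
    phase = np.mod(phase, 2.0 * np.pi)
    return np.interp(phase, _SHAPE_GRID, table, period=2.0 * np.pi)


def _halfcycle_jitter(
    t: np.ndarray, freq_hz: float, sd_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth phase-offset track (radians) with independent per-half-cycle values."""
    if sd_deg <= 0:
        return np.zeros_like(t)
    knots = np.arange(0.0, t[-1] + 1.0 / (2.0 * freq_hz), 1.0 / (2.0 * freq_hz))
    eps = rng.normal(0.0, sd_deg, size=len(knots))
    return np.deg2rad(np.interp(t, knots, eps))


def _halfcycle_drift(
    t: np.ndarray, freq_hz: float, sd_deg: float, rng: np.random.Generator
) -> np.ndarray:
    """Baseline drift track (degrees) with independent per-half-cycle values."""
    if sd_deg <= 0:
        return np.zeros_like(t)
    knots = np.arange(0.0, t[-1] + 1.0 / (2.0 * freq_hz), 1.0 / (2.0 * freq_hz))
    eps = rng.normal(0.0, sd_deg, size=len(knots))
    return np.interp(t, knots, eps)


# ---------------------------------------------------------------------- #


def generate_pattern(config: GeneratorConfig) -> BowingTimeSeries:
    """Synthesize one bowing sequence according to ``config``.

    The configured ``delta_phi_deg`` is the ground truth on the reported
    scale for every pattern: each crossing of the relevant boundary
    precedes its bow change by ``delta_phi_deg / 360`` of one velocity
    cycle (for the circular patterns the velocity and inclination cycles
    coincide, so this equals a lead in the inclination cycle as well).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate_hz
    f_v = config.velocity_frequency_hz
    n_samples = int(round(config.duration_s * fs))
    t = np.arange(n_samples) / fs

    # velocity: sinusoidal at the stroke frequency, down-bow first
    phi_v = 2.0 * np.pi * f_v * t + _halfcycle_jitter(
        t, f_v, config.cycle_jitter_sd_deg, rng
    )
    velocity = config.velocity_amp * np.sin(phi_v)

    # inclination
    table = _unit_waveform_table(config.incl_shape, config.incl_smooth_frac)
    half_extent = config.incl_peak_to_peak_deg / 2.0
    delta = np.deg2rad(config.delta_phi_deg)
    f_i = config.inclination_frequency_hz
    jitter_i = _halfcycle_jitter(t, f_i, config.cycle_jitter_sd_deg, rng)
    drift = _halfcycle_drift(t, f_i, config.offset_jitter_sd_deg, rng)
    band_center = 0.0

    if config.pattern == "Fo8":
        # inclination at half the velocity frequency; boundary crossings at
        # every bow change when delta_phi_deg == 0
        arg = np.pi * f_v * t + np.pi / 4.0 + delta / 2.0 + jitter_i
        unit = _eval_waveform(table, arg)
        boundary = float(half_extent * _eval_waveform(table, np.pi / 4.0))
        boundary_offsets = (boundary, -boundary)
    else:
        sign = 1.0 if config.pattern == "CW" else -1.0
        arg = 2.0 * np.pi * f_i * t + delta + jitter_i
        unit = sign * _eval_waveform(table, arg)
        boundary_offsets = (0.0,)

    inclination = (
        band_center + config.incl_offset_deg + drift + half_extent * unit
    )

    force_total = np.full(n_samples, config.force_total_n)
    band_halfwidth = np.full(n_samples, config.band_halfwidth_deg)

    if config.velocity_noise_sd > 0:
        velocity = velocity + rng.normal(0.0, config.velocity_noise_sd, n_samples)
    if config.inclination_noise_sd > 0:
        inclination = inclination + rng.normal(
            0.0, config.inclination_noise_sd, n_samples
        )
    if config.force_noise_sd > 0:
        force_total = force_total + rng.normal(0.0, config.force_noise_sd, n_samples)
    if config.band_noise_sd > 0:
        band_halfwidth = np.clip(
            band_halfwidth + rng.normal(0.0, config.band_noise_sd, n_samples), 0.0, None
        )

    metadata = {
        "pattern": config.pattern,
        "tempo_bpm": config.tempo_bpm,
        "note_rate_hz": config.note_rate_hz,
        "velocity_frequency_hz": f_v,
        "inclination_frequency_hz": f_i,
        "n_notes": config.n_notes,
        "boundary_offsets_deg": list(boundary_offsets),
        "true_delta_phi_deg": config.delta_phi_deg,
        "true_r_norm": config.r_norm,
        "true_incl_offset_deg": config.incl_offset_deg,
        "seed": config.seed,
    }
    metadata.update(config.metadata)

    return BowingTimeSeries(
        time=t,
        velocity=velocity,
        inclination=inclination,
        force_total=force_total,
        band_halfwidth=band_halfwidth,
        band_center=band_center,
        metadata=metadata,
    )


def snr_to_noise_sd(amplitude: float, snr_db: float) -> float:
    """Additive white-noise SD giving ``snr_db`` for a sine of ``amplitude``."""
    return (amplitude / np.sqrt(2.0)) / (10.0 ** (snr_db / 20.0))


# ---------------------------------------------------------------------- #
# force cross-fade

CROSSFADE_LAWS = ("linear", "raised_cosine")


def crossfade_forces(
    series: BowingTimeSeries, law: str = "linear"
) -> np.ndarray:
    """Partition total bow force across strings at every sample.

    Returns an array of shape ``(n_strings, n_samples)`` with rows ordered
    from the lowest to the highest string (by inclination).  The rows sum
    to ``force_total`` everywhere; outside a crossing band all force sits
    on one string, inside it the force is transferred monotonically as a
    function of the normalized band coordinate.  A zero-width band gives a
    step transfer at the boundary.
    """
    if law not in CROSSFADE_LAWS:
        raise ValueError(f"unknown cross-fade law {law!r}")
    theta = series.inclination
    w = series.band_halfwidth
    boundaries = sorted(series.band_center + o for o in series.boundary_offsets_deg)
    n = series.n_samples

    # fraction of force transferred above each boundary, monotone in theta
    above = np.empty((len(boundaries), n))
    for i, b in enumerate(boundaries):
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(w > 0, (theta - b + w) / (2.0 * w), np.nan)
        x = np.where(w > 0, np.clip(x, 0.0, 1.0), (theta >= b).astype(float))
        if law == "raised_cosine":
            x = 0.5 * (1.0 - np.cos(np.pi * x))
        above[i] = x

    forces = np.empty((len(boundaries) + 1, n))
    prev = np.ones(n)
    for i in range(len(boundaries)):
        forces[i] = (prev - above[i]) * series.force_total
        prev = above[i]
    forces[-1] = prev * series.force_total
    return forces


# ---------------------------------------------------------------------- #
# experimental protocol

#: (force_total [N], band width per newton [deg/N], peak-to-peak extent [deg])
DYNAMIC_PRESETS = {
    # chosen so that forte/piano reproduce a ~factor-2 band-width difference
    "forte": {"force_total_n": 1.0, "band_width_per_newton": 4.8,
              "incl_peak_to_peak_deg": 30.0},
    "piano": {"force_total_n": 0.5, "band_width_per_newton": 4.8,
              "incl_peak_to_peak_deg": 24.0},
}

#: fixed string combination per pattern in the tempo block
_TEMPO_BLOCK_STRINGS = {"CW": "E-A", "ACW": "A-D", "Fo8": "E-A-D"}
#: string combination per pattern and transposition in the dynamic block
_DYNAMIC_BLOCK_STRINGS = {
    ("CW", "high"): "E-A",
    ("CW", "low"): "A-D",
    ("Fo8", "high"): "E-A-D",
    ("Fo8", "low"): "A-D-G",
}
#: nominal tempo used for the dynamic block ("92-112 bpm" indication)
DYNAMIC_BLOCK_TEMPO_BPM = 102.0


@dataclass(frozen=True)
class Condition:
    block: str  # "dynamic" or "tempo"
    pattern: str
    tempo_bpm: float
    dynamic_level: str
    string_combination: str

    @property
    def label(self) -> str:
        return (
            f"{self.block}:{self.pattern}:{self.tempo_bpm:g}bpm:"
            f"{self.dynamic_level}:{self.string_combination}"
        )


def condition_grid() -> list[Condition]:
    """The 20 controlled conditions (slow block excluded).

    Dynamic-level block: 2 dynamic levels x 2 patterns x 2 transpositions.
    Tempo block: 4 tempi x 3 patterns at forte.
    """
    conditions: list[Condition] = []
    for level in ("forte", "piano"):
        for pattern in ("CW", "Fo8"):
            for transposition in ("high", "low"):
                conditions.append(
                    Condition(
                        block="dynamic",
                        pattern=pattern,
                        tempo_bpm=DYNAMIC_BLOCK_TEMPO_BPM,
                        dynamic_level=level,
                        string_combination=_DYNAMIC_BLOCK_STRINGS[(pattern, transposition)],
                    )
                )
    for tempo in (58.0, 72.0, 92.0, 112.0):
        for pattern in ("CW", "ACW", "Fo8"):
            conditions.append(
                Condition(
                    block="tempo",
                    pattern=pattern,
                    tempo_bpm=tempo,
                    dynamic_level="forte",
                    string_combination=_TEMPO_BLOCK_STRINGS[pattern],
                )
            )
    return conditions


def generate_protocol_sequence(
    condition: Condition, config: GeneratorConfig | None = None
) -> BowingTimeSeries:
    """Generate one protocol sequence (six seamlessly repeated bars).

    ``config`` supplies the coordination parameters and noise settings; the
    pattern, tempo, bar count and dynamic-level preset are overridden from
    the condition.
    """
    if condition.dynamic_level not in DYNAMIC_PRESETS:
        raise ValueError(f"unknown dynamic level {condition.dynamic_level!r}")
    base = config if config is not None else GeneratorConfig()
    preset = DYNAMIC_PRESETS[condition.dynamic_level]
    cfg = dataclasses.replace(
        base,
        pattern=condition.pattern,
        tempo_bpm=condition.tempo_bpm,
        n_bars=BARS_PER_SEQUENCE,
        metadata={
            **base.metadata,
            "block": condition.block,
            "dynamic_level": condition.dynamic_level,
            "string_combination": condition.string_combination,
            "condition": condition.label,
        },
        **preset,
    )
    return generate_pattern(cfg)


def count_note_events(series: BowingTimeSeries) -> int:
    """Number of note events (bow strokes) in a generated sequence.

    Detected from the velocity channel: one stroke per velocity half-cycle.
    """
    # local import to avoid a cycle at module import time
    from .transition_features import detect_bow_changes

    events = detect_bow_changes(series.velocity, series.sample_rate_hz)
    return len(events)
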