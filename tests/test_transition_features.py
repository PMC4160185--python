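import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bowcoord.synthetic_data import GeneratorConfig, generate_pattern
from bowcoord.transition_features import (
    BowChangeEvent,
    amplitude_normalized_range,
    crossing_center_time,
    cycle_duration,
    detect_bow_changes,
    extract_features,
    inclination_offset,
    peak_to_peak_extent,
    time_domain_phase,
    time_domain_range,
    transition_duration,
    trim_selection,
)

FS = 240.0


def _events_at(times):
    return [
        BowChangeEvent(index=i, t_bc=t, direction="down_to_up" if i % 2 else "up_to_down")
        for i, t in enumerate(times)
    ]


class TestDetectBowChanges:
    def test_sine_roots_alternating(self):
        f = 3.05
        t = np.arange(0, 2, 1 / FS)
        events = detect_bow_changes(np.sin(2 * np.pi * f * t), FS)
        expected = np.arange(len(events)) / (2 * f)
        assert np.allclose([e.t_bc for e in events], expected, atol=1 / (10 * FS))
        directions = [e.direction for e in events]
        assert all(a != b for a, b in zip(directions, directions[1:]))

    def test_subsample_accuracy(self):
        # oracle: analytic roots of the sine at k/(2f)
        f = 3.0
        t = np.arange(0, 2, 1 / FS)
        events = detect_bow_changes(np.sin(2 * np.pi * f * t), FS)
        for e in events:
            k = round(e.t_bc * 2 * f)
            assert abs(e.t_bc - k / (2 * f)) < 1 / (10 * FS)

    def test_exact_zero_sample(self):
        v = np.array([1.0, 0.5, 0.0, -0.5, -1.0])
        events = detect_bow_changes(v, FS)
        assert len(events) == 1
        assert events[0].t_bc == pytest.approx(2 / FS)
        assert events[0].direction == "down_to_up"

    def test_no_crossings_empty(self):
        assert detect_bow_changes(np.ones(100), FS) == []

    def test_touch_without_reversal_ignored(self):
        v = np.array([1.0, 0.5, 0.0, 0.5, 1.0])
        assert detect_bow_changes(v, FS) == []


class TestTrimSelection:
    def test_72_events_yield_64(self):
        assert len(trim_selection(_events_at(np.arange(72) * 0.1))) == 64

    def test_nine_events_yield_one(self):
        assert len(trim_selection(_events_at(np.arange(9) * 0.1))) == 1

    def test_eight_events_error(self):
        with pytest.raises(ValueError, match="events"):
            trim_selection(_events_at(np.arange(8) * 0.1))

    @given(n=st.integers(9, 200), npb=st.integers(1, 4))
    def test_removes_exactly_two_beats(self, n, npb):
        events = _events_at(np.arange(n) * 0.05)
        if n < 2 * npb + 1:
            with pytest.raises(ValueError):
                trim_selection(events, npb)
        else:
            trimmed = trim_selection(events, npb)
            assert len(trimmed) == n - 2 * npb
            assert trimmed[0] is events[npb]


class TestCrossingCenterTime:
    def test_synthetic_lead(self):
        # delta_phi = 15 deg of a T = 0.5 s cycle -> 0.02083 s lead
        f = 2.0
        t = np.arange(0, 3, 1 / FS)
        lead = np.deg2rad(15.0)
        theta = 10 * np.sin(2 * np.pi * f * t + lead)
        event = BowChangeEvent(0, 1.0, "down_to_up")
        t_c, level = crossing_center_time(theta, t, 0.0, event, 0.5)
        assert level == 0.0
        assert event.t_bc - t_c == pytest.approx(15.0 / 360.0 * 0.5, abs=1e-4)

    def test_zero_phase_coincides(self):
        f = 2.0
        t = np.arange(0, 3, 1 / FS)
        theta = 10 * np.sin(2 * np.pi * f * t)
        event = BowChangeEvent(0, 1.0, "down_to_up")
        t_c, _ = crossing_center_time(theta, t, 0.0, event, 0.5)
        assert abs(t_c - 1.0) < 1 / FS

    def test_unreachable_center_missing(self):
        t = np.arange(0, 2, 1 / FS)
        theta = 5 + 1 * np.sin(2 * np.pi * 2 * t)  # never reaches 0
        event = BowChangeEvent(0, 1.0, "down_to_up")
        t_c, level = crossing_center_time(theta, t, 0.0, event, 0.5)
        assert np.isnan(t_c) and np.isnan(level)


class TestTimeDomainPhase:
    def test_zero_offset(self):
        assert time_domain_phase(1.0, 1.0, 0.5) == 0.0

    def test_direct_arithmetic(self):
        assert time_domain_phase(1.0208333, 1.0, 0.5) == pytest.approx(15.0, abs=1e-4)

    def test_agrees_with_hilbert_on_sweep(self):
        for dphi in (5.0, 15.0, 25.0):
            cfg = GeneratorConfig(pattern="CW", tempo_bpm=92, n_bars=4,
                                  delta_phi_deg=dphi, r_norm=0.32)
            features = extract_features(generate_pattern(cfg))
            assert features["delta_phi_time_deg"].mean() == pytest.approx(
                features["delta_phi_hilbert_deg"].mean(), abs=1.0
            )

    def test_positive_cycle_duration_required(self):
        with pytest.raises(ValueError):
            time_domain_phase(1.0, 0.9, 0.0)


class TestTransitionDuration:
    def test_closed_form_for_half_range(self):
        # sine through a band of r=0.5: duration = T * arcsin(0.5) / pi = T/6
        f, T = 2.0, 0.5
        t = np.arange(0, 3, 1 / FS)
        theta = 10 * np.sin(2 * np.pi * f * t)
        w = 0.5 * 10  # halfwidth = r * amplitude
        dt = transition_duration(theta, t, -w, w, 1.0, T)
        assert dt == pytest.approx(T / 6, rel=1e-3)

    def test_shrinks_with_band(self):
        f, T = 2.0, 0.5
        t = np.arange(0, 3, 1 / FS)
        theta = 10 * np.sin(2 * np.pi * f * t)
        durations = [
            transition_duration(theta, t, -w, w, 1.0, T) for w in (4.0, 2.0, 0.5, 0.1)
        ]
        assert all(a > b for a, b in zip(durations, durations[1:]))
        assert durations[-1] < 0.01

    def test_band_wider_than_extent_missing(self):
        t = np.arange(0, 2, 1 / FS)
        theta = 1.0 * np.sin(2 * np.pi * 2 * t)
        assert np.isnan(transition_duration(theta, t, -5.0, 5.0, 1.0, 0.5))


class TestTimeDomainRange:
    def test_sixth_cycle_gives_half(self):
        assert time_domain_range(0.5 / 6, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        assert time_domain_range(0.0, 0.5) == 0.0
        assert time_domain_range(0.25, 0.5) == pytest.approx(1.0)

    def test_longer_than_half_cycle_rejected(self):
        with pytest.raises(ValueError, match="half a cycle"):
            time_domain_range(0.3, 0.5)

    def test_recovers_configured_r(self, cw_features):
        assert cw_features["r_time"].mean() == pytest.approx(0.32, abs=0.005)

    @given(r=st.floats(0.01, 0.99))
    def test_inverts_sinusoidal_crossing_relation(self, r):
        T = 0.4
        dt = T * np.arcsin(r) / np.pi
        assert time_domain_range(dt, T) == pytest.approx(r, rel=1e-9)


class TestPeakToPeakExtent:
    def test_pure_sine(self):
        t = np.arange(0, 2, 1 / FS)
        theta = 7.0 * np.sin(2 * np.pi * 3 * t)
        event = BowChangeEvent(0, 1.0, "down_to_up")
        assert peak_to_peak_extent(theta, t, event) == pytest.approx(14.0, rel=0.01)

    def test_tracks_local_amplitude(self):
        # slow amplitude modulation; per-event extent follows the local
        # envelope, not the global extremes
        f = 2.0
        t = np.arange(0, 8, 1 / FS)
        envelope = 6.0 + 3.0 * np.sin(2 * np.pi * 0.125 * t)
        theta = envelope * np.sin(2 * np.pi * f * t)
        t_high, t_low = 2.0, 6.0  # envelope maximum / minimum
        ext_high = peak_to_peak_extent(theta, t, BowChangeEvent(0, t_high, "x"))
        ext_low = peak_to_peak_extent(theta, t, BowChangeEvent(1, t_low, "x"))
        assert ext_high == pytest.approx(2 * 9.0, rel=0.1)
        assert ext_low == pytest.approx(2 * 3.0, rel=0.15)
        assert ext_high > ext_low

    def test_monotone_segment_missing(self):
        t = np.arange(0, 1, 1 / FS)
        theta = 3.0 * t
        assert np.isnan(peak_to_peak_extent(theta, t, BowChangeEvent(0, 0.5, "x")))


class TestAmplitudeNormalizedRange:
    def test_direct_ratio(self):
        assert amplitude_normalized_range(0.3 * 20.0, 20.0) == pytest.approx(0.3)

    def test_zero_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            amplitude_normalized_range(1.0, 0.0)

    def test_fo8_missing_with_reason(self):
        cfg = GeneratorConfig(pattern="Fo8", tempo_bpm=92, n_bars=4)
        features = extract_features(generate_pattern(cfg))
        assert features["r_amp"].isna().all()
        assert features["flags"].str.contains("r_amp_undefined_for_Fo8").all()

    def test_equals_time_domain_estimate_noise_free(self, cw_features):
        assert abs(
            cw_features["r_amp"].mean() - cw_features["r_time"].mean()
        ) < 1e-3


class TestInclinationOffset:
    def test_symmetric_sine_near_zero(self, cw_features):
        assert cw_features["theta_offset_deg"].mean() == pytest.approx(0.0, abs=0.1)

    def test_generator_offset_recovered(self):
        cfg = GeneratorConfig(pattern="CW", tempo_bpm=92, n_bars=4,
                              delta_phi_deg=15.0, incl_offset_deg=-2.0)
        features = extract_features(generate_pattern(cfg))
        assert features["theta_offset_deg"].mean() == pytest.approx(-2.0, abs=0.2)

    def test_first_event_missing(self):
        cfg = GeneratorConfig(pattern="CW", tempo_bpm=92, n_bars=2)
        features = extract_features(generate_pattern(cfg), trim=False)
        assert np.isnan(features["theta_offset_deg"].iloc[0])
        assert "no_preceding_event" in features["flags"].iloc[0]

    def test_direct_formula(self):
        assert inclination_offset(3.0, 1.0, 0.5) == pytest.approx(1.5)


class TestCycleDuration:
    def test_reciprocal_of_movement_frequency(self, cw_features):
        f = 92 * 4 / 120  # exact circular movement frequency at 92 bpm
        assert cw_features["cycle_duration_s"].mean() == pytest.approx(1 / f, rel=1e-3)

    def test_jitter_produces_varying_cycles(self):
        cfg = GeneratorConfig(pattern="CW", tempo_bpm=92, n_bars=6,
                              cycle_jitter_sd_deg=4.0, seed=3)
        features = extract_features(generate_pattern(cfg))
        assert features["cycle_duration_s"].std() > 1e-4

    def test_edge_fallback_and_errors(self):
        events = _events_at([0.0, 0.25, 0.5, 0.75])
        assert cycle_duration(events, 0) == pytest.approx(0.5)
        assert cycle_duration(events, 3) == pytest.approx(0.5)
        assert cycle_duration(events, 2) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            cycle_duration(events[:2], 0)


class TestExtractFeatures:
    def test_headline_noise_free_recovery(self, cw_features):
        assert 14.8 < cw_features["delta_phi_hilbert_deg"].mean() < 15.2
        assert 14.8 < cw_features["delta_phi_time_deg"].mean() < 15.2
        assert 0.315 < cw_features["r_amp"].mean() < 0.325
        assert 0.315 < cw_features["r_time"].mean() < 0.325

    def test_trimmed_event_count(self, cw_features, cw_config):
        # filtering may remove the exact-zero event at the very first sample
        assert len(cw_features) in (cw_config.n_notes - 8, cw_config.n_notes - 9)

    def test_transition_ids(self, cw_features):
        assert set(cw_features["transition_id"]) == {0, 1}

    def test_fo8_four_transitions(self):
        cfg = GeneratorConfig(pattern="Fo8", tempo_bpm=92, n_bars=4)
        features = extract_features(generate_pattern(cfg))
        assert set(features["transition_id"]) == {0, 1, 2, 3}

    def test_metadata_columns(self, cw_features):
        assert (cw_features["pattern"] == "CW").all()
        assert (cw_features["tempo_bpm"] == 92.0).all()

    def test_variance_inflation_of_time_domain_estimate_with_tempo(self):
        # center fluctuations hit only the time-domain estimate; additive
        # noise hits the Hilbert estimate less at higher tempo, so the SD
        # ratio time/hilbert grows with tempo
        ratios = []
        for bpm in (58.0, 92.0, 112.0):
            per_seed = []
            for seed in range(3):
                cfg = GeneratorConfig(pattern="CW", tempo_bpm=bpm, n_bars=6,
                                      delta_phi_deg=15.0, r_norm=0.32,
                                      offset_jitter_sd_deg=1.0,
                                      inclination_noise_sd=0.3, seed=seed)
                f = extract_features(generate_pattern(cfg))
                per_seed.append(
                    f["delta_phi_time_deg"].std() / f["delta_phi_hilbert_deg"].std()
                )
            ratios.append(np.mean(per_seed))
        assert ratios[0] < ratios[1] < ratios[2]
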