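"""Feature arithmetic, conventions and recovery of programmed ground truth."""

import numpy as np
import pytest

from conftest import make_sinusoid
from fingertap import (
    CycleSet,
    DistanceSignal,
    InsufficientCyclesError,
    TapSimParams,
    bradykinesia_features,
    combined_speed_features,
    count_interruptions,
    extract_all,
    hesitation_halt_features,
    hypokinesia_features,
    sequence_effect_features,
    simulate_tapping,
)


def cycle_set(amplitudes, durations, cas=None, cms=None) -> CycleSet:
    durations = np.asarray(durations, dtype=float)
    m = len(durations) + 1
    peak_times = np.concatenate([[0.0], np.cumsum(durations)])
    peak_idx = (peak_times * 100).astype(int)
    trough_idx = ((peak_times[:-1] + durations / 2) * 100).astype(int)
    ones = np.ones(len(durations))
    return CycleSet(
        peak_indices=peak_idx,
        trough_indices=trough_idx,
        peak_times_s=peak_times,
        amplitudes=np.asarray(amplitudes, dtype=float),
        durations_s=durations,
        cycle_avg_speeds=ones if cas is None else np.asarray(cas, float),
        cycle_max_speeds=ones if cms is None else np.asarray(cms, float),
    )


@pytest.mark.parametrize(
    "amps, expected",
    [([1, 1, 1], 1.0), ([0.8, 1.0, 1.2], 1.0)],
)
def test_amp_avg(amps, expected):
    cs = cycle_set(amps, [0.5] * len(amps))
    assert hypokinesia_features(cs) == pytest.approx(expected)


@pytest.mark.parametrize(
    "peak_times, expected",
    [([0, 0.5, 1.0], 0.5), ([0, 0.3, 0.9], 0.45)],
)
def test_cd_avg(peak_times, expected):
    cs = cycle_set([1, 1], np.diff(peak_times))
    assert bradykinesia_features(cs) == pytest.approx(expected)


def test_speed_means():
    cs = cycle_set([1, 1], [0.5, 0.5], cas=[4.0, 4.0], cms=[5.0, 7.0])
    cas_avg, cms_avg = combined_speed_features(cs)
    assert cas_avg == pytest.approx(4.0)
    assert cms_avg == pytest.approx(6.0)


class TestSequenceEffect:
    def test_constant_amplitudes_zero_slope(self):
        cs = cycle_set([1, 1, 1, 1], [0.5] * 4)
        amp_slope, _, _ = sequence_effect_features(cs)
        assert amp_slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_ols_on_collinear_points(self):
        cs = cycle_set([1.0, 0.9, 0.8, 0.7], [0.5] * 4)
        amp_slope, _, _ = sequence_effect_features(cs)
        assert amp_slope == pytest.approx(-0.1)

    def test_two_points_insufficient(self):
        cs = cycle_set([1.0, 0.9], [0.5, 0.5])
        with pytest.raises(InsufficientCyclesError):
            sequence_effect_features(cs)

    def test_time_regressor_rescales_slope(self):
        cs = cycle_set([1.0, 0.9, 0.8, 0.7], [0.5] * 4)
        by_index = sequence_effect_features(cs, regressor="index")[0]
        by_time = sequence_effect_features(cs, regressor="time")[0]
        assert by_time == pytest.approx(by_index / 0.5)

    def test_noisy_slope_recovery_over_seeds(self):
        # programmed -0.02 amplitude decrement per cycle, 30 cycles
        slopes = []
        for seed in range(200):
            params = TapSimParams(
                seed=seed, base_cycle_s=0.32, amp_slope_per_cycle=-0.02,
                noise_sd=0.01,
            )
            signal, truth = simulate_tapping(params)
            fv = extract_all(signal)
            assert fv.valid
            slopes.append(fv.amp_slope)
        assert np.mean(slopes) == pytest.approx(-0.02, abs=0.005)


class TestHesitationHalts:
    def test_constant_cycles_all_zero(self):
        cs = cycle_set([1, 1, 1], [0.5, 0.5, 0.5], cas=[4, 4, 4], cms=[5, 5, 5])
        amp_cv, cd_cv, cms_cv, cas_cv, n_int = hesitation_halt_features(cs)
        assert amp_cv == cd_cv == cms_cv == cas_cv == 0.0
        assert n_int == 0

    def test_cd_cv_formula(self):
        # durations 0.4, 0.6: mean 0.5, sum sq dev 0.02 over M-1=1... but the
        # CycleSet needs 2 cycles minimum for variability; use 2 durations
        cs = cycle_set([1, 1], [0.4, 0.6])
        _, cd_cv, _, _, _ = hesitation_halt_features(cs)
        assert cd_cv == pytest.approx(np.sqrt(0.02 / 2) / 0.5)

    def test_amp_cv_denominator_conventions(self):
        # 3 peaks, but only 2 amplitudes (first peak unpaired)
        cs = cycle_set([0.8, 1.2], [0.5, 0.5])
        printed, *_ = hesitation_halt_features(cs, consistent_cv=False)
        consistent, *_ = hesitation_halt_features(cs, consistent_cv=True)
        mean = 1.0
        assert printed == pytest.approx(np.sqrt(0.08 / 3) / mean)
        assert consistent == pytest.approx(np.sqrt(0.08 / 2) / mean)

    @pytest.mark.parametrize(
        "durations, expected",
        [
            ([0.3] * 9 + [0.7], 1),  # median 0.3, threshold 0.6
            ([0.4, 0.6], 0),
            ([0.3, 0.3, 0.3, 0.6], 0),  # exactly at threshold: not counted
        ],
    )
    def test_interruption_rule(self, durations, expected):
        assert count_interruptions(durations) == expected

    def test_interruption_count_time_scaling_invariant(self):
        rng = np.random.default_rng(2)
        durations = rng.uniform(0.3, 0.5, 20)
        durations[5] = 1.2
        for c in (0.1, 1.0, 7.5):
            assert count_interruptions(c * durations) == count_interruptions(
                durations
            )


class TestExtractAll:
    def test_sinusoid_end_to_end(self, sinusoid_signal):
        fv = extract_all(sinusoid_signal)
        assert fv.valid
        assert fv.amp_avg == pytest.approx(1.0, abs=0.02)
        assert fv.cd_avg == pytest.approx(0.5, abs=0.01)
        assert fv.amp_slope == pytest.approx(0.0, abs=0.005)
        assert fv.cd_slope == pytest.approx(0.0, abs=0.005)
        assert fv.amp_cv == pytest.approx(0.0, abs=0.02)
        assert fv.cd_cv == pytest.approx(0.0, abs=0.05)
        assert fv.n_interruptions == 0

    def test_monotone_ramp_invalid_with_reason(self):
        ramp = DistanceSignal(values=np.linspace(0, 1, 200), fps=50)
        fv = extract_all(ramp)
        assert not fv.valid
        assert "peak" in fv.reason or "cycle" in fv.reason.lower()
        assert np.isnan(fv.amp_avg)

    def test_simulator_ground_truth_recovery(self):
        params = TapSimParams(base_amplitude=1.4, base_cycle_s=0.42)
        signal, truth = simulate_tapping(params)
        fv = extract_all(signal)
        assert fv.valid
        assert fv.amp_avg == pytest.approx(1.4, abs=0.02)
        assert fv.cd_avg == pytest.approx(0.42, abs=0.01)

    def test_offset_invariance_of_cvs_and_slopes(self, sinusoid_signal):
        shifted = DistanceSignal(
            values=sinusoid_signal.values + 2.5, fps=sinusoid_signal.fps
        )
        a, b = extract_all(sinusoid_signal), extract_all(shifted)
        for name in ("amp_avg", "amp_cv", "cd_cv", "amp_slope", "cd_slope"):
            assert getattr(a, name) == pytest.approx(
                getattr(b, name), abs=1e-9
            ), name

    def test_frame_rate_coherence(self):
        """Resampling a noise-free signal from 50 to 25 fps moves the
        features by < 3 % (absolute for the near-zero ones)."""
        a = extract_all(make_sinusoid(fps=50, freq_hz=1.25))
        b = extract_all(make_sinusoid(fps=25, freq_hz=1.25))
        assert b.amp_avg == pytest.approx(a.amp_avg, rel=0.03)
        assert b.cd_avg == pytest.approx(a.cd_avg, rel=0.03)
        for name in ("amp_slope", "cd_slope", "amp_cv", "cd_cv"):
            assert getattr(b, name) == pytest.approx(
                getattr(a, name), abs=0.03
            ), name
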