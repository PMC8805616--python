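"""EPSC detection, evoked-response measures and short-term plasticity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ephysopt import (GroundTruth, LightProtocol, SimConfig, TimeSeries,
                      classify_responsive_cell, detect_sepsc, evoked_epsc,
                      paired_pulse_protocol, paired_pulse_ratio,
                      proportion_responsive, pulse_train_protocol,
                      sepsc_stats, simulate_voltage_clamp, train_response)
from ephysopt.core import ConfigError, DataError
from ephysopt.synth import SynapseGT, epsc_kernel, stp_release_sequence

RATE = 10_000.0


def _trace(samples, rate=RATE):
    return TimeSeries(np.asarray(samples, float), rate, "pA")


def _with_events(times_s, amps_pa, duration_s, noise_sd=0.0, seed=0,
                 rise=2.0, decay=12.0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * RATE)
    t = np.arange(n) / RATE
    x = rng.normal(0.0, noise_sd, n) if noise_sd else np.zeros(n)
    for t0, a in zip(times_s, amps_pa):
        x -= a * epsc_kernel(t - t0, rise, decay)
    return _trace(x)


class TestDetection:
    def test_inserted_events_recovered_at_snr_five(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0.5, 59.5, 20))
        times = times[np.insert(np.diff(times) > 0.1, 0, True)]
        tr = _with_events(times, [10.0] * len(times), 60.0, noise_sd=2.0)
        det = detect_sepsc(tr)
        matched = sum(any(abs(d.onset_s - t) < 0.002 for t in times)
                      for d in det)
        assert matched / len(times) >= 0.95      # recall
        assert matched / max(len(det), 1) >= 0.95  # precision

    def test_two_picoamp_event_excluded_by_floor(self):
        tr = _with_events([0.5], [2.0], 1.0, noise_sd=0.0)
        assert detect_sepsc(tr) == []

    def test_false_positive_rate_on_pure_noise(self):
        rng = np.random.default_rng(2)
        n_fp, total_s = 0, 0.0
        for _ in range(20):
            tr = _trace(rng.normal(0, 2.0, int(5 * RATE)))
            n_fp += len(detect_sepsc(tr))
            total_s += 5.0
        assert n_fp / total_s < 0.2

    def test_nonpositive_template_rejected(self):
        tr = _trace(np.zeros(int(RATE)))
        with pytest.raises(ConfigError):
            detect_sepsc(tr, template={"rise_tau_ms": -1.0})

    def test_events_in_time_order_without_duplicates(self):
        times = [0.2, 0.5, 0.8]
        tr = _with_events(times, [15.0, 20.0, 12.0], 1.2)
        det = detect_sepsc(tr)
        onsets = [d.onset_s for d in det]
        assert onsets == sorted(onsets)
        assert len(det) == 3
        for d, t in zip(det, times):
            assert abs(d.onset_s - t) < 0.002


class TestSepscStats:
    def test_frequency_is_count_over_duration(self):
        tr = _with_events(np.linspace(1, 56, 12), [10.0] * 12, 60.0)
        stats = sepsc_stats(detect_sepsc(tr), 60.0)
        assert stats["frequency_hz"] == pytest.approx(0.2)

    def test_empty_event_list(self):
        stats = sepsc_stats([], 10.0)
        assert stats["frequency_hz"] == 0.0
        assert stats["mean_amplitude_pa"] is None
        assert stats["iei_s"].size == 0

    def test_poisson_rate_recovered_within_three_se(self):
        s = SynapseGT(event_rate_hz=0.45, amp_median_pa=12.0,
                      amp_sigma_log=0.1, evoked_amp_pa=0.0)
        prot = LightProtocol(kind="single_pulse", pulse_onsets=(299.5,),
                             n_trials=1)
        trials, ev = simulate_voltage_clamp(GroundTruth(synapse=s), prot,
                                            SimConfig(seed=11))
        stats = sepsc_stats(detect_sepsc(trials[0]), 300.0)
        se = math.sqrt(0.45 / 300.0)
        assert abs(stats["frequency_hz"] - 0.45) < 3 * se


class TestEvoked:
    def test_identical_noiseless_trials(self):
        trials = [_with_events([0.205], [40.0], 0.5) for _ in range(12)]
        resp = evoked_epsc(trials, 0.2, baseline_noise_sd=1.0)
        assert resp.amplitude_pa == pytest.approx(40.0, rel=0.01)
        assert 4.0 <= resp.onset_delay_ms <= 6.0
        assert resp.cv == pytest.approx(0.0, abs=1e-9)
        assert resp.responsive is True

    def test_latency_and_cv_recovered_from_generator(self):
        s = SynapseGT(event_rate_hz=0.0, trial_cv=0.3, latency_ms=5.0)
        prot = LightProtocol(kind="single_pulse", pulse_onsets=(0.2,),
                             n_trials=20)
        trials, _ = simulate_voltage_clamp(GroundTruth(synapse=s), prot,
                                           SimConfig(seed=12))
        resp = evoked_epsc(trials, 0.2, baseline_noise_sd=2.0)
        assert resp.onset_delay_ms == pytest.approx(5.0, abs=1.0)
        assert resp.cv == pytest.approx(0.3, abs=0.12)

    def test_no_event_is_not_responsive(self):
        rng = np.random.default_rng(3)
        trials = [_trace(rng.normal(0, 2.0, int(0.5 * RATE)))
                  for _ in range(12)]
        resp = evoked_epsc(trials, 0.2, baseline_noise_sd=2.0)
        assert resp.responsive is False

    def test_window_beyond_trial_rejected(self):
        trials = [_trace(np.zeros(int(0.1 * RATE)))]
        with pytest.raises(DataError):
            evoked_epsc(trials, 0.09, window_s=0.05)

    def test_amplitude_linear_in_inserted_amplitude(self):
        amps = [10.0, 20.0, 40.0, 80.0]
        measured = []
        for a in amps:
            trials = [_with_events([0.205], [a], 0.5) for _ in range(10)]
            measured.append(evoked_epsc(trials, 0.2).amplitude_pa)
        slope = np.polyfit(amps, measured, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.02)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_cv_is_scale_invariant(self, scale):
        amps = np.array([30.0, 35.0, 40.0, 45.0, 28.0])
        cv = np.std(amps, ddof=1) / np.mean(amps)
        scaled = amps * scale
        cv2 = np.std(scaled, ddof=1) / np.mean(scaled)
        assert cv2 == pytest.approx(cv, rel=1e-9)


class TestResponsiveness:
    def test_zero_amplitude_never_responsive(self):
        trials = [_trace(np.zeros(int(0.5 * RATE))) for _ in range(12)]
        resp = evoked_epsc(trials, 0.2)
        assert classify_responsive_cell(resp, baseline_noise_sd=2.0) is False

    def test_twenty_sd_response_is_responsive(self):
        trials = [_with_events([0.205], [40.0], 0.5) for _ in range(12)]
        resp = evoked_epsc(trials, 0.2)
        assert classify_responsive_cell(resp, baseline_noise_sd=2.0) is True

    def test_connected_fraction_recovered_in_population(self):
        rng = np.random.default_rng(21)
        n_cells, p_connected = 40, 0.6
        connected = rng.uniform(size=n_cells) < p_connected
        n_resp = 0
        for i, c in enumerate(connected):
            # SNR 5 with an event large enough that its true rising speed
            # clears the 10 pA/ms onset criterion (40 pA / 8 pA noise)
            s = SynapseGT(event_rate_hz=0.0, trial_cv=0.2,
                          evoked_amp_pa=40.0 if c else 0.0)
            prot = LightProtocol(kind="single_pulse", pulse_onsets=(0.2,),
                                 n_trials=10)
            trials, _ = simulate_voltage_clamp(GroundTruth(synapse=s), prot,
                                               SimConfig(seed=100 + i,
                                                         vc_noise_pa=8.0))
            r = evoked_epsc(trials, 0.2, baseline_noise_sd=8.0)
            n_resp += bool(r.responsive)
        # binomial 95% bracket around the true connected fraction
        se = math.sqrt(p_connected * (1 - p_connected) / n_cells)
        assert abs(n_resp / n_cells - connected.mean()) < 2 * se + 0.05


class TestPairedPulse:
    def test_no_plasticity_gives_unit_ratio(self):
        trials = [_with_events([0.205, 0.705], [40.0, 40.0], 1.2)
                  for _ in range(10)]
        r = paired_pulse_ratio(trials, (0.2, 0.7))
        assert r.ratio == pytest.approx(1.0, abs=0.02)

    def test_depletion_closed_form_noiseless(self, quiet_synapse):
        prot = paired_pulse_protocol(500.0, n_trials=10)
        trials, _ = simulate_voltage_clamp(GroundTruth(synapse=quiet_synapse),
                                           prot,
                                           SimConfig(seed=13, vc_noise_pa=0.0))
        r = paired_pulse_ratio(trials, prot.pulse_onsets)
        assert r.ratio == pytest.approx(1 - 0.5 * math.exp(-500.0 / 300.0),
                                        rel=0.01)

    def test_ppr_increases_with_interval_for_pure_depression(
            self, quiet_synapse):
        ratios = []
        for dt in (125.0, 250.0, 500.0):
            prot = paired_pulse_protocol(dt, n_trials=15)
            trials, _ = simulate_voltage_clamp(
                GroundTruth(synapse=quiet_synapse), prot, SimConfig(seed=14))
            ratios.append(paired_pulse_ratio(trials, prot.pulse_onsets).ratio)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_noise_floor_flags_undefined_ratio(self):
        rng = np.random.default_rng(5)
        trials = [_trace(rng.normal(0, 2.0, int(1.2 * RATE)))
                  for _ in range(10)]
        with pytest.warns(UserWarning, match="noise floor"):
            r = paired_pulse_ratio(trials, (0.2, 0.7), noise_floor_pa=6.0)
        assert r.ratio is None


class TestTrainResponse:
    def test_no_plasticity_stays_at_unity(self):
        onsets = [0.2 + i / 8.0 for i in range(8)]
        trials = [_with_events([o + 0.005 for o in onsets], [30.0] * 8, 1.5)
                  for _ in range(8)]
        prot = LightProtocol(kind="pulse_train", pulse_onsets=tuple(onsets),
                             n_trials=8, train_rate=8.0)
        seq = train_response(trials, prot)
        np.testing.assert_allclose(seq, 1.0, atol=0.02)

    def test_depressing_train_follows_depletion_recursion(self, quiet_synapse):
        prot = pulse_train_protocol(8.0, 2.0, onset=0.2, n_trials=8,
                                    inter_trial_interval=15.0)
        trials, _ = simulate_voltage_clamp(GroundTruth(synapse=quiet_synapse),
                                           prot,
                                           SimConfig(seed=15, vc_noise_pa=0.0))
        seq = train_response(trials, prot)
        oracle = stp_release_sequence(prot.pulse_onsets, 0.5, 300.0, 0.0)
        assert seq[0] == 1.0
        assert np.all(np.diff(seq) < 0.01)
        np.testing.assert_allclose(seq, oracle, atol=0.05)

    def test_facilitating_synapse_exceeds_unity_early(self):
        s = SynapseGT(event_rate_hz=0.0, trial_cv=0.0, release_u=0.1,
                      tau_rec_ms=5000.0, tau_fac_ms=500.0)
        prot = pulse_train_protocol(8.0, 1.0, onset=0.2, n_trials=8)
        trials, _ = simulate_voltage_clamp(GroundTruth(synapse=s), prot,
                                           SimConfig(seed=16, vc_noise_pa=0.0))
        seq = train_response(trials, prot)
        assert seq[1] > 1.0


class TestProportions:
    @pytest.mark.parametrize("n, total, decimals, expected", [
        (24, 29, 2, 82.76),
        (423, 432, 1, 97.9),
        (72, 239, 1, 30.1),
        (18, 189, 1, 9.5),
        (0, 10, 1, 0.0),
        (6, 16, 1, 37.5),
    ])
    def test_count_derived_percentages(self, n, total, decimals, expected):
        assert proportion_responsive(n, total, decimals) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(DataError):
            proportion_responsive(0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n=st.integers(0, 100), total=st.integers(1, 100))
    def test_rounding_is_half_away_from_zero(self, n, total):
        if n > total:
            n = total
        pct = proportion_responsive(n, total, 2)
        exact = 100.0 * n / total
        assert abs(pct - exact) <= 0.005 + 1e-9
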