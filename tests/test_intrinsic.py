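"""Membrane-property extraction: worked examples and ground-truth recovery."""

import math

import numpy as np
import pytest

from ephysopt import (GroundTruth, SimConfig, StepProtocol, TimeSeries,
                      capacitance, detect_aps, input_resistance,
                      measure_membrane_properties, resting_potential,
                      rheobase, sag_ratio, step_firing_rate, time_constant)
from ephysopt.core import DataError, EstimationError, ProtocolError
from ephysopt.synth import MembraneGT, simulate_current_clamp

from conftest import sweep_at

RATE = 10_000.0


def _sweep(samples, amp_pa=None, rate=RATE):
    meta = {} if amp_pa is None else {"step_pa": float(amp_pa)}
    return TimeSeries(np.asarray(samples, float), rate, "mV", meta=meta)


class TestRestingPotential:
    def test_mean_of_constant_baseline(self):
        assert resting_potential(_sweep(np.full(2000, -70.0))) == -70.0

    def test_noisy_baseline_recovered_within_standard_error(self):
        rng = np.random.default_rng(0)
        v = -70.0 + rng.normal(0, 0.3, 5000)
        assert resting_potential(_sweep(v)) == pytest.approx(-70.0, abs=0.02)

    def test_short_baseline_rejected(self):
        with pytest.raises(DataError):
            resting_potential(_sweep(np.full(100, -70.0)))  # 10 ms

    def test_spike_in_baseline_warns_but_returns(self):
        v = np.full(5000, -70.0)
        t = np.arange(200) / RATE
        from ephysopt.synth import _ap_waveform
        v[2000:2200] = _ap_waveform(MembraneGT(), t)
        with pytest.warns(UserWarning, match="baseline"):
            resting_potential(_sweep(v))


class TestInputResistance:
    def test_ohms_law_on_minus_sixty(self):
        prot = StepProtocol(step_onset=0.2)
        v = np.full(11000, -70.0)
        v[2000:8000] = -94.0  # -24 mV deflection
        assert input_resistance(_sweep(v, -60), prot) == pytest.approx(400.0)

    def test_zero_deflection_gives_zero(self):
        prot = StepProtocol(step_onset=0.2)
        assert input_resistance(_sweep(np.full(11000, -70.0), -60), prot) == 0.0

    def test_wrong_sweep_rejected(self):
        prot = StepProtocol()
        with pytest.raises(ProtocolError):
            input_resistance(_sweep(np.full(11000, -70.0), -40), prot)

    def test_ground_truth_recovered_within_five_percent(self, step_protocol):
        gt = GroundTruth(membrane=MembraneGT(rin_mohm=450.0))
        sweeps, _ = simulate_current_clamp(gt, step_protocol, SimConfig(seed=4))
        rin = input_resistance(sweep_at(sweeps, -60.0), step_protocol)
        assert rin == pytest.approx(450.0, rel=0.05)


class TestTimeConstant:
    def test_exact_monoexponential_recovered(self):
        prot = StepProtocol(step_onset=0.2)
        t = np.arange(11000) / RATE
        v = np.full(11000, -70.0)
        on = t[2000:] - 0.2
        v[2000:] = -70.0 - 24.0 * (1 - np.exp(-on / 0.050))
        tau, diag = time_constant(_sweep(v, -60), prot)
        assert tau == pytest.approx(50.0, rel=1e-3)
        assert diag["converged"] and diag["rmse_mv"] < 1e-6

    def test_ground_truth_recovered_within_ten_percent(self, step_protocol):
        gt = GroundTruth(membrane=MembraneGT(tau_m_ms=80.0))
        sweeps, _ = simulate_current_clamp(gt, step_protocol, SimConfig(seed=5))
        tau, _ = time_constant(sweep_at(sweeps, -60.0), step_protocol)
        assert tau == pytest.approx(80.0, rel=0.10)

    def test_flat_trace_is_unidentifiable(self):
        prot = StepProtocol(step_onset=0.2)
        with pytest.raises(EstimationError):
            time_constant(_sweep(np.full(11000, -70.0), -60), prot)


class TestCapacitance:
    def test_unit_arithmetic(self):
        assert capacitance(40.0, 400.0) == pytest.approx(100.0)
        assert capacitance(83.9, 401.8) == pytest.approx(208.8, abs=0.05)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DataError):
            capacitance(40.0, 0.0)

    def test_reported_cm_uses_the_same_code_path(self, default_cc,
                                                 step_protocol):
        _, sweeps, _ = default_cc
        props = measure_membrane_properties(sweeps, step_protocol)
        assert props.cm_pf == capacitance(props.tau_m_ms, props.rin_mohm)


class TestSag:
    def test_hand_computed_ratio(self):
        # peak deflection -20 mV, steady -15 mV -> 25%
        prot = StepProtocol(step_onset=0.2)
        v = np.full(11000, -70.0)
        v[2000:3500] = -90.0   # early peak within first 200 ms
        v[3500:8000] = -85.0   # steady
        assert sag_ratio(_sweep(v, -100), prot) == pytest.approx(25.0, abs=0.2)

    def test_monoexponential_response_has_no_sag(self):
        prot = StepProtocol(step_onset=0.2)
        gt = GroundTruth(membrane=MembraneGT(sag_fraction=0.0, tau_m_ms=30.0))
        sweeps, _ = simulate_current_clamp(gt, prot, SimConfig(seed=6))
        assert sag_ratio(sweep_at(sweeps, -100.0), prot) == pytest.approx(
            0.0, abs=1.0)

    def test_ground_truth_recovered(self, step_protocol):
        gt = GroundTruth(membrane=MembraneGT(sag_fraction=0.29))
        sweeps, _ = simulate_current_clamp(gt, step_protocol, SimConfig(seed=7))
        assert sag_ratio(sweep_at(sweeps, -100.0), step_protocol) == \
            pytest.approx(29.0, abs=1.5)

    def test_short_step_rejected(self):
        prot = StepProtocol(step_onset=0.2, step_duration=0.25)
        with pytest.raises(ProtocolError):
            sag_ratio(_sweep(np.full(6000, -70.0), -100), prot)


class TestAPDetection:
    def test_subthreshold_sweep_yields_empty_list(self):
        assert detect_aps(_sweep(np.full(5000, -70.0))) == []

    def test_stereotyped_ap_features_recovered(self, default_cc):
        gt, sweeps, info = default_cc
        sw = sweep_at(sweeps, 120.0)
        aps = detect_aps(sw)
        assert len(aps) == len(info["spike_times"][120.0])
        m = gt.membrane
        for ap in aps:
            assert ap.threshold_mv == pytest.approx(m.ap_threshold_mv, abs=1.0)
            assert ap.amplitude_mv == pytest.approx(m.ap_amplitude_mv, abs=1.0)
            assert ap.halfwidth_ms == pytest.approx(m.ap_halfwidth_ms,
                                                    abs=0.15)

    def test_spikes_returned_in_time_order(self, default_cc):
        _, sweeps, _ = default_cc
        aps = detect_aps(sweep_at(sweeps, 120.0))
        times = [a.peak_time_s for a in aps]
        assert times == sorted(times) and len(times) >= 2

    def test_translation_invariance(self, default_cc):
        _, sweeps, _ = default_cc
        sw = sweep_at(sweeps, 100.0)
        shifted = TimeSeries(sw.samples, sw.sampling_rate, "mV", t0=1.5)
        a = detect_aps(sw)
        b = detect_aps(shifted)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert y.peak_time_s - x.peak_time_s == pytest.approx(1.5)
            assert y.threshold_mv == x.threshold_mv
            assert y.halfwidth_ms == x.halfwidth_ms


class TestRheobaseAndFiring:
    def test_first_spiking_amplitude_wins(self, default_cc, step_protocol):
        _, sweeps, info = default_cc
        assert rheobase(sweeps, step_protocol) == info["rheobase_pa"]

    def test_no_spikes_anywhere_is_undefined(self, step_protocol):
        gt = GroundTruth(membrane=MembraneGT(rin_mohm=150.0,
                                             ap_threshold_mv=-20.0))
        sweeps, _ = simulate_current_clamp(gt, step_protocol, SimConfig(seed=8))
        assert rheobase(sweeps, step_protocol) is None

    def test_engineered_cell_reaches_rheobase_at_40_pa(self, step_protocol):
        # threshold placed so the 40 pA step just crosses it
        gt = GroundTruth(membrane=MembraneGT(rmp_mv=-70.0, rin_mohm=400.0,
                                             sag_fraction=0.0,
                                             ap_threshold_mv=-56.0))
        sweeps, info = simulate_current_clamp(gt, step_protocol,
                                              SimConfig(seed=9))
        assert info["rheobase_pa"] == 40.0
        assert rheobase(sweeps, step_protocol) == 40.0

    def test_firing_rate_counts_per_step_duration(self, default_cc,
                                                  step_protocol):
        _, sweeps, info = default_cc
        rate = step_firing_rate(sweep_at(sweeps, 80.0), step_protocol)
        assert rate == pytest.approx(info["firing_rate_80_hz"])

    def test_fi_curve_is_nondecreasing(self, default_cc, step_protocol):
        _, sweeps, _ = default_cc
        rates = []
        for amp in (20.0, 40.0, 60.0, 80.0, 100.0, 120.0):
            sw = sweep_at(sweeps, amp)
            aps = detect_aps(sw)
            rates.append(sum(step_protocol.step_onset <= a.peak_time_s
                             < step_protocol.step_offset for a in aps))
        assert all(b >= a for a, b in zip(rates, rates[1:]))
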