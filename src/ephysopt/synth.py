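"""Synthetic recording generator with exactly known ground truth.

Three modalities are emulated:

* current-clamp step sweeps — a leaky RC membrane (steady deflection I*Rin,
  monoexponential charging with tau_m), an HCN-like sag relaxation on
  hyperpolarization, and stereotyped action-potential waveforms inserted at
  threshold crossings;
* voltage-clamp sweeps — biexponential inward EPSCs at Poisson times with
  log-normal amplitudes, plus light-evoked EPSCs governed by a
  depletion/facilitation (Tsodyks-Markram style) release state and
  multiplicative trial-to-trial variability;
* extracellular recordings — 1/f background, per-band sinusoidal
  oscillations whose amplitude is scaled by a gain during stimulation,
  alpha-function transients after light pulses, and inhomogeneous-Poisson
  unit spiking with stimulus-locked gain.

Action potentials are parametric stereotypes (linear rise at fixed dV/dt, a
short flat peak, exponential repolarization) rather than conductance-based
spikes, so the ground-truth threshold, amplitude and halfwidth are known
exactly.  Stochasticity is reproducible: one named RNG stream per modality
is derived from the master seed, so adding one modality never shifts
another's stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (ConfigError, LightProtocol, StepProtocol, TimeSeries,
                   warn)
from .units import SpikeTrain

_STREAMS = {"cc": 1, "vc": 2, "lfp": 3, "units": 4}


def _rng(seed: int, modality: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[modality]]))


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class MembraneGT:
    """True membrane parameters; defaults follow neonatal deep-layer
    prelimbic pyramidal neurons."""

    rmp_mv: float = -68.4
    rin_mohm: float = 401.8
    tau_m_ms: float = 83.9
    sag_fraction: float = 0.102     # measured sag at -100 pA, as a fraction
    sag_tau_ms: float = 150.0       # slow (HCN-like) relaxation time constant
    sag_v_half_mv: float = -100.0   # HCN activation half-voltage
    sag_k_mv: float = 5.0           # HCN activation slope
    ap_threshold_mv: float = -42.4
    ap_amplitude_mv: float = 71.5
    ap_halfwidth_ms: float = 3.56
    ap_rise_rate_mv_per_ms: float = 100.0
    ap_reset_drop_mv: float = 8.0   # repolarization undershoot below threshold

    @property
    def cm_pf(self) -> float:
        return 1e3 * self.tau_m_ms / self.rin_mohm


@dataclass
class SynapseGT:
    """True synaptic parameters; defaults follow neonatal spontaneous and
    light-evoked EPSCs onto deep-layer prelimbic neurons."""

    event_rate_hz: float = 0.24
    amp_median_pa: float = 7.0      # log-normal amplitude median
    amp_sigma_log: float = 0.3
    rise_tau_ms: float = 2.0
    decay_tau_ms: float = 12.0
    release_u: float = 0.5          # fraction of resources released per pulse
    tau_rec_ms: float = 300.0       # resource recovery time constant
    tau_fac_ms: float = 0.0         # facilitation decay; 0 = pure depression
    trial_cv: float = 0.236
    latency_ms: float = 5.15
    evoked_amp_pa: float = 63.6     # first-pulse evoked amplitude


@dataclass
class UnitGT:
    """One simulated single unit."""

    baseline_hz: float = 2.0
    gain: float = 2.0               # multiplicative rate gain during stimulation
    locked_prob: float = 0.0        # per-pulse probability of a locked spike
    locked_latency_ms: float = 13.0
    locked_jitter_ms: float = 1.0


@dataclass
class NetworkGT:
    """True extracellular-signal parameters (per-band oscillation
    amplitudes in uV, stimulation gains, evoked transient, units)."""

    band_amplitudes: dict = field(default_factory=lambda: {
        (4.0, 12.0): 20.0, (12.0, 30.0): 10.0, (30.0, 45.0): 6.0})
    band_gains: dict = field(default_factory=lambda: {
        (4.0, 12.0): math.sqrt(1.807), (12.0, 30.0): math.sqrt(1.701),
        (30.0, 45.0): math.sqrt(1.383)})
    background_rms_uv: float = 10.0  # 1/f background
    evoked_peak_uv: float = 144.9
    evoked_latency_ms: float = 19.3
    units: tuple = (UnitGT(),)


@dataclass
class GroundTruth:
    membrane: MembraneGT = field(default_factory=MembraneGT)
    synapse: SynapseGT = field(default_factory=SynapseGT)
    network: NetworkGT = field(default_factory=NetworkGT)


@dataclass
class SimConfig:
    """Simulation seeds, sampling rates and noise SDs per modality."""

    seed: int = 0
    cc_rate: float = 10_000.0
    vc_rate: float = 10_000.0
    lfp_rate: float = 1_000.0
    cc_noise_mv: float = 0.3
    vc_noise_pa: float = 2.0
    lfp_noise_uv: float = 15.0


# ---------------------------------------------------------------------------
# current clamp


def solve_sag_depth(sag_fraction: float, tau_m_ms: float, tau_sag_ms: float,
                    step_duration: float = 0.6, initial_window: float = 0.2,
                    steady_window: float = 0.1) -> float:
    """Depth f of the slow relaxation that yields the requested measured sag.

    The hyperpolarizing response is DV(t) = C[(1-e^(-t/tau_m)) -
    f(1-e^(-t/tau_sag))] with C chosen so the steady deflection equals
    I*Rin.  Measured sag compares the extremum within the first
    ``initial_window`` of the step to the mean over the last
    ``steady_window``; this inverts that measurement.
    """
    if not (0 <= sag_fraction < 1):
        raise ConfigError("sag_fraction must lie in [0, 1)")
    if sag_fraction == 0:
        return 0.0
    tm, ts = tau_m_ms / 1e3, tau_sag_ms / 1e3
    t_init = np.linspace(1e-5, initial_window, 2000)
    t_steady = np.linspace(step_duration - steady_window, step_duration, 500)

    def measured(f):
        shape = lambda t: (1 - np.exp(-t / tm)) - f * (1 - np.exp(-t / ts))
        peak = np.max(shape(t_init))
        steady = np.mean(shape(t_steady))
        return (peak - steady) / peak

    return brentq(lambda f: measured(f) - sag_fraction, 1e-9, 0.999, xtol=1e-10)


def _ap_waveform_params(m: MembraneGT):
    """Rise time, plateau, repolarization tau and total length (all in s)."""
    a, r, d = m.ap_amplitude_mv, m.ap_rise_rate_mv_per_ms, m.ap_reset_drop_mv
    plateau_ms = 0.2
    t_rise_ms = a / r
    half_fall = math.log((a + d) / (a / 2 + d))
    tau_rep_ms = (m.ap_halfwidth_ms - a / (2 * r) - plateau_ms) / half_fall
    if tau_rep_ms <= 0:
        raise ConfigError("ap_halfwidth_ms too short for the rise rate")
    length_ms = t_rise_ms + plateau_ms + 6.0 * tau_rep_ms
    return t_rise_ms / 1e3, plateau_ms / 1e3, tau_rep_ms / 1e3, length_ms / 1e3


def _ap_waveform(m: MembraneGT, t: np.ndarray) -> np.ndarray:
    """Stereotyped AP evaluated at times ``t`` (s) since threshold crossing."""
    t_rise, plateau, tau_rep, _ = _ap_waveform_params(m)
    thr, a, d = m.ap_threshold_mv, m.ap_amplitude_mv, m.ap_reset_drop_mv
    v = np.empty_like(t)
    rising = t < t_rise
    flat = (t >= t_rise) & (t < t_rise + plateau)
    falling = t >= t_rise + plateau
    v[rising] = thr + m.ap_rise_rate_mv_per_ms * 1e3 * t[rising]
    v[flat] = thr + a
    v[falling] = (thr - d) + (a + d) * np.exp(-(t[falling] - t_rise - plateau) / tau_rep)
    return v


def simulate_current_clamp(gt: GroundTruth, prot: StepProtocol,
                           cfg: SimConfig):
    """Simulate the full current-clamp step family.

    Returns ``(sweeps, info)``: one voltage TimeSeries per protocol
    amplitude, and a ground-truth manifest with per-sweep spike times, the
    true rheobase on the protocol grid, and the true spike count of the
    +80 pA sweep.
    """
    m = gt.membrane
    rate = cfg.cc_rate
    if rate < 10_000:
        raise ConfigError("current-clamp sampling rate must be >= 10 kHz "
                          "to resolve the AP halfwidth")
    dt = 1.0 / rate
    tau = m.tau_m_ms / 1e3
    tau_sag = m.sag_tau_ms / 1e3
    f100 = solve_sag_depth(m.sag_fraction, m.tau_m_ms, m.sag_tau_ms,
                           prot.step_duration)
    sweep_len = prot.step_onset + prot.step_duration + 0.3
    n = int(round(sweep_len * rate))
    t = np.arange(n) * dt
    rng = _rng(cfg.seed, "cc")
    t_rise, plateau, tau_rep, ap_len = _ap_waveform_params(m)

    sweeps, spike_times = [], {}
    for amp_pa in prot.amplitudes:
        v = np.full(n, m.rmp_mv)
        dv_ss = amp_pa * m.rin_mohm * 1e-3  # pA * MOhm -> mV
        i_on = int(round(prot.step_onset * rate))
        i_off = int(round(prot.step_offset * rate))
        ts_step = t[i_on:i_off] - prot.step_onset
        spikes = []
        if amp_pa < 0:
            # HCN activation is steeply voltage dependent: Boltzmann scaling
            # of the sag depth by the steady hyperpolarized voltage, with
            # the full configured depth at the -100 pA step
            def _act(i_pa):
                v_ss = m.rmp_mv + i_pa * m.rin_mohm * 1e-3
                return 1.0 / (1.0 + math.exp((v_ss - m.sag_v_half_mv)
                                             / m.sag_k_mv))
            f = f100 * _act(amp_pa) / _act(-100.0)
            shape = ((1 - np.exp(-ts_step / tau))
                     - f * (1 - np.exp(-ts_step / tau_sag)))
            scale = dv_ss / (1 - f) if f < 1 else dv_ss
            v[i_on:i_off] = m.rmp_mv + scale * shape
            v_off = v[i_off - 1]
            v[i_off:] = m.rmp_mv + (v_off - m.rmp_mv) * np.exp(
                -(t[i_off:] - prot.step_offset) / tau)
        elif amp_pa == 0:
            pass
        else:
            v_ss = m.rmp_mv + dv_ss
            seg_t0, v0 = prot.step_onset, m.rmp_mv
            thr = m.ap_threshold_mv
            while seg_t0 < prot.step_offset:
                i0 = int(math.ceil(seg_t0 * rate - 1e-9))
                if v_ss > thr and v0 < thr:
                    t_cross = seg_t0 - tau * math.log((v_ss - thr) / (v_ss - v0))
                else:
                    t_cross = math.inf
                seg_end = min(t_cross, prot.step_offset)
                i1 = int(math.ceil(seg_end * rate - 1e-9))
                v[i0:i1] = v_ss + (v0 - v_ss) * np.exp(-(t[i0:i1] - seg_t0) / tau)
                if t_cross >= prot.step_offset:
                    v_off = v_ss + (v0 - v_ss) * math.exp(
                        -(prot.step_offset - seg_t0) / tau)
                    v[i_off:] = m.rmp_mv + (v_off - m.rmp_mv) * np.exp(
                        -(t[i_off:] - prot.step_offset) / tau)
                    break
                # paste the AP starting on the first grid sample at/after
                # the crossing so the detected threshold sample is exact
                ia = int(math.ceil(t_cross * rate - 1e-9))
                ib = min(int(round((t_cross + ap_len) * rate)), i_off)
                v[ia:ib] = _ap_waveform(m, t[ia:ib] - t[ia])
                spikes.append(t[ia] + t_rise + plateau / 2)
                seg_t0 = t[ib - 1] + dt if ib > ia else seg_t0 + dt
                v0 = v[ib - 1] if ib > ia else v0
                if ib >= i_off:
                    v[i_off:] = m.rmp_mv + (v[i_off - 1] - m.rmp_mv) * np.exp(
                        -(t[i_off:] - prot.step_offset) / tau)
                    break
        noisy = v + rng.normal(0.0, cfg.cc_noise_mv, n)
        sweeps.append(TimeSeries(noisy, rate, "mV",
                                 label=f"step_{amp_pa:+.0f}pA",
                                 meta={"step_pa": float(amp_pa)}))
        spike_times[float(amp_pa)] = spikes

    rheobase = next((a for a in prot.amplitudes if spike_times[float(a)]), None)
    firing_80 = (len(spike_times[80.0]) / prot.step_duration
                 if 80.0 in spike_times else None)
    info = {"spike_times": spike_times, "rheobase_pa": rheobase,
            "firing_rate_80_hz": firing_80, "sag_depth": f100}
    return sweeps, info


def sample_membrane_population(n: int, seed: int) -> list:
    """Draw ``n`` membrane ground truths spanning the recorded cell ranges.

    Uniform over Rin 150-550 MOhm, tau_m 30-90 ms, sag 4-30%, threshold
    -48..-38 mV, amplitude 60-95 mV, halfwidth 1.5-3.6 ms, RMP -72..-64 mV.
    Thresholds are rejection-sampled so every cell reaches rheobase within
    the +120 pA protocol ceiling, matching recordings in which all
    neurons fired overshooting APs on sustained depolarization.
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        m = MembraneGT(rmp_mv=rng.uniform(-72, -64),
                       rin_mohm=rng.uniform(150, 550),
                       tau_m_ms=rng.uniform(30, 90),
                       sag_fraction=rng.uniform(0.04, 0.30),
                       ap_threshold_mv=rng.uniform(-48, -38),
                       ap_amplitude_mv=rng.uniform(60, 95),
                       ap_halfwidth_ms=rng.uniform(1.5, 3.6))
        if m.rmp_mv + 0.100 * m.rin_mohm > m.ap_threshold_mv + 2.0:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# voltage clamp


def epsc_kernel(t: np.ndarray, rise_tau_ms: float, decay_tau_ms: float
                ) -> np.ndarray:
    """Biexponential EPSC shape normalized to unit peak (positive)."""
    if rise_tau_ms <= 0 or decay_tau_ms <= rise_tau_ms:
        raise ConfigError("need 0 < rise_tau < decay_tau")
    tr, td = rise_tau_ms / 1e3, decay_tau_ms / 1e3
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    norm = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / td)
                 - np.exp(-np.maximum(t, 0) / tr), 0.0)
    return k / norm


def stp_release_sequence(pulse_times_s: Sequence[float], release_u: float,
                         tau_rec_ms: float, tau_fac_ms: float) -> np.ndarray:
    """Relative release per pulse under depletion + facilitation.

    Resources R (starting at 1) deplete by the running release fraction u at
    each pulse and recover with tau_rec; u starts at U, is incremented by
    facilitation and decays back to U with tau_fac (tau_fac = 0 disables
    facilitation).  Returns R_n * u_n normalized to the first pulse.
    """
    if not (0 < release_u <= 1):
        raise ConfigError("release_u must lie in (0, 1]")
    out, r, u = [], 1.0, release_u
    prev = None
    for tp in pulse_times_s:
        if prev is not None:
            dt_ms = (tp - prev) * 1e3
            r = 1.0 - (1.0 - r) * math.exp(-dt_ms / tau_rec_ms)
            if tau_fac_ms > 0:
                u = release_u + (u - release_u) * math.exp(-dt_ms / tau_fac_ms)
            else:
                u = release_u
        out.append(r * u)
        r = r * (1.0 - u)
        if tau_fac_ms > 0:
            u = u + release_u * (1.0 - u)
        prev = tp
    out = np.asarray(out)
    return out / out[0]


def simulate_voltage_clamp(gt: GroundTruth, prot: LightProtocol,
                           cfg: SimConfig, include_spontaneous: bool = True,
                           include_evoked: bool = True):
    """Simulate voltage-clamp trials under a light protocol.

    Returns ``(trials, true_events)`` where each true event is a dict with
    trial index, absolute time within the trial, inserted (positive)
    amplitude, and kind ('spontaneous' or 'evoked').
    """
    s = gt.synapse
    rate = cfg.vc_rate
    if rate < 5_000:
        raise ConfigError("voltage-clamp sampling rate must be >= 5 kHz")
    trial_len = prot.pulse_onsets[-1] + 0.5
    n = int(round(trial_len * rate))
    t = np.arange(n) / rate
    rng = _rng(cfg.seed, "vc")
    rel = stp_release_sequence(prot.pulse_onsets, s.release_u,
                               s.tau_rec_ms, s.tau_fac_ms)
    if s.trial_cv > 0:
        sig = math.sqrt(math.log(1.0 + s.trial_cv ** 2))
        trial_factors = rng.lognormal(-sig ** 2 / 2, sig, prot.n_trials)
    else:
        trial_factors = np.ones(prot.n_trials)

    trials, true_events = [], []
    total_event_time = 0.0
    for k in range(prot.n_trials):
        i = np.zeros(n)
        if include_spontaneous and s.event_rate_hz > 0:
            n_ev = rng.poisson(s.event_rate_hz * trial_len)
            times = np.sort(rng.uniform(0, trial_len, n_ev))
            amps = rng.lognormal(math.log(s.amp_median_pa), s.amp_sigma_log,
                                 n_ev)
            for t0, a in zip(times, amps):
                i -= a * epsc_kernel(t - t0, s.rise_tau_ms, s.decay_tau_ms)
                true_events.append({"trial": k, "time": float(t0),
                                    "amplitude": float(a),
                                    "kind": "spontaneous"})
            total_event_time += n_ev * 5 * s.decay_tau_ms / 1e3
        if include_evoked and s.evoked_amp_pa > 0:
            for onset, r in zip(prot.pulse_onsets, rel):
                t0 = onset + s.latency_ms / 1e3
                a = s.evoked_amp_pa * r * trial_factors[k]
                i -= a * epsc_kernel(t - t0, s.rise_tau_ms, s.decay_tau_ms)
                true_events.append({"trial": k, "time": float(t0),
                                    "amplitude": float(a), "kind": "evoked"})
        i += rng.normal(0.0, cfg.vc_noise_pa, n)
        trials.append(TimeSeries(i, rate, "pA", label=f"trial_{k:03d}",
                                 meta={"trial": k}))
    if prot.n_trials and total_event_time / (prot.n_trials * trial_len) > 0.5:
        warn("spontaneous events overlap more than 50% of the trace")
    return trials, true_events


# ---------------------------------------------------------------------------
# extracellular


def _one_over_f(rng: np.random.Generator, n: int, rate: float,
                rms: float) -> np.ndarray:
    """Gaussian background with 1/f power spectrum, scaled to target RMS."""
    if rms <= 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spectrum * shaping, n)
    return x * (rms / np.std(x))


def _alpha_transient(t: np.ndarray, peak: float, latency_s: float
                     ) -> np.ndarray:
    """Alpha function peaking at ``latency_s`` with value ``peak``."""
    x = np.maximum(t, 0.0) / latency_s
    return peak * x * np.exp(1.0 - x)


def stimulation_windows(prot: LightProtocol):
    """Absolute (pre_start, stim_start, stim_end) per trial, matched 3-s
    windows; trials are laid end to end separated by the inter-trial
    interval."""
    if prot.kind == "ramp":
        dur = prot.ramp_duration
    else:
        dur = prot.pulse_onsets[-1] - prot.pulse_onsets[0] + max(
            1.0 / prot.train_rate if prot.train_rate else 0.0,
            prot.pulse_duration)
    onset0 = prot.pulse_onsets[0]
    period = dur + prot.inter_trial_interval
    wins = []
    for k in range(prot.n_trials):
        s = onset0 + k * period
        wins.append((s - dur, s, s + dur))
    return wins, period, dur


def simulate_extracellular(gt: GroundTruth, prot: LightProtocol,
                           cfg: SimConfig):
    """Simulate a continuous LFP plus unit spike trains under light trials.

    Returns ``(lfp, spike_trains, info)``.  The LFP is 1/f background plus
    per-band sinusoids (amplitudes multiplied by the configured gain during
    each stimulation window) plus an alpha-function transient after every
    pulse; spike trains are inhomogeneous Poisson with multiplicative gain
    during stimulation.
    """
    net = gt.network
    rate = cfg.lfp_rate
    for (lo, hi) in net.band_amplitudes:
        if not (0 < lo < hi < rate / 2):
            raise ConfigError(f"band ({lo}, {hi}) outside (0, rate/2)")
    wins, period, stim_dur = stimulation_windows(prot)
    total = prot.pulse_onsets[0] + prot.n_trials * period
    n = int(round(total * rate))
    t = np.arange(n) / rate
    rng = _rng(cfg.seed, "lfp")

    lfp = _one_over_f(rng, n, rate, net.background_rms_uv)
    stim_mask = np.zeros(n, dtype=bool)
    for (_, s0, s1) in wins:
        stim_mask[int(s0 * rate):int(s1 * rate)] = True
    for (lo, hi), amp in net.band_amplitudes.items():
        f0 = 0.5 * (lo + hi)
        phase = rng.uniform(0, 2 * np.pi)
        g = net.band_gains.get((lo, hi), 1.0)
        envelope = np.where(stim_mask, amp * g, amp)
        lfp += envelope * np.sin(2 * np.pi * f0 * t + phase)

    pulse_times = []
    if prot.kind in ("pulse_train", "paired_pulse", "single_pulse"):
        for k in range(prot.n_trials):
            shift = k * period
            pulse_times.extend(p + shift for p in prot.pulse_onsets)
        if net.evoked_peak_uv != 0:
            lat = net.evoked_latency_ms / 1e3
            span = int(round(min(8 * lat, 0.3) * rate))
            for tp in pulse_times:
                i0 = int(round(tp * rate))
                i1 = min(i0 + span, n)
                lfp[i0:i1] -= _alpha_transient(t[i0:i1] - tp,
                                               net.evoked_peak_uv, lat)
    lfp += rng.normal(0.0, cfg.lfp_noise_uv, n)
    lfp_ts = TimeSeries(lfp, rate, "uV", label="lfp")

    urng = _rng(cfg.seed, "units")
    spike_trains = []
    for uid, unit in enumerate(net.units):
        base = unit.baseline_hz
        spikes = np.sort(urng.uniform(0, total, urng.poisson(base * total)))
        if unit.gain != 1.0:
            extra_rate = base * (unit.gain - 1.0)
            locked = []
            for (_, s0, s1) in wins:
                if extra_rate > 0:
                    m = urng.poisson(extra_rate * (s1 - s0))
                    locked.append(urng.uniform(s0, s1, m))
                elif extra_rate < 0:
                    # thinning: drop baseline spikes inside the window
                    keep = ~((spikes >= s0) & (spikes < s1)
                             & (urng.uniform(size=spikes.size) < -extra_rate / base))
                    spikes = spikes[keep]
            if locked:
                spikes = np.sort(np.concatenate([spikes] + locked))
        if unit.locked_prob > 0 and pulse_times:
            hits = urng.uniform(size=len(pulse_times)) < unit.locked_prob
            lat = (unit.locked_latency_ms
                   + urng.normal(0, unit.locked_jitter_ms, len(pulse_times))) / 1e3
            extra = np.asarray(pulse_times)[hits] + lat[hits]
            spikes = np.sort(np.concatenate([spikes, extra]))
        spike_trains.append(SpikeTrain(unit_id=f"unit_{uid:03d}",
                                       spike_times=spikes,
                                       trial_windows=tuple(wins)))
    info = {"pulse_times": pulse_times, "trial_windows": wins,
            "duration_s": total}
    return lfp_ts, spike_trains, info
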