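"""Passive and active membrane properties from current-clamp step sweeps.

Conventions: input resistance from the -60 pA step by Ohm's law; membrane
time constant from a monoexponential fit to the same sweep over the first
200 ms of the step; capacitance Cm = tau_m / Rin; sag from the -100 pA
step as the proportional difference between the early extremum (first
200 ms) and the steady state (last 100 ms of the step); AP threshold at the
first point where dV/dt exceeds 10 mV/ms, amplitude from threshold to peak,
halfwidth at half that distance with sub-sample interpolation; rheobase as
the smallest step amplitude eliciting at least one AP; firing rate during
the +80 pA step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import (DataError, EstimationError, ProtocolError, StepProtocol,
                   TimeSeries, UnitError, warn)

DVDT_THRESHOLD_MV_PER_MS = 10.0
RIN_STEP_PA = -60.0
SAG_STEP_PA = -100.0
FIRING_STEP_PA = 80.0


@dataclass
class APFeatures:
    threshold_mv: float
    amplitude_mv: float
    halfwidth_ms: float
    peak_time_s: float


@dataclass
class MembraneProperties:
    rmp_mv: Optional[float] = None
    rin_mohm: Optional[float] = None
    tau_m_ms: Optional[float] = None
    cm_pf: Optional[float] = None
    sag_percent: Optional[float] = None
    ap_threshold_mv: Optional[float] = None
    ap_amplitude_mv: Optional[float] = None
    ap_halfwidth_ms: Optional[float] = None
    rheobase_pa: Optional[float] = None
    firing_rate_hz: Optional[float] = None
    tau_fit_rmse_mv: Optional[float] = None


def _require_voltage(ts: TimeSeries):
    if ts.unit != "mV":
        raise UnitError("expected a voltage (mV) trace")


def _baseline(sweep: TimeSeries, prot: StepProtocol,
              min_duration: float = 0.1) -> np.ndarray:
    if prot.step_onset - sweep.t0 < min_duration:
        raise DataError(f"need >= {min_duration * 1e3:.0f} ms of "
                        "pre-stimulus baseline")
    return sweep.segment(sweep.t0, prot.step_onset)


def resting_potential(baseline: TimeSeries, window: Optional[tuple] = None,
                      min_duration: float = 0.1) -> float:
    """Mean of the pre-stimulus baseline (full segment by default)."""
    _require_voltage(baseline)
    if window is None:
        seg = baseline.samples
        if baseline.duration < min_duration:
            raise DataError("baseline shorter than the minimum window")
    else:
        seg = baseline.segment(*window)
        if len(seg) / baseline.sampling_rate < min_duration:
            raise DataError("baseline window too short")
    if detect_aps(TimeSeries(seg, baseline.sampling_rate, "mV")):
        warn("action potential detected in the baseline window")
    return float(np.mean(seg))


def _sweep_for(sweeps: Sequence[TimeSeries], amp_pa: float) -> TimeSeries:
    for s in sweeps:
        if s.meta.get("step_pa") == amp_pa:
            return s
    raise ProtocolError(f"protocol lacks a {amp_pa:+.0f} pA sweep")


def input_resistance(sweep: TimeSeries, prot: StepProtocol,
                     step_pa: float = RIN_STEP_PA,
                     steady_window: float = 0.1) -> float:
    """Ohm's law on the -60 pA step: steady deflection / injected current."""
    _require_voltage(sweep)
    amp = sweep.meta.get("step_pa", step_pa)
    if amp != step_pa:
        raise ProtocolError(f"expected the {step_pa:+.0f} pA sweep")
    base = float(np.mean(_baseline(sweep, prot)))
    steady = float(np.mean(sweep.segment(prot.step_offset - steady_window,
                                         prot.step_offset)))
    return (steady - base) / step_pa * 1e3  # mV/pA -> MOhm


def time_constant(sweep: TimeSeries, prot: StepProtocol,
                  fit_window: float = 0.2):
    """Monoexponential fit V(t) = V_ss + A exp(-t/tau) on the step onset.

    Returns ``(tau_ms, diagnostics)`` with RMSE and convergence flag.
    Raises :class:`EstimationError` when the deflection is unidentifiable.
    """
    _require_voltage(sweep)
    base = float(np.mean(_baseline(sweep, prot)))
    seg = sweep.segment(prot.step_onset, prot.step_onset + fit_window)
    t = np.arange(seg.size) / sweep.sampling_rate
    a0 = seg[-1] - base
    if abs(a0) < 1.0:  # < 1 mV deflection: tau unidentifiable
        raise EstimationError("no measurable deflection; tau unidentifiable")

    def model(t, v_ss, a, tau):
        return v_ss + a * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(model, t, seg,
                            p0=[base + a0, -a0, 0.05],
                            bounds=([-200, -200, 1e-4], [100, 200, 1.0]),
                            maxfev=10000)
    except RuntimeError as e:
        raise EstimationError(f"tau fit did not converge: {e}") from e
    rmse = float(np.sqrt(np.mean((model(t, *popt) - seg) ** 2)))
    return float(popt[2] * 1e3), {"rmse_mv": rmse, "converged": True,
                                  "v_ss_mv": float(popt[0])}


def capacitance(tau_m_ms: float, rin_mohm: float) -> float:
    """Cm = tau_m / Rin, in pF."""
    if tau_m_ms <= 0 or rin_mohm <= 0:
        raise DataError("tau_m and Rin must be positive")
    return 1e3 * tau_m_ms / rin_mohm  # ms / MOhm -> nF*1e3 = pF


def sag_ratio(sweep: TimeSeries, prot: StepProtocol,
              initial_window: float = 0.2, steady_window: float = 0.1,
              smooth_ms: float = 5.0) -> float:
    """Sag (%) on the -100 pA step: 100 * (|peak| - |steady|) / |peak|.

    The initial response is the extremal deflection within the first
    200 ms of the step; the steady state averages the last 100 ms.  The
    peak is picked on a lightly smoothed segment (``smooth_ms`` moving
    average) so the extremum statistic is not inflated by sample noise.
    """
    _require_voltage(sweep)
    if prot.step_duration < initial_window + steady_window:
        raise ProtocolError("step too short for the sag windows")
    base = float(np.mean(_baseline(sweep, prot)))
    early = sweep.segment(prot.step_onset, prot.step_onset + initial_window)
    steady = float(np.mean(sweep.segment(prot.step_offset - steady_window,
                                         prot.step_offset)))
    w = max(int(round(smooth_ms / 1e3 * sweep.sampling_rate)), 1)
    if w > 1:
        from scipy.ndimage import uniform_filter1d
        early = uniform_filter1d(early, w, mode="nearest")
    dv_early = early - base
    peak = dv_early[np.argmax(np.abs(dv_early))]
    if peak == 0:
        raise EstimationError("no deflection; sag undefined")
    return 100.0 * (abs(peak) - abs(steady - base)) / abs(peak)


def detect_aps(sweep: TimeSeries, dvdt_threshold: float = DVDT_THRESHOLD_MV_PER_MS,
               min_prominence_mv: float = 20.0) -> list:
    """Detect action potentials and measure threshold, amplitude, halfwidth.

    Threshold is the voltage at the first sample, preceding each peak, of
    the contiguous run where the centered-difference dV/dt exceeds
    10 mV/ms.  Amplitude is threshold-to-peak; halfwidth is the spike width
    at threshold + amplitude/2, with linear interpolation at the
    crossings.  Subthreshold sweeps return an empty list.
    """
    _require_voltage(sweep)
    v = sweep.samples
    rate = sweep.sampling_rate
    if rate < 10_000:
        warn("sampling rate below 10 kHz; AP halfwidth may be unresolved")
    dvdt = np.gradient(v) * rate / 1e3  # mV/ms, centered differences
    fast = dvdt > dvdt_threshold
    if not np.any(fast):
        return []
    peaks, _ = find_peaks(v, prominence=min_prominence_mv)
    lookback = int(round(0.010 * rate))  # threshold must lie < 10 ms before peak
    out = []
    for p in peaks:
        w0 = max(p - lookback, 0)
        fast_idx = np.flatnonzero(fast[w0:p + 1]) + w0
        if fast_idx.size == 0:
            continue
        # earliest sample of the last contiguous fast-rise run before the peak
        breaks = np.flatnonzero(np.diff(fast_idx) > 1)
        thr_idx = int(fast_idx[breaks[-1] + 1] if breaks.size else fast_idx[0])
        thr = v[thr_idx]
        amp = v[p] - thr
        if amp < min_prominence_mv:
            continue
        half = thr + amp / 2.0
        left = _cross_time(v, p, half, rate, direction=-1)
        right = _cross_time(v, p, half, rate, direction=+1)
        if left is None or right is None:
            continue
        out.append(APFeatures(threshold_mv=float(thr),
                              amplitude_mv=float(amp),
                              halfwidth_ms=float((right - left) * 1e3),
                              peak_time_s=float(sweep.t0 + p / rate)))
    out.sort(key=lambda a: a.peak_time_s)
    return out


def _cross_time(v, peak_idx, level, rate, direction):
    """Interpolated time (s) where v crosses ``level`` walking from the peak."""
    i = peak_idx
    n = v.size
    while 0 < i < n - 1:
        j = i + direction
        if v[j] < level <= v[i]:
            frac = (v[i] - level) / (v[i] - v[j])
            return (i + direction * frac) / rate
        i = j
    return None


def rheobase(sweeps: Sequence[TimeSeries], prot: StepProtocol
             ) -> Optional[float]:
    """Smallest step amplitude whose sweep fires >= 1 AP; None when no
    sweep spikes (resolution limited to the protocol's 20-pA grid)."""
    for amp in prot.amplitudes:
        if amp <= 0:
            continue
        try:
            sweep = _sweep_for(sweeps, float(amp))
        except ProtocolError:
            continue
        aps = detect_aps(sweep)
        in_step = [a for a in aps
                   if prot.step_onset <= a.peak_time_s - sweep.t0 < prot.step_offset]
        if in_step:
            return float(amp)
    return None


def step_firing_rate(sweep: TimeSeries, prot: StepProtocol,
                     step_pa: float = FIRING_STEP_PA) -> float:
    """AP count within the +80 pA step window divided by the step duration."""
    if sweep.meta.get("step_pa", step_pa) != step_pa:
        raise ProtocolError(f"expected the {step_pa:+.0f} pA sweep")
    aps = detect_aps(sweep)
    n = sum(prot.step_onset <= a.peak_time_s - sweep.t0 < prot.step_offset
            for a in aps)
    return n / prot.step_duration


def measure_membrane_properties(sweeps: Sequence[TimeSeries],
                                prot: StepProtocol) -> MembraneProperties:
    """Full per-cell membrane-property extraction from a step family."""
    props = MembraneProperties()
    ref = sweeps[0]
    props.rmp_mv = resting_potential(
        TimeSeries(_baseline(ref, prot), ref.sampling_rate, "mV"))
    try:
        rin_sweep = _sweep_for(sweeps, RIN_STEP_PA)
        props.rin_mohm = input_resistance(rin_sweep, prot)
        tau, diag = time_constant(rin_sweep, prot)
        props.tau_m_ms = tau
        props.tau_fit_rmse_mv = diag["rmse_mv"]
        props.cm_pf = capacitance(tau, props.rin_mohm)
    except (ProtocolError, EstimationError) as e:
        warn(str(e))
    try:
        props.sag_percent = sag_ratio(_sweep_for(sweeps, SAG_STEP_PA), prot)
    except (ProtocolError, EstimationError) as e:
        warn(str(e))
    props.rheobase_pa = rheobase(sweeps, prot)
    try:
        props.firing_rate_hz = step_firing_rate(
            _sweep_for(sweeps, FIRING_STEP_PA), prot)
    except ProtocolError as e:
        warn(str(e))
    ap_feats = []
    for s in sweeps:
        if s.meta.get("step_pa", 0) > 0:
            ap_feats.extend(a for a in detect_aps(s)
                            if prot.step_onset <= a.peak_time_s - s.t0
                            < prot.step_offset)
    if ap_feats:
        props.ap_threshold_mv = float(np.mean([a.threshold_mv for a in ap_feats]))
        props.ap_amplitude_mv = float(np.mean([a.amplitude_mv for a in ap_feats]))
        props.ap_halfwidth_ms = float(np.mean([a.halfwidth_ms for a in ap_feats]))
    return props
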