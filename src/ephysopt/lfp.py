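"""Field-potential preprocessing, band power and evoked responses.

Raw extracellular signals are zero-phase bandpass filtered (third-order
Butterworth, forward and backward) and decimated to 1000 Hz; spectra use
Welch's method with non-overlapping 1-s Hann windows; band power
integrates the spectrum over the canonical 4-12 / 12-30 / 30-45 Hz bands;
ramp stimulation is quantified as (stim - pre)/pre band-power modulation
between the 1.5 s preceding the ramp and its last 1.5 s; pulse-evoked
LFP responses are averaged over pulse-aligned, baseline-subtracted epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import (ConfigError, DataError, LightProtocol, TimeSeries, warn)

BANDS = ((4.0, 12.0), (12.0, 30.0), (30.0, 45.0))
TARGET_RATE = 1000.0


@dataclass
class BandPower:
    band: tuple
    pre_power: float   # uV^2
    stim_power: float  # uV^2

    @property
    def modulation(self) -> float:
        """(stim - pre)/pre normalized power change."""
        return (self.stim_power - self.pre_power) / self.pre_power


@dataclass
class EvokedLFP:
    mean_trace: TimeSeries
    amplitude_uv: Optional[float]
    delay_ms: Optional[float]
    polarity: int = 0  # sign of the extremal deflection


def preprocess(ts: TimeSeries, low_hz: float = 1.0, high_hz: float = 100.0,
               target_rate: float = TARGET_RATE) -> TimeSeries:
    """Zero-phase third-order Butterworth bandpass, then decimation.

    The forward-backward filter preserves phase; the bandpass itself acts
    as the anti-alias filter, so decimation is plain integer subsampling.
    """
    nyq = ts.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ConfigError(f"band ({low_hz}, {high_hz}) outside (0, {nyq})")
    sos = signal.butter(3, [low_hz, high_hz], btype="bandpass",
                        fs=ts.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.samples)
    if ts.sampling_rate == target_rate:
        out = filtered
        rate = ts.sampling_rate
    else:
        step = ts.sampling_rate / target_rate
        if abs(step - round(step)) > 1e-9 or step < 1:
            raise ConfigError("sampling rate must be an integer multiple "
                              f"of {target_rate} Hz")
        out = filtered[::int(round(step))]
        rate = target_rate
    return TimeSeries(out, rate, ts.unit, t0=ts.t0,
                      label=ts.label, meta=dict(ts.meta, filtered=True))


def welch_psd(segments: Sequence[TimeSeries], rate: float = TARGET_RATE):
    """Welch PSD over concatenated 1-s windows (non-overlapping, Hann).

    Every segment must be exactly 1 s at the common rate; the frequency
    resolution is 1 Hz.  Returns (freqs, psd) with psd in uV^2/Hz.
    """
    if not segments:
        raise DataError("no segments")
    n_per = int(round(rate))
    arrs = []
    for s in segments:
        if s.sampling_rate != rate:
            raise DataError("mixed sampling rates in PSD segments")
        if s.n != n_per:
            raise DataError("each PSD segment must be exactly 1 s long")
        arrs.append(s.samples)
    x = np.concatenate(arrs)
    freqs, psd = signal.welch(x, fs=rate, window="hann", nperseg=n_per,
                              noverlap=0, detrend=False)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple) -> float:
    """Integral of the spectrum over [low, high) by the rectangle rule."""
    lo, hi = band
    if hi <= lo:
        raise ConfigError("empty band")
    if lo < freqs[0] or hi > freqs[-1] + (freqs[1] - freqs[0]):
        raise ConfigError("band outside the spectrum range")
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo) & (freqs < hi)
    return float(np.sum(psd[mask]) * df)


def _segment_band_power(x: np.ndarray, rate: float, band: tuple) -> float:
    """Band power of one (possibly non-1-s) segment via periodogram."""
    freqs, psd = signal.periodogram(x, fs=rate, window="hann", detrend=False)
    df = freqs[1] - freqs[0]
    lo, hi = band
    return float(np.sum(psd[(freqs >= lo) & (freqs < hi)]) * df)


def ramp_power_modulation(trials: Sequence[TimeSeries],
                          ramp_onset_s: float, ramp_duration_s: float = 3.0,
                          window_s: float = 1.5,
                          bands: Sequence[tuple] = BANDS) -> dict:
    """Band-power modulation under ramp light stimulation.

    Per trial, band power is measured in the ``window_s`` (1.5 s) window
    preceding the ramp and in the last ``window_s`` of the ramp; powers
    are averaged across trials before the (stim - pre)/pre ratio.
    Returns {band: BandPower}.
    """
    if len(trials) == 0:
        raise DataError("no trials")
    if len(trials) < 2:
        warn("fewer than 2 usable trials; modulation estimate is unstable")
    out = {}
    pre_segs, stim_segs = [], []
    for t in trials:
        pre_segs.append(t.segment(ramp_onset_s - window_s, ramp_onset_s))
        stim_segs.append(t.segment(ramp_onset_s + ramp_duration_s - window_s,
                                   ramp_onset_s + ramp_duration_s))
    rate = trials[0].sampling_rate
    for band in bands:
        pre = float(np.mean([_segment_band_power(s, rate, band)
                             for s in pre_segs]))
        stim = float(np.mean([_segment_band_power(s, rate, band)
                              for s in stim_segs]))
        out[tuple(band)] = BandPower(tuple(band), pre, stim)
    return out


def evoked_lfp(trials: Sequence[TimeSeries], pulse_onsets_s: Sequence[float],
               window_ms: tuple = (5.0, 50.0), baseline_ms: float = 10.0,
               noise_floor_uv: Optional[float] = None) -> EvokedLFP:
    """Pulse-triggered average LFP response.

    Epochs aligned to every pulse across all trials are baseline-subtracted
    (10-ms pre-pulse mean) and averaged; the amplitude is the maximum
    absolute deflection within the 5-50 ms search window and the delay the
    time of that extremum from pulse onset.  Flat input returns an
    undefined (None) delay.
    """
    lo_ms, hi_ms = window_ms
    rate = trials[0].sampling_rate
    n_pre = int(round(baseline_ms / 1e3 * rate))
    n_post = int(round(hi_ms / 1e3 * rate)) + 1
    epochs = []
    for t in trials:
        for tp in pulse_onsets_s:
            i = t.index_at(tp)
            if i - n_pre < 0 or i + n_post > t.n:
                raise DataError("epoch window outside the trial")
            seg = t.samples[i - n_pre:i + n_post]
            epochs.append(seg - seg[:n_pre].mean())
    if not epochs:
        raise DataError("no epochs")
    mean = np.mean(epochs, axis=0)
    post = mean[n_pre:]
    times_ms = np.arange(post.size) / rate * 1e3
    mask = (times_ms >= lo_ms) & (times_ms <= hi_ms)
    seg = post[mask]
    i_ext = int(np.argmax(np.abs(seg)))
    amp = float(abs(seg[i_ext]))
    delay = float(times_ms[mask][i_ext])
    mean_ts = TimeSeries(mean, rate, trials[0].unit,
                         t0=-baseline_ms / 1e3, label="evoked_lfp_mean")
    if noise_floor_uv is not None and amp <= noise_floor_uv:
        return EvokedLFP(mean_ts, amp, None, 0)
    return EvokedLFP(mean_ts, amp, delay, int(np.sign(seg[i_ext])))


def extract_trials(lfp: TimeSeries, stim_onsets_s: Sequence[float],
                   pre_s: float, post_s: float) -> list:
    """Cut a continuous LFP into per-trial TimeSeries around stimulus
    onsets; trial time is relative, with the stimulus at t = pre_s."""
    out = []
    for s in stim_onsets_s:
        seg = lfp.segment(s - pre_s, s + post_s)
        out.append(TimeSeries(seg, lfp.sampling_rate, lfp.unit, t0=0.0,
                              label=f"trial@{s:.2f}s"))
    return out
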