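"""Single-unit firing around light stimulation.

Rates, the modulation index MI = (stim - pre)/(stim + pre), a
permutation-test responsiveness classification (activated / inhibited /
unmodulated), peri-stimulus response latency, and population fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DataError, LightProtocol, warn


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit plus its per-trial analysis windows.

    ``trial_windows`` holds (pre_start, stim_start, stim_end) per trial;
    the pre window [pre_start, stim_start) is duration-matched to the
    stimulation window [stim_start, stim_end).
    """

    unit_id: str
    spike_times: np.ndarray
    trial_windows: tuple

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)
        for (a, b, c) in self.trial_windows:
            if not (a <= b < c):
                raise DataError("trial window must satisfy pre_start <= "
                                "stim_start < stim_end")

    def counts(self):
        """(pre_counts, stim_counts, pre_dur, stim_dur) over trials."""
        st = self.spike_times
        pre = np.array([np.searchsorted(st, b) - np.searchsorted(st, a)
                        for (a, b, _) in self.trial_windows])
        stim = np.array([np.searchsorted(st, c) - np.searchsorted(st, b)
                         for (_, b, c) in self.trial_windows])
        pre_dur = np.array([b - a for (a, b, _) in self.trial_windows])
        stim_dur = np.array([c - b for (_, b, c) in self.trial_windows])
        return pre, stim, pre_dur, stim_dur


@dataclass
class UnitModulation:
    unit_id: str
    rate_pre: float
    rate_stim: float
    mi: Optional[float]
    p_value: float
    label: str          # activated | inhibited | unmodulated
    latency_ms: Optional[float] = None
    seed: Optional[int] = None


def firing_rate(train: SpikeTrain, windows=None) -> float:
    """Spike count divided by window duration, pooled over windows.

    ``windows`` is a list of (start, stop) intervals; by default the
    stimulation windows of the train's trial structure are used.
    """
    if windows is None:
        windows = [(b, c) for (_, b, c) in train.trial_windows]
    windows = [(float(a), float(b)) for (a, b) in windows]
    total_dur = sum(b - a for (a, b) in windows)
    if total_dur <= 0:
        raise DataError("zero-duration analysis window")
    st = train.spike_times
    count = sum(int(np.searchsorted(st, b) - np.searchsorted(st, a))
                for (a, b) in windows)
    return count / total_dur


def modulation_index(rate_pre: float, rate_stim: float) -> Optional[float]:
    """(stim - pre)/(stim + pre); None when both rates are zero."""
    if rate_pre < 0 or rate_stim < 0:
        raise DataError("rates must be non-negative")
    denom = rate_stim + rate_pre
    if denom == 0:
        return None
    return (rate_stim - rate_pre) / denom


def percent_rate_change(rate_pre: float, rate_stim: float) -> Optional[float]:
    """Percentage rate increase 100*(stim - pre)/pre; None when pre = 0."""
    if rate_pre == 0:
        return None
    return 100.0 * (rate_stim - rate_pre) / rate_pre


def classify_unit(train: SpikeTrain, n_permutations: int = 2000,
                  alpha: float = 0.05, seed: int = 0,
                  min_trials: int = 30) -> UnitModulation:
    """Classify a unit as activated / inhibited / unmodulated.

    Per-trial pre and stimulation spike counts are compared with a paired,
    within-trial label-permutation test on the mean count difference
    (two-sided).  The label follows the sign of MI when the permutation
    p-value falls below ``alpha``.  Deterministic given ``seed``.
    """
    pre, stim, pre_dur, stim_dur = train.counts()
    n_trials = pre.size
    if n_trials < min_trials:
        warn(f"{train.unit_id}: only {n_trials} trials; "
             "classification is low-powered")
    rate_pre = float(pre.sum() / pre_dur.sum())
    rate_stim = float(stim.sum() / stim_dur.sum())
    mi = modulation_index(rate_pre, rate_stim)

    diff = stim - pre
    obs = diff.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n_trials))
    null = (signs * diff).mean(axis=1)
    p = float((1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_permutations + 1))

    if mi is None or p >= alpha:
        label = "unmodulated"
    elif mi > 0:
        label = "activated"
    elif mi < 0:
        label = "inhibited"
    else:
        label = "unmodulated"
    return UnitModulation(train.unit_id, rate_pre, rate_stim, mi, p, label,
                          seed=seed)


def response_latency(train: SpikeTrain, pulse_onsets: Sequence[float],
                     bin_ms: float = 2.0, window_ms: float = 50.0,
                     baseline_ms: float = 50.0, k_sd: float = 3.0,
                     min_consecutive: int = 2) -> Optional[float]:
    """Latency of stimulus-locked firing from the pooled PSTH.

    Builds a peri-stimulus histogram (default 2-ms bins over 0-50 ms after
    each pulse); the latency is the center of the first bin whose rate
    exceeds the pre-pulse baseline mean + ``k_sd`` SD for at least
    ``min_consecutive`` consecutive bins.  Returns None when no bin
    crosses (no locked response).
    """
    onsets = np.asarray(pulse_onsets, dtype=float)
    if onsets.size == 0:
        raise DataError("no pulse onsets")
    st = train.spike_times
    rel = []
    for tp in onsets:
        lo = np.searchsorted(st, tp - baseline_ms / 1e3)
        hi = np.searchsorted(st, tp + window_ms / 1e3)
        rel.append((st[lo:hi] - tp) * 1e3)
    rel = np.concatenate(rel) if rel else np.array([])
    edges = np.arange(-baseline_ms, window_ms + bin_ms / 2, bin_ms)
    hist, _ = np.histogram(rel, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    base = hist[centers < 0]
    post = hist[centers > 0]
    post_centers = centers[centers > 0]
    thresh = base.mean() + k_sd * base.std(ddof=1)
    above = post > thresh
    for i in range(len(above) - min_consecutive + 1):
        if np.all(above[i:i + min_consecutive]):
            return float(post_centers[i])
    return None


def population_fractions(labels: Sequence[str], decimals: int = 1) -> dict:
    """Percentage of activated / inhibited / unmodulated units."""
    from .synaptic import proportion_responsive
    labels = list(labels)
    if not labels:
        raise DataError("empty label list")
    n = len(labels)
    return {lab: proportion_responsive(labels.count(lab), n, decimals)
            for lab in ("activated", "inhibited", "unmodulated")}
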