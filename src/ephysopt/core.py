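"""Shared data model for electrophysiology pipeline stages.

All signals are carried as :class:`TimeSeries` — a uniformly sampled vector
with an explicit unit (mV for current-clamp voltage, pA for voltage-clamp
current, uV for extracellular field potentials).  Stimulation protocols are
plain dataclasses; times are in seconds with t = 0 at sweep start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

VALID_UNITS = ("mV", "pA", "uV")

RS_LIMIT_MOHM = 30.0          # whole-cell access resistance ceiling
RS_CHANGE_LIMIT = 0.25        # max fractional Rs drift before exclusion
JUNCTION_POTENTIAL_MV = -8.65  # measured K-gluconate liquid junction potential


class EphysError(Exception):
    """Base class for pipeline errors."""


class FormatError(EphysError):
    """A file does not conform to the documented layout."""


class DataError(EphysError):
    """Sample values violate an invariant (e.g. non-finite)."""


class UnitError(EphysError):
    """An operation received a trace in the wrong unit."""


class ProtocolError(EphysError):
    """The stimulation protocol lacks a required sweep or stimulus."""


class ConfigError(EphysError):
    """A configuration value is out of its admissible range."""


class EstimationError(EphysError):
    """A fit failed or a quantity is unidentifiable on this input."""


@dataclass
class TimeSeries:
    """Uniformly sampled signal with unit, sampling rate and start time."""

    samples: np.ndarray
    sampling_rate: float
    unit: str
    t0: float = 0.0
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DataError("samples must be a non-empty 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        if not (self.sampling_rate > 0):
            raise DataError("sampling_rate must be positive")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Sample index of time ``t`` (nearest grid point at or before t)."""
        return int(round((t - self.t0) * self.sampling_rate))

    def segment(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples in the half-open interval [t_start, t_stop)."""
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_stop), self.n)
        if i1 <= i0:
            raise DataError(f"empty segment [{t_start}, {t_stop})")
        return self.samples[i0:i1]

    def copy(self) -> "TimeSeries":
        return replace(self, samples=self.samples.copy(), meta=dict(self.meta))


@dataclass(frozen=True)
class StepProtocol:
    """Current-clamp step family: 600-ms steps, -100..+120 pA in 20-pA increments."""

    step_onset: float = 0.2
    step_duration: float = 0.6
    amplitudes: tuple = tuple(range(-100, 121, 20))
    holding_potential: float = -70.0

    def __post_init__(self):
        if not (self.step_duration > 0):
            raise ConfigError("step_duration must be positive")
        amps = tuple(float(a) for a in self.amplitudes)
        if len(amps) == 0 or any(b <= a for a, b in zip(amps, amps[1:])):
            raise ConfigError("amplitudes must be non-empty and strictly increasing")
        object.__setattr__(self, "amplitudes", amps)

    @property
    def step_offset(self) -> float:
        return self.step_onset + self.step_duration


@dataclass(frozen=True)
class LightProtocol:
    """Optogenetic stimulation: pulse trains, ramps, paired or single pulses.

    ``pulse_onsets`` are stimulus times within one trial (seconds from trial
    start); the same schedule repeats every ``inter_trial_interval``.
    """

    kind: str  # pulse_train | ramp | paired_pulse | single_pulse
    pulse_onsets: tuple
    pulse_duration: float = 0.005
    n_trials: int = 1
    inter_trial_interval: float = 7.0
    train_rate: float = 0.0
    ramp_duration: float = 3.0

    def __post_init__(self):
        kinds = ("pulse_train", "ramp", "paired_pulse", "single_pulse")
        if self.kind not in kinds:
            raise ConfigError(f"kind must be one of {kinds}")
        onsets = tuple(float(t) for t in self.pulse_onsets)
        if len(onsets) == 0 or any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConfigError("pulse_onsets must be non-empty and strictly increasing")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        object.__setattr__(self, "pulse_onsets", onsets)


def pulse_train_protocol(rate_hz: float = 8.0, duration: float = 3.0,
                         onset: float = 3.0, pulse_duration: float = 0.005,
                         n_trials: int = 60, inter_trial_interval: float = 7.0
                         ) -> LightProtocol:
    """In vivo style pulse train: 5-ms pulses at 8 Hz for 3 s, 60 repeats."""
    n_pulses = int(round(rate_hz * duration))
    onsets = tuple(onset + i / rate_hz for i in range(n_pulses))
    return LightProtocol(kind="pulse_train", pulse_onsets=onsets,
                         pulse_duration=pulse_duration, n_trials=n_trials,
                         inter_trial_interval=inter_trial_interval,
                         train_rate=rate_hz)


def ramp_protocol(onset: float = 3.0, duration: float = 3.0,
                  n_trials: int = 60, inter_trial_interval: float = 7.0
                  ) -> LightProtocol:
    """Linearly increasing 3-s light ramp, 60 repeats."""
    return LightProtocol(kind="ramp", pulse_onsets=(onset,),
                         pulse_duration=duration, n_trials=n_trials,
                         inter_trial_interval=inter_trial_interval,
                         ramp_duration=duration)


def paired_pulse_protocol(interval_ms: float, onset: float = 0.2,
                          pulse_duration: float = 0.010, n_trials: int = 15,
                          inter_trial_interval: float = 15.0) -> LightProtocol:
    """Two light pulses separated by 125, 250 or 500 ms, repeated every 15 s."""
    return LightProtocol(kind="paired_pulse",
                         pulse_onsets=(onset, onset + interval_ms / 1000.0),
                         pulse_duration=pulse_duration, n_trials=n_trials,
                         inter_trial_interval=inter_trial_interval)


@dataclass
class QCRecord:
    """Series-resistance history of one whole-cell recording."""

    series_resistance_trace: np.ndarray
    seal_ok: bool = True

    def __post_init__(self):
        self.series_resistance_trace = np.asarray(self.series_resistance_trace,
                                                  dtype=np.float64)

    @property
    def rs_change_fraction(self) -> float:
        rs = self.series_resistance_trace
        return float(np.max(np.abs(rs - rs[0])) / rs[0])


@dataclass
class QCDecision:
    include: bool
    reason: str  # "", "rs_limit", "rs_change", "seal"


def qc_cell(qc: QCRecord, rs_limit_mohm: float = RS_LIMIT_MOHM,
            rs_change_limit: float = RS_CHANGE_LIMIT) -> QCDecision:
    """Include/exclude a cell on access-resistance criteria.

    A cell is excluded when the initial Rs is at or above ``rs_limit_mohm``
    (whole-cell access must form below 30 MOhm), when Rs drifts by more than
    ``rs_change_limit`` (25%) of its initial value, or when no GOhm seal
    formed.  The decision carries the first rule that fired.
    """
    rs = qc.series_resistance_trace
    if rs.size == 0:
        raise DataError("empty series-resistance trace")
    if np.any(rs <= 0):
        raise DataError("series resistance must be positive")
    if not qc.seal_ok:
        return QCDecision(False, "seal")
    if rs[0] >= rs_limit_mohm:
        return QCDecision(False, "rs_limit")
    if qc.rs_change_fraction > rs_change_limit:
        return QCDecision(False, "rs_change")
    return QCDecision(True, "")


def apply_junction_correction(ts: TimeSeries,
                              offset_mv: float = JUNCTION_POTENTIAL_MV
                              ) -> TimeSeries:
    """Shift a voltage trace by the liquid-junction-potential offset.

    The correction is applied exactly once; the returned trace carries
    ``meta['junction_corrected'] = True`` and a second application raises.
    """
    if ts.unit != "mV":
        raise UnitError("junction correction applies to voltage (mV) traces")
    if ts.meta.get("junction_corrected", False):
        raise DataError("trace is already junction-corrected")
    out = ts.copy()
    out.samples = out.samples + offset_mv
    out.meta["junction_corrected"] = True
    out.meta["junction_offset_mv"] = float(offset_mv)
    return out


@dataclass
class MeasurementTable:
    """Long-format table of per-cell / per-unit measurements.

    Backed by a pandas DataFrame with columns
    (id, group, age, layer, variable, value, excluded, reason).
    """

    data: "object"  # pandas.DataFrame

    REQUIRED = ("id", "group", "age", "layer", "variable", "value")

    def __post_init__(self):
        import pandas as pd
        df = pd.DataFrame(self.data)
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"MeasurementTable missing column {col!r}")
        if "excluded" not in df.columns:
            df["excluded"] = False
        if "reason" not in df.columns:
            df["reason"] = ""
        dup = df.duplicated(subset=["id", "variable"])
        if dup.any():
            raise DataError("duplicate (id, variable) rows in MeasurementTable")
        self.data = df

    def included(self):
        return self.data[~self.data["excluded"]]


def warn(msg: str):
    warnings.warn(msg, stacklevel=3)
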