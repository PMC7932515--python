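"""Core domain types for alternating-polarity PSTH analysis.

The central objects are :class:`TimeSeries` (any uniformly sampled signal:
stimulus, evoked potential, or a PSTH viewed as a continuous waveform),
:class:`SpikeTrainSet` (per-trial spike times labelled by stimulus polarity),
and :class:`PSTH` (a binned spike-count signal that is also a TimeSeries).
Correlograms, spectra and harmonicgrams have their own light containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "SpikeTrainSet",
    "PSTH",
    "FrequencyTrajectory",
    "AnalyticSignal",
    "Correlogram",
    "Spectrum",
    "Harmonicgram",
    "AlignmentError",
    "ValidationError",
]


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class AlignmentError(ValidationError):
    """Two signals disagree in length, sampling rate or duration."""


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Sample values; must be finite and non-empty.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float, optional
        Time of the first sample in seconds (default 0, stimulus onset).
    unit : str, optional
        Free-form unit tag, e.g. ``"spikes/s"``, ``"volts"``, ``"a.u."``.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError("TimeSeries requires a 1-D, non-empty sample array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("TimeSeries values must be finite")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def copy_with(self, values: np.ndarray, unit: Optional[str] = None) -> "TimeSeries":
        """A new TimeSeries sharing fs/t0 but with different samples."""
        return TimeSeries(np.asarray(values, float), self.fs, self.t0,
                          unit if unit is not None else self.unit)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.values ** 2)))


def _check_aligned(a: TimeSeries, b: TimeSeries) -> None:
    if a.n != b.n:
        raise AlignmentError(f"length mismatch: {a.n} vs {b.n}")
    if not np.isclose(a.fs, b.fs, rtol=1e-12):
        raise AlignmentError(f"sampling-rate mismatch: {a.fs} vs {b.fs}")


@dataclass
class SpikeTrainSet:
    """Spike times from repeated presentations of both stimulus polarities.

    Parameters
    ----------
    trains : sequence of 1-D arrays
        Spike times in seconds, one array per stimulus repetition. Each
        train is sorted ascending on construction.
    polarities : sequence of int
        Stimulus polarity (+1 or -1) for each train.
    duration : float
        Stimulus/analysis duration in seconds; all spikes must fall in
        ``[0, duration)``.
    cf : float, optional
        Characteristic frequency of the recorded/simulated fiber, Hz.
    spont_rate : float, optional
        Spontaneous rate, spikes/s.
    """

    trains: list
    polarities: np.ndarray
    duration: float
    cf: Optional[float] = None
    spont_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.trains = [np.sort(np.asarray(t, dtype=float).ravel()) for t in self.trains]
        self.polarities = np.asarray(self.polarities, dtype=int)
        if len(self.trains) != self.polarities.size:
            raise ValidationError("one polarity label per train is required")
        if not np.all(np.isin(self.polarities, (-1, 1))):
            raise ValidationError("polarities must be +1 or -1")
        if not self.duration > 0:
            raise ValidationError("duration must be positive")
        for i, t in enumerate(self.trains):
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValidationError(
                    f"train {i}: spike times must lie in [0, {self.duration}) s"
                )

    @property
    def n_trains(self) -> int:
        return len(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def select(self, polarity) -> "SpikeTrainSet":
        """Subset of trains for one polarity (+1, -1) or ``"pooled"``."""
        if polarity == "pooled":
            return self
        if polarity not in (1, -1):
            raise ValidationError("polarity must be +1, -1 or 'pooled'")
        idx = np.flatnonzero(self.polarities == polarity)
        if idx.size == 0:
            raise ValidationError(f"no trains with polarity {polarity:+d}")
        return SpikeTrainSet([self.trains[i] for i in idx], self.polarities[idx],
                             self.duration, self.cf, self.spont_rate)


@dataclass
class PSTH(TimeSeries):
    """Peristimulus time histogram: binned spike counts as a TimeSeries.

    ``fs`` is always ``1/bin_width``. ``kind`` tags which member of the
    alternating-polarity family the signal is (p, n, s, d, e or phi) and
    ``unit`` is either ``"count-per-bin"`` or ``"rate"`` (spikes/s).
    """

    bin_width: float = 0.0
    n_reps: int = 1
    kind: str = "p"
    n_ops: int = 0  # increments performed while binning (instrumentation)

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if abs(self.fs * self.bin_width - 1.0) > 1e-9:
            raise ValidationError("PSTH requires fs == 1/bin_width")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")

    def as_rate(self) -> "PSTH":
        """Rate view (spikes/s): count / (n_reps * bin_width)."""
        if self.unit == "rate":
            return self
        out = dataclasses.replace(
            self, values=self.values / (self.n_reps * self.bin_width), unit="rate")
        return out


@dataclass
class FrequencyTrajectory:
    """An instantaneous-frequency contour f(t), sampled at ``fs``.

    Values must be strictly positive; Nyquist validity against the signal
    it will demodulate is checked at use time.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValidationError("empty frequency trajectory")
        if not np.all(self.values > 0):
            raise ValidationError("trajectory frequencies must be > 0")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    def scaled(self, k: float) -> "FrequencyTrajectory":
        return FrequencyTrajectory(self.values * k, self.fs)


@dataclass
class AnalyticSignal:
    """Complex analytic signal a(t) = x(t) + j*H{x(t)}."""

    values: np.ndarray
    fs: float
    source: str = ""

    @property
    def envelope(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class Correlogram:
    """Lag-indexed coincidence counts (SAC/SCC/sumcor/difcor).

    ``lags`` is a symmetric grid ``-L..L`` in seconds; ``normalization``
    is ``"raw-count"`` (integer coincidence counts) or ``"rate"``
    (Louage-style, chance level 1) or ``"rate-detrended"`` (triangular
    compensation subtracted, chance level 0).
    """

    lags: np.ndarray
    values: np.ndarray
    bin_width: float
    normalization: str = "raw-count"
    n_ops: int = 0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValidationError("lag and value grids must match")


@dataclass
class Spectrum:
    """One-sided power (or magnitude) spectrum on an ascending Hz grid."""

    freqs: np.ndarray
    values: np.ndarray
    method: str = "dft-magnitude"
    nw: Optional[float] = None
    k_tapers: Optional[int] = None
    adaptive: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise ValidationError("frequency and value grids must match")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("frequency grid must be strictly ascending")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else np.nan


@dataclass
class Harmonicgram:
    """Harmonic-number x time matrix of demodulated band-limited power."""

    harmonics: np.ndarray
    times: np.ndarray
    values: np.ndarray          # shape (len(harmonics), len(times)), power
    bandwidth: float            # LPF bandwidth W in Hz
    f0: FrequencyTrajectory
    valid: np.ndarray = field(default=None)  # per-row validity flags

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.harmonics.size, self.times.size):
            raise ValidationError("harmonicgram matrix shape mismatch")
        if self.valid is None:
            self.valid = np.ones(self.harmonics.size, dtype=bool)

    def row(self, k: int) -> np.ndarray:
        idx = np.flatnonzero(self.harmonics == k)
        if idx.size != 1:
            raise KeyError(f"harmonic {k} not present")
        return self.values[idx[0]]
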