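"""Frequency-demodulation spectrotemporal filtering and the harmonicgram.

To measure power along a known frequency trajectory f_traj(t) in a signal
x(t), the trajectory is integrated into a phase (cycles)

    Phi[n] = (1/fs) * sum_{m<=n} f_traj[m],

the signal is heterodyned by exp(-j 2 pi Phi[n]) so content along the
trajectory lands near 0 Hz, and a low-pass of bandwidth W (here a
zero-phase FFT brick-wall at +/- W/2) selects it. The power estimate is
doubled because only the original positive-frequency band of the real
signal sits near 0 Hz after demodulation; its negative-frequency image is
shifted far away. Spectral resolution is 1/duration, independent of any
sliding window — the advantage over spectrograms for chirps and formant
transitions.

The harmonicgram applies this along every harmonic k*F0(t) of a
time-varying fundamental, giving a harmonic-number x time power matrix —
a compact alternative to the spectrogram for voiced speech and music.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sg

from .types import (AlignmentError, FrequencyTrajectory, Harmonicgram,
                    TimeSeries, ValidationError)

__all__ = [
    "phase_trajectory",
    "demodulate",
    "brickwall_lowpass",
    "trajectory_power",
    "harmonicgram",
    "formant_harmonic_power",
    "estimate_latency",
    "resolution_fold_gain",
]


def phase_trajectory(f: FrequencyTrajectory) -> np.ndarray:
    """Integrated phase in cycles: Phi[n] = (1/fs) * cumsum(f)[n]."""
    return np.cumsum(f.values) / f.fs


def _check_traj(x: TimeSeries, f: FrequencyTrajectory) -> None:
    if x.n != f.n:
        raise AlignmentError(f"signal ({x.n}) and trajectory ({f.n}) lengths differ")
    if not np.isclose(x.fs, f.fs, rtol=1e-9):
        raise AlignmentError("signal and trajectory sampling rates differ")


def demodulate(x: TimeSeries, f: FrequencyTrajectory) -> np.ndarray:
    """Heterodyne x by the integrated trajectory phase: x * exp(-j2pi Phi).

    Pointwise unitary (|x_demod| = |x|); returns a complex array at x.fs.
    """
    _check_traj(x, f)
    phi = phase_trajectory(f)
    return x.values * np.exp(-2j * np.pi * phi)


def brickwall_lowpass(z: np.ndarray, fs: float, half_bw: float) -> np.ndarray:
    """Zero-phase FFT brick-wall low-pass keeping |f| <= half_bw (complex in/out)."""
    Z = np.fft.fft(z)
    freqs = np.fft.fftfreq(z.size, d=1.0 / fs)
    Z[np.abs(freqs) > half_bw] = 0.0
    return np.fft.ifft(Z)


def trajectory_power(x: TimeSeries, f: FrequencyTrajectory, w: float,
                     return_timeseries: bool = False):
    """Power along the trajectory f(t) within a bandwidth W.

    Scalar mode integrates the demodulated power spectrum over
    [-W/2, W/2] and doubles it (the negative-frequency image of the real
    signal is excluded by the demodulation); time-varying mode returns
    2*|LPF_{+/-W/2}(x_demod)|^2 sampled at x.fs. W must be at least the
    spectral resolution 1/duration and W/2 below Nyquist.
    """
    if w < 1.0 / x.duration - 1e-12:
        raise ValidationError(
            f"bandwidth W={w} Hz is below the spectral resolution "
            f"1/duration = {1.0 / x.duration:.6g} Hz")
    if w / 2.0 >= x.fs / 2.0:
        raise ValidationError("W/2 must be below Nyquist")
    z = demodulate(x, f)
    if return_timeseries:
        y = brickwall_lowpass(z, x.fs, w / 2.0)
        return x.copy_with(2.0 * np.abs(y) ** 2, unit="power")
    Z = np.fft.fft(z)
    freqs = np.fft.fftfreq(z.size, d=1.0 / x.fs)
    sel = np.abs(freqs) <= w / 2.0
    return float(2.0 * np.sum(np.abs(Z[sel]) ** 2) / z.size ** 2)


def harmonicgram(x: TimeSeries, f0: FrequencyTrajectory, ks,
                 w: float = 20.0) -> Harmonicgram:
    """Time-varying power along every requested harmonic k*F0(t).

    Each row k demodulates x with the integrated phase k*Phi_traj(t) and
    low-passes at +/- W/2. Rows whose trajectory exceeds Nyquist anywhere
    are flagged invalid (values NaN-free: filled with 0) rather than
    silently zeroed.
    """
    ks = np.asarray(sorted(int(k) for k in ks), dtype=int)
    if np.any(ks < 1):
        raise ValidationError("harmonic numbers must be positive integers")
    values = np.zeros((ks.size, x.n))
    valid = np.ones(ks.size, dtype=bool)
    fmax = float(np.max(f0.values))
    for i, k in enumerate(ks):
        if k * fmax >= x.fs / 2.0:
            valid[i] = False
            warnings.warn(f"harmonic {k} exceeds Nyquist; row flagged invalid")
            continue
        p = trajectory_power(x, f0.scaled(k), w, return_timeseries=True)
        values[i] = p.values
    return Harmonicgram(ks, x.times, values, w, f0, valid=valid)


def formant_harmonic_power(hg: Harmonicgram, formant: FrequencyTrajectory,
                           n_harmonics: int = 3) -> TimeSeries:
    """Summed harmonicgram power in the harmonics nearest a formant contour.

    At each time the F0-normalized formant frequency formant(t)/F0(t) is
    computed and the ``n_harmonics`` harmonic rows closest to it are
    summed. Exact half-integer ties are broken toward the even harmonic
    (round-half-to-even). Samples whose normalized formant falls outside
    the harmonic range are zeroed (and a warning issued).
    """
    if formant.n != hg.times.size:
        raise AlignmentError("formant contour length must match harmonicgram")
    ratio = formant.values / hg.f0.values
    ks = hg.harmonics.astype(float)
    # distance of each harmonic row to the normalized contour, with an
    # infinitesimal penalty on odd harmonics to realise half-to-even ties
    dist = np.abs(ks[:, None] - ratio[None, :])
    dist += (hg.harmonics[:, None] % 2) * 1e-9
    dist[~hg.valid, :] = np.inf
    order = np.argsort(dist, axis=0, kind="stable")[:n_harmonics]
    power = np.take_along_axis(hg.values, order, axis=0).sum(axis=0)
    out_of_range = (ratio < ks.min() - 0.5) | (ratio > ks.max() + 0.5)
    if out_of_range.any():
        warnings.warn("formant contour leaves the harmonic range; "
                      "those samples are masked (set to 0)")
        power[out_of_range] = 0.0
    return TimeSeries(power, hg.f0.fs, t0=float(hg.times[0]), unit="power")


def estimate_latency(stim: TimeSeries, resp: TimeSeries, max_lag: float) -> float:
    """Stimulus-to-response latency by peak normalized cross-correlation.

    Searches lags in [0, max_lag] seconds; used to shift stimulus
    trajectories before demodulating responses. Raises for flat inputs.
    """
    s = stim.values - np.mean(stim.values)
    r = resp.values - np.mean(resp.values)
    if np.all(s == 0) or np.all(r == 0):
        raise ValidationError("latency undefined for flat inputs")
    cc = sg.correlate(r, s, mode="full")
    lags = sg.correlation_lags(r.size, s.size, mode="full") / stim.fs
    sel = (lags >= 0) & (lags <= max_lag)
    if not sel.any():
        raise ValidationError("max_lag smaller than one sample")
    return float(lags[sel][np.argmax(cc[sel])])


def resolution_fold_gain(duration: float, window: float,
                         sweep_rate: float) -> float:
    """Spectral-resolution gain of demodulation over a windowed spectrogram.

    A spectrogram with a sliding window of length ``window`` resolves
    1/window Hz plus the within-window frequency sweep
    ``sweep_rate * window``; demodulation of the known trajectory resolves
    1/duration. Returns the ratio (fold improvement).
    """
    if duration <= 0 or window <= 0:
        raise ValidationError("duration and window must be positive")
    spectrogram_res = 1.0 / window + abs(sweep_rate) * window
    demod_res = 1.0 / duration
    return spectrogram_res / demod_res
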