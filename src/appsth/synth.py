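"""Stimulus synthesis and a phenomenological auditory-nerve spike simulator.

The simulator is deliberately minimal: a polarity flip, a band-pass
cochlear filter at CF, a saturating sigmoidal rectifier, a low-pass that
models the phase-locking roll-off, and inhomogeneous-Poisson spike
generation with absolute refractoriness. It is not a biophysical model;
it is the smallest chain that produces the phenomena the analyses in this
package quantify — phase locking with a high-frequency roll-off,
rectifier distortion at even carrier harmonics, and envelope following of
amplitude-modulated tones. All stochastic operations take explicit seeds.

Stimuli: SAM tones, the chirp-plus-tones test signal (two stationary
tones at 1.4 and 2 kHz plus a 400-to-800-Hz linear chirp over 2 s), and a
dynamic vowel whose fundamental rises linearly 100 to 120 Hz over 188 ms
while F1 falls 630 to 570 Hz and F2 rises 1200 to 1500 Hz (F3 fixed at
2500 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sg

from .types import FrequencyTrajectory, SpikeTrainSet, TimeSeries, ValidationError

__all__ = [
    "ANFiberParams",
    "cf_grid",
    "make_sam_tone",
    "make_chirp_plus_tones",
    "make_dynamic_vowel",
    "simulate_an_fiber",
    "simulate_both_polarities",
]


def cf_grid(n: int = 24, lo: float = 250.0, hi: float = 8000.0) -> np.ndarray:
    """Log-spaced characteristic-frequency grid (default 24 CFs, 250 Hz-8 kHz)."""
    return np.geomspace(lo, hi, n)


def make_sam_tone(fc: float, fm: float, depth: float, dur: float,
                  fs: float) -> TimeSeries:
    """Sinusoidally amplitude-modulated tone, peak-normalized to 1.

    x(t) = (1 + depth*cos(2 pi Fm t)) * cos(2 pi Fc t); at 100% depth the
    sidebands at Fc +/- Fm sit 6 dB below the carrier.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValidationError("modulation depth must be in [0, 1]")
    if fc + fm >= fs / 2.0:
        raise ValidationError("Fc + Fm must be below Nyquist")
    t = np.arange(round(dur * fs)) / fs
    x = (1.0 + depth * np.cos(2 * np.pi * fm * t)) * np.cos(2 * np.pi * fc * t)
    return TimeSeries(x / (1.0 + depth), fs, unit="pascal")


def make_chirp_plus_tones(dur: float = 2.0, tones: Sequence[float] = (1400.0, 2000.0),
                          chirp=(400.0, 800.0), fs: float = 8000.0):
    """Two stationary tones plus a linear chirp, all equal amplitude.

    Returns ``(TimeSeries, FrequencyTrajectory)`` where the trajectory is
    the true instantaneous frequency of the chirp (for demodulation).
    """
    if dur <= 0:
        raise ValidationError("duration must be positive")
    nyq = fs / 2.0
    if max(max(tones), max(chirp)) >= nyq:
        raise ValidationError("all components must lie below Nyquist")
    n = round(dur * fs)
    t = np.arange(n) / fs
    f0, f1 = chirp
    ftraj = f0 + (f1 - f0) * t / dur
    phase = np.cumsum(ftraj) / fs
    x = np.cos(2 * np.pi * phase)
    for ft in tones:
        x = x + np.cos(2 * np.pi * ft * t)
    return TimeSeries(x, fs, unit="pascal"), FrequencyTrajectory(ftraj, fs)


def make_dynamic_vowel(dur: float = 0.188, f0=(100.0, 120.0),
                       formants=((630.0, 570.0), (1200.0, 1500.0),
                                 (2500.0, 2500.0)),
                       formant_bandwidths=(90.0, 110.0, 170.0),
                       fs: float = 20000.0, max_harmonic_hz: float = None):
    """Harmonic-complex vowel with linearly moving F0 and formants.

    Each harmonic k follows the integrated phase k*Phi0(t) of the linear
    F0 contour; its time-varying amplitude is the sum of second-order
    resonance envelopes centered on the formant contours, evaluated at the
    harmonic's instantaneous frequency k*F0(t).

    Returns ``(TimeSeries, f0_traj, [formant_trajs...])``.
    """
    nyq = fs / 2.0
    if max(max(f) for f in formants) >= nyq:
        raise ValidationError("formants must lie below Nyquist")
    n = round(dur * fs)
    t = np.arange(n) / fs
    u = t / dur
    f0_t = f0[0] + (f0[1] - f0[0]) * u
    formant_trajs = [FrequencyTrajectory(flo + (fhi - flo) * u, fs)
                     for flo, fhi in formants]
    phase0 = np.cumsum(f0_t) / fs
    cap = min(nyq * 0.95, max_harmonic_hz or nyq * 0.95)
    kmax = int(cap / f0_t.max())
    x = np.zeros(n)
    for k in range(1, kmax + 1):
        fk = k * f0_t
        amp = np.zeros(n)
        for traj, bw in zip(formant_trajs, formant_bandwidths):
            amp += 1.0 / (1.0 + ((fk - traj.values) / (bw / 2.0)) ** 2)
        x += amp * np.cos(2 * np.pi * k * phase0)
    x /= np.max(np.abs(x))
    return TimeSeries(x, fs, unit="pascal"), FrequencyTrajectory(f0_t, fs), formant_trajs


@dataclass
class ANFiberParams:
    """Parameters of the phenomenological AN-fiber simulator.

    cf : characteristic frequency, Hz (must be below stim Nyquist)
    spont_rate : spontaneous rate, spikes/s
    max_rate : saturation of the instantaneous driven rate, spikes/s
    bandwidth : cochlear band-pass bandwidth, Hz (default: ERB-like
        0.108*cf + 24.7, floored at 150 Hz — tuning broadens at the
        moderate stimulus levels these analyses emulate)
    pl_cutoff : phase-locking low-pass corner, Hz (shallow 2nd-order
        magnitude roll-off, so carrier locking declines gradually with
        frequency rather than vanishing abruptly)
    sat_slope : steepness of the sigmoidal transduction
    refractory : absolute refractory period, s
    """

    cf: float
    spont_rate: float = 50.0
    max_rate: float = 1000.0
    bandwidth: Optional[float] = None
    pl_cutoff: float = 3000.0
    sat_slope: float = 8.0
    refractory: float = 0.75e-3

    def __post_init__(self) -> None:
        if self.cf <= 0 or self.spont_rate < 0 or self.max_rate < 0:
            raise ValidationError("cf must be positive and rates nonnegative")
        if self.refractory < 0:
            raise ValidationError("refractory period must be nonnegative")
        if self.bandwidth is None:
            self.bandwidth = max(0.108 * self.cf + 24.7, 150.0)


def _driven_rate(stim: TimeSeries, params: ANFiberParams,
                 polarity: int) -> np.ndarray:
    """Deterministic instantaneous rate (spikes/s) for one polarity."""
    if stim.fs < 4.0 * params.cf:
        raise ValidationError("stimulus fs must be at least 4x the fiber CF")
    x = polarity * stim.values
    lo = max(params.cf - params.bandwidth / 2.0, 1.0)
    hi = min(params.cf + params.bandwidth / 2.0, stim.fs / 2.0 * 0.999)
    sos = sg.butter(2, (lo, hi), btype="bandpass", fs=stim.fs, output="sos")
    v = sg.sosfiltfilt(sos, x)
    drive = 1.0 / (1.0 + np.exp(-params.sat_slope * v)) - 0.5
    rate = np.maximum(params.max_rate * drive, 0.0)
    if params.pl_cutoff < stim.fs / 2.0:
        # first-order sections run forward-backward: zero-phase with an
        # effective 2nd-order magnitude roll-off (gradual, physiological)
        sos_lp = sg.butter(1, params.pl_cutoff, btype="lowpass",
                           fs=stim.fs, output="sos")
        rate = sg.sosfiltfilt(sos_lp, rate)
    rate = np.maximum(rate, 0.0) + params.spont_rate
    assert np.all(rate >= 0.0)
    return rate


def _poisson_with_refractory(rate: np.ndarray, fs: float, refractory: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Bernoulli sampling of an inhomogeneous Poisson process with dead time."""
    p = np.clip(rate / fs, 0.0, 1.0)
    cand = np.flatnonzero(rng.random(p.size) < p)
    if refractory <= 0 or cand.size == 0:
        return cand / fs
    dead = int(np.ceil(refractory * fs))
    keep = []
    last = -dead - 1
    for idx in cand:
        if idx - last > dead:
            keep.append(idx)
            last = idx
    return np.asarray(keep, dtype=float) / fs


def simulate_an_fiber(stim: TimeSeries, params: ANFiberParams, n_reps: int,
                      polarity: int = 1, seed: int = 0) -> SpikeTrainSet:
    """Simulate ``n_reps`` spike trains for one stimulus polarity.

    The per-repetition pipeline is: polarity flip -> band-pass at CF ->
    saturating rectifier -> phase-locking low-pass -> inhomogeneous
    Poisson sampling with absolute refractoriness. Identical seeds give
    bitwise-identical spike sets.
    """
    if polarity not in (1, -1):
        raise ValidationError("polarity must be +1 or -1")
    rate = _driven_rate(stim, params, polarity)
    rng = np.random.default_rng(seed)
    trains = [_poisson_with_refractory(rate, stim.fs, params.refractory, rng)
              for _ in range(n_reps)]
    return SpikeTrainSet(trains, [polarity] * n_reps, stim.duration,
                         cf=params.cf, spont_rate=params.spont_rate)


def simulate_both_polarities(stim: TimeSeries, params: ANFiberParams,
                             n_reps_per_polarity: int,
                             seed: int = 0) -> SpikeTrainSet:
    """Both-polarity spike set (positive trains first, then negative)."""
    pos = simulate_an_fiber(stim, params, n_reps_per_polarity, 1, seed)
    neg = simulate_an_fiber(stim, params, n_reps_per_polarity, -1, seed + 1)
    return SpikeTrainSet(pos.trains + neg.trains,
                         np.concatenate([pos.polarities, neg.polarities]),
                         stim.duration, cf=params.cf,
                         spont_rate=params.spont_rate)
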