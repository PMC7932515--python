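"""Canned study-condition experiments built from the library primitives.

Each function wires together the synthesizer, the PSTH decomposition and
one analysis into a complete, seeded numerical experiment:

* :func:`complexity_counts` — operation counts for brute-force correlogram
  tallying versus PSTH construction on a 50-repetition, 100-spikes-per-
  repetition dataset.
* :func:`chirp_resolution_gain` — spectral-resolution fold improvement of
  trajectory demodulation over a 50-ms sliding-window spectrogram for the
  2-s chirp-plus-tones signal.
* :func:`formant_crossing_time` — time at which F1(t)/F0(t) of the dynamic
  vowel crosses a target harmonic number.
* :func:`variance_ratio_experiment` — variance of the untapered
  difcor-spectrum fractional-power estimate relative to the two-taper
  multitaper d(t)-spectrum estimate at the 6th F0 harmonic.
* :func:`sam_grid_metrics` — envelope/TFS metrics for SAM-tone responses
  across a 24-CF log-spaced fiber grid.
* :func:`dynamic_vowel_harmonicgram` — harmonicgram of the pooled
  Hilbert-phase PSTH of low-CF fibers responding to the dynamic vowel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .correlograms import sac_tally, sumcor_difcor
from .decompose import decompose, diff_component
from .demod import harmonicgram, resolution_fold_gain
from .psth import build_psth
from .spectral import (band_power, carrier_sideband_ratio, correlogram_spectrum,
                       dft_spectrum, fractional_power_at, multitaper_psd,
                       rectifier_distortion_power)
from .synth import (ANFiberParams, cf_grid, make_chirp_plus_tones,
                    make_dynamic_vowel, make_sam_tone, simulate_both_polarities)
from .types import SpikeTrainSet, TimeSeries


def fixed_count_trains(n_trains: int, spikes_per_train: int, duration: float,
                       seed: int = 0) -> SpikeTrainSet:
    """Uniform random spike trains with an exact per-train spike count."""
    rng = np.random.default_rng(seed)
    trains = [np.sort(rng.uniform(0, duration, spikes_per_train))
              for _ in range(n_trains)]
    return SpikeTrainSet(trains, [1] * n_trains, duration)


def complexity_counts(n_trains: int = 50, spikes_per_train: int = 100,
                      duration: float = 1.0, bin_width: float = 5e-4,
                      seed: int = 0):
    """Measured operation counts: interval tallying vs PSTH construction.

    Returns ``(tally_ops, psth_ops)`` from the instrumented counters; for
    50 x 100 spikes these are 5000*4900 = 24.5e6 and 5000.
    """
    spikes = fixed_count_trains(n_trains, spikes_per_train, duration, seed)
    sac = sac_tally(spikes, bin_width, max_lag=25e-3)
    psth = build_psth(spikes, "pooled", bin_width)
    return sac.n_ops, psth.n_ops


def chirp_resolution_gain(dur: float = 2.0, window: float = 0.05,
                          chirp=(400.0, 800.0)) -> float:
    """Fold improvement in spectral resolution for the chirp test signal.

    The sliding-window spectrogram resolves 1/window plus the within-window
    chirp sweep; demodulating the known trajectory resolves 1/duration.
    """
    sweep_rate = (chirp[1] - chirp[0]) / dur
    return resolution_fold_gain(dur, window, sweep_rate)


def formant_crossing_time(target_ratio: float = 5.5, dur: float = 0.188,
                          fs: float = 20000.0) -> float:
    """Time (s) at which F1(t)/F0(t) of the dynamic vowel crosses a ratio.

    Solved numerically on the synthesized linear contours (F0 100->120 Hz,
    F1 630->570 Hz over 188 ms).
    """
    _, f0t, formant_trajs = make_dynamic_vowel(dur=dur, fs=fs)
    f1 = formant_trajs[0]
    t = np.arange(f0t.n) / fs

    def ratio_minus_target(tt):
        return (np.interp(tt, t, f1.values) / np.interp(tt, t, f0t.values)
                - target_ratio)

    return float(brentq(ratio_minus_target, t[0], t[-1]))


def variance_ratio_experiment(seed: int = 1, n_draws: int = 12,
                              reps_per_polarity: int = 25, cf: float = 900.0,
                              f0: float = 98.0, dur: float = 0.1,
                              fs: float = 10000.0, bin_width: float = 1e-4,
                              harmonic: int = 6) -> float:
    """Variance of correlogram- vs multitaper-PSTH-based fractional power.

    A fiber at ``cf`` responds to a stationary harmonic complex
    (fundamental ``f0``, formants at 630/1200/2500 Hz). For each of
    ``n_draws`` independent draws of ``reps_per_polarity`` repetitions per
    polarity, fractional power at the ``harmonic``-th F0 harmonic is
    estimated from (a) the DFT of the untapered difcor and (b) the NW=3,
    K=2 adaptive multitaper spectrum of d(t). Returns var(a)/var(b); > 1
    means the multitaper PSTH spectrum is the more precise estimator.
    """
    stim, _, _ = make_dynamic_vowel(
        dur=dur, f0=(f0, f0),
        formants=((630.0, 630.0), (1200.0, 1200.0), (2500.0, 2500.0)), fs=fs)
    params = ANFiberParams(cf=cf)
    target = harmonic * f0
    frac_difcor, frac_mtm = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n_draws):
        s = int(rng.integers(0, 2 ** 31 - 2))
        sts = simulate_both_polarities(stim, params, reps_per_polarity, seed=s)
        p = build_psth(sts, 1, bin_width)
        n = build_psth(sts, -1, bin_width)
        d = diff_component(p, n)
        _, difcor = sumcor_difcor(sts.select(1), sts.select(-1), bin_width)
        frac_difcor.append(fractional_power_at(correlogram_spectrum(difcor),
                                               target))
        frac_mtm.append(fractional_power_at(
            multitaper_psd(d, 3.0, 2, adaptive=True), target))
    return float(np.var(frac_difcor, ddof=1) / np.var(frac_mtm, ddof=1))


@dataclass
class FiberMetrics:
    """Envelope/TFS metrics for one simulated fiber on the SAM grid."""

    cf: float
    s_fm_power: float          # modulation-band power of S(f)
    e_fm_power: float          # modulation-band power of E(f)
    rd_s: float                # rectifier-distortion power in S(f)
    rd_e: float                # rectifier-distortion power in E(f)
    csr_d: tuple               # (carrier/LSB, carrier/USB) of D(f)
    csr_phi: tuple             # same for Phi(f)


def sam_grid_metrics(n_cfs: int = 24, fm: float = 20.0, depth: float = 1.0,
                     dur: float = 1.0, fs: float = 40000.0,
                     reps_per_polarity: int = 75, bin_width: float = 25e-6,
                     band_halfwidth: float = 100.0, seed: int = 0):
    """SAM-tone-at-CF responses across the log-spaced CF grid.

    For each fiber: simulate both polarities, decompose into s/d/e/phi
    (d band-limited to 200 Hz around CF), and measure modulation-band
    power (10-Hz bands at Fm, 2Fm, 3Fm), rectifier-distortion power near
    2*CF, and carrier-to-sideband ratios of D(f) and Phi(f).
    """
    bands = [(k * fm - 5.0, k * fm + 5.0) for k in (1, 2, 3)]
    out = []
    for i, cf in enumerate(cf_grid(n_cfs)):
        stim = make_sam_tone(cf, fm, depth, dur, fs)
        sts = simulate_both_polarities(stim, ANFiberParams(cf=cf),
                                       reps_per_polarity, seed=seed + i)
        p = build_psth(sts, 1, bin_width)
        n = build_psth(sts, -1, bin_width)
        parts = decompose(p, n, band=(max(cf - band_halfwidth, 1.0),
                                      cf + band_halfwidth))
        S = dft_spectrum(parts["s"], "power")
        E = dft_spectrum(parts["e"], "power")
        D = dft_spectrum(parts["d_band"], "power")
        PHI = dft_spectrum(parts["phi"], "power")
        rd_ok = 2 * cf + fm < fs / 2
        out.append(FiberMetrics(
            cf=float(cf),
            s_fm_power=band_power(S, bands),
            e_fm_power=band_power(E, bands),
            rd_s=rectifier_distortion_power(S, cf, fm) if rd_ok else np.nan,
            rd_e=rectifier_distortion_power(E, cf, fm) if rd_ok else np.nan,
            csr_d=carrier_sideband_ratio(D, cf, fm),
            csr_phi=carrier_sideband_ratio(PHI, cf, fm),
        ))
    return out


def dynamic_vowel_harmonicgram(fs: float = 20000.0, reps_per_polarity: int = 25,
                               max_cf: float = 1000.0, kmax: int = 12,
                               bandwidth: float = 20.0, seed: int = 0):
    """Harmonicgram of the pooled low-CF Hilbert-phase response to the vowel.

    Fibers with CF below ``max_cf`` (from the standard grid) are simulated
    to the dynamic vowel; their phi(t) PSTHs are averaged and the
    harmonicgram computed along the true F0 contour. Returns
    ``(Harmonicgram, dominant_harmonic_per_sample)``.
    """
    stim, f0t, _ = make_dynamic_vowel(fs=fs)
    cfs = [cf for cf in cf_grid() if cf < max_cf]
    phis = []
    for i, cf in enumerate(cfs):
        sts = simulate_both_polarities(stim, ANFiberParams(cf=cf),
                                       reps_per_polarity, seed=seed + i)
        p = build_psth(sts, 1, 1.0 / fs)
        n = build_psth(sts, -1, 1.0 / fs)
        parts = decompose(p, n, band=(max(cf - 100.0, 1.0), cf + 100.0))
        phis.append(parts["phi"].values)
    phi_avg = TimeSeries(np.mean(phis, axis=0), fs)
    hg = harmonicgram(phi_avg, f0t, range(1, kmax + 1), bandwidth)
    dominant = hg.harmonics[np.argmax(hg.values, axis=0)]
    return hg, dominant
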