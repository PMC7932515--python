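"""Shuffled correlograms and phase-locking metrics.

The shuffled autocorrelogram (SAC) tallies all between-train interspike
intervals; the shuffled cross-correlogram (SCC) tallies intervals between
two spike-train sets. Both are classically O(N^2) in spike count. Because
the all-pair tally factorises through the binned PSTH, they can instead be
computed from PSTH auto/cross-correlations:

    SAC(X) = R(PSTH_X) - sum_i R(x_i)        (within-train pairs removed)
    SCC(X, Y) = R_xy(PSTH_X, PSTH_Y)

which is O(N) plus a fixed-cost correlation. ``sac_fast``/``scc_fast`` use
this identity; ``sac_tally``/``scc_tally`` are the brute-force oracles.
Both carry instrumented operation counters (``n_ops``): one tally operation
compares two spike times and increments a lag bin; one PSTH operation
increments a time bin.

Lag convention: a pair (t_a from the reference train, t_b from the other)
contributes at lag bin ``floor(t_b/bw) - floor(t_a/bw)``; tallying the
bin-index difference (rather than re-binning the raw time difference) is
what makes the PSTH identity integer-exact.

sumcor/difcor combine same- and cross-polarity correlograms into
polarity-tolerant (ENV) and polarity-sensitive (TFS) parts, with the
Louage-style rate normalization (chance level 1) and a triangular
compensation so a coding-free correlogram is flat at 0.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sg

from .psth import bin_indices, build_psth, n_bins_for
from .types import Correlogram, Spectrum, SpikeTrainSet, ValidationError

__all__ = [
    "sac_tally",
    "sac_fast",
    "scc_tally",
    "scc_fast",
    "normalize_correlogram",
    "detrend_correlogram",
    "sumcor_difcor",
    "sumcor_peak_height",
    "vector_strength",
    "vs_from_spectrum",
    "DEFAULT_BIN_WIDTH",
    "default_max_lag",
]

DEFAULT_BIN_WIDTH = 50e-6  # s


def default_max_lag(duration: float) -> float:
    return min(duration / 2.0, 25e-3)


def _lag_grid(bin_width: float, max_lag: float):
    L = int(round(max_lag / bin_width))
    if L < 1:
        raise ValidationError("max_lag must cover at least one lag bin")
    return L, np.arange(-L, L + 1) * bin_width


def _within_train_autocorr(btrains, L: int) -> np.ndarray:
    """Sum over trains of the ordered within-train pair tally per lag bin."""
    acc = np.zeros(2 * L + 1, dtype=np.int64)
    for b in btrains:
        if b.size == 0:
            continue
        d = b[None, :] - b[:, None]
        d = d[np.abs(d) <= L]
        acc += np.bincount(d + L, minlength=2 * L + 1)
    return acc


def sac_tally(spikes: SpikeTrainSet, bin_width: float = DEFAULT_BIN_WIDTH,
              max_lag: float = None) -> Correlogram:
    """Brute-force SAC: tally every between-train spike-pair interval.

    Every ordered pair of spikes from distinct trains is compared; pairs
    whose bin-index difference falls within ±max_lag increment that lag
    bin. ``n_ops`` counts all comparisons (n_i * n_j per train pair).
    """
    if spikes.n_trains < 2:
        raise ValidationError("SAC requires at least 2 trains")
    if max_lag is None:
        max_lag = default_max_lag(spikes.duration)
    L, lags = _lag_grid(bin_width, max_lag)
    counts = np.zeros(2 * L + 1, dtype=np.int64)
    btrains = [bin_indices(t, bin_width) for t in spikes.trains]
    n_ops = 0
    for i, bi in enumerate(btrains):
        for j, bj in enumerate(btrains):
            if i == j or bi.size == 0 or bj.size == 0:
                continue
            n_ops += bi.size * bj.size
            d = bj[None, :] - bi[:, None]
            d = d[np.abs(d) <= L]
            counts += np.bincount(d + L, minlength=2 * L + 1)
    return Correlogram(lags, counts, bin_width, "raw-count", n_ops=n_ops)


def sac_fast(spikes: SpikeTrainSet, bin_width: float = DEFAULT_BIN_WIDTH,
             max_lag: float = None) -> Correlogram:
    """SAC via the PSTH identity R(PSTH) - sum_i R(x_i); integer-exact.

    ``n_ops`` is the number of PSTH binning increments (= spike count);
    the correlation itself is fixed-cost in the spike count.
    """
    if spikes.n_trains < 2:
        raise ValidationError("SAC requires at least 2 trains")
    if max_lag is None:
        max_lag = default_max_lag(spikes.duration)
    L, lags = _lag_grid(bin_width, max_lag)
    psth = build_psth(spikes, "pooled", bin_width)
    r_full = sg.fftconvolve(psth.values, psth.values[::-1])
    center = psth.n - 1
    r = np.rint(r_full[center - L:center + L + 1]).astype(np.int64)
    btrains = [bin_indices(t, bin_width) for t in spikes.trains]
    r -= _within_train_autocorr(btrains, L)
    return Correlogram(lags, r, bin_width, "raw-count", n_ops=psth.n_ops)


def _check_pair(X: SpikeTrainSet, Y: SpikeTrainSet) -> None:
    if abs(X.duration - Y.duration) > 1e-12:
        raise ValidationError("SCC requires equal durations")


def scc_tally(X: SpikeTrainSet, Y: SpikeTrainSet,
              bin_width: float = DEFAULT_BIN_WIDTH,
              max_lag: float = None) -> Correlogram:
    """Brute-force SCC over all X-spike vs Y-spike pairs (oracle)."""
    _check_pair(X, Y)
    if max_lag is None:
        max_lag = default_max_lag(X.duration)
    L, lags = _lag_grid(bin_width, max_lag)
    counts = np.zeros(2 * L + 1, dtype=np.int64)
    n_ops = 0
    by_all = [bin_indices(t, bin_width) for t in Y.trains]
    for tx in X.trains:
        bx = bin_indices(tx, bin_width)
        for by in by_all:
            if bx.size == 0 or by.size == 0:
                continue
            n_ops += bx.size * by.size
            d = by[None, :] - bx[:, None]
            d = d[np.abs(d) <= L]
            counts += np.bincount(d + L, minlength=2 * L + 1)
    return Correlogram(lags, counts, bin_width, "raw-count", n_ops=n_ops)


def scc_fast(X: SpikeTrainSet, Y: SpikeTrainSet,
             bin_width: float = DEFAULT_BIN_WIDTH,
             max_lag: float = None) -> Correlogram:
    """SCC as the cross-correlation of the two count PSTHs (integer-exact)."""
    _check_pair(X, Y)
    if not X.n_trains or not Y.n_trains:
        raise ValidationError("SCC requires nonempty spike-train sets")
    if max_lag is None:
        max_lag = default_max_lag(X.duration)
    L, lags = _lag_grid(bin_width, max_lag)
    px = build_psth(X, "pooled", bin_width)
    py = build_psth(Y, "pooled", bin_width)
    r_full = sg.fftconvolve(py.values, px.values[::-1])
    center = px.n - 1
    r = np.rint(r_full[center - L:center + L + 1]).astype(np.int64)
    return Correlogram(lags, r, bin_width, "raw-count", n_ops=px.n_ops + py.n_ops)


def normalize_correlogram(c: Correlogram, n_trains, total_spikes, duration: float,
                          kind: str = "sac", n_trains_y=None,
                          total_spikes_y=None) -> Correlogram:
    """Louage-style rate normalization so the chance level is 1.

    SAC: divide by M(M-1) r^2 dt D with r the grand mean rate; SCC: divide
    by L M r_x r_y dt D.
    """
    dt, D = c.bin_width, duration
    if kind == "sac":
        M = n_trains
        r = total_spikes / (M * D)
        denom = M * (M - 1) * r * r * dt * D
    elif kind == "scc":
        rx = total_spikes / (n_trains * D)
        ry = total_spikes_y / (n_trains_y * D)
        denom = n_trains * n_trains_y * rx * ry * dt * D
    else:
        raise ValidationError(f"unknown correlogram kind {kind!r}")
    if denom == 0:
        raise ValidationError("cannot normalize a correlogram with no spikes")
    return Correlogram(c.lags, c.values / denom, c.bin_width, "rate", n_ops=c.n_ops)


def detrend_correlogram(c: Correlogram, duration: float) -> Correlogram:
    """Subtract the finite-duration triangle so chance level becomes 0."""
    tri = np.clip(1.0 - np.abs(c.lags) / duration, 0.0, None)
    return Correlogram(c.lags, c.values - tri, c.bin_width, "rate-detrended",
                       n_ops=c.n_ops)


def sumcor_difcor(X_pos: SpikeTrainSet, X_neg: SpikeTrainSet,
                  bin_width: float = DEFAULT_BIN_WIDTH, max_lag: float = None,
                  normalization: str = "rate-detrended"):
    """Polarity-tolerant (sumcor) and polarity-sensitive (difcor) correlograms.

    sumcor = (mean same-polarity SAC + cross-polarity SCC) / 2,
    difcor = mean same-polarity SAC - cross-polarity SCC, computed from
    rate-normalized correlograms. With ``normalization="rate-detrended"``
    the sumcor additionally has the finite-duration triangle subtracted so
    its chance level is 0 (difcor is chance-0 by construction).
    """
    if X_pos.n_trains < 2 or X_neg.n_trains < 2:
        raise ValidationError("both polarities need >= 2 trains")
    D = X_pos.duration
    if max_lag is None:
        max_lag = default_max_lag(D)
    sp = normalize_correlogram(sac_fast(X_pos, bin_width, max_lag),
                               X_pos.n_trains, X_pos.n_spikes, D)
    sn = normalize_correlogram(sac_fast(X_neg, bin_width, max_lag),
                               X_neg.n_trains, X_neg.n_spikes, D)
    xpx = normalize_correlogram(
        scc_fast(X_pos, X_neg, bin_width, max_lag),
        X_pos.n_trains, X_pos.n_spikes, D, kind="scc",
        n_trains_y=X_neg.n_trains, total_spikes_y=X_neg.n_spikes)
    sac_avg = (sp.values + sn.values) / 2.0
    sumcor = Correlogram(sp.lags, (sac_avg + xpx.values) / 2.0, bin_width, "rate")
    difcor = Correlogram(sp.lags, sac_avg - xpx.values, bin_width, "rate-detrended")
    if normalization == "rate-detrended":
        sumcor = detrend_correlogram(sumcor, D)
    elif normalization != "rate":
        raise ValidationError(f"unknown normalization {normalization!r}")
    return sumcor, difcor


def sumcor_peak_height(sumcor: Correlogram, mode: str = "raw",
                       bands=None) -> float:
    """Peak height of a chance-0 (compensated) sumcor.

    ``mode="raw"`` is the broadband maximum; ``mode="adjusted"`` first
    zeroes spectral content outside ``bands`` (list of (lo, hi) Hz,
    brick-wall in the DFT domain) so the peak reflects only the
    modulation-related bands.
    """
    v = np.asarray(sumcor.values, float)
    if mode == "raw":
        return float(np.max(v))
    if mode != "adjusted":
        raise ValidationError(f"unknown mode {mode!r}")
    if not bands:
        raise ValidationError("adjusted mode requires a nonempty band list")
    spec = np.fft.rfft(v)
    freqs = np.fft.rfftfreq(v.size, d=sumcor.bin_width)
    keep = np.zeros(freqs.size, dtype=bool)
    for lo, hi in bands:
        keep |= (freqs >= lo) & (freqs < hi)
    spec[~keep] = 0.0
    return float(np.max(np.fft.irfft(spec, n=v.size)))


def vector_strength(times, f: float) -> float:
    """Classic vector strength |sum_k exp(-j 2 pi f t_k)| / N, in [0, 1]."""
    t = np.asarray(times, float).ravel()
    if t.size == 0:
        raise ValidationError("vector strength undefined for zero spikes")
    return float(np.abs(np.sum(np.exp(-2j * np.pi * f * t))) / t.size)


def vs_from_spectrum(d_spectrum: Spectrum, n_spikes: int,
                     halved: bool = True) -> Spectrum:
    """Vector-strength curve VS(f) from the difference-PSTH magnitude spectrum.

    ``d_spectrum`` must be the plain-sum (unnormalized) DFT magnitude of
    the count-unit difference PSTH and ``n_spikes`` the total spike count
    over both polarities. ``halved=True`` declares that the difference
    PSTH was formed as (p - n)/2 (the Eq-convention here); the factor 2
    then restores the compound-PSTH scale at which VS(f) agrees with the
    direct vector-strength estimate on polarity-flipped pooled spikes.
    """
    if n_spikes <= 0:
        raise ValidationError("VS undefined for zero spikes")
    scale = (2.0 if halved else 1.0) / n_spikes
    vs = d_spectrum.values * scale
    return Spectrum(d_spectrum.freqs, vs, method="vs")
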