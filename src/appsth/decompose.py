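"""The alternating-polarity PSTH taxonomy.

From the pair of single-polarity responses p(t) and n(t) — PSTHs or
evoked-potential averages — this module derives:

* the sum component ``s(t) = (p + n) / 2``, the polarity-tolerant
  (envelope, ENV) response;
* the difference component ``d(t) = (p - n) / 2``, the polarity-sensitive
  (temporal-fine-structure, TFS) response, in which even-order rectifier
  distortions cancel;
* the analytic signal ``a(t) = d(t) + j H{d(t)}``;
* the Hilbert envelope ``e(t) = |a(t)| / sqrt(2)``;
* the Hilbert phase ``phi(t) = sqrt(2) * rms(d) * cos(angle(a))``, a
  constant-envelope TFS signal with the same rms as d(t).

These obey the exact identities p = s + d, n = s - d and
d = e * phi / rms(d).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sg

from .types import AnalyticSignal, TimeSeries, ValidationError, _check_aligned

__all__ = [
    "sum_component",
    "diff_component",
    "bandlimit",
    "analytic",
    "hilbert_envelope",
    "hilbert_phase",
    "decompose",
]


def sum_component(p: TimeSeries, n: TimeSeries) -> TimeSeries:
    """Polarity-tolerant component s = (p + n) / 2 (ENV)."""
    _check_aligned(p, n)
    return p.copy_with((p.values + n.values) / 2.0)


def diff_component(p: TimeSeries, n: TimeSeries, halve: bool = True) -> TimeSeries:
    """Polarity-sensitive component d = (p - n) / 2 (TFS).

    ``halve=False`` gives the plain subtraction convention sometimes used
    for difference FFRs.
    """
    _check_aligned(p, n)
    d = p.values - n.values
    return p.copy_with(d / 2.0 if halve else d)


def bandlimit(x: TimeSeries, f_lo: float, f_hi: float, order: int = 2,
              zero_phase: bool = True) -> TimeSeries:
    """Butterworth band-pass (low-pass when ``f_lo == 0``) copy of ``x``.

    Default is the 2nd-order, zero-phase configuration used to isolate a
    200-Hz band around CF before Hilbert analysis. Zero-phase applies the
    filter forward and backward (doubling the effective magnitude order).
    """
    nyq = x.fs / 2.0
    if not (0 <= f_lo < f_hi < nyq):
        raise ValidationError(
            f"band ({f_lo}, {f_hi}) Hz invalid for Nyquist {nyq} Hz")
    if f_lo == 0:
        sos = sg.butter(order, f_hi, btype="lowpass", fs=x.fs, output="sos")
    else:
        sos = sg.butter(order, (f_lo, f_hi), btype="bandpass", fs=x.fs, output="sos")
    y = sg.sosfiltfilt(sos, x.values) if zero_phase else sg.sosfilt(sos, x.values)
    return x.copy_with(y)


def analytic(x: TimeSeries) -> AnalyticSignal:
    """Analytic signal via the frequency-domain Hilbert transform.

    The real part equals the input exactly. A DC-only input produces a
    warning (phase undefined), not an error.
    """
    if np.allclose(x.values, x.values[0]):
        warnings.warn("constant (DC-only) signal: analytic phase is undefined")
    return AnalyticSignal(sg.hilbert(x.values), x.fs, source=x.unit)


def hilbert_envelope(d: TimeSeries) -> TimeSeries:
    """Hilbert-envelope component e(t) = |a(t)| / sqrt(2).

    The 1/sqrt(2) normalizes for the power doubling of the analytic signal,
    so a unit-amplitude carrier has envelope 1/sqrt(2) (rms-matched).
    ``d`` should normally be band-limited near CF first (see bandlimit).
    """
    a = analytic(d)
    return d.copy_with(a.envelope / np.sqrt(2.0))


def hilbert_phase(d: TimeSeries) -> TimeSeries:
    """Hilbert-phase component phi(t) = sqrt(2) * rms(d) * cos(angle a(t)).

    cos(angle a) is a constant-envelope signal of rms ~ 1/sqrt(2); scaling
    by sqrt(2)*rms(d) matches the power of phi(t) to that of d(t). Raises
    for an all-zero input (phase undefined, rms 0).
    """
    r = d.rms()
    if r == 0:
        raise ValidationError("hilbert_phase undefined for an all-zero signal")
    a = analytic(d)
    return d.copy_with(np.sqrt(2.0) * r * np.cos(a.phase))


def decompose(p: TimeSeries, n: TimeSeries, band=None, order: int = 2):
    """All taxonomy members at once.

    Parameters
    ----------
    p, n : TimeSeries
        Single-polarity responses (count-unit PSTHs or waveform averages).
    band : (f_lo, f_hi), optional
        Band to isolate in d(t) before Hilbert analysis, e.g. a 200-Hz
        band around CF. When omitted, e/phi are computed from raw d.

    Returns
    -------
    dict with keys ``"s", "d", "e", "phi"`` (and ``"d_band"`` when a band
    is given).
    """
    s = sum_component(p, n)
    d = diff_component(p, n)
    db = bandlimit(d, band[0], band[1], order=order) if band is not None else d
    out = {"s": s, "d": d, "e": hilbert_envelope(db), "phi": hilbert_phase(db)}
    if band is not None:
        out["d_band"] = db
    return out
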