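"""Modulation filterbank front-end.

Rectified PSTHs (p or n) can be passed through a bank of octave-wide
modulation filters to obtain "internal representations" of the kind used
by envelope-based speech-intelligibility models. Filters are Butterworth
band-passes with edges Fm/sqrt(2)..Fm*sqrt(2), applied zero-phase; the
default design uses 2nd-order sections run forward and backward so the
effective magnitude response is 4th-order ("zero-phase, fourth-order").
Default centers: 2, 4, 8, 16, 32, 64, 128 Hz (octave spacing).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sg

from .types import TimeSeries, ValidationError

__all__ = ["DEFAULT_CENTERS", "modulation_filterbank"]

DEFAULT_CENTERS = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


def modulation_filterbank(x: TimeSeries, centers=DEFAULT_CENTERS,
                          order: int = 4, zero_phase: bool = True,
                          order_counts_passes: bool = True):
    """Filter ``x`` through the octave-wide modulation filterbank.

    Parameters
    ----------
    x : TimeSeries
        Typically a rectified PSTH; any waveform is accepted.
    centers : sequence of float
        Band centers Fm in Hz; each band spans Fm/sqrt(2) .. Fm*sqrt(2).
    order : int
        Effective magnitude order of each band filter.
    zero_phase : bool
        Forward-backward filtering (no group delay).
    order_counts_passes : bool
        When true (default) the forward-backward doubling counts toward
        ``order`` (design order//2 per pass); when false each pass is a
        full ``order`` filter.

    Returns
    -------
    list of (center_hz, TimeSeries)
    """
    nyq = x.fs / 2.0
    out = []
    for fm in centers:
        lo, hi = fm / np.sqrt(2.0), fm * np.sqrt(2.0)
        if hi >= nyq:
            raise ValidationError(
                f"band center {fm} Hz too high for fs {x.fs} Hz")
        design_order = order // 2 if (zero_phase and order_counts_passes) else order
        design_order = max(design_order, 1)
        sos = sg.butter(design_order, (lo, hi), btype="bandpass",
                        fs=x.fs, output="sos")
        y = sg.sosfiltfilt(sos, x.values) if zero_phase else sg.sosfilt(sos, x.values)
        out.append((fm, x.copy_with(y)))
    return out
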