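"""PSTH construction from spike-train sets.

Bins are half-open ``[k*bw, (k+1)*bw)``, zero-based from stimulus onset.
The canonical unit is count-per-bin (required for the exact correlogram
identities); the rate view ``count / (n_reps * bin_width)`` is derived.
"""

from __future__ import annotations

import numpy as np

from .types import PSTH, SpikeTrainSet, ValidationError

__all__ = ["build_psth", "n_bins_for"]


def n_bins_for(duration: float, bin_width: float) -> int:
    """Number of bins; duration must be a whole number of bins."""
    nb = duration / bin_width
    nb_round = round(nb)
    if nb_round < 1 or abs(nb - nb_round) > 1e-6 * max(1.0, nb):
        raise ValidationError(
            f"duration {duration} s is not an integer multiple of "
            f"bin_width {bin_width} s (a trailing partial bin is an error)")
    return int(nb_round)


def bin_indices(times: np.ndarray, bin_width: float) -> np.ndarray:
    """Half-open bin index of each spike time (boundary spike opens rightward)."""
    # guard against float jitter placing t = k*bw into bin k-1
    return np.floor(times / bin_width + 1e-9).astype(np.int64)


def build_psth(spikes: SpikeTrainSet, polarity="pooled", bin_width: float = 5e-4,
               unit: str = "count-per-bin") -> PSTH:
    """Bin the selected trains into a PSTH.

    Parameters
    ----------
    spikes : SpikeTrainSet
    polarity : {+1, -1, "pooled"}
        Which trains to include.
    bin_width : float
        Bin width in seconds; ``duration`` must be an exact multiple.
    unit : {"count-per-bin", "rate"}
        Count-per-bin is canonical; rate divides by ``n_reps * bin_width``.

    Returns
    -------
    PSTH
        With ``n_ops`` equal to the number of binning increments performed
        (= number of selected spikes), for complexity accounting.
    """
    sel = spikes.select(polarity)
    nb = n_bins_for(sel.duration, bin_width)
    counts = np.zeros(nb, dtype=float)
    n_ops = 0
    for train in sel.trains:
        if train.size:
            idx = bin_indices(train, bin_width)
            np.add.at(counts, idx, 1.0)
            n_ops += train.size
    kind = {1: "p", -1: "n"}.get(polarity, "p")
    psth = PSTH(values=counts, fs=1.0 / bin_width, t0=0.0, unit="count-per-bin",
                bin_width=bin_width, n_reps=sel.n_trains, kind=kind, n_ops=n_ops)
    if unit == "rate":
        return psth.as_rate()
    if unit != "count-per-bin":
        raise ValidationError(f"unknown PSTH unit {unit!r}")
    return psth
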