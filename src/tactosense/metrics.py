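"""Spike-train features: firing rate, 200-ms binned counts, first-spike
latency, and the Victor-Purpura (VP) edit distance.

The VP distance is the minimal cost of transforming one train into the
other with spike insertions/deletions (cost 1 each) and spike shifts
(cost q per ms of shift), computed by dynamic programming.  At q = 0 it
reduces to the spike-count difference; as q grows it approaches a pure
coincidence count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import SpikeTrain

__all__ = ["VPConfig", "firing_rate", "binned_rate", "first_spike_latency",
           "vp_distance"]

#: Default shift-cost rate (1/ms): 1/(20 ms) temporal precision.
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class VPConfig:
    """Victor-Purpura cost parameter q (1/ms)."""

    q: float = DEFAULT_Q

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be nonnegative")


def firing_rate(train: SpikeTrain, window: tuple[float, float] | None = None) -> float:
    """Spikes per second within ``window`` (ms), default the whole train."""
    t0, t1 = window if window is not None else (0.0, train.duration)
    if t1 <= t0:
        raise ValueError("window must have positive length")
    count = int(np.count_nonzero((train.times >= t0) & (train.times <= t1)))
    return count / ((t1 - t0) / 1000.0)


def binned_rate(train: SpikeTrain, bin_ms: float = 200.0,
                duration: float | None = None) -> np.ndarray:
    """Spike counts in consecutive bins of ``bin_ms`` (last bin may be partial)."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    dur = duration if duration is not None else train.duration
    n_bins = max(1, int(np.ceil(dur / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(train.times, bins=edges)
    return counts


def first_spike_latency(train: SpikeTrain, onset_ms: float = 0.0) -> float | None:
    """Latency (ms) from ``onset_ms`` to the first subsequent spike, or None."""
    after = train.times[train.times >= onset_ms]
    if after.size == 0:
        return None
    return float(after[0] - onset_ms)


def vp_distance(train_a: SpikeTrain | np.ndarray, train_b: SpikeTrain | np.ndarray,
                cfg: VPConfig = VPConfig()) -> float:
    """Victor-Purpura distance between two sorted spike trains.

    Dynamic program over the (nA+1) x (nB+1) cost matrix:
    D[i,j] = min(D[i-1,j] + 1, D[i,j-1] + 1, D[i-1,j-1] + q*|a_i - b_j|).
    """
    a = np.asarray(train_a.times if isinstance(train_a, SpikeTrain) else train_a, float)
    b = np.asarray(train_b.times if isinstance(train_b, SpikeTrain) else train_b, float)
    if np.any(np.diff(a) < 0) or np.any(np.diff(b) < 0):
        raise ValueError("spike trains must be sorted")
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        return float(na + nb)
    # row-wise DP; vectorize the shift term per row
    prev = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        cur = np.empty(nb + 1)
        cur[0] = i
        shift = cfg.q * np.abs(a[i - 1] - b)
        for j in range(1, nb + 1):
            cur[j] = min(prev[j] + 1.0, cur[j - 1] + 1.0, prev[j - 1] + shift[j - 1])
        prev = cur
    return float(prev[nb])
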