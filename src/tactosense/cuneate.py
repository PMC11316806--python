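"""Second-order (cuneate nucleus) integration layer.

Afferent spike trains are convolved with a double-exponential
postsynaptic-potential (PSP) kernel, distributed over a recruited
cuneate population according to the 1700/300 divergence/convergence
ratio, summed (signed, so inhibitory interneuron edges subtract), and
the winner-take-all unit — the one with the largest time-integrated
PSP_total — is driven through the same Izhikevich dynamics to produce
the cuneate spike train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .encoder import SAI_PARAMS, IzhikevichParams, SensorTraceArray, SpikeTrain, \
    encode_array, simulate_afferent

__all__ = [
    "PSPKernelSpec",
    "CuneateLayerMap",
    "psp_kernel",
    "psp_peak_time",
    "convolve_spike_train",
    "recruited_count",
    "build_mapping",
    "integrate_psp",
    "winner_take_all",
    "simulate_cuneate",
    "afferent_to_cuneate",
    "CuneateResponse",
]

DIVERGENCE = 1700
CONVERGENCE = 300
TAU_FAST_MS = 4.0
TAU_SLOW_MS = 12.5


@dataclass(frozen=True)
class PSPKernelSpec:
    """Double-exponential PSP kernel, exp(-t/tau_slow) - exp(-t/tau_fast).

    The printed time constants (decay 4 ms, rise 12.5 ms) are oriented so
    that tau_slow = max(pair) and the kernel is nonnegative and causal.
    """

    tau_fast: float = TAU_FAST_MS
    tau_slow: float = TAU_SLOW_MS
    dt: float = 0.1
    horizon: float = 100.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.tau_fast < self.tau_slow:
            raise ValueError("need 0 < tau_fast < tau_slow")
        if self.horizon < 5 * self.tau_slow:
            raise ValueError("horizon must cover at least 5 * tau_slow")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def from_time_constants(cls, tau_a: float, tau_b: float, **kw) -> "PSPKernelSpec":
        return cls(tau_fast=min(tau_a, tau_b), tau_slow=max(tau_a, tau_b), **kw)


def psp_peak_time(spec: PSPKernelSpec) -> float:
    """Analytic peak location of the double-exponential kernel (ms)."""
    ts, tf = spec.tau_slow, spec.tau_fast
    return ts * tf / (ts - tf) * math.log(ts / tf)


def psp_kernel(spec: PSPKernelSpec) -> np.ndarray:
    """Sampled PSP kernel on [0, horizon]; zero at t=0, peak 1 if normalized."""
    t = np.arange(0.0, spec.horizon + spec.dt / 2, spec.dt)
    k = np.exp(-t / spec.tau_slow) - np.exp(-t / spec.tau_fast)
    if spec.normalize:
        k /= k.max()
    return k


def convolve_spike_train(train: SpikeTrain, kernel: np.ndarray, dt: float,
                         n_samples: int | None = None) -> np.ndarray:
    """PSP series of one afferent: kernel copies superposed at each spike.

    Spike times are binned to the sample grid (nearest index).  Output is
    truncated/padded to ``n_samples`` (default: the train duration).
    """
    if n_samples is None:
        n_samples = int(round(train.duration / dt)) + 1
    impulses = np.zeros(n_samples)
    if len(train):
        idx = np.clip(np.round(train.times / dt).astype(int), 0, n_samples - 1)
        np.add.at(impulses, idx, 1.0)
    out = fftconvolve(impulses, kernel)[:n_samples]
    return out


def recruited_count(n_active: int, divergence: int = DIVERGENCE,
                    convergence: int = CONVERGENCE) -> int:
    """Smallest cuneate count consistent with the divergence/convergence ratio.

    ceil(n_active * divergence / convergence); 100 active afferents with
    the 1700/300 ratio recruit 567 cuneate neurons.
    """
    if convergence == 0:
        raise ValueError("convergence must be nonzero")
    if n_active < 0:
        raise ValueError("n_active must be nonnegative")
    return -(-n_active * divergence // convergence)  # ceiling division


@dataclass
class CuneateLayerMap:
    """Afferent -> cuneate wiring: adjacency index lists and signed weights."""

    divergence: int
    convergence: int
    n_afferents: int
    n_cuneate: int
    adjacency: list[np.ndarray]
    weights: list[np.ndarray]
    inhibitory_fraction: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "divergence": self.divergence,
            "convergence": self.convergence,
            "n_afferents": self.n_afferents,
            "n_cuneate": self.n_cuneate,
            "inhibitory_fraction": self.inhibitory_fraction,
            "seed": self.seed,
            "adjacency": [a.tolist() for a in self.adjacency],
            "weights": [w.tolist() for w in self.weights],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CuneateLayerMap":
        return cls(
            divergence=d["divergence"], convergence=d["convergence"],
            n_afferents=d["n_afferents"], n_cuneate=d["n_cuneate"],
            adjacency=[np.asarray(a, dtype=int) for a in d["adjacency"]],
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            inhibitory_fraction=d.get("inhibitory_fraction", 0.0),
            seed=d.get("seed", 0),
        )


def build_mapping(n_afferents: int, divergence: int = DIVERGENCE,
                  convergence: int = CONVERGENCE, *,
                  inhibitory_fraction: float = 0.0, seed: int = 0,
                  n_cuneate: int | None = None) -> CuneateLayerMap:
    """Sample the recruited cuneate layer's wiring, reproducibly from seed.

    Each cuneate unit draws min(n_afferents, convergence) distinct afferents
    uniformly without replacement; when the array has fewer afferents than
    the convergence cap (36 << 300) every unit connects to all of them.
    A fraction of edges may be inhibitory (weight -1).
    """
    if n_afferents < 1:
        raise ValueError("need at least one afferent")
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise ValueError("inhibitory_fraction must be in [0, 1]")
    if n_cuneate is None:
        n_cuneate = recruited_count(n_afferents, divergence, convergence)
    rng = np.random.default_rng(seed)
    fan_in = min(n_afferents, convergence)
    adjacency, weights = [], []
    for _ in range(n_cuneate):
        if fan_in == n_afferents:
            idx = np.arange(n_afferents)
        else:
            idx = np.sort(rng.choice(n_afferents, size=fan_in, replace=False))
        w = np.ones(fan_in)
        if inhibitory_fraction > 0:
            inhib = rng.random(fan_in) < inhibitory_fraction
            w[inhib] = -1.0
        adjacency.append(idx)
        weights.append(w)
    return CuneateLayerMap(divergence, convergence, n_afferents, n_cuneate,
                           adjacency, weights, inhibitory_fraction, seed)


def integrate_psp(psp: np.ndarray, layer_map: CuneateLayerMap) -> np.ndarray:
    """Signed sum of connected afferent PSP series per cuneate unit.

    ``psp`` is (n_afferents, n_samples); returns (n_cuneate, n_samples).
    """
    psp = np.asarray(psp, dtype=float)
    if psp.shape[0] != layer_map.n_afferents:
        raise ValueError("PSP row count does not match the layer map")
    W = np.zeros((layer_map.n_cuneate, layer_map.n_afferents))
    for j, (idx, w) in enumerate(zip(layer_map.adjacency, layer_map.weights)):
        W[j, idx] = w
    return W @ psp


def winner_take_all(psp_total: np.ndarray, dt: float = 1.0) -> tuple[int, np.ndarray]:
    """Unit with the largest time-integrated PSP_total; ties -> lowest index."""
    psp_total = np.atleast_2d(np.asarray(psp_total, dtype=float))
    integrals = np.trapezoid(psp_total, dx=dt, axis=1)
    winner = int(np.argmax(integrals))
    return winner, psp_total[winner]


def simulate_cuneate(psp_total: np.ndarray, params: IzhikevichParams | None = None,
                     gain_cuneate: float = 1.0, dt: float = 0.1, *,
                     unit_id: str = "cuneate") -> SpikeTrain:
    """Drive an Izhikevich unit with gain_cuneate * PSP_total.

    Defaults to the calibrated SAI parameter set relabelled as a cuneate
    unit (no separate cuneate calibration data exists).
    """
    if params is None:
        params = SAI_PARAMS.replace(unit_type="cuneate")
    train = simulate_afferent(gain_cuneate * np.asarray(psp_total, float),
                              params, dt, unit_id=unit_id)
    return train


@dataclass
class CuneateResponse:
    """End-to-end result of the afferent -> cuneate stage for one trial."""

    afferent_trains: list[SpikeTrain]
    winner_index: int
    winner_psp: np.ndarray
    cuneate_train: SpikeTrain
    layer_map: CuneateLayerMap


def afferent_to_cuneate(
    trace: SensorTraceArray,
    afferent_params: IzhikevichParams = SAI_PARAMS,
    kernel_spec: PSPKernelSpec | None = None,
    *,
    gain_cuneate: float = 1.0,
    cuneate_params: IzhikevichParams | None = None,
    layer_map: CuneateLayerMap | None = None,
    seed: int = 0,
) -> CuneateResponse:
    """Full second-order pipeline: encode taxels, convolve, integrate, WTA, spike."""
    if kernel_spec is None:
        kernel_spec = PSPKernelSpec(dt=trace.dt)
    elif kernel_spec.dt != trace.dt:
        raise ValueError("kernel dt must match the trace dt")
    trains = encode_array(trace, afferent_params)
    kernel = psp_kernel(kernel_spec)
    psp = np.stack([
        convolve_spike_train(t, kernel, trace.dt, trace.n_samples) for t in trains
    ])
    if layer_map is None:
        layer_map = build_mapping(trace.n_taxels, seed=seed)
    psp_total = integrate_psp(psp, layer_map)
    winner, winner_series = winner_take_all(psp_total, trace.dt)
    cuneate_train = simulate_cuneate(winner_series, cuneate_params, gain_cuneate,
                                     trace.dt, unit_id=f"cuneate_{winner}")
    return CuneateResponse(trains, winner, winner_series, cuneate_train, layer_map)
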