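"""Muscle-synergy extraction from multichannel EMG.

EMG envelopes V (muscles x time, nonnegative) are factorized as
V ~ W H with nonnegative weights W and activations H by multiplicative-
update NMF (squared-error objective, best of several seeded restarts).
The synergy count is the smallest k whose variance accounted for,
VAF(k) = 1 - ||V - WH||_F^2 / ||V||_F^2, exceeds 0.85 with less than a
0.06 increment from adding another synergy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, decimate, sosfiltfilt

__all__ = [
    "EMGEnvelope",
    "SynergyDecomposition",
    "NMFResult",
    "emg_envelope",
    "nmf",
    "vaf",
    "select_synergy_count",
    "extract_synergies",
]

_EPS = 1e-12


@dataclass
class EMGEnvelope:
    """Nonnegative envelope matrix (n_muscles x n_samples) at rate fs (Hz)."""

    matrix: np.ndarray
    fs: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("envelope matrix must be 2-D")
        if np.any(self.matrix < 0):
            raise ValueError("envelope must be nonnegative")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.matrix.shape[0]))


@dataclass
class SynergyDecomposition:
    W: np.ndarray                   # n_muscles x k, nonnegative
    H: np.ndarray                   # k x n_samples, nonnegative
    vaf_by_k: dict[int, float]
    selected_k: int
    rule_satisfied: bool = True


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray     # squared error per iteration (best restart)
    seed: int


def emg_envelope(raw: np.ndarray, fs: float, *, band=(20.0, 450.0),
                 lowpass_hz: float = 4.0, order: int = 4,
                 normalize: bool = True, target_fs: float | None = None,
                 labels: tuple[str, ...] = ()) -> EMGEnvelope:
    """Conventional synergy-analysis preprocessing.

    Band-pass (default 20-450 Hz, 4th-order Butterworth, zero phase),
    full-wave rectification, low-pass envelope (4 Hz), optional
    unit-maximum normalization per channel and decimation to ``target_fs``.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if band[1] >= fs / 2:
        raise ValueError("band upper edge must be below Nyquist")
    sos_bp = butter(order, band, btype="bandpass", fs=fs, output="sos")
    sos_lp = butter(order, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    env = sosfiltfilt(sos_lp, np.abs(sosfiltfilt(sos_bp, raw, axis=1)), axis=1)
    env = np.clip(env, 0.0, None)
    out_fs = fs
    if target_fs is not None and target_fs < fs:
        factor = int(round(fs / target_fs))
        env = decimate(env, factor, axis=1, zero_phase=True)
        env = np.clip(env, 0.0, None)
        out_fs = fs / factor
    if normalize:
        peaks = env.max(axis=1, keepdims=True)
        peaks[peaks == 0] = 1.0
        env = env / peaks
    return EMGEnvelope(env, out_fs, labels)


def _mu_nmf(V: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, m = V.shape
    scale = np.sqrt(V.mean() / k) + _EPS
    W = scale * rng.random((n, k)) + _EPS
    H = scale * rng.random((k, m)) + _EPS
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(V - W @ H) ** 2)
        trace.append(err)
        # improvement measured against the starting objective, so the slow
        # tail of the multiplicative updates is not mistaken for convergence
        if prev - err <= tol * trace[0]:
            break
        prev = err
    return W, H, trace


def nmf(V: EMGEnvelope | np.ndarray, k: int, *, seed: int = 0,
        restarts: int = 20, max_iter: int = 500, tol: float = 1e-6) -> NMFResult:
    """Multiplicative-update NMF, best of ``restarts`` seeded initializations.

    The squared-error objective is non-increasing over iterations (a
    property of the multiplicative updates); the per-iteration trace of
    the winning restart is returned.
    """
    V = V.matrix if isinstance(V, EMGEnvelope) else np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > V.shape[0]:
        raise ValueError("k cannot exceed the number of muscles")
    best = None
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        W, H, trace = _mu_nmf(V, k, rng, max_iter, tol)
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = NMFResult(W, H, np.asarray(trace), seed=r)
    return best


def vaf(V: EMGEnvelope | np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Uncentered variance accounted for: 1 - ||V - WH||^2 / ||V||^2."""
    V = V.matrix if isinstance(V, EMGEnvelope) else np.asarray(V, dtype=float)
    denom = float(np.linalg.norm(V) ** 2)
    if denom == 0.0:
        raise ValueError("VAF undefined for an all-zero matrix")
    return 1.0 - float(np.linalg.norm(V - W @ H) ** 2) / denom


def vaf_per_muscle(V: EMGEnvelope | np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Mean of per-muscle (per-row) uncentered VAF; alternative criterion."""
    V = V.matrix if isinstance(V, EMGEnvelope) else np.asarray(V, dtype=float)
    R = V - W @ H
    denom = np.sum(V * V, axis=1)
    if np.any(denom == 0.0):
        raise ValueError("per-muscle VAF undefined for an all-zero channel")
    return float(np.mean(1.0 - np.sum(R * R, axis=1) / denom))


def select_synergy_count(vaf_by_k: dict[int, float], threshold: float = 0.85,
                         max_increment: float = 0.06) -> tuple[int, bool]:
    """Smallest k with VAF above threshold and a below-increment gain at k+1.

    At the largest k probed the increment condition cannot be evaluated and
    is taken as satisfied if the threshold is met.  Returns (k, satisfied);
    if no k qualifies, returns (k_max, False).
    """
    if not vaf_by_k:
        raise ValueError("empty VAF curve")
    ks = sorted(vaf_by_k)
    for k in ks:
        if vaf_by_k[k] <= threshold:
            continue
        if k + 1 not in vaf_by_k or vaf_by_k[k + 1] - vaf_by_k[k] < max_increment:
            return k, True
    warnings.warn("no synergy count satisfied the VAF rule; returning k_max")
    return ks[-1], False


def extract_synergies(envelope: EMGEnvelope, max_k: int | None = None, *,
                      seed: int = 0, restarts: int = 20, max_iter: int = 500,
                      tol: float = 1e-6, threshold: float = 0.85,
                      max_increment: float = 0.06) -> SynergyDecomposition:
    """Factorize for k = 1..max_k, apply the VAF rule, keep the chosen k."""
    n_muscles = envelope.matrix.shape[0]
    if max_k is None:
        max_k = n_muscles
    results = {
        k: nmf(envelope, k, seed=seed, restarts=restarts,
               max_iter=max_iter, tol=tol)
        for k in range(1, max_k + 1)
    }
    vaf_by_k = {k: vaf(envelope, r.W, r.H) for k, r in results.items()}
    selected, ok = select_synergy_count(vaf_by_k, threshold, max_increment)
    chosen = results[selected]
    return SynergyDecomposition(chosen.W, chosen.H, vaf_by_k, selected, ok)
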