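"""Object-size discrimination under signal detection theory (SDT).

Repeated touches of a baseline object (100 mm cylinder or sphere) define
the "noise" feature distribution; touches of a smaller target object
define the "signal".  Two features are supported: the firing rate of the
winning cuneate unit over the trial, and the Victor-Purpura distance
between cuneate trains.  Sensitivity is summarized as

    d' = (mean_signal - mean_noise) / sqrt((sd_signal^2 + sd_noise^2)/2)

and percent correct of the unbiased yes/no observer, hit rate = Phi(d'/2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .encoder import SpikeTrain
from .metrics import VPConfig, firing_rate, vp_distance

__all__ = [
    "DiscriminationProtocol",
    "SDTResult",
    "dprime",
    "hit_rate_from_dprime",
    "vp_noise_signal_sets",
    "run_discrimination_protocol",
]


@dataclass(frozen=True)
class DiscriminationProtocol:
    shapes: tuple[str, ...] = ("cylinder", "sphere")
    diameters_mm: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0, 90.0, 100.0)
    baseline_diameter_mm: float = 100.0
    touches_per_object: int = 10
    features: tuple[str, ...] = ("rate", "vp")
    vp_config: VPConfig = field(default_factory=VPConfig)
    vp_pairing: str = "index"  # or "full"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_diameter_mm not in self.diameters_mm:
            raise ValueError("baseline diameter must be among diameters_mm")
        if self.touches_per_object < 2:
            raise ValueError("need at least 2 touches per object")
        if self.vp_pairing not in ("index", "full"):
            raise ValueError("vp_pairing must be 'index' or 'full'")


@dataclass
class SDTResult:
    shape: str
    diameter_mm: float
    feature: str
    d_prime: float
    hit_rate: float
    n_signal: int
    n_noise: int
    degenerate: bool = False


def dprime(signal_samples: Sequence[float], noise_samples: Sequence[float]) -> float:
    """Sensitivity index with the rms of the two sample sds as the unit."""
    s = np.asarray(signal_samples, float)
    n = np.asarray(noise_samples, float)
    if s.size < 2 or n.size < 2:
        raise ValueError("need at least 2 samples in each distribution")
    pooled = np.sqrt((s.std(ddof=1) ** 2 + n.std(ddof=1) ** 2) / 2.0)
    if pooled == 0.0:
        raise ValueError("zero pooled sd: d' undefined")
    return float((s.mean() - n.mean()) / pooled)


def hit_rate_from_dprime(d_prime: float) -> float:
    """Percent correct of the unbiased criterion observer, Phi(d'/2)."""
    return float(norm.cdf(d_prime / 2.0))


def vp_noise_signal_sets(
    trains_by_object: Mapping[float, Sequence[SpikeTrain]],
    baseline: float,
    cfg: VPConfig = VPConfig(),
    pairing: str = "index",
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """VP-distance noise and signal sets for one shape.

    Noise: all C(n,2) pairwise distances among the baseline touches.
    Signal (per target object): with ``pairing='index'`` one distance per
    touch, target touch i vs baseline touch i (10 per object); with
    ``'full'`` all target x baseline cross pairs.
    """
    base = list(trains_by_object[baseline])
    noise = np.array([
        vp_distance(a, b, cfg) for a, b in itertools.combinations(base, 2)
    ])
    signal: dict[float, np.ndarray] = {}
    for diameter, trains in trains_by_object.items():
        if diameter == baseline:
            continue
        trains = list(trains)
        if pairing == "index":
            if len(trains) != len(base):
                raise ValueError("index pairing needs equal touch counts")
            d = [vp_distance(t, b, cfg) for t, b in zip(trains, base)]
        else:
            d = [vp_distance(t, b, cfg) for t in trains for b in base]
        signal[diameter] = np.array(d)
    return noise, signal


def _sdt_result(shape: str, diameter: float, feature: str,
                signal: np.ndarray, noise: np.ndarray) -> SDTResult:
    try:
        d = dprime(signal, noise)
        hr = hit_rate_from_dprime(d)
        degenerate = False
    except ValueError:
        d, hr, degenerate = float("nan"), float("nan"), True
    return SDTResult(shape, float(diameter), feature, d, hr,
                     n_signal=signal.size, n_noise=noise.size,
                     degenerate=degenerate)


def run_discrimination_protocol(
    protocol: DiscriminationProtocol,
    response_source: Callable[[str, float, int], SpikeTrain],
) -> pd.DataFrame:
    """Run the full discrimination protocol against a response source.

    ``response_source(shape, diameter_mm, touch_index)`` returns the
    cuneate spike train for one touch.  Returns one row per
    (shape, non-baseline diameter, feature) with d', hit rate and set
    sizes; provenance (seed, q, pairing) is stored in ``DataFrame.attrs``.
    """
    rows: list[SDTResult] = []
    for shape in protocol.shapes:
        trains: dict[float, list[SpikeTrain]] = {
            d: [response_source(shape, d, i)
                for i in range(protocol.touches_per_object)]
            for d in protocol.diameters_mm
        }
        baseline = protocol.baseline_diameter_mm
        if "rate" in protocol.features:
            rates = {d: np.array([firing_rate(t) for t in ts])
                     for d, ts in trains.items()}
            for d in protocol.diameters_mm:
                if d == baseline:
                    continue
                rows.append(_sdt_result(shape, d, "rate", rates[d], rates[baseline]))
        if "vp" in protocol.features:
            noise, signal = vp_noise_signal_sets(
                trains, baseline, protocol.vp_config, protocol.vp_pairing)
            for d in protocol.diameters_mm:
                if d == baseline:
                    continue
                rows.append(_sdt_result(shape, d, "vp", signal[d], noise))
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["seed"] = protocol.seed
    df.attrs["q"] = protocol.vp_config.q
    df.attrs["vp_pairing"] = protocol.vp_pairing
    return df
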