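"""Sensorimotor transduction functions and their identification.

The mapping from second-order (cuneate) tactile signal S to the
muscle-synergy activation level is modelled as an all-pole continuous
transfer function in the Laplace variable:

    active grasping:    a / (S^2 + b S + c)        (2 poles)
    reactive grasping:  a / (S^3 + b S^2 + c S + d) (3 poles, monic form)

Coefficients are identified from input/output records by output-error
minimization: the denominator is searched (Nelder-Mead over
log-parameterized positive coefficients, seeded multi-start) while the
scalar numerator is concentrated out by linear least squares.  Fit is
reported as the NRMSE goodness 1 - ||y - yhat|| / ||y - mean(y)||.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.signal import BadCoefficients, cont2discrete, lfilter

__all__ = [
    "TransferFunctionModel",
    "STRUCTURE_ORDERS",
    "tf_simulate",
    "fit_transfer_function",
    "select_structure",
    "default_transduction_model",
]

STRUCTURE_ORDERS = {"active": 2, "reactive": 3}


@dataclass
class TransferFunctionModel:
    """Proper rational transfer function num(S)/den(S), den monic."""

    num: np.ndarray
    den: np.ndarray
    structure: str = "custom"
    fit: float | None = None
    dt: float | None = None          # seconds, discretization step used
    stable: bool | None = None

    def __post_init__(self) -> None:
        self.num = np.atleast_1d(np.asarray(self.num, dtype=float))
        self.den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if self.den[0] == 0:
            raise ValueError("denominator leading coefficient must be nonzero")
        if self.num.size > self.den.size - 1:
            raise ValueError("model must be strictly proper (num order < den order)")
        expected = STRUCTURE_ORDERS.get(self.structure)
        if expected is not None and self.den.size - 1 != expected:
            raise ValueError(
                f"{self.structure} structure requires {expected} poles")
        self.stable = bool(np.all(np.real(self.poles()) < 0))

    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    def dc_gain(self) -> float:
        return float(self.num[-1] / self.den[-1])

    def order(self) -> int:
        return self.den.size - 1

    def to_json(self) -> str:
        return json.dumps({
            "structure": self.structure,
            "num": self.num.tolist(),
            "den": self.den.tolist(),
            "fit": self.fit,
            "dt": self.dt,
            "stable": self.stable,
        })

    @classmethod
    def from_json(cls, s: str) -> "TransferFunctionModel":
        d = json.loads(s)
        return cls(np.asarray(d["num"]), np.asarray(d["den"]),
                   structure=d.get("structure", "custom"),
                   fit=d.get("fit"), dt=d.get("dt"))


def tf_simulate(model: TransferFunctionModel, u: np.ndarray, dt: float) -> np.ndarray:
    """Zero-state response to input ``u`` sampled at ``dt`` seconds (ZOH)."""
    u = np.asarray(u, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BadCoefficients)
        sysd = cont2discrete((model.num, model.den), dt, method="zoh")
    return lfilter(sysd[0].ravel(), sysd[1].ravel(), u)


def _nrmse_fit(y: np.ndarray, yhat: np.ndarray) -> float:
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        return float("-inf")
    return 1.0 - float(np.linalg.norm(y - yhat) / denom)


def _simulate_all_pole(den: np.ndarray, u: np.ndarray, dt: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BadCoefficients)
        sysd = cont2discrete(([1.0], den), dt, method="zoh")
    return lfilter(sysd[0].ravel(), sysd[1].ravel(), u)


def _concentrated_residual(log_den_tail: np.ndarray, u, y, dt):
    """Residual norm with the scalar numerator solved in closed form."""
    den = np.concatenate(([1.0], np.exp(log_den_tail)))
    with np.errstate(over="ignore", invalid="ignore"):
        base = _simulate_all_pole(den, u, dt)
        bb = float(base @ base)
        if not np.isfinite(bb) or bb == 0:
            return np.inf, 0.0, den
        a = float(base @ y) / bb
        resid = float(np.linalg.norm(y - a * base))
    if not np.isfinite(resid):
        return np.inf, 0.0, den
    return resid, a, den


def fit_transfer_function(
    u: np.ndarray,
    y: np.ndarray,
    structure: str | int = "active",
    dt: float = 0.01,
    *,
    n_starts: int = 10,
    seed: int = 0,
    maxiter: int = 400,
) -> TransferFunctionModel:
    """Identify an all-pole transduction function from input/output data.

    ``structure`` is 'active' (2 poles), 'reactive' (3 poles) or a pole
    count.  Multi-start Nelder-Mead over log-parameterized denominator
    coefficients (monic, positive), scalar numerator concentrated out.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    order = STRUCTURE_ORDERS.get(structure, structure)
    if not isinstance(order, int) or order < 1:
        raise ValueError(f"unknown structure {structure!r}")
    if u.shape != y.shape or u.ndim != 1:
        raise ValueError("u and y must be equal-length 1-D series")
    if u.size < 10 * order:
        raise ValueError("need at least 10 samples per model order")
    if np.ptp(u) == 0:
        warnings.warn("constant input excites no dynamics; fit is unidentifiable")
    tag = structure if isinstance(structure, str) else "custom"
    if np.allclose(y, 0):
        model = TransferFunctionModel(np.zeros(1), np.concatenate(([1.0], np.ones(order))),
                                      structure=tag, fit=float("-inf"), dt=dt)
        return model

    # pole-rate scale from the record length and the sampling rate
    T = u.size * dt
    rate_lo, rate_hi = 1.0 / T, 0.3 / dt
    rng = np.random.default_rng(seed)

    best = (np.inf, None, None)
    for s in range(n_starts):
        rates = np.exp(rng.uniform(np.log(rate_lo), np.log(rate_hi), size=order))
        den0 = np.real(np.poly(-rates))
        x0 = np.log(np.maximum(den0[1:], 1e-12))
        res = minimize(lambda x: _concentrated_residual(x, u, y, dt)[0], x0,
                       method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-12})
        if res.fun < best[0]:
            best = (res.fun, res.x, s)
    _, a, den = _concentrated_residual(best[1], u, y, dt)
    num = np.array([a])
    yhat = a * _simulate_all_pole(den, u, dt)
    model = TransferFunctionModel(num, den, structure=tag,
                                  fit=_nrmse_fit(y, yhat), dt=dt)
    return model


def select_structure(
    u: np.ndarray,
    y: np.ndarray,
    candidates: tuple = tuple(range(1, 10)),
    dt: float = 0.01,
    *,
    seed: int = 0,
    n_starts: int = 10,
    tie_tol: float = 1e-3,
) -> TransferFunctionModel:
    """Fit every candidate pole count and keep the best NRMSE fit.

    Fits within ``tie_tol`` of the maximum are treated as ties, resolved
    toward the lowest total order (the parsimonious nested model).
    """
    if len(candidates) == 0:
        raise ValueError("no candidate structures")
    models = [fit_transfer_function(u, y, c, dt, n_starts=n_starts, seed=seed)
              for c in candidates]
    fits = np.array([m.fit for m in models])
    best_fit = fits.max()
    tied = [m for m, f in zip(models, fits) if best_fit - f <= tie_tol]
    return min(tied, key=lambda m: m.order())


def default_transduction_model(mode: str = "active") -> TransferFunctionModel:
    """Stock transduction controllers for the synthetic grasp plant.

    Coefficients are a control design for the bundled plant (DC gain sized
    so a ~50 spikes/s cuneate rate maps to a holding activation, poles
    fast enough to answer an impact within ~150 ms), not measured values.
    """
    if mode == "active":
        # poles at -8, -12 rad/s; DC gain 0.005 activation per spike/s
        den = np.array([1.0, 20.0, 96.0])
        num = np.array([0.005 * 96.0])
        return TransferFunctionModel(num, den, structure="active")
    if mode == "reactive":
        # poles at -12, -18, -25 rad/s; DC gain 0.005
        den = np.real(np.poly([-12.0, -18.0, -25.0]))
        num = np.array([0.005 * den[-1]])
        return TransferFunctionModel(num, den, structure="reactive")
    raise ValueError("mode must be 'active' or 'reactive'")
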