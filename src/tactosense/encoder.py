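"""First-order tactile afferent encoding.

Converts per-taxel sensor drive into SAI/FAI spike trains with the
Izhikevich spiking-neuron model,

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I/Cm
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

where the drive ``I`` is the gain-ported sensor current ``K * I_sensor``
for slowly-adapting (SAI) units and ``K * |dI_sensor/dt|`` for
fast-adapting (FAI) units: SAI units sustain firing under held pressure,
FAI units fire only on stimulus transients.  Parameters are calibrated
against reference firing-rate tables by maximizing the fractional
sum-of-squares goodness of fit (FSS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "IzhikevichParams",
    "SensorTraceArray",
    "SpikeTrain",
    "SAI_PARAMS",
    "FAI_PARAMS",
    "INITIAL_PARAMS",
    "port_sensor_current",
    "drive_derivative",
    "simulate_afferent",
    "simulate_afferent_population",
    "encode_array",
    "fss",
    "fit_afferent_params",
    "FitResult",
]

V_PEAK = 30.0  # mV, spike cutoff


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich neuron parameters plus the sensor-drive gain.

    a: recovery time scale (1/ms); b: recovery sensitivity; c: reset
    potential (mV); d: recovery increment (mV); K: drive gain; Cm:
    capacitance scale (only K/Cm is identifiable, so Cm defaults to 1).
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 6.0
    K: float = 25.0
    Cm: float = 1.0
    v_peak: float = V_PEAK
    unit_type: str = "SAI"

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.d < 0:
            raise ValueError("d must be nonnegative")
        if self.c >= self.v_peak:
            raise ValueError("reset potential c must lie below v_peak")
        if self.K < 0:
            raise ValueError("gain K must be nonnegative")
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        if self.unit_type not in ("SAI", "FAI", "cuneate"):
            raise ValueError(f"unknown unit_type {self.unit_type!r}")

    def replace(self, **kw) -> "IzhikevichParams":
        return replace(self, **kw)


#: Literature initialization used before calibration.
INITIAL_PARAMS = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=6.0, K=25.0)
#: Calibrated SAI unit.
SAI_PARAMS = IzhikevichParams(a=0.02, b=0.205, c=-65.0, d=6.20, K=55.0, unit_type="SAI")
#: Calibrated FAI unit.
FAI_PARAMS = IzhikevichParams(a=0.02, b=0.210, c=-65.5, d=6.15, K=56.0, unit_type="FAI")


@dataclass
class SensorTraceArray:
    """Per-taxel drive time series for the 6x6 sensor array.

    data: (n_taxels, n_samples) drive values in arbitrary units, taxels in
    row-major grid order; dt in ms.  ``annotations`` records event times in
    ms (e.g. contact onset, impact).
    """

    data: np.ndarray
    dt: float
    rows: int = 6
    cols: int = 6
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_taxels, n_samples)")
        if self.data.shape[0] != self.rows * self.cols:
            raise ValueError(
                f"taxel count {self.data.shape[0]} != rows*cols {self.rows * self.cols}"
            )

    @property
    def n_taxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return (self.n_samples - 1) * self.dt

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def taxel(self, row: int, col: int) -> np.ndarray:
        return self.data[row * self.cols + col]


@dataclass
class SpikeTrain:
    """Sorted spike times (ms) of one unit over [0, duration]."""

    times: np.ndarray
    duration: float
    unit_id: str = ""
    unit_type: str = "SAI"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return self.times.size


def port_sensor_current(trace: SensorTraceArray | np.ndarray, K: float) -> np.ndarray:
    """Apply the porting gain I(t) = K * I_sensor(t) elementwise."""
    if K < 0:
        raise ValueError("gain K must be nonnegative")
    data = trace.data if isinstance(trace, SensorTraceArray) else np.asarray(trace, float)
    return K * data


def drive_derivative(drive: np.ndarray, dt: float) -> np.ndarray:
    """Time derivative of a drive series, per ms.

    Central differences in the interior, one-sided at the ends; output has
    the same length as the input.
    """
    drive = np.asarray(drive, dtype=float)
    if drive.shape[-1] < 2:
        raise ValueError("drive needs at least 2 samples to differentiate")
    return np.gradient(drive, dt, axis=-1)


def _effective_drive(drive: np.ndarray, params: IzhikevichParams, dt: float,
                     signed_derivative: bool) -> np.ndarray:
    if params.unit_type == "FAI":
        d = drive_derivative(drive, dt)
        return d if signed_derivative else np.abs(d)
    return drive


def simulate_afferent_population(
    drive: np.ndarray,
    params: IzhikevichParams,
    dt: float,
    *,
    signed_derivative: bool = False,
    v0: float = -70.0,
    return_state: bool = False,
):
    """Forward-Euler Izhikevich integration of many units in parallel.

    ``drive`` is (n_units, n_samples), already gain-ported.  For FAI
    parameters the derivative pathway (|dI/dt| by default) is applied
    internally.  Returns a list of spike-time arrays (ms), plus the (v, u)
    trajectories when ``return_state``.
    """
    drive = np.atleast_2d(np.asarray(drive, dtype=float))
    if not np.all(np.isfinite(drive)):
        raise ValueError("drive contains non-finite values")
    if dt >= 1.0:
        warnings.warn(f"dt={dt} ms is coarse for Euler integration of spiking dynamics")
    I = _effective_drive(drive, params, dt, signed_derivative) / params.Cm
    n_units, n_samples = I.shape

    v = np.full(n_units, v0, dtype=float)
    u = params.b * v
    spikes: list[list[float]] = [[] for _ in range(n_units)]
    if return_state:
        v_traj = np.empty((n_units, n_samples))
        u_traj = np.empty((n_units, n_samples))
        v_traj[:, 0] = v
        u_traj[:, 0] = u

    vp = params.v_peak
    pending_reset = np.zeros(n_units, dtype=bool)
    for k in range(1, n_samples):
        # units that spiked on the previous sample show the reset value c
        # on this sample and resume integration on the next one
        stepping = ~pending_reset
        v_next = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I[:, k - 1])
        v = np.where(stepping, v_next, params.c)
        u = np.where(stepping, u + dt * params.a * (params.b * v - u), u)
        fired = stepping & (v >= vp)
        if np.any(fired):
            t = k * dt
            for i in np.nonzero(fired)[0]:
                spikes[i].append(t)
            v = np.where(fired, vp, v)  # record the 30 mV peak
            u = np.where(fired, u + params.d, u)
        pending_reset = fired
        if return_state:
            v_traj[:, k] = v
            u_traj[:, k] = u

    trains = [np.asarray(s) for s in spikes]
    if return_state:
        return trains, (v_traj, u_traj)
    return trains


def simulate_afferent(
    drive: np.ndarray,
    params: IzhikevichParams,
    dt: float,
    duration: float | None = None,
    *,
    unit_id: str = "",
    signed_derivative: bool = False,
    return_state: bool = False,
) -> SpikeTrain | tuple[SpikeTrain, tuple[np.ndarray, np.ndarray]]:
    """Encode one gain-ported drive series as a spike train.

    A spike is recorded at the first sample where v reaches 30 mV; v then
    resets to c and u jumps by d (the recorded v shows the 30 mV peak).
    """
    drive = np.asarray(drive, dtype=float)
    if drive.ndim != 1:
        raise ValueError("simulate_afferent expects a 1-D drive; see simulate_afferent_population")
    out = simulate_afferent_population(
        drive[None, :], params, dt,
        signed_derivative=signed_derivative, return_state=return_state,
    )
    trains, state = (out[0], out[1]) if return_state else (out, None)
    dur = duration if duration is not None else (drive.size - 1) * dt
    train = SpikeTrain(trains[0], duration=dur, unit_id=unit_id, unit_type=params.unit_type)
    if return_state:
        return train, (state[0][0], state[1][0])
    return train


def encode_array(
    trace: SensorTraceArray,
    params: IzhikevichParams,
    *,
    signed_derivative: bool = False,
) -> list[SpikeTrain]:
    """Gain-port and encode every taxel of a sensor array trace."""
    drive = port_sensor_current(trace, params.K)
    trains = simulate_afferent_population(
        drive, params, trace.dt, signed_derivative=signed_derivative
    )
    return [
        SpikeTrain(t, duration=trace.duration_ms,
                   unit_id=f"{params.unit_type.lower()}_taxel{i}",
                   unit_type=params.unit_type)
        for i, t in enumerate(trains)
    ]


def fss(measured: Sequence[float], predicted: Sequence[float]) -> float:
    """Fractional sum-of-squares goodness of fit.

    FSS = 1 - sum((meas - pred)^2) / sum(meas^2); 1 iff the prediction is
    exact, 0 for an all-zero prediction, unbounded below.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.size == 0 or m.shape != p.shape:
        raise ValueError("measured and predicted must be equal-length nonempty vectors")
    denom = float(np.sum(m * m))
    if denom == 0.0:
        raise ValueError("FSS undefined for an all-zero measured vector")
    return 1.0 - float(np.sum((m - p) ** 2)) / denom


@dataclass
class FitResult:
    params: IzhikevichParams
    fss: float
    improved: bool
    underdetermined: bool


def _predict_rates(stimuli: np.ndarray, params: IzhikevichParams, dt: float,
                   duration: float) -> np.ndarray:
    """Steady firing rate (spikes/s) for constant sensor drives."""
    n = int(round(duration / dt)) + 1
    drive = params.K * np.repeat(stimuli[:, None], n, axis=1)
    trains = simulate_afferent_population(drive, params, dt)
    return np.array([len(t) for t in trains]) / (duration / 1000.0)


def fit_afferent_params(
    reference: Sequence[tuple[float, float]],
    init: IzhikevichParams = INITIAL_PARAMS,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    *,
    dt: float = 0.1,
    duration: float = 1000.0,
    grid_points: int = 7,
    seed: int = 0,
) -> FitResult:
    """Calibrate afferent parameters against a stimulus -> firing-rate table.

    ``reference`` is a sequence of (constant sensor drive, rate in
    spikes/s) pairs.  Only the parameters named in ``bounds`` (default:
    K only, over [1, 200]) are searched, by a seeded coarse grid followed
    by Nelder-Mead refinement, maximizing FSS.  The returned set never
    scores below the initialization.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference table")
    if ref.ndim != 2 or ref.shape[1] != 2:
        raise ValueError("reference must be (stimulus, rate) pairs")
    underdetermined = ref.shape[0] < 3
    stimuli, rates = ref[:, 0], ref[:, 1]
    if bounds is None:
        bounds = {"K": (1.0, 200.0)}
    names = list(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])

    def score(x: np.ndarray) -> float:
        p = init.replace(**dict(zip(names, np.clip(x, lo, hi))))
        return fss(rates, _predict_rates(stimuli, p, dt, duration))

    # coarse grid (full factorial up to 3 dims, seeded Latin-ish sample beyond)
    rng = np.random.default_rng(seed)
    if len(names) <= 3:
        axes = [np.linspace(l, h, grid_points) for l, h in zip(lo, hi)]
        grid = np.stack([g.ravel() for g in np.meshgrid(*axes)], axis=-1)
    else:
        grid = lo + (hi - lo) * rng.random((grid_points ** 3, len(names)))
    grid_scores = [score(x) for x in grid]
    x0 = grid[int(np.argmax(grid_scores))]

    res = minimize(lambda x: -score(x), x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-6, "maxiter": 200})
    x_best = np.clip(res.x, lo, hi)
    best = init.replace(**dict(zip(names, x_best)))
    best_fss = score(x_best)
    init_fss = fss(rates, _predict_rates(stimuli, init, dt, duration))
    if best_fss < init_fss:
        return FitResult(init, init_fss, improved=False, underdetermined=underdetermined)
    return FitResult(best, best_fss, improved=best_fss > init_fss,
                     underdetermined=underdetermined)
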