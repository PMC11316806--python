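"""Synthetic stand-ins for the physical rig.

Everything the instrumented hand produced is generated here under seeded
control: 6x6 taxel drive traces for active/reactive grasps of cylinders
and spheres (curvature-dependent plateau, center-peaked spatial profile,
damped impact transient for a dropped 20 g weight), synergy-structured
surface EMG, and a minimal grasp plant for exercising the transduction-
function controller in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cuneate import PSPKernelSpec, psp_kernel
from .encoder import SAI_PARAMS, IzhikevichParams, SensorTraceArray, SpikeTrain
from .sysid import TransferFunctionModel

__all__ = [
    "GraspScenario",
    "GraspPlant",
    "generate_grasp_scenario",
    "generate_synergy_emg",
    "run_closed_loop",
    "scenario_response_source",
]


@dataclass(frozen=True)
class GraspScenario:
    """One synthetic touch of a cylinder or sphere.

    The plateau drive of each taxel is (base_amplitude +
    curvature_gain / diameter_mm) * spatial profile: contact intensity
    grows with curvature, peaking on the central taxels.  Cylinders decay
    across one grid axis only, spheres across both.  Reactive mode
    superimposes a damped impact transient (dropped 20 g weight) at
    ``impact_time_ms``.  ``amplitude_jitter_sd`` is the per-touch
    multiplicative grip-force variability; ``noise_sd`` is additive white
    sample noise.
    """

    shape: str = "cylinder"
    diameter_mm: float = 100.0
    mode: str = "active"
    duration_ms: float = 1000.0
    dt: float = 0.1
    onset_ms: float = 100.0
    ramp_ms: float = 100.0
    impact_time_ms: float = 500.0
    impact_mass_g: float = 20.0
    impact_peak_factor: float = 3.0
    impact_tau_ms: float = 25.0
    dropout_depth: float = 0.3
    dropout_ms: float = 30.0
    base_amplitude: float = 0.18
    curvature_gain: float = 9.0
    profile_sigma: float = 1.5
    amplitude_jitter_sd: float = 0.05
    noise_sd: float = 0.0
    rows: int = 6
    cols: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError("shape must be 'cylinder' or 'sphere'")
        if self.mode not in ("active", "reactive"):
            raise ValueError("mode must be 'active' or 'reactive'")
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        if self.mode == "reactive" and not 0 < self.impact_time_ms < self.duration_ms:
            raise ValueError("impact_time_ms must fall within the trial")

    @property
    def plateau_amplitude(self) -> float:
        return self.base_amplitude + self.curvature_gain / self.diameter_mm


def _spatial_profile(scenario: GraspScenario) -> np.ndarray:
    r = np.arange(scenario.rows) - (scenario.rows - 1) / 2.0
    c = np.arange(scenario.cols) - (scenario.cols - 1) / 2.0
    rr, cc = np.meshgrid(r, c, indexing="ij")
    s2 = 2.0 * scenario.profile_sigma ** 2
    if scenario.shape == "sphere":
        prof = np.exp(-(rr ** 2 + cc ** 2) / s2)
    else:  # cylinder: uniform along its axis, decays across it
        prof = np.exp(-(cc ** 2) / s2) * np.ones_like(rr)
    return prof.ravel()


def _impact_pulse(t_ms: np.ndarray, t0: float, tau: float) -> np.ndarray:
    """Critically damped (alpha-function) pulse, unit peak at t0 + tau."""
    s = np.clip(t_ms - t0, 0.0, None)
    return (s / tau) * np.exp(1.0 - s / tau)


def generate_grasp_scenario(scenario: GraspScenario) -> SensorTraceArray:
    """Render a scenario into a per-taxel drive trace, reproducible from seed."""
    n = int(round(scenario.duration_ms / scenario.dt)) + 1
    t = np.arange(n) * scenario.dt
    rng = np.random.default_rng(scenario.seed)

    # smooth contact onset: raised-cosine ramp to the plateau
    x = np.clip((t - scenario.onset_ms) / scenario.ramp_ms, 0.0, 1.0)
    onset = 0.5 * (1.0 - np.cos(np.pi * x))

    jitter = 1.0 + scenario.amplitude_jitter_sd * rng.standard_normal()
    amp = scenario.plateau_amplitude * max(jitter, 0.0)
    envelope = amp * onset

    if scenario.mode == "reactive":
        mass_scale = scenario.impact_mass_g / 20.0
        pulse = _impact_pulse(t, scenario.impact_time_ms, scenario.impact_tau_ms)
        envelope = envelope + scenario.impact_peak_factor * mass_scale * amp * pulse
        # brief drive dropout right after the impact, mimicking slip shear
        drop = _impact_pulse(t, scenario.impact_time_ms + scenario.impact_tau_ms,
                             scenario.dropout_ms / 3.0)
        envelope = envelope * (1.0 - scenario.dropout_depth * drop)

    profile = _spatial_profile(scenario)
    data = profile[:, None] * envelope[None, :]
    if scenario.noise_sd > 0:
        data = data + scenario.noise_sd * rng.standard_normal(data.shape)
    data = np.clip(data, 0.0, None)

    annotations = {"contact_onset_ms": scenario.onset_ms}
    if scenario.mode == "reactive":
        annotations["impact_ms"] = scenario.impact_time_ms
    return SensorTraceArray(data, scenario.dt, scenario.rows, scenario.cols,
                            annotations)


def scenario_response_source(
    base_scenario: GraspScenario,
    *,
    afferent_params: IzhikevichParams = SAI_PARAMS,
    gain_cuneate: float = 1.0,
    seed: int | None = None,
):
    """Build a ``(shape, diameter_mm, touch) -> cuneate SpikeTrain`` callable.

    Each touch derives its own seed from (protocol seed, shape, diameter,
    touch index), so repeated touches differ only through the scenario's
    stochastic terms.
    """
    from dataclasses import replace
    from .cuneate import afferent_to_cuneate

    proto_seed = base_scenario.seed if seed is None else seed

    def source(shape: str, diameter_mm: float, touch: int) -> SpikeTrain:
        shape_code = 0 if shape == "cylinder" else 1
        touch_seed = int(np.random.SeedSequence(
            [proto_seed, shape_code, int(diameter_mm), touch]
        ).generate_state(1)[0] % (2 ** 31))
        sc = replace(base_scenario, shape=shape, diameter_mm=diameter_mm,
                     seed=touch_seed)
        trace = generate_grasp_scenario(sc)
        resp = afferent_to_cuneate(trace, afferent_params,
                                   gain_cuneate=gain_cuneate, seed=proto_seed)
        return resp.cuneate_train

    return source


def generate_synergy_emg(
    activation: np.ndarray,
    weights: np.ndarray,
    *,
    fs: float = 2000.0,
    noise_fraction: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Raw surface-EMG-like traces with low-rank synergy structure.

    ``activation`` is (k, n_samples) (or 1-D for one synergy) and
    ``weights`` (n_muscles, k): each channel's amplitude is the synergy
    mixture W @ H, slowly perturbed by ``noise_fraction`` multiplicative
    noise plus a small noise floor, and modulates a band-limited
    (20-450 Hz) zero-mean carrier.
    """
    activation = np.atleast_2d(np.asarray(activation, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if weights.ndim == 1:
        weights = weights[:, None]
    if np.any(activation < 0) or np.any(weights < 0):
        raise ValueError("activation and weights must be nonnegative")
    if weights.shape[1] != activation.shape[0]:
        raise ValueError("weights and activation ranks disagree")
    rng = np.random.default_rng(seed)
    amplitude = weights @ activation  # n_muscles x n
    n_muscles, n = amplitude.shape

    from scipy.signal import butter, sosfiltfilt
    sos = butter(4, (20.0, min(450.0, 0.45 * fs)), btype="bandpass", fs=fs,
                 output="sos")
    carrier = sosfiltfilt(sos, rng.standard_normal((n_muscles, n)), axis=1)
    carrier /= np.std(carrier, axis=1, keepdims=True)

    sos_slow = butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
    slow = sosfiltfilt(sos_slow, rng.standard_normal((n_muscles, n)), axis=1)
    slow /= np.maximum(np.std(slow, axis=1, keepdims=True), 1e-12)

    floor = 0.02 * max(float(amplitude.max()), 1e-12)
    amp = np.clip(amplitude * (1.0 + noise_fraction * slow), 0.0, None) \
        + noise_fraction * floor
    return amp * carrier


@dataclass
class GraspPlant:
    """Minimal grasp plant: grip command -> contact pressure, with slip.

    Contact pressure equals grip_stiffness * applied grip while the object
    is held.  The object is lost (permanently: pressure and tactile drive
    drop to zero) the moment pressure falls below the slip threshold,
    which rises transiently during an impact.  The grip command is
    actuated after ``motor_delay_ms`` and capped at ``max_grip``
    (= 100% MVC).
    """

    grip_stiffness: float = 1.0
    object_weight: float = 0.05      # baseline slip threshold, pressure units
    slip_impact_gain: float = 5.0    # threshold multiplier at impact peak
    impact_rise_ms: float = 200.0
    impact_decay_ms: float = 300.0
    motor_delay_ms: float = 80.0
    max_grip: float = 1.0
    pretension: float = 0.12         # firm initial grasp the trial starts from
    sensor_scale: float = 2.5        # pressure -> sensor drive (identity map, scaled)
    sensor_max: float = 1.5          # drive saturation of the piezoresistive array

    def __post_init__(self) -> None:
        if self.object_weight <= 0 or self.grip_stiffness <= 0:
            raise ValueError("thresholds must be positive")
        if self.motor_delay_ms < 0:
            raise ValueError("motor delay must be nonnegative")

    def slip_threshold(self, t_ms: float, scenario: GraspScenario) -> float:
        thr = self.object_weight
        if scenario.mode == "reactive":
            s = t_ms - scenario.impact_time_ms
            if s > 0:
                rise = min(s / self.impact_rise_ms, 1.0)
                decay = np.exp(-max(s - self.impact_rise_ms, 0.0) / self.impact_decay_ms)
                mass_scale = scenario.impact_mass_g / 20.0
                thr = thr * (1.0 + self.slip_impact_gain * mass_scale * rise * decay)
        return thr


def run_closed_loop(
    controller: TransferFunctionModel | float,
    plant: GraspPlant,
    scenario: GraspScenario,
    *,
    sai_params: IzhikevichParams = SAI_PARAMS,
    cuneate_params: IzhikevichParams | None = None,
    kernel_spec: PSPKernelSpec | None = None,
    gain_cuneate: float = 1.0,
    control_dt_ms: float = 10.0,
    rate_window_ms: float = 200.0,
    rate_smoothing_tau_ms: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the sensorimotor loop for one grasp trial.

    Per control step: contact pressure (from the delayed grip command and
    the plant) plus any impact transient drive the 6x6 SAI encoding; the
    afferent spikes are low-pass filtered by the PSP kernel dynamics and
    summed into the winner cuneate unit, whose trailing-window firing
    rate feeds the controller (a transduction transfer function, or a
    constant MVC fraction).  Returns a log with columns time_ms,
    pressure, grip_cmd, cuneate_rate, activation, slip_flag.
    """
    if controller is None:
        raise ValueError("a controller (model or constant MVC level) is required")
    if cuneate_params is None:
        cuneate_params = SAI_PARAMS.replace(unit_type="cuneate")
    if kernel_spec is None:
        kernel_spec = PSPKernelSpec(dt=scenario.dt)
    dt = scenario.dt
    n_tax = scenario.rows * scenario.cols
    profile = _spatial_profile(scenario)
    rng = np.random.default_rng(seed)

    # PSP kernel as a pair of first-order filters (double exponential)
    tau_s, tau_f = kernel_spec.tau_slow, kernel_spec.tau_fast
    decay_s, decay_f = np.exp(-dt / tau_s), np.exp(-dt / tau_f)
    kern_norm = 1.0 / psp_kernel(kernel_spec).max() if kernel_spec.normalize else 1.0

    # controller discretization at the control rate
    is_constant = not isinstance(controller, TransferFunctionModel)
    if not is_constant:
        from scipy.signal import cont2discrete
        sysd = cont2discrete((controller.num, controller.den),
                             control_dt_ms / 1000.0, method="zoh")
        numd, dend = np.asarray(sysd[0]).ravel(), np.asarray(sysd[1]).ravel()
        u_hist = np.zeros(numd.size)
        y_hist = np.zeros(dend.size - 1)

    n_steps = int(round(scenario.duration_ms / control_dt_ms))
    sub = int(round(control_dt_ms / dt))
    delay_steps = int(round(plant.motor_delay_ms / control_dt_ms))
    grip_queue = [plant.pretension] * max(delay_steps, 1)

    v = np.full(n_tax, -70.0)
    u = sai_params.b * v
    vc, uc = -70.0, cuneate_params.b * -70.0
    pend = np.zeros(n_tax, dtype=bool)
    pend_c = False
    s_slow = np.zeros(n_tax)
    s_fast = np.zeros(n_tax)
    cune_spikes: list[float] = []

    contact = True
    rows = []
    impact_pulse_amp = scenario.impact_peak_factor * scenario.plateau_amplitude

    for step in range(n_steps):
        t_ms = step * control_dt_ms
        grip_applied = grip_queue.pop(0) if not is_constant else controller * plant.max_grip
        pressure = plant.grip_stiffness * grip_applied if contact else 0.0

        if contact and pressure < plant.slip_threshold(t_ms, scenario):
            contact = False
            pressure = 0.0

        # sensor drive over this control interval
        if contact:
            base_amp = min(plant.sensor_scale * pressure, plant.sensor_max)
            tt = t_ms + np.arange(sub) * dt
            env = np.full(sub, base_amp)
            if scenario.mode == "reactive":
                env = env + impact_pulse_amp * _impact_pulse(
                    tt, scenario.impact_time_ms, scenario.impact_tau_ms)
            drive = profile[:, None] * env[None, :]
            if scenario.noise_sd > 0:
                drive = np.clip(
                    drive + scenario.noise_sd * rng.standard_normal(drive.shape),
                    0.0, None)
        else:
            drive = np.zeros((n_tax, sub))

        I = sai_params.K * drive / sai_params.Cm
        for k in range(sub):
            stepping = ~pend
            v_next = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I[:, k])
            v = np.where(stepping, v_next, sai_params.c)
            u = np.where(stepping, u + dt * sai_params.a * (sai_params.b * v - u), u)
            fired = stepping & (v >= sai_params.v_peak)
            s_slow *= decay_s
            s_fast *= decay_f
            if np.any(fired):
                u = np.where(fired, u + sai_params.d, u)
                s_slow[fired] += 1.0
                s_fast[fired] += 1.0
            pend = fired
            psp_total = kern_norm * float(np.sum(s_slow - s_fast))

            Ic = gain_cuneate * psp_total / cuneate_params.Cm
            if pend_c:
                vc = cuneate_params.c
                pend_c = False
            else:
                vc = vc + dt * (0.04 * vc * vc + 5.0 * vc + 140.0 - uc + Ic)
                uc = uc + dt * cuneate_params.a * (cuneate_params.b * vc - uc)
                if vc >= cuneate_params.v_peak:
                    cune_spikes.append(t_ms + (k + 1) * dt)
                    uc += cuneate_params.d
                    pend_c = True

        t_end = t_ms + control_dt_ms
        w0 = t_end - rate_window_ms
        n_recent = sum(1 for s in cune_spikes if s > w0)
        raw_rate = n_recent / (min(rate_window_ms, t_end) / 1000.0) if t_end > 0 else 0.0
        # exponential smoothing irons out the one-spike quantization of the
        # trailing-window count before it reaches the controller
        if step == 0:
            rate = raw_rate
        else:
            alpha = control_dt_ms / (control_dt_ms + rate_smoothing_tau_ms)
            rate = rate + alpha * (raw_rate - rate)

        if is_constant:
            activation = float(controller)
            grip_cmd = activation * plant.max_grip
        else:
            u_hist = np.roll(u_hist, 1)
            u_hist[0] = rate
            y_new = float(numd @ u_hist - dend[1:] @ y_hist)
            y_hist = np.roll(y_hist, 1)
            y_hist[0] = y_new
            activation = max(y_new, 0.0)
            grip_cmd = min(plant.pretension + activation * plant.max_grip,
                           plant.max_grip)
            grip_queue.append(grip_cmd)

        rows.append((t_ms, pressure, grip_cmd, rate, activation, not contact))

    log = pd.DataFrame(rows, columns=["time_ms", "pressure", "grip_cmd",
                                      "cuneate_rate", "activation", "slip_flag"])
    log.attrs["seed"] = seed
    log.attrs["controller"] = ("constant" if is_constant else controller.structure)
    return log
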