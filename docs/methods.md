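# Methods

This note records the models implemented in `tactosense`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the design decisions taken where the modelling was genuinely
open.

## First-order afferent model

Tactile afferents are modelled with the Izhikevich neuron.  The membrane
state (v, u) obeys

    dv/dt = 0.04 v² + 5 v + 140 − u + I/Cm
    du/dt = a (b v − u)
    if v ≥ 30 mV:  v ← c,  u ← u + d

with v in mV and time in ms.  The drive I is the gain-ported sensor
current K·I_sensor(t) for SAI units and K·|dI_sensor/dt| for FAI units,
which reproduces the defining slowly/fast-adapting behaviors: SAI fires
throughout a held pressure, FAI only at stimulus transients.  The
derivative is rectified by default so that both contact onset and release
excite the FAI unit — fast-adapting afferents respond to both transients —
with a signed mode available (`signed_derivative=True`).

Parameter sets (one per unit type):

| set | a (1/ms) | b | c (mV) | d (mV) | K |
|---|---|---|---|---|---|
| initialization | 0.02 | 0.200 | −65.0 | 6.00 | 25 |
| SAI (calibrated) | 0.02 | 0.205 | −65.0 | 6.20 | 55 |
| FAI (calibrated) | 0.02 | 0.210 | −65.5 | 6.15 | 56 |

Only the ratio K/Cm is identifiable, so all gain is folded into K with
Cm = 1 (overridable).  Unit physics of I_sensor are left as arbitrary
units: the sensor is piezoresistive and its calibration is outside this
package's scope; a configurable linear pressure→current scale stands in.

Numerics: fixed-step forward Euler, default dt = 0.1 ms, v updated before
u each step (the model's original ordering).  A spike is recorded at the
first sample where v reaches 30 mV; that sample stores the 30 mV peak,
the next sample shows the reset value c exactly, and integration resumes
from c afterwards.  Initial state is the rest point v₀ = −70 mV,
u₀ = b·v₀.  A dt of 1 ms or coarser triggers a warning; tests hold the
dt = 0.1 ms solution to within ±1 spike/s of a dt = 0.01 ms reference.

Calibration (`fit_afferent_params`) maximizes the fractional
sum-of-squares FSS = 1 − Σ(measᵢ−predᵢ)²/Σmeasᵢ² over a stimulus→rate
table using a seeded coarse grid followed by Nelder–Mead refinement —
a deterministic, derivative-free stand-in for response-surface
optimization, of which only the objective and endpoints are specified.
Fewer than three reference points sets an `underdetermined` flag; a
search that cannot improve on the initialization returns it with
`improved=False`.

## Second-order (cuneate) layer

Each afferent spike evokes a postsynaptic potential modelled as the
causal double exponential

    PSP(t) = exp(−t/τ_slow) − exp(−t/τ_fast),   τ_fast = 4 ms, τ_slow = 12.5 ms,

peak-normalized, sampled to a 100 ms horizon.  (A positive-exponent or
τ_rise > τ_decay reading of this kernel diverges; the implementation
orients τ_slow = max of the pair so the kernel is nonnegative and decays.
Its peak sits at t* = τs·τf/(τs−τf)·ln(τs/τf), which the tests check.)
Afferent PSP series are the convolution of the kernel with the spike
indicator (spike times binned to the sample grid).

Wiring uses the feed-forward divergence/convergence ratio 1700/300: n
active afferents recruit ⌈n·1700/300⌉ cuneate units (100 → 567).  Each
cuneate unit samples min(n_afferents, 300) distinct afferents uniformly
without replacement, reproducibly from a seed; with the 36-taxel array the
cap is not binding and every unit integrates all 36 afferents.  Synaptic
weights are +1; a configurable fraction of edges can be made inhibitory
(−1) as an extension point for interneuron modelling — the default is
purely excitatory since no inhibitory kinetics are specified.

PSP_total per cuneate unit is the signed weighted sum of its afferent PSP
series.  Winner-take-all selects the unit with the largest
*time-integrated* PSP_total over the trial (trapezoid rule, ties to the
lowest index); the integral was chosen over the instantaneous maximum
because it is stable under sample-level noise and directly testable
against a brute-force oracle.  The winner's PSP_total, scaled by
`gain_cuneate` (default 1), drives an Izhikevich unit re-using the
calibrated SAI parameters (no separate cuneate calibration data exists;
both choices are config-overridable).

## Spike metrics

Victor–Purpura distance: dynamic program over the (nA+1)×(nB+1) matrix
with insertion/deletion cost 1 and shift cost q·|Δt|; q defaults to
0.05/ms (a 20 ms temporal precision, mid-range for this metric) and is
recorded in every output since no value is prescribed.  At q = 0 the
distance collapses to |nA − nB|; it never exceeds nA + nB.  The DP is
verified against exhaustive enumeration of all monotone spike matchings
on small trains.  Rates are counts over a window; binned rates use 200 ms
bins; first-spike latency is measured from a stated onset and is absent
when no spike follows it.

## Discrimination protocol

Each shape (cylinder, sphere) is touched 10 times per diameter
{50…100 mm}; the 100 mm object is the baseline.  Features per touch come
from the winning cuneate unit over the 1000 ms trial: its spike rate
(rate coding) and VP distances.  For VP, "noise" is the C(10,2) = 45
pairwise distances among baseline touches and "signal" is one distance
per target touch against the same-index baseline touch — 10 per object,
50 per shape, 100 across both shapes.  (Full 10×10 cross-pairing is
available via `vp_pairing="full"`.)  Sensitivity is
d′ = (μ_signal − μ_noise)/√((σ²_signal + σ²_noise)/2) — the rms of the
two sds handles unequal variances — and accuracy is reported as the
percent correct of the unbiased yes/no observer, hit rate = Φ(d′/2).
Degenerate feature sets (zero pooled sd) are flagged rather than fatal.

## Muscle synergies

Raw EMG is band-passed 20–450 Hz (4th-order Butterworth, zero-phase),
full-wave rectified, low-passed at 4 Hz, optionally unit-maximum
normalized per channel and decimated — conventional synergy-analysis
settings, all configurable, since no preprocessing pipeline is
prescribed for the named hardware.  NMF uses multiplicative updates on
the squared error with 20 seeded restarts, 500 iterations and a 1e-6
relative tolerance (improvement measured against the starting objective;
the update's monotone non-increase is asserted numerically in tests).
It is written in-package because the per-iteration objective trace is
part of the contract; scikit-learn's implementation serves as an
independent quality cross-check in the test suite.

VAF is global and uncentered, 1 − ‖V−WH‖²_F/‖V‖²_F (a per-muscle mean
variant is provided as `vaf_per_muscle`).  The synergy count is the
smallest k with VAF > 0.85 and VAF(k+1) − VAF(k) < 0.06; at the largest k
probed the increment clause is vacuous and the threshold alone decides;
if nothing qualifies the largest k is returned with a warning flag rather
than failing.

## Transduction functions and identification

The sensorimotor mapping from second-order tactile signal S to synergy
activation is an all-pole continuous transfer function: two poles
a/(S²+bS+c) for active grasping, three poles a/(S³+bS²+cS+d) for
reactive grasping (monic denominator — the redundant leading coefficient
of the alternative printed form is normalized away).  The identification
input is the binned cuneate firing rate interpolated to the activation
sampling rate: the rate is the only scalar signal both sides share.

Simulation uses zero-order-hold discretization (`cont2discrete`) and a
direct-form filter; ZOH is exact for piecewise-constant inputs, which the
step-response tests exploit.  Fitting is output-error: for a candidate
denominator the scalar numerator has a closed-form least-squares solution
and is concentrated out, and the denominator is searched by Nelder–Mead
over log-parameterized (positive) coefficients from 10 seeded multi-starts
with pole-rate guesses log-spaced between 1/record-length and 0.3/dt.
Fit is the NRMSE goodness 1 − ‖y−ŷ‖/‖y−mean(y)‖.  Stability is checked
and flagged, not enforced.  Structure search fits each candidate pole
count (1…9 by default, i.e. bounded below 10th order) and keeps the best
fit; fits within 1e-3 are treated as ties resolved toward the lowest
order — without a numerical tie band the lowest-order rule could never
fire for nested models fit to noisy data.

`default_transduction_model` ships fixed active/reactive coefficient sets
for driving the bundled plant: DC gain 0.005 activation per spike/s
(sized so a ~50 spikes/s cuneate rate maps to a holding grip) with poles
at −8, −12 rad/s (active) and −12, −18, −25 rad/s (reactive; fast enough
to answer an impact within ~150 ms).  These are control designs for the
synthetic plant, not measured physiology.

## Synthetic generator and closed-loop plant

The generator emulates what the physical rig produced, under full seed
control.  A grasp trace is a raised-cosine contact onset (100 ms ramp at
100 ms) to a plateau whose amplitude is base + curvature_gain/diameter —
contact intensity grows with curvature — spatially weighted by a
center-peaked Gaussian profile (σ = 1.5 taxels) that decays across both
grid axes for spheres and across one axis only for cylinders.  Reactive
mode superimposes a critically-damped (alpha-function) impact transient
at 500 ms, peak 3× the plateau and ~100 ms settling for the default 20 g
mass, followed by a brief drive dropout mimicking slip shear.  Stochastic
terms: additive white sample noise (noise_sd) and a per-touch
multiplicative amplitude jitter (amplitude_jitter_sd, default 5%)
representing grip-force variability across repeated touches — the latter
is what gives the SDT feature distributions realistic spread, which
per-sample noise alone cannot (it averages out of a 1 s rate).  Default
drive constants (base 0.18, gain 9 a.u.·mm) put SAI and winner-cuneate
rates in the tens of spikes/s.

Synthetic EMG is a nonnegative synergy mixture W·H whose per-channel
amplitude, slowly perturbed by multiplicative noise plus a 2% floor,
modulates a band-limited (20–450 Hz) zero-mean carrier; its envelope is
recoverable by the synergy pipeline.

The grasp plant is deliberately minimal: contact pressure equals the
applied grip (stiffness 1) while the object is held; the object is lost —
permanently, with pressure and tactile drive falling to zero — the moment
pressure drops below a slip threshold of 0.05 pressure units, which rises
transiently to 6× during an impact (200 ms rise, 300 ms decay).  The grip
command is actuated after an 80 ms motor delay, capped at max_grip ≡ 100%
MVC; trials start from a 0.12 pretension ("grasped firmly").  Sensor
drive is 2.5× pressure, saturating at 1.5 a.u. (piezoresistive dynamic
range), plus the impact vibration while in contact.  The control step is
10 ms; the controller input is the winner-cuneate rate over a trailing
200 ms window, exponentially smoothed with a 100 ms time constant —
without smoothing, the one-spike quantization of the window count
(5 spikes/s steps) excites a delay-induced limit cycle in grip.  Under
these defaults the reactive transduction controller retains contact
through the impact in every seeded trial while a constant 10% MVC grip
always drops the object, and a no-impact trial settles to a grip plateau
(within 5% over the final 0.5 s of a 4 s trial; the loop's fixed point is
reached in ~2.5 s).

What the generator does **not** emulate: skin/finite-element contact
mechanics and strain-energy-density transduction, sensor electronics and
hysteresis, hand kinematics, somatotopy beyond a single taxel patch, and
motor-side torque dynamics.  Passing tests therefore demonstrate the
internal consistency of the computational chain and its qualitative
behaviors (curvature monotonicity, SA/FA distinction, controller
contrast), not quantitative agreement with recordings from skin, nerve or
robot.

## Reproducibility and I/O

Every stochastic stage takes an explicit seed; pipeline stages derive
per-stage seeds from a single global seed by hashing.  Numeric text
output is formatted at 12 significant digits, so identical configurations
reproduce byte-identical CSV/JSON and round-trips preserve values to
1e-12; outputs embed the configuration hash and seeds.  Problem sizes
used by the test suite — 1 s trials at dt = 0.1 ms, 10 touches per
object, 100 synergy-recovery trials, 2000-sample identification records —
were chosen as the smallest sizes at which the statistical checks are
stable.

## Known limitations

- The cuneate population under full connectivity is homogeneous, so
  winner-take-all is degenerate (any unit ties); heterogeneity enters only
  through sub-sampled wiring when afferent count exceeds the convergence
  cap, or through inhibitory fractions.
- FAI closed-loop feedback is not used by the bundled controller; only
  SAI-path rates drive it.
- The identification supports all-pole structures (matching both
  transduction forms); models with zeros can be simulated but not fitted.
- d′ assumes Gaussian features; spike-count features at low rates are
  discrete and mildly skewed, which the unbiased-observer hit rate
  inherits.
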