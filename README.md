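# tactosense

Neuromorphic tactile sensing and sensorimotor control for robotic/prosthetic
grasping, as a tested Python library: it models the chain from a 6×6
fingertip pressure-sensor array all the way to grip-force commands.

The pipeline, stage by stage:

1. **Afferent encoding** (`tactosense.encoder`) — per-taxel sensor current
   I_sensor(t) is gain-ported (I = K·I_sensor) and fed through the
   Izhikevich spiking-neuron model

   dv/dt = 0.04v² + 5v + 140 − u + K·I/Cm,  du/dt = a(bv − u),
   with reset v←c, u←u+d whenever v ≥ 30 mV,

   to produce slowly-adapting (SAI, drive = I) and fast-adapting (FAI,
   drive = |dI/dt|) type-I afferent spike trains.  Parameters are
   calibrated against stimulus→firing-rate tables by maximizing the
   fractional sum-of-squares goodness FSS = 1 − Σ(exp−pre)²/Σexp².
2. **Cuneate layer** (`tactosense.cuneate`) — spikes are convolved with a
   double-exponential PSP kernel (τ = 4 and 12.5 ms), wired onto the
   recruited second-order population under the 1700/300
   divergence/convergence ratio (100 active afferents ⇒ 567 cuneate
   units), summed with signed synaptic weights, and the winner-take-all
   unit (largest time-integrated PSP_total) spikes through the same
   Izhikevich dynamics.
3. **Spike metrics** (`tactosense.metrics`) — firing rate, 200-ms binned
   counts, first-spike latency, and the Victor–Purpura edit distance
   (insert/delete cost 1, shift cost q per ms; default q = 0.05/ms).
4. **Discrimination** (`tactosense.discrimination`) — repeated touches of
   a 100 mm baseline cylinder/sphere vs smaller targets build "noise" and
   "signal" feature sets; sensitivity d′ = Δmean / rms(sd) and the
   unbiased hit rate Φ(d′/2) quantify object-size discrimination by rate
   coding and by VP distance.
5. **Muscle synergies** (`tactosense.synergy`) — multichannel EMG
   envelopes are factorized V ≈ WH by multiplicative-update NMF; the
   synergy count is the smallest k with VAF > 85% and < 6% gain from one
   more synergy.
6. **Transduction identification** (`tactosense.sysid`) — the mapping from
   cuneate rate to synergy activation is fit as a/(S² + bS + c) for
   active grasping and a/(S³ + bS² + cS + d) for reactive grasping by
   output-error system identification, with an order search.
7. **Closed loop** (`tactosense.synthetic`) — a seeded generator of grasp
   scenarios (curvature-dependent contact, 20 g impact transients) and
   synergy-structured EMG, plus a minimal grasp plant on which the
   transduction controller is deployed and contrasted with constant
   10%/100% MVC grips.

## Worked example

```python
import numpy as np
from tactosense import (GraspScenario, generate_grasp_scenario,
                        afferent_to_cuneate, firing_rate, recruited_count)

print(recruited_count(100))   # cuneate units recruited by 100 afferents
for d in (50.0, 75.0, 100.0):
    sc = GraspScenario(shape="cylinder", diameter_mm=d,
                       noise_sd=0.0, amplitude_jitter_sd=0.0, seed=1)
    resp = afferent_to_cuneate(generate_grasp_scenario(sc))
    print(f"{d:5.0f} mm  cuneate rate {firing_rate(resp.cuneate_train):5.1f} spikes/s")
```

prints

```
567
   50 mm  cuneate rate  65.0 spikes/s
   75 mm  cuneate rate  56.0 spikes/s
  100 mm  cuneate rate  51.0 spikes/s
```

567 is the second-order recruitment implied by the 1700/300 ratio, and the
winner-cuneate firing rate falls monotonically with object diameter: higher
surface curvature drives the array harder, which is exactly the cue the
discrimination stage exploits.  The `examples/` directory has one short
script per capability (encoding, cuneate integration, discrimination,
synergies, identification, closed loop), each printing the numbers it
computes and what they mean.

## Command line

A thin CLI wraps the library:

```bash
tactosense simulate --shape cylinder --diameter 60 --seed 1 --out trace.csv
tactosense encode --input trace.csv --unit sai --out spikes.json
tactosense metrics rate --spikes spikes.json
tactosense closed-loop --mode reactive --controller transduction --out loop.csv
tactosense run --config cfg.yaml        # whole pipeline from a YAML config
```

Every command logs to stderr, writes a JSON run manifest next to its
outputs, and formats numbers at fixed precision so identical configurations
reproduce byte-identical files.

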