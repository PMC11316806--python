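"""Muscle-synergy extraction from synthetic three-muscle EMG.

Builds raw EMG from a single shared activation (one synergy) plus 10%
noise, recovers the envelope, factorizes with NMF for k = 1..3 and
applies the VAF rule (> 85% with < 6% gain from one more synergy).
"""

import numpy as np

from tactosense import emg_envelope, extract_synergies, generate_synergy_emg

fs = 2000.0
t = np.linspace(0, 1, 4000)
activation = np.clip(np.sin(np.pi * t), 0, None)       # one grasp burst
weights = np.array([1.0, 0.7, 0.4])                    # FDP, FDS, FPL loading

raw = generate_synergy_emg(activation, weights, fs=fs, noise_fraction=0.10,
                           seed=3)
# keep per-channel scale (normalize=False) so the weight ratios survive
envelope = emg_envelope(raw, fs, target_fs=100.0, normalize=False,
                        labels=("FDP", "FDS", "FPL"))
decomp = extract_synergies(envelope, max_k=3, seed=0)

for k in sorted(decomp.vaf_by_k):
    print(f"k={k}: VAF = {decomp.vaf_by_k[k]:.4f}")
print(f"selected synergy count: {decomp.selected_k}")
print(f"true weight ratios:      {np.round(weights / weights.max(), 3)}")
print(f"recovered weight ratios: {np.round(decomp.W[:, 0] / decomp.W[:, 0].max(), 3)}")

print("\nA single synergy already explains >90% of the envelope variance and")
print("adding more gains <6%, so the rule selects k=1 -- one shared neural")
print("activation drives all three forearm muscles during the grasp.")
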