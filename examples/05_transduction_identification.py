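"""Identify the sensorimotor transduction function from input/output data.

Simulates a known active-grasp model a/(S^2 + bS + c), adds 1% noise,
re-identifies the coefficients by output-error fitting, and runs the
order search to confirm the two-pole structure wins.
"""

import numpy as np
from scipy.signal import butter, sosfiltfilt

from tactosense import TransferFunctionModel, fit_transfer_function, \
    select_structure, tf_simulate

dt = 0.01  # s
true = TransferFunctionModel([2.0], [1.0, 3.0, 5.0], structure="active")

rng = np.random.default_rng(1)
sos = butter(3, 2.0, fs=1 / dt, output="sos")
u = sosfiltfilt(sos, rng.standard_normal(2000))
u /= np.abs(u).max()                       # band-limited afferent-rate input
y = tf_simulate(true, u, dt)
y_noisy = y + 0.01 * y.std() * rng.standard_normal(y.size)

model = fit_transfer_function(u, y_noisy, "active", dt, seed=0)
print(f"true   a/(S^2+bS+c): a={true.num[0]:.3f}, b={true.den[1]:.3f}, c={true.den[2]:.3f}")
print(f"fitted a/(S^2+bS+c): a={model.num[0]:.3f}, b={model.den[1]:.3f}, "
      f"c={model.den[2]:.3f}  (NRMSE fit {model.fit:.4f})")

search = select_structure(u, y_noisy, candidates=(1, 2, 3, 4), dt=dt, seed=0)
print(f"order search over 1-4 poles picks {search.order()} poles")

print("\nCoefficients come back within a few percent and the parsimonious")
print("two-pole structure wins the search: the identification recovers the")
print("active-grasp transduction dynamics from noisy records.")
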