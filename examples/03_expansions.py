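"""Weak-non-Markovian expansions of the persistence exponent.

Evaluates the second-order expansions around H = 1/2 for the quench
(type I) and past-observation (type II) problems and prints the
temperature dependence they predict.
"""

import numpy as np

from quenchfp import theta_I_expansion, theta_II_expansion

print("type I (temperature quench), H = 0.54:")
for T in (0.0, 0.5, 1.0, 2.0):
    th = theta_I_expansion(0.54, T)
    print(f"   T = {T:3.1f}: theta_I = {th:.4f}   "
          f"(1 - H = {1 - 0.54:.2f})")

print("type II (observed past):")
for H in (0.4, 0.45, 0.5, 0.55, 0.6):
    th = theta_II_expansion(H)
    print(f"   H = {H:4.2f}: theta_II = {th:.5f}  >=  1 - H = {1-H:.2f}  "
          f"(excess {th - (1 - H):+.5f})")

# Observing the past can only accelerate the effective kinetics:
# theta_II - (1 - H) = 4 ln 2 (H - 1/2)^2 >= 0, while a quench moves
# theta in either direction depending on whether T < 1 or T > 1.
print("\n4 ln 2 =", round(4 * np.log(2), 5))
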