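"""Indirect Fourier transform: P(r), Dmax scanning and I(0) extrapolation.

Inverts a noisy sphere curve to its pair-distance distribution, checks the
recovered Rg against the closed-form sphere value, and shows how a Dmax
scan exposes the true maximum dimension.
"""

import numpy as np

from bundlesans import SyntheticSpec, generate_curve, ift, scan_dmax

radius = 25.82  # sphere with Rg = sqrt(3/5) R = 20.0 A
curve, truth = generate_curve(SyntheticSpec(
    "sphere", {"radius": radius, "i0": 1.0},
    q_grid=(0.01, 0.35, 150, "linear"), seed=3))

res = ift(curve, dmax=2 * radius, q_range=(0.01, 0.35))
print(f"P(r) inversion: Rg = {res.rg:.2f} +/- {res.rg_err:.2f} A "
      f"(sphere value {np.sqrt(3 / 5) * radius:.2f}), "
      f"I(0) = {res.i0:.3f}, chi2_red = {res.chi2_reduced:.2f}, "
      f"alpha = {res.alpha:.2e}")
print(f"P(r) peak at r = {res.r[np.argmax(res.pr)]:.1f} A "
      f"(sphere peak is near 1.05 R = {1.05 * radius:.1f} A)")

print("\nDmax scan (the caller picks the elbow / best quality):")
for row in scan_dmax(curve, [40, 48, 2 * radius, 56, 64], q_range=(0.01, 0.35)):
    print(f"  dmax {row['dmax']:5.1f} A  chi2_red {row['chi2_reduced']:7.3f}  "
          f"Rg {row['rg']:5.2f}  quality {row['quality']:.2f}")

# chi2 drops sharply when dmax reaches the true diameter (51.6 A) and then
# flattens; the oscillation-penalty quality score saturates at the same
# point — the elbow marks Dmax.
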