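"""Guinier analysis of a computed curve.

A uniform ball of radius R has Rg = sqrt(3/5) R; the vacuum intensity
of 2000 points filling a 20 A sphere should therefore yield
Rg ≈ 15.49 A from the low-q Guinier fit ln I ≈ ln I0 − q²Rg²/3.
"""

import numpy as np

from solvaxs import QGrid, guinier_fit, load_default_table, vacuum_intensity

rng = np.random.default_rng(7)
pts = []
while len(pts) < 2000:
    cand = rng.uniform(-1, 1, (4000, 3))
    pts.extend(cand[np.sum(cand * cand, axis=1) <= 1.0].tolist())
coords = 20.0 * np.asarray(pts[:2000])

table = load_default_table()
curve = vacuum_intensity(coords, ["C"] * 2000, table, QGrid.uniform(0.12, 30))
g = guinier_fit(curve)

print(f"I(0) = {g.I0:.4e} e^2")
print(f"Rg   = {g.Rg:.3f} A   (analytic sqrt(3/5)*20 = {np.sqrt(3 / 5) * 20:.3f} A)")
print(f"window: q in [{g.q_range_used[0]:.4f}, {g.q_range_used[1]:.4f}] A^-1, "
      f"{g.n_points} points with q*Rg <= 1.3")
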