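"""Relative pressure mapping and P<0 helix extraction on a vortex phantom.

Builds a steady Rankine-vortex tube phantom, recovers the relative pressure
map from the velocity field via the Navier-Stokes momentum balance, and
compares the solved vortex-core pressure deficit with the analytic closed
form.  The P < 0 mmHg region is then compared with the true vortex core.
"""

import numpy as np

from helixflow import helix_mask, postprocess_pressure
from helixflow.phantom import (analytic_rankine_pressure, make_tube_phantom,
                               preset_rankine_steady)
from helixflow.pressure import (PressureSolverConfig, pressure_gradient,
                                solve_relative_pressure)

spec = preset_rankine_steady()          # Omega 100 rad/s, core 5 mm, 2 mm grid
field, mask, cl, gt = make_tube_phantom(spec)

cfg = PressureSolverConfig()
G = pressure_gradient(field, mask, cfg)
raw = solve_relative_pressure(G[..., :1], mask, cfg)

idx = np.argwhere(mask.voxels)
r = np.hypot(*(mask.origin[:2, None] + idx[:, :2].T * mask.spacing[:2, None]))
core = r <= 5.0
pa = analytic_rankine_pressure(r[core])
ps = raw.values[..., 0][mask.voxels][core]
err = np.linalg.norm((ps - ps.mean()) - (pa - pa.mean())) / np.linalg.norm(pa - pa.mean())

print(f"analytic axis pressure deficit : {gt.core_pressure_deficit_mmhg:.3f} mmHg")
print(f"solved core profile rel. L2 err: {100 * err:.1f} %")
print(f"solver iterations (converged)  : {raw.iterations[0]} ({bool(raw.converged[0])})")

pp = postprocess_pressure(raw)
hm = helix_mask(pp)
flagged = hm.voxels[..., 0]
truth = np.zeros(mask.shape, bool)
truth[tuple(idx[core].T)] = True
dice = 2 * (flagged & truth).sum() / (flagged.sum() + truth.sum())
print(f"P<0 region vs true vortex core : Dice {dice:.2f}")
print("A Dice well above 0.5 means the negative-pressure threshold finds the")
print("vortex core; the residual error is finite-difference discretisation.")
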