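"""Linking registrations = composing transforms.

Builds two random smooth B-spline free-form deformations, composes them into
a dense displacement field, and compares the interpolated composition with
the exact function composition — the cheap field-based linking loses almost
nothing.
"""

import numpy as np

import atlaslink as al
from atlaslink.synthetic import random_ffd

grid = al.ImageGrid((32, 32, 24), (2.0, 2.0, 3.0))
rng = np.random.default_rng(0)
t_outer = random_ffd(grid, 12.0, 1.5, rng)
t_inner = random_ffd(grid, 12.0, 1.5, rng)

linked = al.compose(t_outer, t_inner, grid)

pts = rng.uniform(grid.origin, np.asarray(grid.origin) + grid.extent, (2000, 3))
exact = t_outer.evaluate(t_inner.evaluate(pts))
approx = linked.evaluate(pts)
err = np.linalg.norm(approx - exact, axis=1)

print(f"composed field on a {grid.shape} grid, voxel {grid.spacing} mm")
print(f"vs exact functional composition at 2000 random points:")
print(f"  mean error {err.mean():.4f} mm, max {err.max():.4f} mm")
print("One trilinear interpolation per link is enough: the discrepancy is far")
print("below voxel size, so linking through stored fields is essentially free.")
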