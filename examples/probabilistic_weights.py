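"""Similarity-driven fusion weights and the k/s slope-angle parameterization.

Draws (SIM, DSC) pairs from the linear quality-vs-similarity model, shows
that the slope-angle form of k/s evaluated at the regression angle equals
slope / residual-sd, and prints the erf weights it implies for a set of
atlas similarities.
"""

import math

import numpy as np

import atlaslink as al

data = al.simulate_sim_dsc(500, k=1.5, s=0.06, seed=1, intercept=0.35)
sims, dscs = data[:, 0], data[:, 1]

slope, intercept = np.polyfit(sims, dscs, 1)
resid = dscs - (slope * sims + intercept)
direct = slope / math.sqrt(np.mean(resid**2))
theta = math.degrees(math.atan(slope))
via_theta = al.k_over_s_from_theta(theta, sims, dscs)
print(f"OLS slope {slope:.3f}, residual sd {math.sqrt(np.mean(resid**2)):.4f}")
print(f"k/s directly: {direct:.3f}   via slope angle {theta:.2f} deg: {via_theta:.3f}")

print("\natlas similarities -> fusion weights (k/s = %.1f):" % via_theta)
atlas_sims = [0.95, 0.92, 0.88, 0.80]
best = max(atlas_sims)
for sim in atlas_sims:
    w = al.probabilistic_weight(sim, best, via_theta)
    print(f"  SIM = {sim:.2f}  ->  w = {w:.3f}")
print("The most similar atlas always gets 1/2; weights decay with the similarity gap.")
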