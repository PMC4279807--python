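# atlaslink

Multi-atlas segmentation label fusion with **linked deformable
registrations** — a toolkit for radiotherapy-style autosegmentation research.

## The problem

Multi-atlas segmentation transfers expert contours from several reference
images (atlases) to a new patient via deformable registration and fuses the
proposals into one consensus contour. Registering every atlas at runtime is
slow. If atlas-to-atlas registrations are pre-computed, only **one** runtime
registration is needed: labels reach the patient through *linked* (composed)
transformations,

```
T_{M←I(l)←F} = T_{M←I_l} ∘ … ∘ T_{I_1←F}
```

at the price of accumulating registration error with every link. This
package provides the machinery to build, apply and evaluate that trade:

- **Transforms** — cubic B-spline free-form deformations and dense
  displacement fields, composition (one trilinear interpolation per link),
  image/mask/label warping. Pull-back convention: `R(x) = M(T(x))`.
- **Fusion** — per-structure signed Euclidean distance maps `D_j` fused as
  `D_fus = Σ w_j D_j / Σ w_j`; the consensus segmentation is the iso-level
  zero `D_fus ≤ 0`. Majority voting as a baseline.
- **Weighting** — probabilistic weights
  `w_i = ½(1 − erf((k/s)/√2 · (SIM_best − SIM_i)))` from normalized cross
  correlation computed over a distance band around each structure, with the
  `k/s` ratio calibrated by sweeping the regression slope angle
  `k/s = √N tanθ / √(ss_DSC + ss_SIM tan²θ − 2 ss_SIM,DSC tanθ)`.
- **Metrics** — Dice similarity coefficient `DSC = 2|B₁∩B₂|/(|B₁|+|B₂|)`
  and the fractional mean absolute surface distance curve (fMAD).
- **Evaluation** — the leave-one-out experiment: N(N−1) direct pairs,
  N(N−1)(N−2) one-link combinations, sampled longer chains, matched
  relative DSC changes, quartile summaries, rank-sum tests, and the linear
  fit of median DSC against link count.
- **Synthetic cohort** — a head-and-neck-like digital phantom population
  with known ground-truth correspondences and controllable registration
  error, standing in for clinical CT atlases.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import atlaslink as al

spec = al.PhantomSpec(grid=al.ImageGrid((32, 32, 24), (4.0, 4.0, 6.0)))
template = al.make_template(spec, seed=0)
cohort = al.make_population(template, al.PopulationSpec(n_atlases=4, seed=0),
                            organs=spec.organs)
provider = al.pairwise_provider(cohort, 2.5, seed=0)       # 2.5 mm RMS error
table = al.run_experiment({a.atlas_id: a for a in cohort}, provider,
                          al.ExperimentConfig(links=(0, 1, 2), n_samples=24, seed=3))
for l in sorted(table.n_links.unique()):
    med, p25, p75 = al.summarize(table[table.n_links == l].dsc)
    print(f"{l} intermediate(s): median DSC {med:.3f}  IQR [{p25:.3f}, {p75:.3f}]")
print(al.fit_link_trend([(l, al.summarize(table[table.n_links == l].dsc)[0])
                         for l in sorted(table.n_links.unique())]))
```

prints (`examples/link_decay.py`):

```
0 intermediate(s): median DSC 0.768  IQR [0.691, 0.816]
1 intermediate(s): median DSC 0.717  IQR [0.633, 0.782]
2 intermediate(s): median DSC 0.689  IQR [0.586, 0.745]
(-0.0396..., 0.764...)
```

Direct registration (0 intermediates) scores a median DSC of 0.77; each
additional composed registration costs roughly 0.04 DSC here, and the
ordinary-least-squares intercept (0.76) extrapolates to the quality of an
error-free transfer at this resolution. The other scripts in `examples/`
demonstrate distance-map fusion, probabilistic weighting and transform
composition, each printing the numbers it computes.

A thin CLI mirrors the pipeline stages:

```bash
atlaslink simulate --n-atlases 6 --seed 7 --out pop/
atlaslink evaluate --atlases pop/ --links 0,1,2 --samples 50 --seed 11 --out results/
atlaslink calibrate --atlases pop/ --out params.json
```

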