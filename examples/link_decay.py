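"""Segmentation-quality decay under linked registrations, at desk scale.

Builds a small synthetic cohort (four subjects, coarse grid), emulates
imperfect pairwise registrations (2.5 mm RMS error), and scores label
transfer through chains of 1..3 composed transformations against direct
registration.  Median DSC falls roughly linearly with the number of links.
"""

import atlaslink as al

spec = al.PhantomSpec(grid=al.ImageGrid((32, 32, 24), (4.0, 4.0, 6.0)))
template = al.make_template(spec, seed=0)
population = al.make_population(
    template, al.PopulationSpec(n_atlases=4, seed=0), organs=spec.organs
)

provider = al.pairwise_provider(population, 2.5, seed=0)
config = al.ExperimentConfig(links=(0, 1, 2), n_samples=24, seed=3)
table = al.run_experiment({a.atlas_id: a for a in population}, provider, config)

medians = []
for l in sorted(table.n_links.unique()):
    med, p25, p75 = al.summarize(table[table.n_links == l].dsc)
    medians.append((l, med))
    print(f"{l} intermediate(s): median DSC {med:.3f}  IQR [{p25:.3f}, {p75:.3f}]")

slope, intercept = al.fit_link_trend(medians)
print(f"\nlinear fit: slope {slope:+.4f} DSC per link, zero-link intercept {intercept:.3f}")
print("Each extra link composes one more imperfect registration, so quality decays;")
print("the intercept extrapolates to the quality of a hypothetical error-free transfer.")
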