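"""Diversity trends over consecutive planting years.

Injects a year-linked richness gradient into the generator, groups
quadrats into year classes (<5, 5–7, ≥8 years), and runs one-way ANOVA
with LSD letters per diversity index.
"""

import seedbank as sb
from seedbank.trends import year_trends

design = sb.SimulationDesign(
    sites_per_mode=8,
    richness_fraction_by_year_class=(0.2, 0.6, 1.0),
    rng_seed=2,
)
quadrats, practices, _ = sb.generate_dataset(design)
profile = sb.diversity_profile(quadrats)

for res in year_trends(profile, practices,
                       responses=("lambda_simpson", "evenness_E", "dominance_C")):
    transform = f" [{res.transform}]" if res.transform else ""
    print(f"\n{res.response}{transform}: F = {res.F:.1f}, p = {res.p_value:.2g}")
    print(res.class_stats.round(4).to_string())

print("\nClasses sharing no letter differ by the LSD test at α = 0.05."
      "\nSimpson λ rises with planting years while evenness and dominance"
      "\nfall — richer but more skewed communities.")
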