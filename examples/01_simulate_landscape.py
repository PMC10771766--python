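"""Simulate an annual land-cover mosaic and a presence/absence census.

The generator grows one categorical landscape per year (cereal-dominated
mosaics across three protection strata), then places census points with a
minimum spacing, measures buffer composition around each point, and samples
presences from a logistic habitat-selection model with known coefficients.
"""

import steppefav as sf

config = sf.SyntheticConfig(
    rng_seed=7,
    extent=(10000.0, 10000.0),   # 10 x 10 km keeps this example quick
    n_points=120,
    n_reserve_points=25,
    protection_fractions={"reserve": 0.2, "spa": 0.3, "unprotected": 0.5},
    target_prevalence=0.25,
)

landscape = sf.generate_landscape(config)
first = landscape[min(landscape.years)]
print(f"years: {landscape.years[0]}-{landscape.years[-1]}, "
      f"grid {first.shape[0]} x {first.shape[1]} cells of {first.cell_size:.0f} m")
print("\nland-cover composition (first year):")
print(first.group_fractions().round(3).to_string())

census, truth = sf.generate_census(landscape, config)
print(f"\ncensus: {len(census)} points, {census['presence'].sum()} presences "
      f"(target prevalence {config.target_prevalence:.3f})")
print("\ntrue habitat-selection slopes (standardized buffer proportions):")
print({k: round(v, 2) for k, v in truth.true_beta.items()})
print("\nfirst census rows:")
print(census.head().round(3).to_string())
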