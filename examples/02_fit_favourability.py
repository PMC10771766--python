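"""Fit a prevalence-corrected favourability model to a census.

Candidate variables are the six buffer land-use proportions plus Shannon
diversity; they are standardized, screened with VIF, and selected by
bidirectional stepwise AIC. The fitted probabilities are then mapped to
favourability, which is 0.5 exactly at the sample prevalence and therefore
comparable across samples with different prevalence.
"""

import steppefav as sf
from steppefav.synthetic import FEATURE_COLUMNS

config = sf.SyntheticConfig(
    rng_seed=7, extent=(10000.0, 10000.0), n_points=120, n_reserve_points=25,
    protection_fractions={"reserve": 0.2, "spa": 0.3, "unprotected": 0.5},
    target_prevalence=0.25,
)
landscape = sf.generate_landscape(config)
census, _ = sf.generate_census(landscape, config)

features = census[FEATURE_COLUMNS]
std_features, standardizer = sf.standardize(features)

print("variance inflation factors:")
print(sf.vif(std_features).round(2).to_string())

fit = sf.stepwise_aic(census["presence"], std_features)
model = sf.build_favourability_model(fit, standardizer)
model.auc = sf.auc(fit.fitted, census["presence"])

print(f"\nselected variables: {fit.variables}")
print("coefficients (logit scale, standardized covariates):")
print(fit.params.round(3).to_string())
print(f"\nfavourability intercept (prevalence-corrected): {model.b0f:.3f}")
print(f"AUC: {model.auc:.3f}")
print(f"explained deviance R2: {model.r2_deviance:.3f}")

# residual spatial autocorrelation check
resid = sf.quantile_residuals(fit.fitted, census["presence"], rng_seed=7)
moran_i, moran_p = sf.morans_test(resid, census[["x", "y"]].to_numpy(),
                                  rng_seed=7)
print(f"Moran's I of quantile residuals: {moran_i:.4f} (permutation p = {moran_p:.3f})")

fav = model.predict_favourability(census)
print(f"\nmean favourability at presences: {fav[census['presence'] == 1].mean():.3f}")
print(f"mean favourability at absences:  {fav[census['presence'] == 0].mean():.3f}")
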