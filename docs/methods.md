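# Methods

This note documents the statistical methods implemented in `steppefav` and
the assumptions behind the synthetic data generator, so that every default
has a stated rationale.

## 1. Occurrence model and the favourability transform

Presence/absence at census points is modelled with a binomial GLM (logit
link) on buffer land-use features. Candidate variables are the proportions of
the six functional groups (cereal, legume, seminatural, woody, urban, other)
in a 250 m buffer plus the Shannon diversity of those proportions
(natural log, renormalized over the non-zero groups). All candidates are
standardized to mean 0 and sample SD 1 (ddof = 1); collinearity is screened
with variance inflation factors, VIF = 1/(1−R²), where R² comes from
regressing each candidate on all others. VIFs at or above 5 are flagged but
nothing is dropped automatically — the stepwise search decides.

Model selection is bidirectional stepwise AIC starting from the full model:
at each step every single-variable drop and addition is scored and the lowest
AIC wins; ties break toward fewer parameters, then variable order. If the
full starting model is (quasi-)separated, the search restarts forward from
the intercept-only model. The result is invariant to candidate-column order
because subsets are cached under a canonical ordering.

Predicted probabilities P depend on sample prevalence, which makes them
incomparable across samples. The favourability transform removes that
dependence:

    F = (P/(1−P)) / (n1/n0 + P/(1−P))

with n1 presences and n0 absences in the training sample. Equivalently F is
the logistic function at the linear predictor with intercept shifted by
−ln(n1/n0); both routes are implemented and asserted to agree to 1e-12.
F = 0.5 exactly at P = prevalence.

Diagnostics: AUC as the Mann–Whitney concordance probability with midranks
for ties; Dunn–Smyth randomized quantile residuals (exactly standard normal
under a correct model); and Moran's I on those residuals with
row-standardized inverse-distance weights and a two-sided permutation test,
p = (1 + #exceedances)/(n_perm + 1) around the null expectation −1/(n−1).

## 2. Extrapolation and trend model

The fitted model is projected onto annual coarse (default 1 km) composition
grids: per-cell group fractions are standardized with the *training* means
and SDs, and favourability is evaluated with the shifted intercept. Shannon
diversity on coarse cells is computed from the group fractions renormalized
over the analysed groups (excluding the `excluded` class), mirroring how it
is computed in buffers.

Cells are retained when their across-year *mean* favourability reaches the
threshold (default 0.2, a conventional cut-off for unsuitable habitat).
Filtering on the mean keeps the panel balanced — every retained cell
contributes every year — which keeps the year × protection design orthogonal.
A per-year filter is available as an option.

The trend model is a Gaussian GLM (OLS) of cell favourability on standardized
year, protection level and their interaction under sum-to-zero contrasts,
summarized with type III sums of squares: each term's SS compares the full
model against the model deleting that term's columns while keeping all
others. The table reports SS, df, F, p and partial R² = SS/(SS + RSS).
Residual spatial structure is checked with Moran's I on standardized
cell-mean residuals.

## 3. Count models

**Abundance GLM.** Males per census point ~ protection level, Poisson with
log link. With the canonical link the fitted level means equal observed
means; the protection effect is a likelihood-ratio χ² with levels − 1 df.
An all-zero level puts its log-mean at the boundary and is flagged with a
warning rather than an error.

**Reserve GLMM.** Annual counts at fixed reserve points are modelled as
Poisson with log μ = β₀ + β₁·zyear + β₂·neighbours + u_i, where neighbours is
the number of males at *other* points within 1.7 km in the same year and
u_i ~ N(0, σ²) is a point-level random intercept. The marginal likelihood
integrates u out by adaptive Gauss–Hermite quadrature. Because the random
effect is additive on the log scale for all of a group's observations, the
group integrand depends on u only through ΣY and Σexp(η); the quadrature is
centred at each group's conditional mode (found by a vectorized Newton
iteration on a strictly concave function) and scaled by the local curvature.
Fifteen nodes are the default — against a dense trapezoid oracle the error is
below 1e-5 in the regimes tested, and 25 nodes reach 1e-6; at σ = 0 the
formula reduces exactly to the plain Poisson GLM likelihood (verified to
1e-4). β and σ are maximized jointly (L-BFGS-B, σ ≥ 0); standard errors come
from a central finite-difference Hessian, with the σ row reported as NaN when
the estimate sits at the zero boundary. Per-term likelihood-ratio tests refit
the model without each covariate. Dispersion is Pearson χ²/df with
conditional means at the empirical-Bayes modes.

## 4. Synthetic generator

The generator exists so that every estimator above can be validated against
known truth. Its design choices:

- **Landscape.** Per-category Gaussian random fields (smoothed white noise,
  300 m correlation length, periodic boundaries) define softmax scores whose
  per-stratum biases are calibrated by fixed-point iteration so expected
  category fractions match the stratum mixture; hard labels come from a
  single Gumbel-argmax draw, and fields evolve between years as an AR(1)
  process (ρ = 0.9), so year-to-year change is gradual rotation of the same
  mosaic. Calibration is exact in the first year and drifts by well under
  0.01 in later years at the default extent.
- **Strata.** Three vertical bands (reserve / SPA / unprotected). Default
  fractions 0.12 / 0.25 / 0.63: the reserve band must be wide enough to hold
  72 census points at 600 m spacing, so it is proportionally larger than a
  real reserve would be. Default extent 24 × 24 km at 20 m cells — large
  enough to place 438 points at 600 m minimum spacing (random sequential
  packing saturates near 1100 here) while keeping a full run under a minute.
- **Composition.** Cereal dominates every stratum (~0.53–0.58); legumes and
  seminatural cover decline from reserve to unprotected (0.185/0.125/0.085
  and 0.175/0.125/0.085) while woody cover increases (0.02/0.09/0.17),
  reproducing the conservation gradient of cereal-steppe landscapes. A small
  (3 %) `excluded` class stands in for rare cover types (water,
  horticulture) that real land-cover products route out of analysis; it also
  keeps the analysed proportions from summing exactly to 1, so the
  seven-candidate design matrix has full rank.
- **Census.** Points are placed by dart throwing with 600 m minimum spacing
  and a 250 m margin. Presence probability is logistic in the standardized
  buffer features with slopes cereal 1.3, seminatural 1.0, legume 0.7; the
  intercept is calibrated by root finding to hit the target prevalence
  (default 30/438) in expectation. Male counts at presences follow a
  two-round lek process: a seed count (1 + Poisson(0.3)), then Poisson
  reinforcement proportional to neighbouring males.
- **Reserve time series.** Fixed points censused every year (default
  2011–2020) with log-linear decline (default ln(0.5)/9 per year: a halving
  over the decade), conspecific attraction 0.1 per neighbouring male, and
  point random intercepts with variance 0.3. Counts are drawn in two passes
  so the neighbour covariate used in generation is well defined; it is stored
  in the ground truth for clean recovery studies.
- **Determinism.** Every generator operation draws from its own
  `numpy` `SeedSequence((seed, op_index))` stream, so each artifact is a pure
  function of the config; reruns are bit-identical.

## 5. Limitations

- The landscape generator produces compositional change without land-use
  *conversion events* (parcel rotation, consolidation); trends in synthetic
  favourability are therefore weaker than in real mosaics.
- Protection strata are vertical bands, not realistic polygons; spatial
  autocorrelation between strata is limited to the field correlation length.
- The GLMM supports a single Gaussian random intercept — no crossed or nested
  effects, no overdispersion family beyond the diagnostic.
- Buffer composition uses cell-centre containment, so buffer proportions are
  exact only up to the fine-cell resolution (20 m by default, i.e. <2 %
  error at a 250 m radius).
- Coordinates are assumed to be in a projected metric CRS already;
  reprojection and raster ingestion are out of scope (land cover arrives as
  long-format CSV).
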