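# Methods

`socbench` implements a benchmarking pipeline for functional soil organic
carbon (SOC) fractions — mineral-associated (MAOC) and particulate (POC)
organic carbon — in planted versus natural forests. It estimates (i) how
forest conversion interacts with climate on the site scale, (ii) wall-to-wall
concentration and stock maps with bootstrap uncertainty, (iii) the
counterfactual stock deficit of plantations relative to natural forests,
(iv) quantile-based storage-potential objectives, and (v) the pooled effect
of close-to-nature plantation management from published experiments. All
components are exercisable against a synthetic data generator with exact
ground truth.

## Generative model and site-scale analysis

The site-scale model for a fraction concentration y (g C kg⁻¹) is

    ln y = β₀ + Σⱼ βⱼ zⱼ + T (β_T + β_Tm z_MAT + β_Ta z_AI) + u_study + ε,

with standardized covariates zⱼ (mean annual temperature MAT, aridity index
AI = precipitation/PET, NPP, elevation, pH, clay+silt fraction, sampling
depth, mineral-activity class), plantation dummy T, study-level random
intercept u ~ N(0, σ²_study) and residual ε ~ N(0, σ²_resid). The
`mixed_effects` module fits this with statsmodels `MixedLM` (REML for the
reported fit, ML during model selection), reports Wald (normal) 95%
intervals and p-values, and computes marginal/conditional pseudo-R²
(fixed ÷ total variance and fixed+random ÷ total). Backward elimination
removes, at each step, the droppable term whose removal lowers the ML AIC
the most, never removing a main effect while its interaction is active;
AIC ties within 0.01 resolve toward the smaller model. Coefficients are
also reported per raw covariate unit (standardized estimate divided by the
standardization SD), which is the scale used for parameter-recovery checks
because it is invariant to whether standardization constants are empirical
or theoretical.

### Synthetic-data calibration

The generator's defaults emulate the study system the package benchmarks:
71 studies × 15 sites = 1065 cases, MAT from −5 to 21 °C, AI 0.2–2.0,
pH 4–8.5, clay+silt 30–95%, ~80% high-activity mineral soils, sampling
depths 0–10 or 0–20 cm, 47% plantations. Covariates are uniform over these
ranges and standardized with the theoretical moments of those ranges, so
generator coefficients live on the same scale as fitted standardized
coefficients. Effect signs follow the field's expectation: plantation
offset negative, MAT negative, AI positive, MAT×plantation negative and
AI×plantation positive (warming and drying hit plantations harder). Two
quantities are calibrated exactly:

* the plantation offset β_T solves the closed-form expression for the
  population natural:planted mean-concentration ratio (2.3 for MAOC, 2.5
  for POC); the expression uses the moment-generating function of the
  standardized uniform, since type×climate interactions shift the climate
  terms' lognormal-mean factors between forest types;
* σ_resid (0.28 MAOC, 0.30 POC) is set so the predictable variance
  fraction of ln y matches cross-validated predictive skill of roughly
  0.77/0.75 — the performance regime of the real compilations this
  generator stands in for.

What the generator does **not** emulate: real spatial covariate
correlations (grid fields are independent smoothed-uniform layers),
soil-geography (regions are quadrants), measurement error in covariates,
unbalanced study sizes, and non-lognormal residuals. Passing recovery
tests therefore demonstrates statistical correctness of the estimators
under the stated model, not robustness to violations of it.

Grid ground truth stores the per-cell mean ln-concentration under both
forest-type counterfactuals. True stocks and deficits are defined on the
*expected-concentration* scale — the lognormal mean
exp(μ + (σ²_study+σ²_resid)/2) — because the quantity of scientific
interest is carbon mass, whose truth includes the residual lognormal
factor. True conditional quantiles are μ + z_q·σ_tot, which is what a
quantile forest targets (its conditional distribution includes site noise).

## Upscaling

Five learners (random forest, SVR, multivariable linear regression, MLP,
regression tree) are compared by ten-fold CV with shared fold assignment on
ln-concentration; only the RMSE ranking is consumed, so the non-forest
learners use fixed, ordinary hyperparameters (recorded in
`upscale_rf.default_learners`). The production upscaler is a random forest
(default 1000 trees; a sensitivity test shows OOB R² moves < 0.02 between
250 and 1000 trees, which justifies smaller forests in simulation studies).
Permutation importances are computed on a held-out quarter against a forest
trained on the rest (not in-sample), clipped at zero and normalized to sum
to one. Diagnostic residuals are out-of-bag, not in-sample.

### Back-transform and bootstrap uncertainty

Maps are produced by B refits (default 100) on random 70% subsamples drawn
without replacement (a config switch enables sampling with replacement);
per-cell map layers are the replicate mean and the empirical (linear
interpolation) 5%/95% quantiles, with the band widened, never narrowed, to
contain the mean. Non-forest cells carry NaN.

Predictions are made on the ln scale and exponentiated. Plain
exponentiation of noisy predictions inflates aggregates (Jensen), and does
so *asymmetrically* between counterfactual-natural and as-mapped
predictions, which biases counterfactual differences; attenuation of the
sampling-depth effect also fails to cancel when maps are predicted at a
fixed 0–20 cm depth. Each bootstrap replicate therefore carries a
stratified ratio back-transform calibration: for each forest type, the mean
observed concentration on the replicate's held-out rows at the prediction
depth divided by the mean back-transformed prediction there. This is a
ratio/smearing-style correction for lognormal responses; with it,
integrated stocks target the expected-concentration scale and the
counterfactual deficit is approximately unbiased (≈ +1% in simulation,
versus ≈ +5% without). `calibrate=False` restores the uncorrected
convention.

## Stocks, deficit and scenarios

Stocks follow

    stock (kg C m⁻²) = concentration (g C kg⁻¹) × BD (g cm⁻³)
                       × (1 − coarse fraction) × depth (cm) × 0.01,

integrated over equal-area cells (explicit `cell_area`, m²) and reported in
Pg C (1 Pg = 10¹² kg); depth is fixed at 20 cm (topsoil) by default and
configurable. The plantation deficit re-predicts plantation cells twice per
bootstrap replicate — forest type as mapped and forced to natural —
integrates the stock difference, and takes 5%/95% quantiles of the
replicate totals as bounds; natural cells contribute zero by construction.

Storage-potential objectives use a quantile regression forest: a standard
forest on (X, ln y) whose conditional quantiles are read from the
leaf-co-occurrence-weighted empirical CDF of training responses (per tree,
weight 1/leaf-size for co-resident points, averaged over trees; the
quantile is the smallest response whose cumulative weight reaches q).
Quantiles are computed on the ln scale and exponentiated — monotone
transforms commute with quantiles, so this is exact — with forest type
forced to natural. The 0.60/0.80/0.90 quantiles define the minimal,
intermediate and ambitious objectives; monotonicity across q holds cell-wise
by construction and is asserted. "Current" stock uses the forest-type mask
as-is; additional storage = potential − current. The deficit uses the
conditional-mean model and the potentials the quantile model: they answer
different questions (what was lost vs what the pedoclimate could hold).

## Diagnostics

Moran's I on OOB residuals uses row-standardized k-nearest-neighbour
weights (k = 8 by default; inverse-distance available), expectation
−1/(n−1), variance under the normality assumption, and optionally a
permutation test; duplicate coordinates receive a deterministic 10⁻⁹-span
jitter. The semivariogram is the classical Matheron estimator
γ(h) = mean[(vᵢ−vⱼ)²]/2 per distance bin; empty bins report NaN with zero
pair count. Constraint analysis ranks covariates by the R² of a univariate
quadratic fit (linear for binary covariates; covariates standardized before
fitting for conditioning) of cell-level additional storage, and traces the
partial dependence of a random-forest fit on MAT.

## Meta-analysis

Effect sizes are ln response ratios RR = ln(x_t/x_c) with sampling variance
v = S_t²/(n_t x_t²) + S_c²/(n_c x_c²); a missing SD is imputed as one tenth
of its mean and flagged. Pooling is DerSimonian–Laird:
τ² = max(0, (Q − (k−1))/C), C = Σw − Σw²/Σw with fixed weights w = 1/v,
final weights 1/(v+τ²), and a 1.96-normal CI (no Knapp–Hartung adjustment —
matching common default behaviour). Duration subgroups (default threshold
15 years) pool independently; strata with fewer than two studies are
flagged rather than pooled. Percent change is (e^RR − 1)×100.

## Numerical choices and problem sizes

All randomness derives from `numpy.random.default_rng`; the pipeline uses
one master seed with named per-stage substreams, so reruns are
byte-identical. Simulation studies in the test-suite/validation script use
deliberately scaled problem sizes: 200 datasets of n = 1000 for mixed-model
coverage; 100 landscapes (30×30 cells, n = 2000, B = 40 replicates of
25-tree forests) for deficit coverage; ten-fold CV with 300 trees for
predictive-skill checks (backed by the tree-count stability result);
natural:planted ratios estimated at n = 12 000 because a single n ≈ 1000
draw carries ratio sampling noise (SD ≈ 0.13) larger than the quantity's
own tolerance. Default grid cell area (4×10⁹ m²) puts national-scale totals
in the Pg range typical for a large forest estate.

## Known limitations

* Quantile-forest weight computation is O(n_query × n_train) in memory;
  fine for the intended grid sizes, not for 10⁶-cell rasters without
  chunking.
* The ratio calibration corrects aggregate multiplicative bias but not
  covariate-local bias of the forest; deficit bounds are bootstrap
  percentiles and do not account for model misspecification.
* No spatial cross-validation; CV skill is optimistic when residuals are
  spatially autocorrelated (the Moran's I diagnostic is the guard).
* Subsoil (> 20 cm) stocks are out of scope; depth enters only through the
  sampling-depth predictor.
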