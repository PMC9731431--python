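# Methods

## The model

`fednorm` estimates normative models of regional biomedical phenotypes
(the motivating case is regional cortical thickness) on multi-site
data. For one region, subject ages enter a basis expansion
`phi(age)` and every *batch* — an observed (site, sex) cell — gets its
own coefficient and noise parameters, partially pooled under shared
Gaussian priors:

    y_i      ~ Normal( phi(age) . theta_i , sigma_i^2 )    batch i
    theta_i[j] ~ Normal( mu_theta[j] , sd_theta[j]^2 )
    mu_theta[j]      ~ Normal(0, 10^3)        (variance 10^3)
    log sd_theta[j]  ~ Normal(0, 2.5^2)

With homoscedastic noise (the default), the per-batch log noise sd is
pooled the same way: `log sigma_i ~ Normal(mu_ln, sd_ln^2)` with the
same weakly-informative hyperpriors on `mu_ln` and `log sd_ln`. With
heteroscedastic noise, `sigma = softplus(phi(age) . theta_sigma_i)`
and the noise coefficient vector is pooled per coefficient exactly
like the mean block.

Partial pooling interpolates between complete pooling (one global fit:
stable but blind to site effects) and no pooling (independent per-batch
fits: flexible but unstable for small sites). Deviations are scored
with batch-specific functions, `z = (y - f_mu_i(x)) / f_sigma_i(x)`, so
additive and multiplicative site effects are compensated in the
z-statistics without modifying the data — unlike harmonization, which
removes site-associated variance from the phenotypes themselves and
with it any unknown biological signal that happens to correlate with
site (the latent-subtype failure mode demonstrated in the test suite).
The abnormal probability index is `P_abn(z) = 2 Phi(|z|) - 1`.

Site and sex are composed as a cross-product of group effects: each
observed (site, sex) cell is one exchangeable draw from the shared
prior. Only observed cells are registered; an unobserved cell is
reported at prediction time rather than silently imputed, unless the
caller explicitly requests the prior-level prediction (the n = 0
few-shot path).

## Inference

Everything in the model is Gaussian, so the joint log density and its
gradient are closed form (`fednorm/_model.py`). Sampling is by a
No-U-Turn sampler (`fednorm/_sampling.py`): dynamic trajectory
doubling with a slice variable, dual-averaging step-size adaptation
(target acceptance 0.9), windowed diagonal mass-matrix estimation with
step-size re-adaptation after each mass update, and divergence
detection at an energy-error threshold of 1000. Defaults are 2 chains
of 1000 tuning + 1000 kept draws; R-hat (via arviz, when >= 2 chains)
above 1.05 or a divergence rate above 5% attaches a warning to the
fitted model rather than failing silently.

Parameterization is chosen per batch. Small and empty batches are
non-centered (`theta_i = mu + sd * eps_i`), which is the
well-conditioned choice when the prior dominates; batches with at
least `center_threshold` (default 10) rows are centered, the
well-conditioned choice when the likelihood dominates. The mixed
scheme is what makes one sampler serve both the population sites
(hundreds of subjects) and few-shot sites (0–1 subjects) without
pathological funnel geometry. The hot per-observation loops are
numba-compiled with a pure-numpy fallback; both paths are checked
against finite differences in the tests.

The basis (`linear`, cubic polynomial, or cubic B-spline with 5 evenly
spaced interior knots by default) is evaluated on age affinely rescaled
to [-1, 1] over the training range (`standardize=True`). This leaves
the spline basis unchanged and is a pure linear reparameterization of
the polynomial coefficients, but decorrelates the design columns and
conditions the posterior dramatically better. Test-time ages outside
the training range are clamped to the boundary by default (conservative
for centile charts); linear continuation is available. Prediction uses
posterior means of the per-batch parameters; the reported sigma is the
posterior-mean noise sd (aleatory spread), not the predictive sd
inflated by parameter uncertainty, matching how normative z-scores are
defined.

## Federation

*Extension* adds a new site's dataset to a trained model without the
earlier sites' raw data: a synthetic cohort is drawn from the posterior
predictive over the model's known batches — by default 5 replicates at
each integer age in [10, 90) for each sex, i.e. 800 rows per prior
site — concatenated with the new data, and the model is refit from the
weakly-informative hyperpriors. The operation's inputs are only
(model, new data), which enforces the privacy constraint structurally.

*Adaptation* transfers the reference model to a local site: the
posterior of each hyperparameter is summarized as an independent
Gaussian (mean and sd of draws; log-space for scales, floored at 1e-3
so a degenerate posterior still yields a proper prior) and used as the
informative hyperprior for a fresh fit on local data alone. The
reference `fit_range` travels with the prior because the transferred
coefficients live in the standardized-age coordinate system of the
reference fit; a basis or dimension mismatch raises before sampling.
Full-covariance transfer of the hyperparameter posterior would retain
more information and is a possible extension; the independent-Gaussian
summary keeps the payload a small site-free JSON object.

## Baselines

Naive pooling, fixed-effect pooling (one-hot site covariates, which by
construction cannot be deployed to unseen sites), and no pooling use
maximum-likelihood least-squares mean fits with homoscedastic noise
(global, or per batch for no pooling; batches without a residual
degree of freedom are flagged unusable). Sex enters the pooled
baselines as an indicator covariate. ComBat is implemented in its
standard parametric empirical-Bayes form (normal / inverse-gamma
priors across regions, the iterative conditional solution), fitted on
training data and applied to held-out data, with age and a sex
indicator preserved in the design; it is cross-checked against
`sva::ComBat` (Bioconductor) in the test suite. The non-parametric EB
variant and the GAM variant are not implemented.

## Metrics

RHO is the Pearson correlation of observed and predicted values on the
test set. SMSE divides the mean squared error by the variance of the
test targets, so 1 is the level of the trivial mean predictor. MSLL
subtracts from the Gaussian negative log density of the test targets
under the model the same quantity under a trivial Gaussian using the
training mean and variance of that region, computed globally across
sites (per-site standardization would be an alternative; global was
chosen so the trivial reference is the same for every strategy). The
site-leakage audit trains a linear SVM (C = 1) per site pair on the
z-score matrix under 5-fold stratified cross-validation and reports
one-vs-one balanced accuracies; pairs with fewer subjects than folds
in either site are skipped with a warning.

Anomaly detection maps z to `P_abn`, computes region-wise rank AUCs
(midrank ties), assigns two-sided permutation p-values by shuffling
diagnosis labels at the subject level (the same permutation across
regions, preserving their correlation), corrects across regions with
Benjamini–Hochberg, and reports a region only if it passes FDR in at
least `stability_k` of the repeated runs (default 9 of 10).

## The synthetic-data generator

Real multi-site cohorts are emulated at cortical-thickness scale:
region intercepts near 2.5, age slopes from 0 to about -0.012 units
per year laid out evenly across regions (so signal strength is
heterogeneous, including regions with none), sex offsets within
±0.1, per-site additive shifts drawn N(0, 0.2²) — roughly twice the
typical noise sd, matching how salient site effects are in cortical
thickness — multiplicative slope scales U(0.8, 1.2), per-site noise
sds U(0.08, 0.15), and per-site age windows that overlap
heterogeneously within [10, 90]. Ages are uniform within each site's
window; sex is a categorical label so it can be treated as a group
effect. One master seed expands into per-site substreams, so appending
a site never changes earlier sites' draws. Patients are healthy draws
shifted by a per-region multiple of the local noise sd. The
confounded variant correlates the age window and an unlabeled binary
"latent subtype" effect with site, for demonstrating the
signal-removal failure mode of harmonization.

What the generator does not emulate: non-Gaussian (skewed or bounded)
phenotypes, cross-region residual correlation, scanner drift within
site, and realistic missingness. Passing tests therefore demonstrate
correctness of the machinery under the stated generative assumptions,
not robustness to their violation.

## Benchmark experiment scales

The benchmark experiments in `fednorm.experiments` (run by the test
suite and by `scripts/acceptance.py`) use desk-scale cohorts chosen to
sit in the same statistical regime as large multi-site studies:

* extension fidelity: 8 sites × 150 subjects, 20 regions of varied
  signal, reduced sampler settings (1 chain, 250 warmup + 250 draws);
  the test suite runs a 5-site × 120 × 6-region version.
* site-leakage audit: 4 sites × 300 subjects, 20 regions, strong site
  effects. Site sizes of a few hundred keep per-batch estimation error
  small; with much smaller sites, finite-sample error in the batch
  estimates itself becomes classifiable site information, which large
  reference cohorts do not suffer from.
* adaptation: a 6-site reference model, then 10 simulated single-sex
  clinical sites with 10 recalibration and 150 held-out subjects each.
* calibration: 20 cohorts of 4 sites × 150; per-batch sample sizes in
  the tens keep the short-chain posteriors themselves from being the
  accuracy bottleneck.

## Known limitations

* Gaussian likelihood only; skewed or bounded phenotypes would need a
  warped or shape-parameterized likelihood.
* Regions are modeled independently; multivariate residual site
  signal across regions is not removed (the audit accuracy of HBR
  z-scores is therefore slightly above chance at desk scale).
* With only a handful of subjects per batch *and* a handful of
  batches, short-chain fits can undersample the hierarchy (diagnostics
  flag this); credible-interval calibration was verified in the
  data-dominated regime.
* The homoscedastic noise hierarchy pools per-batch log noise sds; if
  all batches share exactly identical noise, the spread hyperparameter
  concentrates near zero and sampling that funnel is slow (flagged by
  divergence warnings, accuracy of predictions unaffected in the cases
  exercised).
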