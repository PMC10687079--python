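# Methods

## The location-scale site-effect model

`connharm` treats a vectorised FC feature `v` of subject `j` at site `i` as

    x_ijv = α_v + (M_j β)_v + γ_iv + δ_iv ε_ijv ,   ε_ijv ~ N(0, σ_v²),

the classic batch-adjustment decomposition: `α` the covariate-adjusted grand
mean, `M_j` the covariate row (age in years z-scored with training-split
statistics; gender one-hot), `γ`/`δ` additive and multiplicative site
effects, `ε` the subject-specific residual that carries the biology of
interest.  Harmonised features are `x_res = α + ε`; by default the covariate
contribution is *not* added back, so downstream models see neither site nor
confounder structure.  Restoration inverts the map exactly:
`restore(remove(x)) = x` to machine precision for any admissible parameters
(δ ≥ a positivity floor of 1e-6).

**Identifiability.**  Only two reduced parameterisations are estimable from
data: `γ` relative to its subject-weighted site mean (the grand mean absorbs
any common offset) and `δ` relative to a common scale (only the product
`δ_i·σ` is observable).  The least-squares fitter (`combat_fit`) therefore
regresses features on per-site intercepts plus covariates (gender with one
reference level dropped for full rank — omitting site intercepts would let
the site effects inflate the covariate-coefficient noise and leak covariate
misfit into the residuals), defines `α` as the weighted mean of the site
intercepts, `γ_i` as the intercept offsets, and pins `σ_v` to the
*geometric* mean of the per-site residual standard deviations so that the
fitted `δ` has geometric mean one across sites.  This matches the
generator's LogNormal(0, ·) site-scale prior (median 1), and recovers e.g.
γ = (+2, −2), δ = (2, 0.5) essentially exactly at 200 subjects per site.
Empirical-Bayes shrinkage of the original batch-adjustment literature is
deliberately not implemented; a config hook is reserved for it.

## The encoder-decoder-classifier

The end-to-end model has four blocks:

* a learnable harmonisation layer: `α` (length V), covariate projection
  (C×V), site-location projection (I×V) and site-log-scale projection (I×V),
  all zero-initialised so harmonisation starts as the identity; the site
  scale is parameterised as `δ = exp(u)` so positivity needs no projection
  step;
* two parallel encoders `f_μ`, `f_σ` (one 32-unit hidden layer each) mapping
  the V harmonised features to a 16-dimensional latent mean and to the log
  latent s.d. (`z_σ = exp(raw)`);
* a decoder (one 32-unit hidden layer) reconstructing `x_res`, whose output
  is carried back to the original scale through the inverted harmonisation;
* a single dense softmax layer classifying from the latent sample
  `z = z_μ + z_σ ⊙ u`, `u ~ N(0, I)` (reparameterisation; in evaluation
  `z = z_μ` and dropout is off, so the forward pass is a pure function of
  weights and input — required for stable attribution).

Hidden activations default to **softplus** rather than ReLU.  This is a
deliberate choice for the attribution stage: with ReLU the logit is
piecewise linear and the midpoint Riemann approximation of the integrated-
gradients path integral converges only at O(1/steps) (measured completeness
gaps of 2e-3–8e-3 at 200 steps), whereas a smooth activation restores
O(steps⁻²) convergence (measured gaps ≈ 1e-6).  Classification behaviour is
indistinguishable on the synthetic test-bed; ReLU remains available via
`EDCConfig(activation="relu")`.  Dropout (0.2) follows each hidden
activation.

The plain DNN baseline uses hidden sizes (75, 50, 30), chosen for parameter
parity with the EDC stack (within 20 % at V = 1000).

**Variants.**  `dnn` (no harmonisation, cross-entropy only); `dnn_dh`
(learnable harmonisation + DNN, trained with `L_C + γ₃ L_R` so the site
layers receive a harmonisation objective — the reference work gives no loss
detail for this ablation); `edc_sl`/`edc_ssl` (VAE + classifier on raw
features, without/with an unlabelled pool); `shred` (end-to-end
harmonisation that adds the covariate contribution back into `x_res`);
`shred_ii` (two-stage: least-squares harmonisation fitted on the training
split — covariates retained, as is conventional for a standalone
batch-adjustment pass — then an EDC trained on the residualised data; its
joint loss has no `L_R` because the site parameters are fixed, not live);
`shred_iii` (end-to-end, covariates removed, all four loss terms).

## Losses and optimisation

    L = L_C + γ₁ L_L + γ₂ L_D + γ₃ L_R

with per-variant defaults γ = (1e-4, 1e-3, 0) for the EDC family,
(1e-4, 1e-3, 1) for the covariate-retaining end-to-end variant and
(1e-5, 1e-3, 1e-4) for the default end-to-end variant.  `σ_v` in `L_L` and
`L_R` is one fixed quantity: the per-feature s.d. of the *unharmonised*
training-split features, computed once (the loss treats it as a constant
scale, not a learned parameter).  `L_L` compares the input with the
reconstruction on the original scale (after restoration); a config flag
switches to the residual scale, which the printed equations leave ambiguous.
`L_R`'s `γ_iv`, `δ_iv` are the live harmonisation weights, so its gradients
are what estimate the site effects end to end.  Cross-entropy floors
probabilities at 1e-12 (logged when triggered); the training path uses the
equivalent log-softmax form.

Optimisation is Adam (learning rate 0.002, weight decay 0.001 added to the
gradient) with global-norm gradient clipping at 1.0 every step — without
clipping the VAE loss can diverge on small high-dimensional data.  Epochs
default to 100 with batch size 32 and no early stopping; both are
configurable and the acceptance/test runs use 15–60 epochs, which the
synthetic conditions comfortably converge within.  Semi-supervised batching
draws a labelled batch and an equally sized unlabelled batch per step;
`L_C` sees only the labelled rows, the VAE terms see both.  All randomness
(initialisation, shuffling, dropout, latent sampling) derives from the
single training seed, so identical calls give bit-identical weights.

## Cross-validation protocol

Stratified k-fold (default 5) repeated over independent seeds (default 10,
hence 50 models), stratifying the labelled subjects jointly by diagnosis and
site; unlabelled subjects join every training split and are never tested.
Everything fitted from data — covariate scaling, `σ_v`, the two-stage
harmonisation — is computed on the training split only.  Fold RNGs and
per-fold training seeds are derived deterministically from the global seed.

## Biomarker generation

Integrated gradients of the pre-softmax patient logit, evaluated in
deterministic mode, against the baseline `x̄` = mean feature vector of the
training-split normal controls:

    R_v(x_j | F) = (x_jv − x̄_v) · (1/S) Σ_k ∂F/∂x_v at x̄ + ((k−½)/S)(x_j − x̄)

(midpoint rule, S = 100 by default; the path runs from baseline to input —
completeness Σ_v R_v = F(x_j) − F(x̄) is verified as a test axiom).  Group
scores are the mean *absolute* per-subject scores over the patient (SZ)
test subjects; model-level group scores are averaged across all
cross-validation models and then z-scored across features (a flag z-scores
per model before averaging).  Matrix heatmaps place the score vector in the
strict lower triangle (row-major, rows 2..R — the same fixed convention the
feature vectoriser uses, so saliency indices map back to ROI pairs), zero
the upper triangle and diagonal, and keep the top fraction (default 1 %,
k = floor(fraction·V) survivors; ties at the threshold resolve toward the
lower feature index via a stable sort).

## Evaluation statistics

* Accuracy / sensitivity (true patient rate) / specificity (true control
  rate) from the confusion table; ratios with an empty class are reported
  missing, never zero.
* Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
  freedom for between-model comparisons of CV accuracies.
* Hellinger distance between per-site feature distributions: Gaussian KDE
  with a single Silverman bandwidth computed on the pooled sample, a
  512-point grid spanning the pooled range ± 3 bandwidths, clipped to
  [0, 1].  Sharing the bandwidth makes the distance a property of the
  samples, not of per-group estimator choices.
* Spearman correlation between selected FC features and symptom scales,
  exact-permutation p-values for n ≤ 10 and the t approximation above,
  with Benjamini–Yekutieli FDR control (valid under arbitrary dependence)
  applied across all computed tests — the conservative choice when the
  tested family is not pre-registered.

## The synthetic test-bed

The generator draws data from exactly the location-scale model above: site
locations `γ_iv ~ N(0, 1)` and scales `δ_iv ~ LogNormal(0, 0.25)` drawn once
per site and feature (the exchangeability assumptions of the canonical
batch-adjustment model), residual s.d. σ = 0.2, grand means ≈ N(0.2, 0.25)
(Fisher-z-scale FC values), ages uniform on 18–65 with small linear feature
effects, and a diagnosis effect of −2σ (patients below controls) on a
random 10-feature support.  Defaults are two sites × 200 subjects per site
and class × 500 features.  A second scenario makes the first site three
times larger and adds a patient shift confined to that site on 10 dedicated
features riding a threefold site-scale inflation — the synthetic analogue
of a dominant-site artefact that pooled models mistake for a biomarker and
harmonising models suppress.  A block-covariance Gaussian time-series
generator feeds the FC-construction stage, and a cohort helper reproduces
the four-site study's demographic margins (417 subjects; 249 controls, 168
patients) for manifest-shaped bookkeeping.

**What the generator does not emulate:** temporal autocorrelation and
physiological/motion noise in the time series, spatial structure among ROI
coordinates, heavy-tailed or feature-correlated site effects, label noise,
and site-by-covariate confounding.  Passing tests therefore demonstrate
correctness of the estimators and the end-to-end mechanics under the model's
own assumptions — not performance on real multi-site fMRI.

## Numerical choices and limitations

* Networks run on the package's own reverse-mode autograd over numpy
  (float64); problem sizes here (≤ 10⁵ parameters) do not warrant a
  framework dependency.
* Fisher transform clips |r| at 1 − 1e-7 before arctanh; FC matrices must be
  symmetric within 1e-8; constant ROI time series raise an error naming the
  ROI.
* Nearest-centroid atlas label transfer breaks distance ties toward the
  lowest destination ROI id, making the mapping deterministic.
* The fitted `γ̂`, `δ̂` are interpretable only in the reduced
  parameterisation (site-mean-centred, geometric-mean-one); comparisons with
  generative truth must apply the same reduction.
* Known limitations: no empirical-Bayes shrinkage (small sites get noisy
  site-effect estimates), no nonparametric harmonisation, no dynamic FC,
  single-study binary diagnosis only.
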