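# connharm

Multi-site resting-state functional-connectivity (FC) studies suffer from
*site effects*: scanner and protocol differences shift and rescale FC features
systematically, so classifiers trained on pooled data learn site artefacts as
readily as disease biology. `connharm` is a toolkit for neuroimaging groups
who want to pool small schizophrenia (or other case–control) FC cohorts
across sites: it couples ComBat-style location-scale harmonisation with a
variational encoder-decoder-classifier (EDC) trained end to end, and turns
the fitted models into biomarker maps with integrated gradients —
distinguishing *site-invariant* biomarkers from *site-specific* salient
features.

## The model

Feature `v` of subject `j` scanned at site `i` is modelled as

```
x_ijv = α_v + (M_j β)_v + γ_iv + δ_iv ε_ijv ,   ε_ijv ~ N(0, σ_v²)
```

with grand mean `α`, covariate design `M` (age, gender), additive site effect
`γ`, multiplicative site effect `δ > 0`, and subject residual `ε`.
Harmonisation solves for `ε` and re-centres on `α`, so the network input is
`x_res = α + ε` — both site effects *and* covariates removed.  A VAE
(two 32-unit encoders for the latent mean and s.d., 16-dim latent, 32-unit
decoder) reconstructs `x_res`; a single dense softmax head classifies from
the latent code; the decoder output is carried back to the original scale by
inverting the harmonisation.  Training minimises

```
L = L_C + γ₁ L_L + γ₂ L_D + γ₃ L_R        (γ₁, γ₂, γ₃ = 1e-5, 1e-3, 1e-4)
```

where `L_C` is cross-entropy on labelled subjects, `L_L` a Gaussian
reconstruction likelihood, `L_D` the KL term against the standard-normal
prior, and `L_R` a location-scale likelihood that pulls the learnable site
layers toward the least-squares harmonisation solution.  Ablation variants
(plain DNN, DNN + harmonisation, EDC with/without unlabelled data, the
covariate-retaining end-to-end variant, and a two-stage fit-then-train
variant) share the same interface.  Biomarkers come from integrated
gradients of the patient logit against a normal-control baseline, aggregated
as mean absolute scores over patients, averaged across all cross-validation
models, z-scored, and filtered to the top 1 % of lower-triangle features.

There is no deep-learning framework dependency: the networks run on a small
reverse-mode autograd engine (`connharm.autograd`) over numpy.

## Worked example

`examples/` contains one narrative script per capability.  For instance
`python examples/03_train_classify.py` simulates two sites (500 → 200
features here, 100 subjects per site and class, site effects drawn from the
location-scale model, a −2σ patient shift on 10 features), trains the
end-to-end variant and prints:

```
final losses: L_C=0.0221  L_L=142.6  L_D=14.59  L_R=215.7  joint=0.0597
held-out accuracy 1.000, sensitivity 1.000, specificity 1.000 on 80 subjects
```

The joint loss is dominated by `L_C` because the VAE terms carry small
weights; accuracy/sensitivity/specificity are computed on the held-out 20 %.
`examples/04_biomarkers.py` continues to biomarker mapping and reports that
all 10 simulated effect features are recovered among the top-20 saliency
ranks; `examples/02_harmonisation.py` shows the fitted site effects
(γ̂ ≈ ±2.0, δ̂ ≈ 2.0/0.5 for the true (2, −2) / (2, 0.5)) and the collapse of
the between-site Hellinger distance from ≈1.0 to ≈0.1 after removal.

A thin CLI mirrors the pipeline stages
(`connharm simulate | fc | train | crossval | attribute | evaluate | run`).

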