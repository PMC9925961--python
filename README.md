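# cmedgan

Conditional medical GAN pipeline for in-hospital mortality prediction among
ICU patients.

Predicting which ICU patients will die in hospital is limited less by model
capacity than by labelled data: mortality is a minority outcome (~10% of
stays) and clinical feature tables are expensive to label. `cmedgan`
implements a data-augmentation approach: a **label-conditioned autoencoder**
learns a latent representation of patient feature vectors, a **conditional
Wasserstein GAN with gradient penalty (WGAN-GP)** learns to generate latent
codes that the frozen decoder maps to realistic labelled patient records, and
those synthetic records are added to the real training data at a **1:1 ratio**
before fitting an MLP mortality classifier. Baselines (the SAPS II logistic
formula, an RBF-SVM, a plain MLP) and a full evaluation/ablation harness are
included, together with a seeded synthetic ICU-cohort generator so the whole
pipeline is testable without access to a credential-gated clinical database.

## The model

Let `x ∈ [0,1]^d` be a preprocessed patient feature vector (continuous
features min-max scaled, categoricals dummy-coded) and `y ∈ {0,1}` the
in-hospital death label.

**Autoencoder** — encoder `E(x, y) → V` and decoder `D(V, y) → x̂`, trained to
minimise cross-entropy on binary columns plus squared error on continuous
columns. The label is concatenated to the input of both halves.

**Adversarial stage** — generator `G(z, y) → V′` (noise `z ~ N(0, I)`, `V′` in
the latent space of `V`); fake records are `D(V′, y)`. The critic `C(x, y)`
is trained with the WGAN-GP loss

    L_C = E[C(fake)] − E[C(real)] + λ · E[(‖∇ C(x̂, y)‖₂ − 1)²],   λ = 10,

with `x̂` a per-row uniform interpolate between real and fake features, and
the generator with `L_G = −E[C(fake)]`, alternating 5 critic steps per
generator step. The decoder stays frozen during adversarial training.

**Augmented classifier** — fake rows with labels matching the real label
distribution are appended 1:1 to the real training data; a 5-layer MLP
(three hidden layers, sigmoid output, binary cross-entropy) is trained on the
union and scored on untouched test data.

**SAPS II baseline** — the published logistic formula
`logit(p) = −7.7631 + 0.0737·s + 0.9971·ln(1 + s)` applied directly to the
severity score `s`.

Evaluation reports PR-AUC (average precision), ROC-AUC, F1/precision/recall,
Hosmer–Lemeshow-style calibration curves, and percentile-bootstrap 95%
confidence intervals; `run_ablation` shrinks the training set (100% / 50% /
10%) to measure robustness to small data.

All networks run on a compact numpy backprop core (`cmedgan.nn`) with an
analytic double-backward for the gradient penalty, so training is exactly
reproducible under a fixed seed.

## Worked example

```python
import numpy as np
from cmedgan import (
    CohortSpec, generate_cohort, dummy_code, impute, normalize,
    AEConfig, GANConfig, MLPSpec, MLPTrainConfig, PipelineConfig,
    run_cmedgan_pipeline, train_mlp, predict_mlp, roc_auc, pr_auc,
)

spec = CohortSpec(n_patients=1500, n_continuous=14, n_binary=6,
                  n_categorical=0, prevalence=0.10, effect_size=0.6,
                  missing_rate=0.0, seed=7)
cohort = generate_cohort(spec)
ft, _ = normalize(dummy_code(impute(cohort.raw)))
y = cohort.raw.labels.to_numpy(dtype=int)
tr, te = ft.take(np.arange(1000)), ft.take(np.arange(1000, 1500))

cfg = PipelineConfig(ae=AEConfig(d_latent=16, hidden=64, epochs=150),
                     gan=GANConfig(d_noise=16, hidden=128, iters=1500, lr=2e-4),
                     mlp=MLPSpec(hidden=64), mlp_train=MLPTrainConfig(epochs=80))
scores = run_cmedgan_pipeline(tr, y[:1000], te, cfg, seed=0)
plain = predict_mlp(train_mlp(tr, y[:1000], MLPSpec(hidden=64, seed=0),
                              MLPTrainConfig(epochs=80)), te)
print(f"augmented  ROC-AUC {roc_auc(scores, y[1000:]):.3f}  "
      f"PR-AUC {pr_auc(scores, y[1000:]):.3f}")
print(f"plain MLP  ROC-AUC {roc_auc(plain, y[1000:]):.3f}  "
      f"PR-AUC {pr_auc(plain, y[1000:]):.3f}")
```

prints

```
augmented  ROC-AUC 0.907  PR-AUC 0.641
plain MLP  ROC-AUC 0.808  PR-AUC 0.484
```

i.e. on this 10%-prevalence synthetic cohort the GAN-augmented classifier
improves the precision–recall trade-off over the identical MLP trained on
real rows only; the gap widens as the training set shrinks (see
`run_ablation`).

A command-line interface mirrors the library:

```sh
cmedgan synth --n 2000 --prevalence 0.105 --seed 7 --out cohort.csv
cmedgan preprocess --input cohort.csv --schema cohort.schema.yaml --out data/
cmedgan train-ae --data data/ --latent 16 --epochs 150 --seed 0 --out ae.npz
cmedgan train-gan --data data/ --ae ae.npz --iters 1500 --seed 0 --out gan.npz
cmedgan generate --gan gan.npz --labels labels.csv --seed 0 --out fake.csv
cmedgan evaluate --scores scores.csv --boot 1000 --seed 0 --out report.json
```

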