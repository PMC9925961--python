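# Methods

## Problem setting

The package targets in-hospital mortality prediction from a tabular ICU
feature vector under strong class imbalance (roughly one death per ten
stays). The core idea is label-conditioned data augmentation: learn a
generative model of `(features, label)` pairs and enlarge the real training
set with synthetic labelled records before fitting the classifier. Because
access to the real critical-care extract it emulates is credential-gated, all
development and testing runs on a synthetic cohort generator with a known
ground truth.

## Preprocessing

Raw tables carry three column kinds: continuous, categorical, binary.
Missing cells are imputed (mean for continuous, mode otherwise — the simplest
defensible default; median is available); categoricals are one-hot expanded
with level-sorted, deterministically named dummy columns; continuous columns
are min-max scaled to [0, 1] with training-set statistics reused on held-out
data (out-of-range values clipped by default). Min-max rather than z-scoring
is deliberate: the decoder's outputs are sigmoid-bounded, so real and
generated features must share the unit interval. Columns are matched by name
throughout and row order is never permuted implicitly.

## Conditional autoencoder

Encoder and decoder are single-hidden-layer ReLU networks (hidden width 256
by default, latent dimension `d_latent` 128 by default; the desk-scale
fixtures use 64/16). The binary 0/1 label is concatenated to the input of
both halves — the standard conditioning-by-concatenation reading.
Reconstruction loss is cross-entropy over binary columns plus squared error
over continuous columns, unit weight per column. The decoder applies a
sigmoid to every output, valid since all features live in [0, 1]. Optimiser:
Adam, lr 1e-3, batch 128. A latent dimension at or above the feature count
is permitted (warning only): small fixtures legitimately use an expressive
autoencoder.

## Conditional WGAN-GP

The generator maps `z ~ N(0, I)` (noise width 128 default; the label is
concatenated to the generator input as well, so it can shape latent codes
per class — a flag disables this) to a latent code; the *frozen* trained
decoder maps (code, label) to feature space; the critic scores
(features, label) with no output squashing. Losses are the Wasserstein forms:
critic `E[C(fake)] − E[C(real)] + GP`, generator `−E[C(fake)]`, with
`n_critic` = 5 critic steps per generator step and Adam (lr 1e-4 default,
β₁ 0.5, β₂ 0.9). Decoder fine-tuning during the adversarial stage is
available behind a flag but off by default.

**Gradient penalty.** The penalty is the two-sided form
`λ·E[(‖∇C‖₂ − 1)²]`, λ = 10, evaluated at per-row uniform interpolates
between real and fake feature vectors, with the gradient taken with respect
to the critic's *full* input — the feature block concatenated with the label
coordinate. This choice is load-bearing: if only the feature-gradient norm
is penalised, then on a problem whose critic input is effectively
one-dimensional the two-sided penalty erects a barrier of height ≈ λ between
the `+1` and `−1` gradient basins (a sign change must pass `‖∇C‖ = 0`, which
costs λ). The critic then locks into whichever sign its initialisation leans
toward and, in the wrong basin, actively rewards degenerate fakes. Including
the label coordinate lets the gradient rotate between basins without passing
through zero. For critics that ignore the label the two definitions
coincide, so the analytic identities (unit-gradient critic → 0 penalty;
slope-k 1-D critic → λ(k−1)²; constant critic → λ) hold exactly either way.

Because the whole stack is plain ReLU networks, the penalty's parameter
gradient (a double backward) is computed analytically: with ReLU masks fixed
(exact almost everywhere), the input-gradient is a mask-gated linear chain in
the weight matrices and its derivative follows by one more chain rule. The
implementation is validated against finite differences to ~1e-9 in the test
suite.

During critic steps, fake rows are generated with the real batch's labels so
interpolates are label-consistent.

## Classifiers

* **MLP** — five layers: input, three hidden (1024 nodes in the reference
  configuration; fixtures use 64), one sigmoid output; binary cross-entropy;
  Adam, lr 1e-3, batch 128; optional early stopping on a held-out stratified
  fold (off by default in the deterministic fixtures). ReLU hidden and
  sigmoid output activations.
* **Augmented MLP** — identical architecture, trained on real rows plus
  `round(ratio × n_real)` fake rows at ratio 1:1, with fake label counts
  matching the real label distribution exactly (a flag allows class-balanced
  fakes as an oversampling mode). Provenance of each row is retained for
  diagnostics and never fed to the model.
* **SVM** — RBF kernel via scikit-learn; decision scores mapped to [0, 1] by
  a logistic link, which is strictly monotone and therefore leaves both AUCs
  unchanged.
* **SAPS II formula** — `logit(p) = −7.7631 + 0.0737·s + 0.9971·ln(1+s)`
  applied to the integer severity score; no fitting.

Decision threshold for F1/precision/recall defaults to 0.5 (configurable;
no canonical value exists for this pipeline).

## Evaluation

ROC-AUC is the Mann–Whitney probability (ties ½); PR-AUC is average
precision with ties grouped at a single threshold — both via scikit-learn,
cross-checked in the tests against brute-force pairwise enumeration and an
explicit threshold sweep at 1e-12. Confidence intervals are percentile
bootstrap over test rows (default 1000 resamples; single-class resamples are
redrawn). Calibration curves use 10 equal-frequency bins (the
Hosmer–Lemeshow convention); an equal-width mode drops empty bins with a
warning. Grid search uses stratified k-fold (k = 5) and selects by mean
validation PR-AUC — chosen because PR-AUC is the better-behaved metric under
the ~10% prevalence — then refits on the full training data.

The dataset-size ablation draws stratified subsamples of the training set at
fractions 1.0 / 0.5 / 0.1 (five repeats each, fixed test set), reports mean
metrics per model and size, and percent change against the full-data mean.

## Synthetic cohorts

The generator emulates the shape of the emulated ICU extract: ~136 mixed
columns (default 100 continuous + 30 binary + 2 three-level categoricals) at
38,597 patients with 10.5% mortality, all configurable. Continuous features
are class-conditional unit-variance Gaussians whose positive-class mean is
shifted by `effect_size`; binary features are class-conditional Bernoullis
(rate shift 0.15·effect_size, clipped); categoricals are class-independent
multinomials (they exercise dummy coding, not signal); missingness is
completely at random. Labels use an exact-count mode by default so
prevalence assertions are sharp. The optional simulated SAPS II column draws
integer scores in [0, 163], negatives centred at 30 (≈10% formula mortality)
and positives right-shifted by 15·effect_size — so a zero-effect cohort
yields an uninformative score column, which the no-signal null tests rely
on. This family was chosen because the Bayes-optimal ROC-AUC is computable
(Monte-Carlo over the true log-likelihood ratio; closed form Φ(d/√2) for a
single Gaussian feature), giving every classifier test a known ceiling.

What the generator deliberately does not model: temporal structure,
physiologic correlations between features, informative missingness, heavy
tails, or the real data's marginal distributions. Passing tests therefore
demonstrate the pipeline's mechanics and its relative behaviour under
imbalance and shrinking data — not clinical performance on real records.

## Fixture scales and numerical choices

Desk-scale problem sizes used by the tests and the acceptance script, chosen
so each stage trains to convergence at its size:

* memorisation fixture: n = 50, 10 features, latent 8, 500 epochs;
* fidelity fixture: n = 2000, 20 features, AE 100 epochs, GAN 800
  iterations (hidden 128, lr 2e-4) — the Wasserstein estimate and
  dimension-wise fidelity plateau by this budget;
* ablation fixture: n = 1500 (1000 train / 500 test, stratified), GAN 1500
  iterations — the augmented classifier needs a converged generator to match
  the plain MLP at the full size; under-trained fakes dilute the boundary;
* no-signal null: zero-effect cohorts, 5 seeds, mean ROC-AUC per model.

Other numerics: sigmoid is computed in its numerically stable split form;
BCE clips probabilities at 1e-7; the gradient-penalty norm adds 1e-12 before
the square root; non-finite losses abort training with the iteration index;
all randomness flows through `numpy.random.default_rng` seeded per stage, so
end-to-end runs are bit-reproducible single-threaded.

## Known limitations

* The adversarial stage is a stochastic optimisation; individual seeds can
  produce weak generators. Aggregate checks use 5-seed medians/means.
* Equilibrium conditioning is approximate: fake class separation is
  attenuated relative to the real classes at small n.
* The SAPS II baseline requires the score as an input column; computing the
  score from raw physiology is out of scope.
* No statistical model comparison (e.g. paired tests between classifiers) is
  provided, and no external validation data is bundled.
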