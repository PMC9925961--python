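"""Predictors and the 1:1 augmentation head.

Four ways to score in-hospital death risk:

* :func:`saps2_mortality` — the published logistic formula mapping a SAPS II
  severity score straight to a death probability,
  logit(p) = -7.7631 + 0.0737 * s + 0.9971 * ln(1 + s);
* :func:`train_svm` — a max-margin (RBF-kernel) baseline via scikit-learn;
* :func:`train_mlp` — the 5-layer perceptron (input, three hidden layers,
  sigmoid output) trained on binary cross-entropy;
* :func:`run_cmedgan_pipeline` — the full conditional-GAN pipeline: train the
  conditional autoencoder and WGAN-GP on the training split, generate fake
  labelled rows, add them to the real rows at a 1:1 ratio, and train another
  MLP on the union.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from sklearn.svm import SVC

from . import nn
from .adversarial import GANConfig, generate_fake, train_cmedgan
from .autoencoder import AEConfig, train_autoencoder
from .preprocess import FeatureTable

__all__ = [
    "Saps2Coefficients",
    "SAPS2",
    "saps2_mortality",
    "MLPSpec",
    "MLPTrainConfig",
    "MLPParams",
    "train_mlp",
    "predict_mlp",
    "SVMParams",
    "train_svm",
    "predict_svm",
    "augment",
    "PipelineConfig",
    "run_cmedgan_pipeline",
]


@dataclass(frozen=True)
class Saps2Coefficients:
    """Published logistic coefficients for SAPS II -> hospital mortality."""

    intercept: float = -7.7631
    linear: float = 0.0737
    log_term: float = 0.9971


SAPS2 = Saps2Coefficients()


def saps2_mortality(score, c: Saps2Coefficients = SAPS2) -> np.ndarray:
    """Death probability from an integer SAPS II score (strictly increasing)."""
    s = np.asarray(score, dtype=float)
    if np.any(s < 0):
        raise ValueError("SAPS II scores must be non-negative")
    return expit(c.intercept + c.linear * s + c.log_term * np.log1p(s))


@dataclass
class MLPSpec:
    """Architecture of the mortality MLP: 5 layers in total.

    Input width follows the data; three hidden layers of ``hidden`` nodes
    (1024 in the reference configuration); one sigmoid output trained on
    binary cross-entropy.
    """

    hidden: int = 1024
    n_hidden: int = 3
    seed: int = 0


@dataclass
class MLPTrainConfig:
    epochs: int = 100
    lr: float = 1e-3
    batch_size: int = 128
    early_stopping: bool = False
    val_fraction: float = 0.1
    patience: int = 10


@dataclass
class MLPParams:
    net: nn.Net
    columns: list[str]
    spec: MLPSpec
    loss_trace: list[float] = field(default_factory=list)


def _bce(p: np.ndarray, t: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(p, eps, 1 - eps)
    return float(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean())


def train_mlp(
    ft: FeatureTable, y: np.ndarray, spec: MLPSpec, cfg: MLPTrainConfig | None = None
) -> MLPParams:
    """Mini-batch Adam on BCE; optional early stopping on a held-out fold.

    ``cfg.epochs == 0`` returns the freshly initialised network untouched.
    """
    cfg = cfg or MLPTrainConfig()
    y = np.asarray(y, dtype=float).reshape(-1)
    rng = np.random.default_rng(spec.seed)
    dims = [ft.n_cols] + [spec.hidden] * spec.n_hidden + [1]
    net = nn.init_net(dims, rng, output="sigmoid")
    opt = nn.Adam(lr=cfg.lr)

    X, t = ft.X, y
    Xv = tv = None
    if cfg.early_stopping and cfg.epochs > 0:
        n_val = max(1, int(round(cfg.val_fraction * len(t))))
        order = rng.permutation(len(t))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(np.unique(t[tr_idx])) == 2:
            X, t = X[tr_idx], y[tr_idx]
            Xv, tv = ft.X[val_idx], y[val_idx]

    trace: list[float] = []
    best = (np.inf, None, 0)
    n = len(t)
    bs = min(cfg.batch_size, n)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            p, cache = nn.forward(net, X[idx])
            p = p[:, 0]
            loss = _bce(p, t[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite BCE at epoch {epoch}")
            epoch_loss += loss * len(idx)
            dz = ((p - t[idx]) / len(idx)).reshape(-1, 1)
            gw, gb, _ = nn.backward(net, cache, dz)
            opt.step(net.params(), gw + gb)
        trace.append(epoch_loss / n)
        if Xv is not None:
            pv, _ = nn.forward(net, Xv)
            val = _bce(pv[:, 0], tv)
            if val < best[0] - 1e-6:
                best = (val, net.copy(), epoch)
            elif epoch - best[2] >= cfg.patience:
                net = best[1]
                break
    if Xv is not None and best[1] is not None and cfg.epochs > 0:
        net = best[1] if best[0] < np.inf else net
    return MLPParams(net, list(ft.columns), spec, trace)


def predict_mlp(params: MLPParams, ft: FeatureTable) -> np.ndarray:
    """Deterministic death probabilities in (0, 1), one per row."""
    if list(ft.columns) != params.columns:
        raise ValueError("feature columns do not match the trained model")
    p, _ = nn.forward(params.net, ft.X)
    return p[:, 0]


@dataclass
class SVMParams:
    model: SVC
    columns: list[str]


def train_svm(
    ft: FeatureTable, y: np.ndarray, *, kernel: str = "rbf", C: float = 1.0,
    gamma: str | float = "scale", seed: int = 0,
) -> SVMParams:
    """Max-margin baseline; decision scores mapped to [0, 1] by a logistic link.

    The link is strictly monotone, so ranking metrics (both AUCs) are
    unaffected by it.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("SVM training requires both classes")
    m = SVC(kernel=kernel, C=C, gamma=gamma, random_state=seed)
    m.fit(ft.X, y)
    return SVMParams(m, list(ft.columns))


def predict_svm(params: SVMParams, ft: FeatureTable) -> np.ndarray:
    if list(ft.columns) != params.columns:
        raise ValueError("feature columns do not match the trained model")
    return expit(params.model.decision_function(ft.X))


def augment(
    real_ft: FeatureTable,
    real_y: np.ndarray,
    fake_ft: FeatureTable,
    fake_y: np.ndarray,
    ratio: float = 1.0,
    *,
    match_labels: bool = True,
    seed: int = 0,
) -> tuple[FeatureTable, np.ndarray, np.ndarray]:
    """Append round(ratio * n_real) fake rows to the real data.

    By default the fake rows are chosen so their label counts match the real
    label distribution exactly (``match_labels=False`` draws fakes uniformly
    instead, which enables class-balanced oversampling if the fakes were
    generated balanced).  Returns (features, labels, provenance) where
    provenance is 0 for real rows and 1 for fake rows — diagnostics only,
    never a training input.
    """
    if list(real_ft.columns) != list(fake_ft.columns):
        raise ValueError("real and fake column schemas differ")
    real_y = np.asarray(real_y, dtype=int)
    fake_y = np.asarray(fake_y, dtype=int)
    n_fake = int(round(ratio * real_ft.n_rows))
    if n_fake == 0:
        return real_ft, real_y, np.zeros(real_ft.n_rows, dtype=int)
    rng = np.random.default_rng(seed)
    if match_labels:
        n_pos = int(round(n_fake * real_y.mean()))
        picks = []
        for lab, want in ((1, n_pos), (0, n_fake - n_pos)):
            avail = np.flatnonzero(fake_y == lab)
            if len(avail) < want:
                raise ValueError(
                    f"need {want} fake rows with label {lab} but only {len(avail)} "
                    "are available; regenerate with more of that label"
                )
            picks.append(rng.choice(avail, want, replace=False))
        idx = np.concatenate(picks)
    else:
        if fake_ft.n_rows < n_fake:
            raise ValueError("not enough fake rows; regenerate")
        idx = rng.choice(fake_ft.n_rows, n_fake, replace=False)
    X = np.vstack([real_ft.X, fake_ft.X[idx]])
    yy = np.concatenate([real_y, fake_y[idx]])
    prov = np.concatenate([np.zeros(real_ft.n_rows, dtype=int), np.ones(n_fake, dtype=int)])
    ft = FeatureTable(X, list(real_ft.columns), list(real_ft.kinds), dict(real_ft.parents))
    return ft, yy, prov


@dataclass
class PipelineConfig:
    """End-to-end conditional-GAN pipeline configuration (desk-scale defaults)."""

    ae: AEConfig = field(default_factory=AEConfig)
    gan: GANConfig = field(default_factory=GANConfig)
    mlp: MLPSpec = field(default_factory=MLPSpec)
    mlp_train: MLPTrainConfig = field(default_factory=MLPTrainConfig)
    ratio: float = 1.0


def run_cmedgan_pipeline(
    train_ft: FeatureTable,
    train_y: np.ndarray,
    test_ft: FeatureTable,
    cfg: PipelineConfig,
    seed: int = 0,
) -> np.ndarray:
    """Train AE -> WGAN-GP -> generate -> 1:1 augment -> MLP; score the test set.

    Test labels are never an input; the caller evaluates the returned scores.
    All stage seeds derive from ``seed`` so the composition is deterministic.
    """
    train_y = np.asarray(train_y, dtype=int)
    ae_cfg = replace(cfg.ae, seed=seed)
    gan_cfg = replace(cfg.gan, seed=seed + 1)
    mlp_spec = replace(cfg.mlp, seed=seed + 2)

    ae = train_autoencoder(train_ft, train_y, ae_cfg)
    gan = train_cmedgan(train_ft, train_y, ae, gan_cfg)
    # request fake labels mirroring the real training label counts
    want = np.repeat([0, 1], [int((train_y == 0).sum()), int((train_y == 1).sum())])
    fake_ft, fake_y = generate_fake(gan, want, seed=seed + 3)
    aug_ft, aug_y, _ = augment(
        train_ft, train_y, fake_ft, fake_y, ratio=cfg.ratio, seed=seed + 4
    )
    params = train_mlp(aug_ft, aug_y, mlp_spec, cfg.mlp_train)
    return predict_mlp(params, test_ft)
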