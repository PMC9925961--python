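"""Label-conditioned autoencoder.

Encoder(features, label) -> latent code V; decoder(V, label) -> reconstructed
features.  The label (0/1 in-hospital death) is concatenated to the input of
both halves, so the latent space and the reconstruction are class-aware — this
is what later lets the generator produce class-specific records through the
frozen decoder.

Reconstruction loss is cross-entropy over binary columns plus squared error
over continuous columns (all features live in [0, 1] after min-max scaling, so
a sigmoid output is valid for both kinds).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import FeatureTable

__all__ = ["AEConfig", "AEParams", "train_autoencoder", "encode", "decode", "reconstruction_loss"]


@dataclass
class AEConfig:
    d_latent: int = 128
    hidden: int = 256
    epochs: int = 200
    lr: float = 1e-3
    batch_size: int = 128
    seed: int = 0


@dataclass
class AEParams:
    encoder: nn.Net
    decoder: nn.Net
    d_latent: int
    columns: list[str]
    kinds: list[str]
    parents: dict[str, str]
    seed: int
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_cols(self) -> int:
        return len(self.columns)

    def save(self, path: str | Path) -> None:
        arrays = {}
        for tag, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, (w, b) in enumerate(zip(net.weights, net.biases)):
                arrays[f"{tag}_w{i}"] = w
                arrays[f"{tag}_b{i}"] = b
        meta = {
            "format": "cmedgan-ae-v1",
            "d_latent": self.d_latent,
            "columns": self.columns,
            "kinds": self.kinds,
            "parents": self.parents,
            "seed": self.seed,
            "loss_trace": self.loss_trace,
            "enc_layers": self.encoder.n_layers,
            "dec_layers": self.decoder.n_layers,
            "dec_output": self.decoder.output,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AEParams":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        if meta.get("format") != "cmedgan-ae-v1":
            raise ValueError("not a cmedgan autoencoder checkpoint")
        enc = nn.Net(
            [data[f"enc_w{i}"] for i in range(meta["enc_layers"])],
            [data[f"enc_b{i}"] for i in range(meta["enc_layers"])],
            "linear",
        )
        dec = nn.Net(
            [data[f"dec_w{i}"] for i in range(meta["dec_layers"])],
            [data[f"dec_b{i}"] for i in range(meta["dec_layers"])],
            meta["dec_output"],
        )
        return cls(
            enc, dec, meta["d_latent"], meta["columns"], meta["kinds"],
            meta["parents"], meta["seed"], meta["loss_trace"],
        )


def _with_label(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.hstack([x, np.asarray(y, dtype=float).reshape(-1, 1)])


def reconstruction_loss(
    recon: np.ndarray, target: np.ndarray, binary_mask: np.ndarray
) -> float:
    """Mean per-cell loss: BCE on binary columns, squared error on continuous."""
    eps = 1e-7
    p = np.clip(recon, eps, 1 - eps)
    t = target
    bce = -(t[:, binary_mask] * np.log(p[:, binary_mask])
            + (1 - t[:, binary_mask]) * np.log(1 - p[:, binary_mask])).sum()
    se = ((p[:, ~binary_mask] - t[:, ~binary_mask]) ** 2).sum()
    return float((bce + se) / t.size)


def _output_grad(recon: np.ndarray, target: np.ndarray, binary_mask: np.ndarray) -> np.ndarray:
    """Gradient of the summed mixed loss w.r.t. the decoder's pre-activation."""
    dz = np.empty_like(recon)
    # sigmoid + BCE collapses to (p - t); sigmoid + SE needs the sigmoid slope
    dz[:, binary_mask] = recon[:, binary_mask] - target[:, binary_mask]
    cm = ~binary_mask
    dz[:, cm] = 2.0 * (recon[:, cm] - target[:, cm]) * recon[:, cm] * (1 - recon[:, cm])
    return dz


def train_autoencoder(ft: FeatureTable, y: np.ndarray, cfg: AEConfig) -> AEParams:
    """Train the conditional autoencoder to reproduce its input features.

    Deterministic given ``cfg.seed``; records a per-epoch mean per-cell loss
    trace.  A latent dimension at or above the feature count is allowed (the
    autoencoder is then trivially expressive) but draws a warning.
    """
    if ft.X.min() < 0 or ft.X.max() > 1:
        raise ValueError("features must be normalised to [0, 1]")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != ft.n_rows:
        raise ValueError("labels misaligned with feature rows")
    if cfg.d_latent >= ft.n_cols:
        warnings.warn("d_latent >= n_cols: autoencoder is trivially expressive")

    rng = np.random.default_rng(cfg.seed)
    enc = nn.init_net([ft.n_cols + 1, cfg.hidden, cfg.d_latent], rng, output="linear")
    dec = nn.init_net([cfg.d_latent + 1, cfg.hidden, ft.n_cols], rng, output="sigmoid")
    opt = nn.Adam(lr=cfg.lr)
    bmask = ft.binary_mask
    n = ft.n_rows
    trace: list[float] = []

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = ft.X[idx], y[idx]
            v, enc_cache = nn.forward(enc, _with_label(xb, yb))
            recon, dec_cache = nn.forward(dec, _with_label(v, yb))
            loss = reconstruction_loss(recon, xb, bmask)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite autoencoder loss at epoch {_epoch}; "
                    f"lr={cfg.lr}, batch={cfg.batch_size}"
                )
            epoch_loss += loss * xb.size
            dz = _output_grad(recon, xb, bmask) / xb.size
            dgw, dgb, dvin = nn.backward(dec, dec_cache, dz)
            dv = dvin[:, :-1]  # drop the label column
            egw, egb, _ = nn.backward(enc, enc_cache, dv)
            opt.step(
                enc.params() + dec.params(),
                egw + egb + dgw + dgb,
            )
        trace.append(epoch_loss / ft.X.size)

    return AEParams(
        enc, dec, cfg.d_latent, list(ft.columns), list(ft.kinds),
        dict(ft.parents), cfg.seed, trace,
    )


def encode(p: AEParams, ft: FeatureTable, y: np.ndarray) -> np.ndarray:
    """Map rows to latent codes; one code (length d_latent) per row."""
    if ft.n_cols != p.n_cols:
        raise ValueError(f"expected {p.n_cols} columns, got {ft.n_cols}")
    v, _ = nn.forward(p.encoder, _with_label(ft.X, np.asarray(y, dtype=float)))
    return v


def decode(p: AEParams, v: np.ndarray, y: np.ndarray) -> FeatureTable:
    """Map latent codes (plus labels) back to feature space; outputs in (0, 1)."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 2 or v.shape[1] != p.d_latent:
        raise ValueError(f"expected latent dimension {p.d_latent}, got {v.shape}")
    x, _ = nn.forward(p.decoder, _with_label(v, np.asarray(y, dtype=float)))
    return FeatureTable(x, list(p.columns), list(p.kinds), dict(p.parents))
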