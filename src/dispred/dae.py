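"""Disentangling autoencoder.

An encoder F_theta maps a dosage vector x to two latent blocks: an
ancestry-specific representation z_a and a phenotype-specific representation
z_d.  A decoder G_theta' reconstructs x from their concatenation.  Training
minimises

    L = L_recon + ramp(epoch) * alpha_d * L_SC(z_d | y)
               + ramp(epoch) * alpha_a * L_SC(z_a | a)

where L_recon is the mean squared reconstruction error and L_SC is the
supervised contrastive loss: the batch is duplicated into 2N views, each
embedding is L2-normalised, and same-label pairs are pulled together under a
temperature-scaled softmax over pairwise dot products.  The contrastive
weights are held at zero for the first ramp_start epochs (reconstruction
warm-up) and then ramped linearly to their full values, so the latent space
is organised only after the autoencoder can reconstruct.

Ancestry labels are needed only while training; embedding new individuals
requires genotypes alone, which is the point — downstream risk models built
on z_d do not ask for ancestry at test time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from ._mlp import MLP, Adam
from .data_io import Cohort

__all__ = [
    "AEHyperparams",
    "AEModel",
    "forward",
    "reconstruction_loss",
    "supervised_contrastive_loss",
    "ramp_weight",
    "total_loss",
    "train_dae",
    "embed",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class AEHyperparams:
    """Architecture and training settings for the autoencoder.

    Defaults follow the tuned real-data configuration: 40+40 latent units,
    temperature 0.03, latent-loss weights 1e-4, 500 epochs with the
    contrastive ramp over epochs 100-250, batch size 256, Adam at a constant
    5e-3.  Hidden widths taper m -> 512 -> 256 -> 128 -> (dim_za + dim_zd)
    in the 4-layer encoder; the 3-layer decoder mirrors back up.

    ``unit_norm_latents`` constrains each latent block to the unit
    hypersphere (each of z_a and z_d is L2-normalised as the encoder's final
    operation, and the decoder consumes the normalised concatenation).  The
    contrastive loss only ever sees directions, so without this constraint
    the unconstrained block magnitudes remain a reconstruction side channel
    through which label information can bypass the disentanglement pressure.
    """

    dim_zd: int = 40
    dim_za: int = 40
    tau: float = 0.03
    alpha_d: float = 1e-4
    alpha_a: float = 1e-4
    n_epochs: int = 500
    ramp_start: int = 100
    ramp_end: int = 250
    batch_size: int = 256
    learning_rate: float = 5e-3
    encoder_hidden: tuple[int, ...] = (512, 256, 128)
    decoder_hidden: tuple[int, ...] = (256, 512)
    normalize_embeddings: bool = True
    unit_norm_latents: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ramp_start <= self.ramp_end <= self.n_epochs):
            raise ValueError(
                "need 0 < ramp_start <= ramp_end <= n_epochs, got "
                f"({self.ramp_start}, {self.ramp_end}, {self.n_epochs})"
            )
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        for name in ("dim_zd", "dim_za", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(w <= 0 for w in self.encoder_hidden + self.decoder_hidden):
            raise ValueError("hidden widths must be positive")


@dataclass
class AEModel:
    """Trained encoder/decoder pair plus the per-epoch loss history."""

    encoder: MLP
    decoder: MLP
    hyperparams: AEHyperparams
    n_features: int
    history: list[dict[str, float]] = field(default_factory=list)
    snp_fingerprint: str = ""

    @property
    def latent_dim(self) -> int:
        return self.hyperparams.dim_za + self.hyperparams.dim_zd


def build_model(n_features: int, hp: AEHyperparams) -> AEModel:
    """Fresh model with seeded He-initialised weights."""
    rng = np.random.default_rng(hp.seed)
    latent = hp.dim_za + hp.dim_zd
    enc_widths = (n_features, *hp.encoder_hidden, latent)
    dec_widths = (latent, *hp.decoder_hidden, n_features)
    return AEModel(
        encoder=MLP(enc_widths, rng),
        decoder=MLP(dec_widths, rng),
        hyperparams=hp,
        n_features=n_features,
    )


def _normalize_blocks(
    z: np.ndarray, da: int
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Project each latent block onto the unit sphere; returns norms too."""
    za, zd = z[:, :da], z[:, da:]
    na = np.maximum(np.linalg.norm(za, axis=1, keepdims=True), 1e-12)
    nd = np.maximum(np.linalg.norm(zd, axis=1, keepdims=True), 1e-12)
    return np.hstack([za / na, zd / nd]), (na, nd)


def _normalize_blocks_backward(
    g: np.ndarray, z_unit: np.ndarray, norms: tuple[np.ndarray, np.ndarray], da: int
) -> np.ndarray:
    """Chain rule through per-block L2 normalisation."""
    out = np.empty_like(g)
    for sl, nrm in ((slice(0, da), norms[0]), (slice(da, None), norms[1])):
        u = z_unit[:, sl]
        gu = g[:, sl]
        out[:, sl] = (gu - (gu * u).sum(axis=1, keepdims=True) * u) / nrm
    return out


def _encode(model: AEModel, x_batch: np.ndarray) -> np.ndarray:
    z = model.encoder.forward(x_batch)
    if model.hyperparams.unit_norm_latents:
        z, _ = _normalize_blocks(z, model.hyperparams.dim_za)
    return z


def forward(
    model: AEModel, x_batch: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a batch and reconstruct it; returns (z_a, z_d, x_hat).

    The encoder output is split with z_a first, and the decoder consumes the
    concatenation [z_a || z_d] in that fixed order.  With
    ``unit_norm_latents`` each block is L2-normalised before the split.
    """
    x_batch = np.asarray(x_batch, dtype=float)
    if x_batch.ndim != 2 or x_batch.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} columns, got shape {x_batch.shape}"
        )
    z = _encode(model, x_batch)
    da = model.hyperparams.dim_za
    z_a, z_d = z[:, :da], z[:, da:]
    x_hat = model.decoder.forward(z)
    return z_a, z_d, x_hat


def reconstruction_loss(x_batch: np.ndarray, x_hat_batch: np.ndarray) -> float:
    """Mean over examples of the per-example mean squared error."""
    x_batch = np.asarray(x_batch, dtype=float)
    x_hat_batch = np.asarray(x_hat_batch, dtype=float)
    if x_batch.shape != x_hat_batch.shape:
        raise ValueError("x and x_hat shapes must match")
    if x_batch.size == 0:
        raise ValueError("empty batch")
    return float(np.mean((x_batch - x_hat_batch) ** 2))


def _supcon_core(
    z: np.ndarray, labels: np.ndarray, tau: float, normalize: bool
) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. the ORIGINAL (pre-duplication) embeddings.

    The 2N multi-view batch is the batch stacked with itself; the gradient of
    the duplicated batch therefore folds back as the sum over both copies.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2:
        raise ValueError("embeddings must be 2-D (batch, dim)")
    n = z.shape[0]
    if n < 2:
        raise ValueError("supervised contrastive loss needs a batch of size >= 2")
    if not np.isfinite(z).all():
        raise ValueError("non-finite embeddings")
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("one label per embedding required")

    z2 = np.vstack([z, z])
    lab2 = np.concatenate([labels, labels])
    if normalize:
        norms = np.linalg.norm(z2, axis=1, keepdims=True)
        norms = np.maximum(norms, 1e-12)
        u = z2 / norms
    else:
        u = z2
    n2 = 2 * n

    sims = (u @ u.T) / tau
    np.fill_diagonal(sims, -np.inf)  # r != i in the denominator
    row_max = sims.max(axis=1, keepdims=True)
    ex = np.exp(sims - row_max)
    denom = ex.sum(axis=1)
    log_denom = np.log(denom) + row_max[:, 0]

    pos = (lab2[:, None] == lab2[None, :]) & ~np.eye(n2, dtype=bool)
    cnt = pos.sum(axis=1)  # >= 1 always: the duplicate shares the label
    sims_finite = np.where(np.isfinite(sims), sims, 0.0)
    loss = float(np.sum(log_denom - (pos * sims_finite).sum(axis=1) / cnt))

    # dL/d(sims_ij) = softmax_ij - pos_ij / cnt_i; sims is symmetric in u,
    # so the gradient w.r.t. u collects both orientations.
    p = ex / denom[:, None]
    g = (p - pos / cnt[:, None]) / tau
    gu = (g + g.T) @ u
    if normalize:
        gz2 = (gu - (gu * u).sum(axis=1, keepdims=True) * u) / norms
    else:
        gz2 = gu
    return loss, gz2[:n] + gz2[n:]


def supervised_contrastive_loss(
    z_batch: np.ndarray,
    labels: np.ndarray,
    tau: float,
    normalize: bool = True,
) -> float:
    """Supervised contrastive loss over the duplicated (2N-view) batch.

    For every index i in the 2N views, with S(i) the same-label indices other
    than i, the loss accumulates

        -(1/|S(i)|) * sum_{s in S(i)} log[ exp(u_i . u_s / tau)
                                           / sum_{r != i} exp(u_i . u_r / tau) ]

    with u the L2-normalised embeddings (normalisation can be switched off).
    Views are exact duplicates — no augmentation — so each i always has at
    least one positive.
    """
    loss, _ = _supcon_core(z_batch, labels, tau, normalize)
    return loss


def ramp_weight(epoch: int, ramp_start: int, ramp_end: int) -> float:
    """Contrastive-weight multiplier: 0 through ramp_start, then linear to 1.

    Epochs are 1-based.  The multiplier is exactly 0 at ``epoch <=
    ramp_start``, exactly 1 at ``epoch >= ramp_end``, and linear in between.
    """
    if ramp_start > ramp_end:
        raise ValueError(f"ramp_start {ramp_start} exceeds ramp_end {ramp_end}")
    if epoch <= ramp_start:
        return 0.0
    if epoch >= ramp_end:
        return 1.0
    return (epoch - ramp_start) / (ramp_end - ramp_start)


def total_loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    z_a: np.ndarray,
    z_d: np.ndarray,
    y: np.ndarray,
    a: np.ndarray,
    hp: AEHyperparams,
    epoch: int,
) -> tuple[float, dict[str, float]]:
    """Composite objective and its separately reported components."""
    w = ramp_weight(epoch, hp.ramp_start, hp.ramp_end)
    recon = reconstruction_loss(x, x_hat)
    sc_d = supervised_contrastive_loss(z_d, y, hp.tau, hp.normalize_embeddings)
    sc_a = supervised_contrastive_loss(z_a, a, hp.tau, hp.normalize_embeddings)
    total = recon + w * hp.alpha_d * sc_d + w * hp.alpha_a * sc_a
    return total, {
        "recon": recon,
        "sc_d": sc_d,
        "sc_a": sc_a,
        "ramp": w,
        "total": total,
    }


def train_dae(
    train_cohort: Cohort,
    validation_cohort: Cohort | None,
    hp: AEHyperparams,
) -> AEModel:
    """Train the autoencoder with Adam on shuffled mini-batches.

    The training cohort must be imputed and carry both phenotype (y) and
    ancestry (a) labels; the validation cohort, when given, is only used to
    record a validation reconstruction loss per epoch (model selection is
    external — there is no early stopping).  The last incomplete mini-batch
    is kept.  Fully deterministic under the hyperparameter seed.
    """
    if np.isnan(train_cohort.x).any():
        raise ValueError("training cohort contains missing dosages; impute first")
    if train_cohort.y is None:
        raise ValueError("phenotype labels are required to train")
    if train_cohort.a is None:
        raise ValueError("ancestry labels are required to train")

    model = build_model(train_cohort.m, hp)
    model.snp_fingerprint = _fingerprint(train_cohort)
    params = model.encoder.parameters + model.decoder.parameters
    grads = model.encoder.gradients + model.decoder.gradients
    opt = Adam(params, grads, lr=hp.learning_rate)
    rng = np.random.default_rng(hp.seed + 1)

    x = train_cohort.x
    y = train_cohort.y
    a = train_cohort.a
    n = train_cohort.n
    da = hp.dim_za

    for epoch in range(1, hp.n_epochs + 1):
        w = ramp_weight(epoch, hp.ramp_start, hp.ramp_end)
        order = rng.permutation(n)
        ep = {"recon": 0.0, "sc_d": 0.0, "sc_a": 0.0}
        n_batches = 0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            if len(idx) < 2:
                continue  # SC loss is undefined on a singleton batch
            xb, yb, ab = x[idx], y[idx], a[idx]
            z_raw = model.encoder.forward(xb)
            if hp.unit_norm_latents:
                z, norms = _normalize_blocks(z_raw, da)
            else:
                z = z_raw
            x_hat = model.decoder.forward(z)

            recon = reconstruction_loss(xb, x_hat)
            g_xhat = 2.0 * (x_hat - xb) / xb.size
            model.encoder.zero_grad()
            model.decoder.zero_grad()
            g_z = model.decoder.backward(g_xhat)

            sc_d_val = sc_a_val = 0.0
            if w > 0.0 and (hp.alpha_d > 0 or hp.alpha_a > 0):
                if hp.alpha_d > 0:
                    sc_d_val, g_zd = _supcon_core(
                        z[:, da:], yb, hp.tau, hp.normalize_embeddings
                    )
                    g_z[:, da:] += w * hp.alpha_d * g_zd
                if hp.alpha_a > 0:
                    sc_a_val, g_za = _supcon_core(
                        z[:, :da], ab, hp.tau, hp.normalize_embeddings
                    )
                    g_z[:, :da] += w * hp.alpha_a * g_za
            if hp.unit_norm_latents:
                g_z = _normalize_blocks_backward(g_z, z, norms, da)
            model.encoder.backward(g_z)
            opt.step()

            ep["recon"] += recon
            ep["sc_d"] += sc_d_val
            ep["sc_a"] += sc_a_val
            n_batches += 1

        record = {k: v / max(n_batches, 1) for k, v in ep.items()}
        record["ramp"] = w
        record["total"] = (
            record["recon"]
            + w * hp.alpha_d * record["sc_d"]
            + w * hp.alpha_a * record["sc_a"]
        )
        if validation_cohort is not None:
            _, _, xv_hat = forward(model, validation_cohort.x)
            record["val_recon"] = reconstruction_loss(validation_cohort.x, xv_hat)
        model.history.append(record)
    return model


def embed(model: AEModel, cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Latents (z_a, z_d) for every individual; no labels needed."""
    if cohort.m != model.n_features:
        raise ValueError(
            f"cohort has {cohort.m} SNPs but the model was trained on "
            f"{model.n_features}"
        )
    if np.isnan(cohort.x).any():
        raise ValueError("cohort contains missing dosages; impute first")
    z = _encode(model, cohort.x)
    da = model.hyperparams.dim_za
    return z[:, :da], z[:, da:]


def _fingerprint(cohort: Cohort) -> str:
    import hashlib

    h = hashlib.sha256("\n".join(s.snp_id for s in cohort.snps).encode())
    return h.hexdigest()[:16]


def save_model(model: AEModel, path: str | os.PathLike) -> None:
    """Serialise weights, hyperparameters and the SNP-list fingerprint."""
    hp = model.hyperparams
    arrays = {
        f"enc_{i}": arr for i, arr in enumerate(model.encoder.get_state())
    }
    arrays.update(
        {f"dec_{i}": arr for i, arr in enumerate(model.decoder.get_state())}
    )
    import json

    meta = {
        "hyperparams": {
            **{k: getattr(hp, k) for k in (
                "dim_zd", "dim_za", "tau", "alpha_d", "alpha_a", "n_epochs",
                "ramp_start", "ramp_end", "batch_size", "learning_rate",
                "normalize_embeddings", "unit_norm_latents", "seed",
            )},
            "encoder_hidden": list(hp.encoder_hidden),
            "decoder_hidden": list(hp.decoder_hidden),
        },
        "n_features": model.n_features,
        "snp_fingerprint": model.snp_fingerprint,
    }
    np.savez(path, _meta=json.dumps(meta, sort_keys=True), **arrays)


def load_model(path: str | os.PathLike) -> AEModel:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["_meta"]))
        hp_dict = meta["hyperparams"]
        hp_dict["encoder_hidden"] = tuple(hp_dict["encoder_hidden"])
        hp_dict["decoder_hidden"] = tuple(hp_dict["decoder_hidden"])
        hp = AEHyperparams(**hp_dict)
        model = build_model(meta["n_features"], hp)
        n_enc = len(model.encoder.parameters)
        model.encoder.set_state([data[f"enc_{i}"] for i in range(n_enc)])
        n_dec = len(model.decoder.parameters)
        model.decoder.set_state([data[f"dec_{i}"] for i in range(n_dec)])
        model.snp_fingerprint = meta["snp_fingerprint"]
    return model
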