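"""Latent-space Cycle-GAN for missing-modality imputation.

Two generators and two discriminators bridge a pair of per-modality latent
spaces (e.g. sMRI <-> fMRI). Generators are MLPs with hidden widths 256,
512, 512, 1024, 512 (ReLU) and a linear output at the latent width;
discriminators are MLPs with widths 256, 128, 64, 1 (LeakyReLU) with
dropout 0.3 between layers. Training combines an adversarial objective
(least-squares by default, binary cross-entropy by config) with L1
cycle-consistency in both directions, Adam at learning rate 1e-4, one
discriminator step then one generator step per mini-batch. Held-out
imputation quality is tracked as the mean absolute error per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .models import LatentVector
from .nn import (
    Adam,
    Dense,
    Dropout,
    LeakyReLU,
    ReLU,
    Sequential,
    bce_discriminator_loss,
    bce_generator_loss,
    l1_loss,
    lsgan_discriminator_loss,
    lsgan_generator_loss,
)
from .nn.layers import Layer

GENERATOR_HIDDEN = (256, 512, 512, 1024, 512)
DISCRIMINATOR_HIDDEN = (256, 128, 64)


class FixedAffine(Layer):
    """Non-trainable elementwise affine map (latent standardization)."""

    def __init__(self, scale: np.ndarray, shift: np.ndarray):
        self.scale = np.asarray(scale, dtype=np.float64)
        self.shift = np.asarray(shift, dtype=np.float64)

    def forward(self, x, train=False):
        return x * self.scale + self.shift

    def backward(self, gy):
        return gy * self.scale

    def out_shape(self, in_shape):
        return in_shape


def build_generator(
    latent_dim: int,
    rng: np.random.Generator,
    hidden: tuple[int, ...] = GENERATOR_HIDDEN,
) -> Sequential:
    layers: list = []
    width = latent_dim
    for h in hidden:
        layers += [Dense(width, h, rng), ReLU()]
        width = h
    layers.append(Dense(width, latent_dim, rng))
    return Sequential(layers)


def build_discriminator(
    latent_dim: int,
    rng: np.random.Generator,
    hidden: tuple[int, ...] = DISCRIMINATOR_HIDDEN,
    dropout: float = 0.3,
) -> Sequential:
    layers: list = []
    width = latent_dim
    for h in hidden:
        layers += [Dense(width, h, rng), LeakyReLU(), Dropout(dropout, rng)]
        width = h
    layers.append(Dense(width, 1, rng))
    return Sequential(layers)


@dataclass
class GANLossReport:
    epoch: int
    d_a: float
    d_b: float
    g_ab_adv: float
    g_ba_adv: float
    cycle_a: float
    cycle_b: float
    val_mae_ab: float | None = None
    val_mae_ba: float | None = None

    def __post_init__(self):
        for name in ("d_a", "d_b", "g_ab_adv", "g_ba_adv", "cycle_a", "cycle_b"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name}={v} is not a finite non-negative loss")


@dataclass
class CycleGANPair:
    domain_a: str
    domain_b: str
    g_ab: Sequential
    g_ba: Sequential
    d_a: Sequential
    d_b: Sequential
    norm_a: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)
    norm_b: tuple[np.ndarray, np.ndarray] | None = None
    history: list[GANLossReport] = field(default_factory=list)

    def bridge(self, src: str, dst: str) -> Sequential:
        """The latent-to-latent map from ``src`` to ``dst``, including any
        standardization affines, as a single backprop-capable network."""
        if (src, dst) == (self.domain_a, self.domain_b):
            gen, ns, nd = self.g_ab, self.norm_a, self.norm_b
        elif (src, dst) == (self.domain_b, self.domain_a):
            gen, ns, nd = self.g_ba, self.norm_b, self.norm_a
        else:
            raise ValueError(
                f"pair bridges {self.domain_a}<->{self.domain_b}, not {src}->{dst}"
            )
        if ns is None and nd is None:
            return gen
        layers: list = []
        if ns is not None:
            mu, sd = ns
            layers.append(FixedAffine(1.0 / sd, -mu / sd))
        layers += gen.layers
        if nd is not None:
            mu, sd = nd
            layers.append(FixedAffine(sd, mu))
        return Sequential(layers)

    def generator_checksums(self) -> tuple[float, float]:
        return self.g_ab.checksum(), self.g_ba.checksum()


def adversarial_loss(
    scores_real: np.ndarray | None,
    scores_fake: np.ndarray,
    side: str,
    form: str = "lsgan",
) -> float:
    """Adversarial loss value. ``side='D'`` needs both score batches;
    ``side='G'`` uses the fake scores only."""
    scores_fake = np.asarray(scores_fake, dtype=np.float64)
    if side == "D":
        if scores_real is None:
            raise ValueError("discriminator loss needs real scores")
        scores_real = np.asarray(scores_real, dtype=np.float64)
        fn = lsgan_discriminator_loss if form == "lsgan" else bce_discriminator_loss
        return fn(scores_real, scores_fake)[0]
    if side == "G":
        fn = lsgan_generator_loss if form == "lsgan" else bce_generator_loss
        return fn(scores_fake)[0]
    raise ValueError(f"side must be 'D' or 'G', got {side!r}")


def cycle_consistency_loss(
    x: np.ndarray, g_ab: Sequential, g_ba: Sequential
) -> float:
    """Mean absolute difference between ``x`` and ``G_ba(G_ab(x))``."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if x.size == 0:
        raise ValueError("empty batch")
    rec = g_ba.forward(g_ab.forward(x))
    if rec.shape != x.shape:
        raise ValueError(f"cycle output shape {rec.shape} != input {x.shape}")
    return float(np.mean(np.abs(rec - x)))


def evaluate_generator_mae(
    pair: CycleGANPair, a_val: np.ndarray, b_val: np.ndarray
) -> dict[str, float]:
    """Held-out MAE per direction: mean over subjects and latent dimensions
    of the absolute difference between the true and generated latents."""
    a_val, b_val = np.atleast_2d(a_val), np.atleast_2d(b_val)
    if a_val.size == 0 or b_val.size == 0:
        raise ValueError("empty held-out set")
    if a_val.shape[0] != b_val.shape[0]:
        raise ValueError("held-out latents are not paired")
    mae_ab = float(np.mean(np.abs(pair.bridge(pair.domain_a, pair.domain_b).forward(a_val) - b_val)))
    mae_ba = float(np.mean(np.abs(pair.bridge(pair.domain_b, pair.domain_a).forward(b_val) - a_val)))
    return {
        f"{pair.domain_a}->{pair.domain_b}": mae_ab,
        f"{pair.domain_b}->{pair.domain_a}": mae_ba,
    }


def impute_latent(pair: CycleGANPair, source: LatentVector, target: str) -> LatentVector:
    """Generate the ``target`` modality's latent from ``source``."""
    bridge = pair.bridge(source.modality, target)
    values = bridge.forward(np.atleast_2d(source.values))[0]
    return LatentVector(values=values, modality=target, provenance="generated", source=source.modality)


def train_cyclegan(
    latents_a: np.ndarray,
    latents_b: np.ndarray,
    config: RunConfig,
    domain_a: str = "smri",
    domain_b: str = "fmri",
    subject_ids_a: list[str] | None = None,
    subject_ids_b: list[str] | None = None,
    batches: list[np.ndarray] | None = None,
    val_indices: np.ndarray | None = None,
    generator_hidden: tuple[int, ...] = GENERATOR_HIDDEN,
    discriminator_hidden: tuple[int, ...] = DISCRIMINATOR_HIDDEN,
    seed: int | None = None,
) -> CycleGANPair:
    """Train a generator/discriminator pair on paired latent sets.

    ``batches`` lets the caller reuse the bi-modal models' batch
    composition (same subjects per batch); when omitted, fixed sequential
    batches of ``config.batch_smri_fmri`` are formed. ``val_indices``
    subjects are excluded from training and used for per-epoch MAE.
    """
    a = np.atleast_2d(np.asarray(latents_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(latents_b, dtype=np.float64))
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"unpaired latent sets: {a.shape[0]} vs {b.shape[0]} subjects")
    if subject_ids_a is not None and subject_ids_b is not None:
        if list(subject_ids_a) != list(subject_ids_b):
            raise ValueError("subject id lists do not match; latents must be paired")
    n = a.shape[0]
    rng = np.random.default_rng(config.seed if seed is None else seed)

    norm_a = norm_b = None
    train_idx = np.arange(n)
    if val_indices is not None:
        val_indices = np.asarray(val_indices)
        train_idx = np.setdiff1d(train_idx, val_indices)
    if config.standardize_latents:
        norm_a = (a[train_idx].mean(axis=0), a[train_idx].std(axis=0) + 1e-8)
        norm_b = (b[train_idx].mean(axis=0), b[train_idx].std(axis=0) + 1e-8)
        a = (a - norm_a[0]) / norm_a[1]
        b = (b - norm_b[0]) / norm_b[1]

    d = a.shape[1]
    pair = CycleGANPair(
        domain_a=domain_a,
        domain_b=domain_b,
        g_ab=build_generator(d, rng, generator_hidden),
        g_ba=build_generator(d, rng, generator_hidden),
        d_a=build_discriminator(d, rng, discriminator_hidden),
        d_b=build_discriminator(d, rng, discriminator_hidden),
    )
    if batches is None:
        bs = config.batch_smri_fmri
        batches = [train_idx[i : i + bs] for i in range(0, len(train_idx), bs)]
        batches = [bt for bt in batches if len(bt) > 0]

    opt_g = Adam(pair.g_ab.params() + pair.g_ba.params(), lr=config.learning_rate)
    opt_d = Adam(pair.d_a.params() + pair.d_b.params(), lr=config.learning_rate)
    lam = config.cycle_loss_weight
    lsgan = config.adversarial_form == "lsgan"
    d_loss_fn = lsgan_discriminator_loss if lsgan else bce_discriminator_loss
    g_loss_fn = lsgan_generator_loss if lsgan else bce_generator_loss

    for epoch in range(config.epochs_cgan):
        ep = dict(d_a=0.0, d_b=0.0, g_ab_adv=0.0, g_ba_adv=0.0, cycle_a=0.0, cycle_b=0.0)
        for bt in batches:
            xa, xb = a[bt], b[bt]
            m = len(bt)
            # --- discriminator step (generators held fixed) -------------
            fake_b = pair.g_ab.forward(xa)
            fake_a = pair.g_ba.forward(xb)
            for dsc, real, fake, key in (
                (pair.d_b, xb, fake_b, "d_b"),
                (pair.d_a, xa, fake_a, "d_a"),
            ):
                dsc.zero_grad()
                scores = dsc.forward(np.vstack([real, fake]), train=True)
                loss, g_real, g_fake = d_loss_fn(scores[:m], scores[m:])
                dsc.backward(np.vstack([g_real, g_fake]))
                ep[key] += loss
            opt_d.step()
            # --- generator step ----------------------------------------
            pair.g_ab.zero_grad()
            pair.g_ba.zero_grad()
            for g_fwd, g_cyc, dsc, x_src, adv_key, cyc_key in (
                (pair.g_ab, pair.g_ba, pair.d_b, xa, "g_ab_adv", "cycle_a"),
                (pair.g_ba, pair.g_ab, pair.d_a, xb, "g_ba_adv", "cycle_b"),
            ):
                fake = g_fwd.forward(x_src)
                scores = dsc.forward(fake, train=False)
                adv, g_scores = g_loss_fn(scores)
                dsc.zero_grad()  # discard D grads from this pass
                g_fake_adv = dsc.backward(g_scores)
                dsc.zero_grad()
                rec = g_cyc.forward(fake)
                cyc, g_rec = l1_loss(rec, x_src)
                g_fake_cyc = g_cyc.backward(lam * g_rec)
                g_fwd.backward(g_fake_adv + g_fake_cyc)
                ep[adv_key] += adv
                ep[cyc_key] += cyc
            opt_g.step()
        nb = max(len(batches), 1)
        report = GANLossReport(epoch=epoch, **{k: v / nb for k, v in ep.items()})
        if val_indices is not None and len(val_indices):
            mae = evaluate_generator_mae(
                CycleGANPair(domain_a, domain_b, pair.g_ab, pair.g_ba, pair.d_a, pair.d_b),
                a[val_indices],
                b[val_indices],
            )
            report.val_mae_ab = mae[f"{domain_a}->{domain_b}"]
            report.val_mae_ba = mae[f"{domain_b}->{domain_a}"]
        pair.history.append(report)

    pair.norm_a, pair.norm_b = norm_a, norm_b
    return pair
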