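"""Feature-reduction encoders and the fusion/classification head.

Three per-modality CNN encoders map each channel to a shared-width latent
vector (100 features per channel in the reference configuration):

* sMRI: 3D CNN, six conv layers (3x3x3 kernels for the first four, 2x2x2
  for the last two; 64, 64, 64, 128, 128, 128 filters), three max-pooling
  layers, then four fully-connected layers (1536, 768, 384, 192) and a
  final linear projection to the latent width;
* rs-fMRI: 1D CNN over the 1378-length sFNC vector, four conv layers
  (kernel 5; 64, 128, 128, 128 filters), two max-pooling layers, two
  fully-connected layers (384, latent width);
* SNPs: 1D CNN over the dosage vector, three blocks of conv (kernel 3;
  64, 64, 128 filters) + batch-norm + max-pooling, then three
  fully-connected layers (1024, 512, 128) and a projection to the latent
  width.

The fused classifier concatenates the per-channel latents (3 x 100 = 300
features) and applies a three-layer MLP (150, 75, 2) with ReLU, softmax on
the output. When a modality is missing, ``forward_routed`` consults the
latent-space generators: a missing fMRI or SNP latent is generated from
the sMRI latent; a missing sMRI latent has no direct bridge and is an
error unless chained bridging is enabled in the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .features import ModalityInputs
from .nn import (
    BatchNorm,
    Conv1D,
    Conv3D,
    Dense,
    Flatten,
    MaxPool1D,
    MaxPool3D,
    ReLU,
    Sequential,
    softmax,
)

MODALITY_TAGS = {"smri": "s", "fmri": "f", "snp": "g"}


class RoutingError(RuntimeError):
    """No generator bridge can supply a required missing latent."""


@dataclass
class ConvBlock:
    kernel: int
    filters: int
    batchnorm: bool = False
    pool: bool = False


@dataclass
class EncoderSpec:
    modality: str
    conv: list[ConvBlock]
    fc: list[int]
    project_to_latent: bool = True

    def __post_init__(self):
        if self.modality not in MODALITY_TAGS:
            raise ValueError(f"unknown modality {self.modality!r}")
        for b in self.conv:
            if b.kernel < 1 or b.filters < 1:
                raise ValueError("conv kernel and filter counts must be positive")
        if any(w < 1 for w in self.fc):
            raise ValueError("fully-connected widths must be positive")


def reference_encoder_spec(modality: str) -> EncoderSpec:
    """The reference architectures (pooling placed evenly: sMRI after conv
    2/4/6, fMRI after conv 2/4, SNP one pool per block)."""
    if modality == "smri":
        return EncoderSpec(
            modality="smri",
            conv=[
                ConvBlock(3, 64),
                ConvBlock(3, 64, pool=True),
                ConvBlock(3, 64),
                ConvBlock(3, 128, pool=True),
                ConvBlock(2, 128),
                ConvBlock(2, 128, pool=True),
            ],
            fc=[1536, 768, 384, 192],
        )
    if modality == "fmri":
        return EncoderSpec(
            modality="fmri",
            conv=[
                ConvBlock(5, 64),
                ConvBlock(5, 128, pool=True),
                ConvBlock(5, 128),
                ConvBlock(5, 128, pool=True),
            ],
            fc=[384, 100],
            project_to_latent=False,  # last FC width is the latent width
        )
    if modality == "snp":
        return EncoderSpec(
            modality="snp",
            conv=[
                ConvBlock(3, 64, batchnorm=True, pool=True),
                ConvBlock(3, 64, batchnorm=True, pool=True),
                ConvBlock(3, 128, batchnorm=True, pool=True),
            ],
            fc=[1024, 512, 128],
        )
    raise ValueError(f"unknown modality {modality!r}")


def scaled_encoder_spec(
    modality: str, width: int = 8, fc_width: int = 32, pool: bool = True
) -> EncoderSpec:
    """Desk-scale variants preserving each channel's layer pattern.

    ``pool=False`` drops the max-pooling stages: on small grids pooling
    costs feature localization (the pooled maximum moves from subject to
    subject), which blurs gradient-based attribution.
    """
    if modality == "smri":
        conv = [ConvBlock(3, width, pool=pool), ConvBlock(3, width, pool=pool)]
    elif modality == "fmri":
        conv = [ConvBlock(5, width, pool=pool), ConvBlock(5, width, pool=pool)]
    else:
        conv = [ConvBlock(3, width, batchnorm=True, pool=pool)]
    return EncoderSpec(modality=modality, conv=conv, fc=[fc_width])


def encoder_input_shape(modality: str, config: RunConfig) -> tuple[int, ...]:
    if modality == "smri":
        return (1,) + tuple(config.volume_shape)
    if modality == "fmri":
        return (1, config.n_fnc_features)
    if modality == "snp":
        return (1, config.n_snps)
    raise ValueError(f"unknown modality {modality!r}")


def encoder_layout(
    spec: EncoderSpec, config: RunConfig
) -> list[tuple[str, dict, tuple[int, ...]]]:
    """Plan an encoder as ``(kind, params, out_shape)`` entries, without
    allocating any weights.

    This is the single source of truth for encoder construction;
    :func:`build_encoder` materializes the plan. Validating the
    full-resolution reference architectures goes through the plan alone —
    the first fully-connected layer of the printed sMRI stack holds ~10^9
    weights, far beyond what is sensible to allocate for a shape check.

    When the input grid is too small for the full conv/pool chain (scaled
    volume shapes), trailing conv or pool layers that no longer fit are
    dropped rather than failing, preserving filter counts where possible.
    """
    layout: list[tuple[str, dict, tuple[int, ...]]] = []
    shape = encoder_input_shape(spec.modality, config)
    for block in spec.conv:
        pad = (block.kernel - 1) // 2 if block.kernel % 2 == 1 else 0
        if min(shape[1:]) + 2 * pad < block.kernel:
            break  # grid exhausted; truncate remaining conv chain
        delta = 2 * pad - block.kernel + 1
        shape = (block.filters,) + tuple(s + delta for s in shape[1:])
        layout.append(("conv", {"kernel": block.kernel, "filters": block.filters}, shape))
        layout.append(("relu", {}, shape))
        if block.batchnorm:
            layout.append(("batchnorm", {"channels": block.filters}, shape))
        if block.pool and min(shape[1:]) >= 2:
            shape = (shape[0],) + tuple(s // 2 for s in shape[1:])
            layout.append(("pool", {}, shape))
    width = int(np.prod(shape))
    layout.append(("flatten", {}, (width,)))
    fc = list(spec.fc)
    if not spec.project_to_latent and fc:
        fc[-1] = config.latent_dim
    for w in fc:
        layout.append(("dense", {"n_in": width, "n_out": w}, (w,)))
        layout.append(("relu", {}, (w,)))
        width = w
    if width != config.latent_dim or spec.project_to_latent:
        layout.append(("dense", {"n_in": width, "n_out": config.latent_dim},
                       (config.latent_dim,)))
    return layout


def build_encoder(
    modality: str,
    spec: EncoderSpec,
    config: RunConfig,
    rng: np.random.Generator,
) -> Sequential:
    """Materialize the encoder plan as a ``Sequential`` ending in
    ``latent_dim``; see :func:`encoder_layout` for the construction rules."""
    if spec.modality != modality:
        raise ValueError(f"spec is for {spec.modality!r}, not {modality!r}")
    is3d = modality == "smri"
    conv_cls = Conv3D if is3d else Conv1D
    pool_cls = MaxPool3D if is3d else MaxPool1D
    c_in = encoder_input_shape(modality, config)[0]
    layers: list = []
    for kind, params, shape in encoder_layout(spec, config):
        if kind == "conv":
            layers.append(conv_cls(c_in, params["filters"], params["kernel"], rng))
            c_in = params["filters"]
        elif kind == "relu":
            layers.append(ReLU())
        elif kind == "batchnorm":
            layers.append(BatchNorm(params["channels"]))
        elif kind == "pool":
            layers.append(pool_cls())
        elif kind == "flatten":
            layers.append(Flatten())
        elif kind == "dense":
            layers.append(Dense(params["n_in"], params["n_out"], rng))
    model = Sequential(layers)
    out = model.out_shape(encoder_input_shape(modality, config))
    assert out == (config.latent_dim,), out
    return model


@dataclass
class FusionClassifierSpec:
    n_channels: int = 3
    hidden: tuple[int, int] = (150, 75)
    n_classes: int = 2

    def input_width(self, latent_dim: int) -> int:
        return self.n_channels * latent_dim


def build_head(
    spec: FusionClassifierSpec, latent_dim: int, rng: np.random.Generator
) -> Sequential:
    layers: list = []
    width = spec.input_width(latent_dim)
    for h in spec.hidden:
        layers += [Dense(width, h, rng), ReLU()]
        width = h
    layers.append(Dense(width, spec.n_classes, rng))
    return Sequential(layers)


@dataclass
class LatentVector:
    values: np.ndarray
    modality: str
    provenance: str  # "encoded" | "generated"
    source: str | None = None  # generating modality when provenance == "generated"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent vector has non-finite entries")
        if self.provenance not in ("encoded", "generated"):
            raise ValueError(f"bad provenance {self.provenance!r}")


class FusionModel:
    """Per-modality encoders + fusion head, with latent-space routing.

    ``generators`` maps directed modality pairs like ``("smri", "fmri")``
    to latent-to-latent ``Sequential`` networks (the frozen Cycle-GAN
    generators in the full framework).
    """

    def __init__(
        self,
        encoders: dict[str, Sequential],
        head: Sequential,
        config: RunConfig,
        generators: dict[tuple[str, str], Sequential] | None = None,
    ):
        self.modalities = list(encoders)
        self.encoders = encoders
        self.head = head
        self.config = config
        self.generators = generators or {}

    # --- parameter plumbing (generators intentionally excluded) ----------
    def trainable_params(self):
        params = []
        for enc in self.encoders.values():
            params += enc.params()
        params += self.head.params()
        return params

    def zero_grad(self):
        for enc in self.encoders.values():
            enc.zero_grad()
        self.head.zero_grad()
        for gen in self.generators.values():
            gen.zero_grad()

    # --- complete-data path ----------------------------------------------
    def _stack(self, batch: list[ModalityInputs], modality: str) -> np.ndarray:
        attr = {"smri": "volume", "fmri": "fnc", "snp": "snp"}[modality]
        arrays = [getattr(mi, attr) for mi in batch]
        if any(a is None for a in arrays):
            raise ValueError(f"batch has subjects missing {modality}")
        x = np.stack(arrays)
        return x[:, None, ...]  # channel axis

    def forward_arrays(
        self, arrays: dict[str, np.ndarray], train: bool = False
    ) -> np.ndarray:
        """Encode pre-stacked channel arrays ``(N, 1, ...)`` and classify."""
        latents = [
            self.encoders[m].forward(arrays[m], train=train) for m in self.modalities
        ]
        self._latent_dims = [z.shape[1] for z in latents]
        fused = np.concatenate(latents, axis=1)
        return self.head.forward(fused, train=train)

    def backward_arrays(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        dfused = self.head.backward(dlogits)
        grads, ofs = {}, 0
        for m, d in zip(self.modalities, self._latent_dims):
            grads[m] = self.encoders[m].backward(dfused[:, ofs : ofs + d])
            ofs += d
        return grads

    def forward(self, batch: list[ModalityInputs], train: bool = False) -> np.ndarray:
        arrays = {m: self._stack(batch, m) for m in self.modalities}
        return self.forward_arrays(arrays, train=train)

    # --- routed path ------------------------------------------------------
    def _route_plan(self, mask: dict[str, bool]) -> list[tuple[str, str | None]]:
        """Return [(modality, source_or_None), ...]; source None = encoded."""
        plan: list[tuple[str, str | None]] = []
        if mask.get("smri", False):
            plan.append(("smri", None))
            for m in ("fmri", "snp"):
                if m in self.modalities:
                    plan.append((m, None if mask.get(m, False) else "smri"))
            return plan
        if not self.config.allow_chained_bridges:
            raise RoutingError(
                "sMRI is missing and no direct bridge exists between fMRI and "
                "SNP latents; enable allow_chained_bridges to chain through sMRI"
            )
        source = "fmri" if mask.get("fmri", False) else "snp" if mask.get("snp", False) else None
        if source is None:
            raise RoutingError("no modality available")
        # encode the source first, bridge to sMRI, then fill the rest from it
        plan.append((source, None))
        plan.append(("smri", source))
        for m in ("fmri", "snp"):
            if m in self.modalities and m != source:
                plan.append((m, None if mask.get(m, False) else "smri"))
        return plan

    def _generator(self, src: str, dst: str) -> Sequential:
        try:
            return self.generators[(src, dst)]
        except KeyError:
            raise RoutingError(f"no trained generator for {src} -> {dst}")

    def forward_routed(
        self, batch: list[ModalityInputs], train: bool = False
    ) -> tuple[np.ndarray, list[dict[str, str]]]:
        """Forward pass for a batch sharing one availability mask.

        Present modalities are encoded; absent ones are imputed by the
        designated latent generator. Returns logits and, per subject, a
        provenance record per channel.
        """
        mask = {m: batch[0].mask()["smri fmri snp".split().index(m)] for m in self.modalities}
        for mi in batch[1:]:
            other = {m: mi.mask()["smri fmri snp".split().index(m)] for m in self.modalities}
            if other != mask:
                raise ValueError("forward_routed requires a uniform availability mask")
        plan = self._route_plan(mask)
        latents: dict[str, np.ndarray] = {}
        self._routed_plan = plan
        for modality, source in plan:
            if source is None:
                latents[modality] = self.encoders[modality].forward(
                    self._stack(batch, modality), train=train
                )
            else:
                gen = self._generator(source, modality)
                latents[modality] = gen.forward(latents[source], train=False)
        self._latent_dims = [latents[m].shape[1] for m in self.modalities]
        fused = np.concatenate([latents[m] for m in self.modalities], axis=1)
        logits = self.head.forward(fused, train=train)
        record = {}
        for m, src in plan:  # later entries do not overwrite encoded sources
            record.setdefault(m, "encoded" if src is None else f"generated:{src}")
        return logits, [dict(record) for _ in batch]

    def backward_routed(self, dlogits: np.ndarray) -> None:
        """Backpropagate through the routed graph.

        Gradients flow *through* frozen generators into the source
        encoder; generator parameter gradients are accumulated but their
        weights are never stepped by the full-framework optimizer.
        """
        dfused = self.head.backward(dlogits)
        dlat, ofs = {}, 0
        for m, d in zip(self.modalities, self._latent_dims):
            dlat[m] = dfused[:, ofs : ofs + d]
            ofs += d
        for modality, source in reversed(self._routed_plan):
            if source is None:
                self.encoders[modality].backward(dlat[modality])
            else:
                gen = self._generator(source, modality)
                dlat[source] = dlat[source] + gen.backward(dlat[modality])

    def predict_proba(self, batch: list[ModalityInputs]) -> np.ndarray:
        groups = group_by_mask(batch)
        proba = np.empty((len(batch), 2))
        for idx, sub in groups:
            logits, _ = self.forward_routed(sub, train=False)
            proba[idx] = softmax(logits)
        return proba


def group_by_mask(batch: list[ModalityInputs]) -> list[tuple[np.ndarray, list[ModalityInputs]]]:
    """Split a batch into uniform-availability groups, keeping indices."""
    groups: dict[tuple, list[int]] = {}
    for i, mi in enumerate(batch):
        groups.setdefault(mi.mask(), []).append(i)
    return [
        (np.array(idx), [batch[i] for i in idx]) for idx in groups.values()
    ]


def fuse_and_classify(
    latents: list[np.ndarray], head: Sequential
) -> np.ndarray:
    """Concatenate per-channel latent vectors and classify; returns
    softmax class probabilities (rows sum to 1)."""
    if len(latents) == 0:
        raise ValueError("no latents supplied")
    latents = [np.atleast_2d(np.asarray(z, dtype=np.float64)) for z in latents]
    d = latents[0].shape[1]
    if any(z.shape[1] != d for z in latents):
        raise ValueError("latent vectors have mismatched lengths")
    fused = np.concatenate(latents, axis=1)
    return softmax(head.forward(fused, train=False))
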