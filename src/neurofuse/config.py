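"""Run configuration: every tunable of the framework in one serializable record.

Defaults mirror the reference study design (latent width 100, learning
rate 1e-4, epochs 40/600/70 for the bi-modal, Cycle-GAN and full-framework
stages, batch sizes 14/9/12, stratified 10-fold CV on an 80/20 split, five
generalization runs, attribution thresholds at the 99.5th/98th/65th
percentiles and the 99% region-retention rule). Scaled-down values for
desk-size experiments live in :mod:`neurofuse.presets`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CLASS_LABELS = ("CN", "AD", "MCInc", "MCIc")
MODALITIES = ("smri", "fmri", "snp")


@dataclass
class RunConfig:
    latent_dim: int = 100
    volume_shape: tuple[int, int, int] = (121, 145, 121)
    n_components: int = 53
    n_snps: int = 565
    n_regions: int = 55

    learning_rate: float = 1e-4
    epochs_bimodal: int = 40
    epochs_cgan: int = 600
    epochs_full: int = 70
    batch_smri_fmri: int = 14
    batch_smri_snp: int = 9
    batch_full: int = 12
    n_folds: int = 10
    test_fraction: float = 0.2
    n_runs: int = 5
    seed: int = 0

    cycle_loss_weight: float = 10.0
    adversarial_form: str = "lsgan"  # or "bce"
    standardize_latents: bool = False
    allow_chained_bridges: bool = False
    warm_start_step2: bool = False

    ig_steps: int = 64
    ig_target: str = "logit"  # or "probability"
    percentile_smri: float = 99.5
    percentile_fmri: float = 98.0
    percentile_snp: float = 65.0
    retention_fraction: float = 0.99

    # scaled-architecture knobs (None -> reference architecture)
    encoder_scale: dict | None = None

    @property
    def n_fnc_features(self) -> int:
        return self.n_components * (self.n_components - 1) // 2

    def __post_init__(self):
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        counts = dict(
            latent_dim=self.latent_dim,
            n_components=self.n_components,
            n_snps=self.n_snps,
            n_regions=self.n_regions,
            epochs_bimodal=self.epochs_bimodal,
            epochs_cgan=self.epochs_cgan,
            epochs_full=self.epochs_full,
            batch_smri_fmri=self.batch_smri_fmri,
            batch_smri_snp=self.batch_smri_snp,
            batch_full=self.batch_full,
            n_folds=self.n_folds,
            n_runs=self.n_runs,
            ig_steps=self.ig_steps,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be positive, got {v}")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 1:
            raise ValueError(f"invalid volume_shape {self.volume_shape}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(f"test_fraction must be in (0,1), got {self.test_fraction}")
        for name in ("percentile_smri", "percentile_fmri", "percentile_snp"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must be in (0,100), got {v}")
        if not 0.0 < self.retention_fraction <= 1.0:
            raise ValueError(
                f"retention_fraction must be in (0,1], got {self.retention_fraction}"
            )
        if self.adversarial_form not in ("lsgan", "bce"):
            raise ValueError(f"unknown adversarial_form {self.adversarial_form!r}")
        if self.ig_target not in ("logit", "probability"):
            raise ValueError(f"unknown ig_target {self.ig_target!r}")
        if self.ig_steps < 2:
            raise ValueError("ig_steps must be >= 2")

    # --- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration, for run-directory audit trails."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
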