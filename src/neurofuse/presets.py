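"""Desk-scale presets.

The reference configuration (full-scale volumes, 53 components, 565
SNPs, epochs 40/600/70) is the ``RunConfig`` default. The presets here
shrink the problem so the full two-step pipeline trains in minutes on one
CPU while keeping every structural element: 12x12x12 volumes parcellated
into 30 atlas regions, 10 ICs (45 connections), 50 SNPs, latent width 16,
narrower Cycle-GAN generators, and reduced epoch/fold counts. Class
signal in the recovery cohort is deliberately strong and confined to
designated regions/edges/SNPs so end-to-end recovery is testable.
"""

from __future__ import annotations

from .config import RunConfig
from .simulate import SimulationSpec

DESK_CGAN_HIDDEN = (64, 128, 128, 256, 128)

#: training-time missingness for the recovery cohort's CN/AD groups: the
#: fusion head must see generator-imputed latents during Step 2 to handle
#: them at test time, mirroring the incomplete real cohort
DESK_RECOVERY_MISSINGNESS = {
    "CN": {"fmri": 0.3, "snp": 0.2},
    "AD": {"fmri": 0.3, "snp": 0.2},
}


def desk_scale_config(seed: int = 0, **overrides) -> RunConfig:
    params = dict(
        latent_dim=16,
        volume_shape=(12, 12, 12),
        n_components=10,
        n_snps=50,
        n_regions=30,
        epochs_bimodal=30,
        epochs_cgan=150,
        epochs_full=70,
        n_folds=3,
        seed=seed,
        # pooling is dropped for the sMRI and SNP channels at desk scale:
        # on small grids the pooled maximum wanders between subjects, which
        # blurs gradient-based attribution without helping accuracy
        encoder_scale={
            "width": 8,
            "fc_width": 32,
            "pool": {"smri": False, "fmri": True, "snp": False},
        },
        ig_steps=64,
    )
    params.update(overrides)
    return RunConfig(**params)


def desk_recovery_simspec(seed: int = 0, **overrides) -> SimulationSpec:
    """Strong-signal cohort: class effects confined to 2 regions, 3
    connections and 2 SNPs, low noise, no missingness."""
    params = dict(
        n_per_class={"CN": 100, "AD": 100, "MCInc": 30, "MCIc": 30},
        volume_shape=(12, 12, 12),
        n_components=10,
        n_timepoints=150,
        n_snps=50,
        n_regions=30,
        k_latent=3,
        delta_gm=0.3,
        delta_fnc=0.5,
        delta_af=0.7,
        affected_af_base=0.15,
        gm_noise=0.1,
        factor_scale=0.05,
        fnc_factor_coupling=0.1,
        n_affected_regions=2,
        n_affected_edges=3,
        n_affected_snps=2,
        # patients express each imaging effect independently with
        # probability 0.7 while the genetic effect is constitutive, so no
        # single channel separates the classes alone and the trained
        # classifier must consult all three
        imaging_effect_prob=0.7,
        seed=seed,
    )
    params.update(overrides)
    return SimulationSpec(**params)
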