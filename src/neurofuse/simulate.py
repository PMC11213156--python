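"""Synthetic multimodal cohorts with known ground truth.

Emulates the statistical structure the fusion framework assumes: three
modalities per subject driven by shared low-dimensional subject factors
plus class-dependent effects —

* gray-matter probability volumes: a smooth baseline field, smooth
  factor-loading maps weighted by the subject's latent factors, a
  class-scaled mean reduction ``delta_gm`` confined to designated atlas
  regions, and voxelwise Gaussian noise;
* IC time courses: draws from a multivariate normal whose correlation
  matrix carries class- and factor-scaled shifts ``delta_fnc`` on
  designated component pairs (nearest-positive-definite projection keeps
  the sampling covariance valid);
* SNP dosages: Binomial(2, p_j), with allele frequencies of designated
  SNPs shifted by a class-scaled ``delta_af``.

All effects are additive on the *generating parameters*, so closed-form
expected values exist for testing, and every draw is reproducible from the
spec seed. Class effect multipliers place the four diagnostic groups on a
severity continuum (CN 0 < MCInc < MCIc < AD 1).

This simulator makes no attempt at MRI physics, spatial autocorrelation of
real atrophy, or linkage disequilibrium between SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import CLASS_LABELS
from .features import (
    ModalityInputs,
    compute_sfnc,
    upper_triangle_index_pairs,
    vectorize_upper_triangle,
)
from .io import CohortManifest, Subject, save_manifest, write_table, write_volume

DEFAULT_CLASS_SEVERITY = {"CN": 0.0, "MCInc": 0.25, "MCIc": 0.6, "AD": 1.0}

#: Per-class modality missingness. MCI rates follow the study cohort
#: (MCInc: 59.6% missing SNPs, 60.1% missing fMRI; MCIc: 30.8% and 92%);
#: CN/AD rates are a simulator choice since per-class values are unpublished.
DEFAULT_MISSINGNESS = {
    "CN": {"fmri": 0.5, "snp": 0.35},
    "AD": {"fmri": 0.5, "snp": 0.35},
    "MCInc": {"fmri": 0.601, "snp": 0.596},
    "MCIc": {"fmri": 0.92, "snp": 0.308},
}


@dataclass
class SimulationSpec:
    n_per_class: dict = field(
        default_factory=lambda: {"CN": 500, "AD": 300, "MCInc": 800, "MCIc": 311}
    )
    volume_shape: tuple[int, int, int] = (24, 24, 24)
    n_components: int = 53
    n_timepoints: int = 200
    n_snps: int = 565
    n_regions: int = 55
    k_latent: int = 5

    delta_gm: float = 0.15
    delta_fnc: float = 0.25
    delta_af: float = 0.15
    gm_noise: float = 0.1
    factor_scale: float = 0.05
    fnc_factor_coupling: float = 0.15

    n_affected_regions: int = 6
    n_affected_edges: int = 40
    n_affected_snps: int = 30
    #: when set, effect SNPs start from this allele frequency instead of a
    #: uniform draw, so large delta_af shifts stay inside (0, 1)
    affected_af_base: float | None = None
    #: probability that an affected-class subject expresses the imaging
    #: effects (GM reduction and connectivity shift); the genetic effect is
    #: constitutive. Values < 1 model heterogeneous presentations in which
    #: part of the patient group is imaging-silent, so a classifier cannot
    #: reach ceiling accuracy from the imaging channels alone.
    imaging_effect_prob: float = 1.0

    class_severity: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SEVERITY))
    missingness: dict = field(default_factory=lambda: {})
    seed: int = 0

    def __post_init__(self):
        for cls, n in self.n_per_class.items():
            if cls not in CLASS_LABELS:
                raise ValueError(f"unknown class {cls!r}")
            if n < 1:
                raise ValueError(f"n_per_class[{cls}] must be >= 1, got {n}")
        for name in ("delta_gm", "delta_fnc", "delta_af"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for cls, rates in self.missingness.items():
            for mod, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"missingness[{cls}][{mod}]={r} outside [0,1]")
        if not 0.0 <= self.imaging_effect_prob <= 1.0:
            raise ValueError(
                f"imaging_effect_prob={self.imaging_effect_prob} outside [0,1]"
            )

    @property
    def n_fnc_features(self) -> int:
        return self.n_components * (self.n_components - 1) // 2


@dataclass
class GroundTruth:
    subject_ids: list[str]
    class_labels: list[str]
    latents: np.ndarray  # (n_subjects, k_latent)
    affected_regions: list[int]
    affected_edges: list[tuple[int, int]]
    affected_snps: list[int]
    base_allele_freq: np.ndarray
    class_severity: dict
    atlas: np.ndarray
    baseline_volume: np.ndarray
    base_correlation: np.ndarray


def make_atlas(
    volume_shape: tuple[int, int, int], n_regions: int, seed: int
) -> np.ndarray:
    """Voronoi-style label volume: 0 = background (outside an ellipsoidal
    mask), 1..n_regions contiguous non-empty parcels inside it."""
    shape = tuple(int(v) for v in volume_shape)
    rng = np.random.default_rng(seed)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = [(s - 1) / 2 for s in shape]
    radii = [max(s / 2 - 0.5, 0.5) for s in shape]
    mask = (
        sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0
    )
    coords = np.argwhere(mask)
    if n_regions > len(coords):
        raise ValueError(
            f"cannot place {n_regions} regions in a mask of {len(coords)} voxels"
        )
    centers = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(coords.T)] = d2.argmin(axis=1) + 1
    return labels


def _nearest_correlation(a: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Symmetrize, clip eigenvalues, and rescale to unit diagonal."""
    a = (a + a.T) / 2
    w, v = np.linalg.eigh(a)
    a = (v * np.clip(w, eig_floor, None)) @ v.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    np.fill_diagonal(a, 1.0)
    return (a + a.T) / 2


def _smooth_field(rng: np.random.Generator, shape, sigma: float = 2.0) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return f / max(f.std(), 1e-12)


def simulate_inputs(spec: SimulationSpec) -> tuple[list[ModalityInputs], GroundTruth]:
    """Generate the cohort in memory (all modalities present)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)

    atlas = make_atlas(shape, spec.n_regions, seed=int(rng.integers(2**31)))
    baseline = 0.5 + 0.1 * _smooth_field(rng, shape)
    loadings = np.stack(
        [spec.factor_scale * _smooth_field(rng, shape) for _ in range(spec.k_latent)]
    )

    region_ids = list(range(1, spec.n_regions + 1))
    affected_regions = sorted(
        rng.choice(region_ids, size=min(spec.n_affected_regions, spec.n_regions), replace=False).tolist()
    )
    pairs = upper_triangle_index_pairs(spec.n_components)
    edge_idx = sorted(
        rng.choice(len(pairs), size=min(spec.n_affected_edges, len(pairs)), replace=False).tolist()
    )
    affected_edges = [tuple(pairs[i]) for i in edge_idx]
    affected_snps = sorted(
        rng.choice(spec.n_snps, size=min(spec.n_affected_snps, spec.n_snps), replace=False).tolist()
    )

    # base correlation structure from a random low-rank factor model
    w = rng.normal(0, 1, size=(spec.n_components, max(spec.k_latent, 2)))
    base_corr = _nearest_correlation(0.3 * (w @ w.T) / w.shape[1] + 0.7 * np.eye(spec.n_components))

    base_af = rng.uniform(0.05, 0.5, size=spec.n_snps)
    if spec.affected_af_base is not None:
        base_af[affected_snps] = spec.affected_af_base
    severities = spec.class_severity

    # validate allele-frequency shifts up front
    for cls, sev in severities.items():
        p = base_af[affected_snps] + sev * spec.delta_af
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError(
                f"delta_af={spec.delta_af} pushes allele frequencies outside (0,1) "
                f"for class {cls}"
            )

    delta_mask = np.zeros((spec.n_components, spec.n_components))
    for i, j in affected_edges:
        delta_mask[i, j] = delta_mask[j, i] = 1.0

    subjects: list[ModalityInputs] = []
    ids, labels_out, latents = [], [], []
    region_voxels = {r: atlas == r for r in affected_regions}

    counter = 0
    for cls in CLASS_LABELS:
        n = spec.n_per_class.get(cls, 0)
        sev = severities[cls]
        for _ in range(n):
            sid = f"sub-{counter:05d}"
            counter += 1
            z = rng.standard_normal(spec.k_latent)
            # imaging effects silence independently per channel, so with
            # imaging_effect_prob < 1 no single channel can separate the
            # classes on its own
            sev_gm = sev if rng.random() < spec.imaging_effect_prob else 0.0
            sev_fnc = sev if rng.random() < spec.imaging_effect_prob else 0.0

            vol = baseline + np.tensordot(z, loadings, axes=1)
            for r in affected_regions:
                vol = vol - sev_gm * spec.delta_gm * region_voxels[r]
            vol = vol + spec.gm_noise * rng.standard_normal(shape)

            shift = (sev_fnc + spec.fnc_factor_coupling * z[0]) * spec.delta_fnc
            corr = _nearest_correlation(base_corr + shift * delta_mask)
            chol = np.linalg.cholesky(corr + 1e-10 * np.eye(spec.n_components))
            tc = chol @ rng.standard_normal((spec.n_components, spec.n_timepoints))

            p = base_af.copy()
            p[affected_snps] = np.clip(p[affected_snps] + sev * spec.delta_af, 1e-6, 1 - 1e-6)
            snp = rng.binomial(2, p).astype(np.float64)

            fnc = vectorize_upper_triangle(compute_sfnc(tc)).values
            subjects.append(
                ModalityInputs(subject_id=sid, class_label=cls, volume=vol, fnc=fnc, snp=snp)
            )
            ids.append(sid)
            labels_out.append(cls)
            latents.append(z)

    gt = GroundTruth(
        subject_ids=ids,
        class_labels=labels_out,
        latents=np.array(latents),
        affected_regions=affected_regions,
        affected_edges=affected_edges,
        affected_snps=affected_snps,
        base_allele_freq=base_af,
        class_severity=dict(severities),
        atlas=atlas,
        baseline_volume=baseline,
        base_correlation=base_corr,
    )
    return subjects, gt


def simulate_cohort(
    spec: SimulationSpec, out_dir: str | Path
) -> tuple[CohortManifest, GroundTruth]:
    """Generate the cohort and write it in the formats the loaders read.

    Per subject: a NIfTI GM volume, an FNC-vector TSV and a dosage TSV;
    plus ``manifest.tsv`` and ``atlas.nii.gz``. Missingness from
    ``spec.missingness`` is applied to the manifest flags (the files are
    still written, mirroring a roster that references more data than a
    study visit delivered).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs, gt = simulate_inputs(spec)

    write_volume(gt.atlas.astype(np.float64), out_dir / "atlas.nii.gz")
    subjects = []
    for mi in inputs:
        smri = out_dir / f"{mi.subject_id}_gm.nii.gz"
        fmri = out_dir / f"{mi.subject_id}_fnc.tsv"
        snp = out_dir / f"{mi.subject_id}_snp.tsv"
        write_volume(mi.volume, smri)
        write_table(mi.fnc[None, :], fmri, kind="fnc_vector", row_ids=[mi.subject_id])
        write_table(
            mi.snp[None, :].astype(int), snp, kind="dosage", row_ids=[mi.subject_id]
        )
        subjects.append(
            Subject(
                subject_id=mi.subject_id,
                class_label=mi.class_label,
                smri_path=str(smri),
                fmri_path=str(fmri),
                snp_path=str(snp),
                has_smri=True,
                has_fmri=True,
                has_snp=True,
            )
        )
    manifest = CohortManifest(subjects)
    if spec.missingness:
        manifest = apply_missingness(manifest, spec.missingness, seed=spec.seed + 1)
    save_manifest(manifest, out_dir / "manifest.tsv")
    return manifest, gt


def mask_inputs(
    inputs: list[ModalityInputs], rates: dict, seed: int
) -> list[ModalityInputs]:
    """In-memory counterpart of :func:`apply_missingness`: returns copies
    with masked channels set to ``None`` (MCAR within class)."""
    rng = np.random.default_rng(seed)
    out = []
    attr = {"smri": "volume", "fmri": "fnc", "snp": "snp"}
    for mi in inputs:
        m2 = ModalityInputs(
            subject_id=mi.subject_id, class_label=mi.class_label,
            volume=mi.volume, fnc=mi.fnc, snp=mi.snp,
        )
        for mod in ("smri", "fmri", "snp"):
            rate = rates.get(mi.class_label, {}).get(mod, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} for {mi.class_label}/{mod} outside [0,1]")
            if getattr(m2, attr[mod]) is not None and rng.random() < rate:
                setattr(m2, attr[mod], None)
        if not any(m2.mask()):
            raise ValueError(
                f"missingness rates left subject {mi.subject_id} with no modalities"
            )
        out.append(m2)
    return out


def apply_missingness(
    manifest: CohortManifest, rates: dict, seed: int
) -> CohortManifest:
    """Clear availability flags, independently per subject (MCAR within class).

    ``rates[class_label][modality]`` is the probability that the modality is
    missing for a subject of that class. A draw that would leave a subject
    with zero modalities raises.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in manifest.subjects:
        s2 = Subject(**{k: getattr(s, k) for k in (
            "subject_id", "class_label", "smri_path", "fmri_path", "snp_path",
            "has_smri", "has_fmri", "has_snp")})
        for mod in ("smri", "fmri", "snp"):
            rate = rates.get(s.class_label, {}).get(mod, 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} for {s.class_label}/{mod} outside [0,1]")
            if getattr(s2, f"has_{mod}") and rng.random() < rate:
                setattr(s2, f"has_{mod}", False)
        if not any(s2.mask()):
            raise ValueError(
                f"missingness rates left subject {s.subject_id} with no modalities"
            )
        out.append(s2)
    return CohortManifest(out)
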