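"""Feature engineering for the three input channels.

From independent-component time courses to the static functional network
connectivity (sFNC) vector — the Pearson correlation matrix between IC
time courses, upper triangle vectorized (53 components give 1378
features) — and from genotype calls to minor-allele dosage {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortManifest, Table, ValidationError, read_table, read_volume

RSN_NAMES = ("SC", "AUD", "SM", "VI", "CC", "DM", "CB")


@dataclass
class FNCVector:
    """Upper-triangle (strict, row-major) Pearson correlations."""

    values: np.ndarray
    n_components: int
    ordering: str = "row-major-upper"

    def __post_init__(self):
        n = self.n_components
        expected = n * (n - 1) // 2
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (expected,):
            raise ValidationError(
                f"FNC vector length {self.values.shape} != n(n-1)/2 = {expected}"
            )
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValidationError("correlation values outside [-1, 1]")


@dataclass
class DosageVector:
    values: np.ndarray
    snp_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        bad = np.argwhere(~np.isin(self.values, (0, 1, 2)))
        if bad.size:
            raise ValidationError(
                f"dosage value {self.values[bad[0][0]]} at index {bad[0][0]} not in {{0,1,2}}"
            )


def compute_sfnc(timecourses: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of IC time courses (components x T)."""
    tc = np.asarray(timecourses, dtype=np.float64)
    if tc.ndim != 2:
        raise ValidationError(f"expected components x T matrix, got shape {tc.shape}")
    n, t = tc.shape
    if t < 3:
        raise ValidationError(f"need at least 3 timepoints, got {t}")
    sd = tc.std(axis=1, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValidationError(
            f"component {constant[0]} has a constant time course; correlation undefined"
        )
    c = np.corrcoef(tc)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def vectorize_upper_triangle(matrix: np.ndarray) -> FNCVector:
    """Strictly-upper-triangular entries in row-major order."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {m.shape}")
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    return FNCVector(values=m[iu], n_components=n)


def devectorize(vec: FNCVector | np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (unit diagonal)."""
    if isinstance(vec, FNCVector):
        values, n = vec.values, vec.n_components
    else:
        values = np.asarray(vec, dtype=np.float64)
        if n_components is None:
            n = int(round((1 + np.sqrt(1 + 8 * values.size)) / 2))
        else:
            n = n_components
        if values.size != n * (n - 1) // 2:
            raise ValidationError(f"length {values.size} is not n(n-1)/2 for n={n}")
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = values
    m[(iu[1], iu[0])] = values
    return m


def upper_triangle_index_pairs(n: int) -> np.ndarray:
    """Row-major (i, j) pairs matching the vectorization order."""
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def encode_dosage(
    calls: list[str] | np.ndarray,
    wild: str,
    mutant: str,
    snp_ids: list[str] | None = None,
) -> DosageVector:
    """Allele-pair strings to dosage: W/W -> 0, W/M or M/W -> 1, M/M -> 2."""
    calls = list(calls)
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(len(calls))]
    out = np.empty(len(calls), dtype=np.int64)
    for i, call in enumerate(calls):
        alleles = call.replace("|", "/").split("/")
        if len(alleles) != 2 or any(a not in (wild, mutant) for a in alleles):
            raise ValidationError(
                f"SNP {snp_ids[i]!r}: call {call!r} not a pair over "
                f"{{{wild!r}, {mutant!r}}}"
            )
        out[i] = sum(a == mutant for a in alleles)
    return DosageVector(values=out, snp_ids=snp_ids)


@dataclass
class NetworkPartition:
    """Component -> resting-state-network assignment over the seven RSNs."""

    assignment: dict[int, str]

    def __post_init__(self):
        for comp, rsn in self.assignment.items():
            if rsn not in RSN_NAMES:
                raise ValidationError(f"component {comp}: unknown network {rsn!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkPartition":
        df = pd.read_csv(path, sep="\t")
        if not {"component", "network"} <= set(df.columns):
            raise ValidationError(f"{path}: expected columns 'component', 'network'")
        return cls({int(r.component): str(r.network) for r in df.itertuples()})

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.assignment.items()), columns=["component", "network"]
        ).to_csv(path, sep="\t", index=False)

    def network_of(self, component: int) -> str:
        try:
            return self.assignment[component]
        except KeyError:
            raise ValidationError(f"component {component} has no network assignment")


@dataclass
class ModalityInputs:
    """One subject's model-ready channels; absent channels are ``None``."""

    subject_id: str
    class_label: str
    volume: np.ndarray | None = None
    fnc: np.ndarray | None = None
    snp: np.ndarray | None = None

    def mask(self) -> tuple[bool, bool, bool]:
        return (self.volume is not None, self.fnc is not None, self.snp is not None)


def assemble_inputs(manifest: CohortManifest, config) -> list[ModalityInputs]:
    """Load every flagged modality, validating shapes against the config.

    Missing channels stay ``None`` — imputation belongs to the latent-space
    generative module, never to input assembly.
    """
    out = []
    n_fnc = config.n_fnc_features
    for s in manifest.subjects:
        mi = ModalityInputs(subject_id=s.subject_id, class_label=s.class_label)
        if s.has_smri:
            mi.volume, _ = read_volume(s.smri_path, expected_shape=config.volume_shape)
        if s.has_fmri:
            table = read_table(s.fmri_path, kind="fnc_vector")
            vec = table.values.ravel()
            if vec.size != n_fnc:
                raise ValidationError(
                    f"{s.subject_id}: FNC vector length {vec.size} != {n_fnc}"
                )
            mi.fnc = vec
        if s.has_snp:
            table = read_table(s.snp_path, kind="dosage")
            vec = table.values.ravel()
            if vec.size != config.n_snps:
                raise ValidationError(
                    f"{s.subject_id}: dosage length {vec.size} != {config.n_snps}"
                )
            mi.snp = vec.astype(np.float64)
        out.append(mi)
    return out
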