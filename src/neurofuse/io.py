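"""On-disk artifacts: cohort manifests, NIfTI volumes, TSV tables, weights.

The manifest is a TSV with fixed columns (``subject_id``, ``class_label``,
``smri_path``, ``fmri_path``, ``snp_path``). Modality availability is
derived at load time: a flag is true only when the path cell is non-empty
and the file exists, so the manifest cannot claim data it does not have.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import CLASS_LABELS, RunConfig

logger = logging.getLogger("neurofuse")

MANIFEST_COLUMNS = ["subject_id", "class_label", "smri_path", "fmri_path", "snp_path"]


class ValidationError(ValueError):
    """Input data violated a structural invariant."""


@dataclass
class Subject:
    subject_id: str
    class_label: str
    smri_path: str = ""
    fmri_path: str = ""
    snp_path: str = ""
    has_smri: bool = False
    has_fmri: bool = False
    has_snp: bool = False

    def mask(self) -> tuple[bool, bool, bool]:
        return (self.has_smri, self.has_fmri, self.has_snp)


@dataclass
class CohortManifest:
    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for i, s in enumerate(self.subjects):
            if s.subject_id in seen:
                raise ValidationError(f"row {i}: duplicate subject_id {s.subject_id!r}")
            seen.add(s.subject_id)
            if s.class_label not in CLASS_LABELS:
                raise ValidationError(
                    f"row {i} ({s.subject_id}): class_label {s.class_label!r} "
                    f"not in {CLASS_LABELS}"
                )
            if not any(s.mask()):
                raise ValidationError(
                    f"row {i} ({s.subject_id}): no modality available"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def by_class(self, *labels: str) -> "CohortManifest":
        return CohortManifest([s for s in self.subjects if s.class_label in labels])

    def with_modalities(self, *mods: str) -> "CohortManifest":
        """Subjects having every named modality (``smri``/``fmri``/``snp``)."""
        keep = []
        for s in self.subjects:
            if all(getattr(s, f"has_{m}") for m in mods):
                keep.append(s)
        return CohortManifest(keep)

    def labels(self) -> np.ndarray:
        return np.array([s.class_label for s in self.subjects])


def load_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns: {missing}")
    subjects = []
    for i, row in df.iterrows():
        s = Subject(
            subject_id=row["subject_id"],
            class_label=row["class_label"],
            smri_path=row["smri_path"],
            fmri_path=row["fmri_path"],
            snp_path=row["snp_path"],
        )
        for mod, p in (("smri", s.smri_path), ("fmri", s.fmri_path), ("snp", s.snp_path)):
            setattr(s, f"has_{mod}", bool(p) and Path(p).exists())
        subjects.append(s)
    manifest = CohortManifest(subjects)
    logger.info("loaded manifest %s: %d subjects", path, len(manifest))
    return manifest


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "class_label": s.class_label,
            "smri_path": s.smri_path if s.has_smri else "",
            "fmri_path": s.fmri_path if s.has_fmri else "",
            "snp_path": s.snp_path if s.has_snp else "",
        }
        for s in manifest.subjects
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# --- volumes -------------------------------------------------------------

def read_volume(path: str | Path, expected_shape: tuple[int, ...] | None = None):
    """Read a NIfTI-1 volume; returns ``(data, affine)``."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64)
    except Exception as exc:  # corrupt header / truncated file
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if expected_shape is not None and data.shape != tuple(expected_shape):
        raise IOError(
            f"{path}: shape {data.shape} does not match configured {tuple(expected_shape)}"
        )
    return data, img.affine


def write_volume(grid: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {grid.shape}")
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(grid.astype(np.float32), affine), str(path))


# --- tables --------------------------------------------------------------

TABLE_KINDS = ("dosage", "timecourse", "fnc_vector")


@dataclass
class Table:
    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    kind: str
    orientation: str = ""


def read_table(path: str | Path, kind: str) -> Table:
    """Read a TSV table of the given kind.

    dosage     : rows = subjects (or one row), columns = SNP ids; values in {0,1,2}
    timecourse : rows = components, columns = timepoints
    fnc_vector : single row, columns = connection ids
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=np.float64)
    if kind == "dosage":
        bad = np.argwhere(~np.isin(values, (0.0, 1.0, 2.0)))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"{path}: dosage value {values[i, j]} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r} is not in {{0,1,2}}"
            )
        values = values.astype(np.int64)
    orientation = "components_by_time" if kind == "timecourse" else ""
    return Table(
        values=values,
        row_ids=[str(r) for r in df.index],
        col_ids=[str(c) for c in df.columns],
        kind=kind,
        orientation=orientation,
    )


def write_table(
    values: np.ndarray,
    path: str | Path,
    kind: str,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
) -> None:
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    values = np.atleast_2d(np.asarray(values))
    if row_ids is None:
        row_ids = [f"r{i}" for i in range(values.shape[0])]
    if col_ids is None:
        col_ids = [f"c{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t")


# --- trained weights -----------------------------------------------------

def save_weights(model, path: str | Path, metadata: dict | None = None) -> None:
    """Save a ``Sequential``'s arrays plus a JSON sidecar (seed, config hash)."""
    path = Path(path)
    arrays = model.state_arrays()
    np.savez(path, **{f"arr_{i}": a for i, a in enumerate(arrays)})
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(metadata or {}, sort_keys=True, indent=1))


def load_weights(model, path: str | Path) -> dict:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    with np.load(npz_path if npz_path.exists() else path) as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    sidecar = path.with_suffix(path.suffix + ".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}
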