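"""Readers and writers for volumes, profiles, annotations and ground truth.

Volumes travel as NIfTI-1 (via nibabel) with values preserved to 32-bit
float precision; tabular data (wellbeing profiles, annotations, results)
travel as comma-delimited text; planted ground truth is serialised as JSON.
All spatial indexing inside the package is 0-based voxel indexing; the
NIfTI affine is carried as metadata only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import ANNOTATION_CHANNELS, AnnotationSet, GroundTruth
from .types import N_ITEMS, WellbeingProfile

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_profiles",
    "write_profiles",
    "read_annotations",
    "write_annotations",
    "read_truth",
    "write_truth",
]

PROFILE_COLUMNS = (
    ["participant_id"] + [f"item{i}" for i in range(1, N_ITEMS + 1)] + ["age", "gender"]
)


def write_volume(
    volume: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    voxel_size_mm: float = 3.2,
) -> Path:
    """Write a 3D/4D volume as NIfTI-1 (float32)."""
    path = Path(path)
    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (float64 data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), np.asarray(img.affine)


def read_mask(path: str | Path, grid_shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Read a binary mask volume, optionally validating its grid."""
    data, _ = read_volume(path)
    if grid_shape is not None and data.shape != tuple(grid_shape):
        raise ValueError(
            f"mask grid {data.shape} does not match cohort grid {tuple(grid_shape)}"
        )
    return data > 0.5


def write_profiles(profiles: Sequence[WellbeingProfile], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        [p.participant_id, *p.items.tolist(), p.age, p.gender] for p in profiles
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)
    return path


def read_profiles(path: str | Path) -> list[WellbeingProfile]:
    """Parse a delimited profile table; validates columns and unique ids."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table is missing columns: {missing}")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise ValueError(f"duplicate participant ids: {dupes}")
    item_cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    items = df[item_cols].to_numpy()
    if not np.issubdtype(items.dtype, np.number) or np.isnan(items).any():
        raise ValueError("wellbeing items must be numeric and complete")
    return [
        WellbeingProfile(
            str(row.participant_id),
            items[i],
            int(row.age),
            str(row.gender),
        )
        for i, row in enumerate(df.itertuples())
    ]


def write_annotations(ann: AnnotationSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({k: ann.channels[k] for k in ANNOTATION_CHANNELS if k in ann.channels}).to_csv(
        path, index=False
    )
    return path


def read_annotations(path: str | Path, segment_duration_s: int = 3) -> AnnotationSet:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing channels: {missing}")
    return AnnotationSet(
        channels={c: df[c].to_numpy(dtype=np.float64) for c in ANNOTATION_CHANNELS},
        segment_duration_s=segment_duration_s,
    )


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "planted_networks": [n.tolist() for n in truth.planted_networks],
        "active_windows": [
            [[int(a), int(b)] for a, b in wins] for wins in truth.active_windows
        ],
        "coupling_strength": truth.coupling_strength,
        "annotation_coupling": truth.annotation_coupling,
        "seed": truth.seed,
        "grid_shape": list(truth.grid_shape),
        "n_timepoints": truth.n_timepoints,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_networks=[np.asarray(n, dtype=np.intp) for n in payload["planted_networks"]],
        active_windows=[
            [(int(a), int(b)) for a, b in wins] for wins in payload["active_windows"]
        ],
        coupling_strength=[float(c) for c in payload["coupling_strength"]],
        annotation_coupling=payload["annotation_coupling"],
        seed=int(payload["seed"]),
        grid_shape=tuple(payload["grid_shape"]),
        n_timepoints=int(payload["n_timepoints"]),
    )
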