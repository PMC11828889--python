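"""Core data containers shared across pipeline stages.

All spatial indexing is 0-based voxel indexing on a regular grid; the NIfTI
affine is carried only as I/O metadata.  A recording is a 4D scalar field
(x, y, z, t), a wellbeing profile is a 7-item T-score vector plus age and
gender, and the central intermediate product is a ``RhoSeries``: a voxel ×
timepoint field of partial Spearman correlations between participant-pair
brain-pattern distances and wellbeing-profile distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Number of wellbeing questionnaire items per participant (T-score scale).
N_ITEMS = 7


class InvalidCohortError(ValueError):
    """Cohort too small or inconsistent for pairwise statistics."""


class InvalidGeometryError(ValueError):
    """Requested planted networks cannot be placed on the grid."""


class SearchlightError(ValueError):
    """A searchlight sphere does not contain enough in-mask voxels."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


@dataclass
class ParticipantRecording:
    """One participant's masked 4D recording.

    Parameters
    ----------
    participant_id
        Unique label for the participant.
    volume
        4D array (x, y, z, timepoint), float.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (metadata only; the
        analysis itself is grid-native).
    """

    participant_id: str
    volume: np.ndarray
    voxel_size_mm: float = 3.2

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if self.volume.ndim != 4:
            raise ValueError(
                f"recording volume must be 4D (x,y,z,t), got {self.volume.ndim}D"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volume.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.volume.shape[3]


@dataclass
class WellbeingProfile:
    """7-item wellbeing profile (T-scores: population mean 50, SD 10)."""

    participant_id: str
    items: np.ndarray
    age: int
    gender: str

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=np.float64)
        if self.items.shape != (N_ITEMS,):
            raise ValueError(f"profile must have exactly {N_ITEMS} items")
        if not self.age > 0:
            raise ValueError("age must be positive")


@dataclass
class PairDistanceMatrix:
    """Symmetric participant-by-participant distance (or similarity) matrix.

    ``kind`` is one of ``"correlation-distance"`` (entries in [0, 2], zero
    diagonal), ``"absolute-difference"`` (zero diagonal) or
    ``"same-category-indicator"`` (entries in {0, 1}, unit diagonal).
    Undefined entries (e.g. from constant patterns) are NaN.
    """

    values: np.ndarray
    kind: str = "correlation-distance"

    _KINDS = ("correlation-distance", "absolute-difference", "same-category-indicator")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("pair matrix must be square")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        finite = np.isfinite(self.values)
        sym = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-12,
        )
        if not sym or not np.array_equal(finite, finite.T):
            raise ValueError("pair matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Strict upper triangle, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class RhoSeries:
    """Voxel × timepoint field of partial Spearman rho values.

    ``rho`` has shape grid + (timepoints,); entries outside the mask or at
    undefined searchlights are NaN.
    """

    rho: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rho.ndim != 4:
            raise ValueError("rho must be 4D (x,y,z,t)")
        if self.mask.shape != self.rho.shape[:3]:
            raise ValueError("mask grid does not match rho grid")

    @property
    def n_timepoints(self) -> int:
        return self.rho.shape[3]

    def masked_matrix(self) -> np.ndarray:
        """(n_mask_voxels, timepoints) view in lexicographic voxel order."""
        return self.rho[self.mask]


@dataclass
class Cohort:
    """Recordings plus matched wellbeing profiles on one shared grid."""

    recordings: list[ParticipantRecording]
    profiles: list[WellbeingProfile]

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.profiles):
            raise InvalidCohortError(
                "recordings and profiles must have equal participant counts"
            )
        if len(self.recordings) < 4:
            raise InvalidCohortError(
                "pairwise statistics are undefined for fewer than 4 participants"
            )
        shapes = {r.volume.shape for r in self.recordings}
        if len(shapes) > 1:
            raise InvalidCohortError("all recordings must share one grid and duration")
        for rec, prof in zip(self.recordings, self.profiles):
            if rec.participant_id != prof.participant_id:
                raise InvalidCohortError(
                    "recording/profile participant ids do not line up"
                )

    @property
    def n_participants(self) -> int:
        return len(self.recordings)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.recordings[0].grid_shape

    @property
    def n_timepoints(self) -> int:
        return self.recordings[0].n_timepoints

    def data_array(self) -> np.ndarray:
        """Stack volumes into (n_participants, x, y, z, t)."""
        return np.stack([r.volume for r in self.recordings])


def pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strict upper triangle, row-major."""
    return np.triu_indices(n, k=1)


def check_items_matrix(profiles: Sequence[WellbeingProfile]) -> np.ndarray:
    """Stack item vectors into (n, 7), validating count."""
    if len(profiles) < 4:
        raise InvalidCohortError("need at least 4 profiles")
    return np.stack([p.items for p in profiles])
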