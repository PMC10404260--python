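"""Core containers shared across the pipeline.

Conventions: volumes are indexed ``(x, y, z[, t])`` with 0-based voxel
indices; world coordinates are obtained through the NIfTI-style 4x4
affine.  Region tables are plain :class:`pandas.DataFrame` objects with
the columns listed in :data:`REGION_COLUMNS`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required columns of a region table (one row per atlas label).
REGION_COLUMNS = ("id", "acronym", "name", "hemisphere", "family")

HEMISPHERES = ("left", "right", "midline")
COHORTS = ("control", "mutant", "treated")


def default_affine(voxel_size_mm) -> np.ndarray:
    """Scaling-only voxel->world affine for data generated in atlas space."""
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = voxel_size_mm
    return a


@dataclass
class MotionTrace:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    translations_mm: np.ndarray  # (T, 3)
    rotations_deg: np.ndarray    # (T, 3)
    reference_index: int = 0
    degenerate: list = field(default_factory=list)  # volume indices that failed

    def __post_init__(self):
        self.translations_mm = np.asarray(self.translations_mm, dtype=float)
        self.rotations_deg = np.asarray(self.rotations_deg, dtype=float)
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translation and rotation arrays must have equal shape")

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[0]

    def as_frame(self) -> pd.DataFrame:
        cols = {f"t{ax}_mm": self.translations_mm[:, i] for i, ax in enumerate("xyz")}
        cols.update({f"r{ax}_deg": self.rotations_deg[:, i] for i, ax in enumerate("xyz")})
        return pd.DataFrame(cols)


@dataclass
class Volume4D:
    """A single 4-D BOLD run, ``data[x, y, z, t]``."""

    data: np.ndarray
    voxel_size_mm: tuple = (0.25, 0.25, 0.5)
    tr_s: float = 1.0
    affine: np.ndarray | None = None
    provenance: list = field(default_factory=list)
    motion_truth: MotionTrace | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.n_timepoints < 1:
            raise ValueError("need at least one volume")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def dims(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray, step: str) -> "Volume4D":
        """Copy carrying the provenance log forward, appending ``step``."""
        return Volume4D(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            tr_s=self.tr_s,
            affine=self.affine.copy(),
            provenance=[*self.provenance, step],
            motion_truth=self.motion_truth,
        )


@dataclass
class AtlasVolume:
    """Integer label volume; 0 = background, 1..R = region ids."""

    labels: np.ndarray
    voxel_size_mm: tuple = (0.25, 0.25, 0.5)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def dims(self) -> tuple:
        return self.labels.shape

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)


def validate_region_table(table: pd.DataFrame, atlas: AtlasVolume | None = None) -> None:
    """Check region-table invariants (unique ids/acronyms, known hemispheres)."""
    missing = [c for c in REGION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    if table["id"].duplicated().any():
        raise ValueError("region ids must be unique")
    if table["acronym"].duplicated().any():
        raise ValueError("region acronyms must be unique")
    bad = set(table["hemisphere"]) - set(HEMISPHERES)
    if bad:
        raise ValueError(f"unknown hemisphere labels: {bad}")
    if atlas is not None:
        atlas_ids = set(atlas.region_ids.tolist())
        table_ids = set(int(i) for i in table["id"])
        if atlas_ids != table_ids:
            raise ValueError("region table ids are not bijective with atlas labels")


@dataclass
class RegionSeries:
    """Mean BOLD time course per atlas region (rows follow ``region_ids``)."""

    values: np.ndarray       # (R, T)
    region_ids: np.ndarray   # (R,)
    missing: list = field(default_factory=list)  # ids absent from the atlas

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class SeedMap:
    """Voxelwise Pearson correlation with one seed region's mean series."""

    seed_region_id: int
    r: np.ndarray            # 3-D, NaN outside the brain mask
    n_timepoints: int
    provenance: str = ""

    @property
    def dims(self) -> tuple:
        return self.r.shape


@dataclass
class ConnMatrix:
    """Region-by-region Pearson correlation matrix."""

    values: np.ndarray       # (R, R)
    region_ids: np.ndarray   # (R,)
    n_timepoints: int
    degenerate_ids: list = field(default_factory=list)  # zero-variance regions

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        if self.values.shape[0] != self.values.shape[1]:
            raise ValueError("correlation matrix must be square")
        if self.values.shape[0] != self.region_ids.size:
            raise ValueError("region id list must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass
class GroupMap:
    """Voxelwise group statistic map (one- or two-sample t on Fisher z)."""

    t: np.ndarray
    p: np.ndarray
    mean_r: np.ndarray
    n: tuple                # (n,) for one-sample, (nA, nB) for two-sample
    df: np.ndarray | float
    contrast: str = ""
    capped: np.ndarray | None = None  # voxels where an infinite t was capped


@dataclass
class StatResult:
    """Generic hypothesis-test result."""

    test: str
    statistic: float
    df: tuple
    p: float
    posthoc: dict | None = None
    notes: str = ""


@dataclass
class GroupSummary:
    cohort: str
    n: int
    mean: float
    sem: float
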