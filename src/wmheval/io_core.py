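"""Imaging and tabular I/O for the evaluation pipeline.

All volumes live on a :class:`VoxelGrid` — a shape plus voxel spacing in mm.
Every computation happens in voxel index space: no resampling or registration
is ever performed, and two volumes may only be compared when their grids are
compatible (equal shape, equal spacing within a relative tolerance of 1e-4).
Orientation metadata is carried along for provenance but never interpreted;
a differing orientation tag only triggers a logged warning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger("wmheval")

#: Relative tolerance on voxel spacing when deciding grid compatibility.
SPACING_RTOL = 1e-4

#: Values loaded as "probabilities" may exceed [0, 1] by at most this much
#: (float noise from lossy encodings); larger violations are treated as a
#: wrong-file mistake and rejected.
PROBABILITY_SLACK = 1e-6

#: Threshold used to binarize stored mask values on load.  Strictly greater
#: than 0.5 so that masks survive lossy/interpolated encodings.
MASK_BINARIZE_THRESHOLD = 0.5


class GridCompatibilityError(ValueError):
    """Raised when an operation receives volumes on incompatible grids."""


class VolumeShapeError(ValueError):
    """Raised when a loaded volume is not a 3D scalar image."""


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D volume: shape in voxels and spacing in mm.

    Parameters
    ----------
    shape
        Number of voxels along each axis.
    voxel_size
        Voxel edge lengths in mm.
    orientation
        Opaque tag describing the spatial frame (e.g. axis codes derived
        from a NIfTI affine).  Carried, never interpreted.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise VolumeShapeError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(float(v) <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel size must be 3 positive reals, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def compatible(self, other: "VoxelGrid") -> bool:
        """True iff shapes are equal and spacings agree within 1e-4 (relative)."""
        if self.shape != other.shape:
            return False
        a = np.asarray(self.voxel_size)
        b = np.asarray(other.voxel_size)
        if not np.allclose(a, b, rtol=SPACING_RTOL, atol=0.0):
            return False
        if self.orientation != other.orientation:
            logger.warning(
                "grids share shape/spacing but orientation tags differ (%s vs %s); "
                "proceeding on index-space comparison",
                self.orientation,
                other.orientation,
            )
        return True


def assert_compatible(a: VoxelGrid, b: VoxelGrid) -> bool:
    """Pure compatibility predicate; see :meth:`VoxelGrid.compatible`."""
    return a.compatible(b)


def require_compatible(a: VoxelGrid, b: VoxelGrid, what: str = "volumes") -> None:
    if not a.compatible(b):
        raise GridCompatibilityError(
            f"{what} are on incompatible grids: {a.shape}@{a.voxel_size} vs {b.shape}@{b.voxel_size}"
        )


@dataclass
class BinaryMask:
    """A 3D boolean lesion map bound to a voxel grid."""

    grid: VoxelGrid
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.shape != self.grid.shape:
            raise VolumeShapeError(f"mask shape {arr.shape} does not match grid {self.grid.shape}")
        self.voxels = arr.astype(bool, copy=False)

    @property
    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def volume_ml(self) -> float:
        return mask_volume_ml(self)


@dataclass
class ProbabilityVolume:
    """A 3D per-voxel lesion-probability map on a voxel grid, values in [0, 1]."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.shape != self.grid.shape:
            raise VolumeShapeError(
                f"probability shape {arr.shape} does not match grid {self.grid.shape}"
            )
        lo, hi = float(arr.min(initial=0.0)), float(arr.max(initial=0.0))
        if lo < -PROBABILITY_SLACK or hi > 1.0 + PROBABILITY_SLACK:
            raise ValueError(
                f"probability values outside [0,1] beyond tolerance: range [{lo}, {hi}]"
            )
        # within-slack excursions are float noise: clamp them
        self.values = np.clip(arr, 0.0, 1.0)


def mask_volume_ml(m: BinaryMask) -> float:
    """Total mask volume in mL: foreground voxel count x voxel volume."""
    return m.foreground_count * m.grid.voxel_volume_ml


# ---------------------------------------------------------------------------
# NIfTI reading / writing


def _grid_from_image(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    try:
        orientation = "".join(nib.aff2axcodes(img.affine))
    except Exception:  # malformed affine: orientation stays opaque
        orientation = "unknown"
    return VoxelGrid(shape=tuple(int(s) for s in img.shape[:3]), voxel_size=zooms,
                     orientation=orientation)


def _load_3d(path: str | Path) -> tuple[np.ndarray, VoxelGrid, nib.Nifti1Image]:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # unreadable / not NIfTI
        raise OSError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeShapeError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, _grid_from_image(img), img


def load_mask(path: str | Path) -> BinaryMask:
    """Load a binary lesion mask from NIfTI.

    Stored values strictly greater than 0.5 become foreground, which keeps
    masks intact through lossy or interpolated encodings.
    """
    data, grid, _ = _load_3d(path)
    return BinaryMask(grid=grid, voxels=np.asarray(data, dtype=np.float64) > MASK_BINARIZE_THRESHOLD)


def load_probability(path: str | Path) -> ProbabilityVolume:
    """Load a probability map from NIfTI, enforcing the [0, 1] range policy."""
    data, grid, _ = _load_3d(path)
    return ProbabilityVolume(grid=grid, values=data)


def load_label_volume(path: str | Path) -> tuple[VoxelGrid, np.ndarray]:
    """Load an integer parcellation/label volume from NIfTI."""
    data, grid, _ = _load_3d(path)
    labels = np.asarray(np.rint(np.asarray(data, dtype=np.float64)), dtype=np.int32)
    return grid, labels


def _affine_for(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size) + [1.0])
    return aff


def save_mask(m: BinaryMask, path: str | Path) -> None:
    """Write a BinaryMask as a uint8 NIfTI volume (0/1)."""
    img = nib.Nifti1Image(m.voxels.astype(np.uint8), _affine_for(m.grid))
    img.header.set_zooms(m.grid.voxel_size)
    nib.save(img, str(path))


def save_probability(p: ProbabilityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(p.values.astype(np.float32), _affine_for(p.grid))
    img.header.set_zooms(p.grid.voxel_size)
    nib.save(img, str(path))


def save_label_volume(grid: VoxelGrid, labels: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine_for(grid))
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort manifests

MANIFEST_COLUMNS = (
    "subject_id",
    "reference_path",
    "prediction_path",
    "prediction_kind",
    "parcellation_path",
    "method_label",
)


@dataclass(frozen=True)
class ManifestRow:
    subject_id: str
    reference_path: str
    prediction_path: str
    prediction_kind: str = "mask"  # "mask" | "probability"
    parcellation_path: str | None = None
    method_label: str = "method"

    def __post_init__(self) -> None:
        if self.prediction_kind not in ("mask", "probability"):
            raise ValueError(f"prediction_kind must be mask|probability, got {self.prediction_kind!r}")


@dataclass
class CohortManifest:
    """Listing of subjects and their reference / predicted volume files."""

    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.rows:
            key = (r.subject_id, r.method_label)
            if key in seen:
                raise ValueError(f"duplicate subject/method pair in manifest: {key}")
            seen.add(key)

    def check_paths(self) -> None:
        """Raise if any referenced file is missing."""
        for r in self.rows:
            for p in (r.reference_path, r.prediction_path, r.parcellation_path):
                if p and not Path(p).exists():
                    raise FileNotFoundError(f"manifest references missing file: {p}")

    @property
    def subject_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.subject_id not in seen:
                seen.append(r.subject_id)
        return seen


def read_manifest(path: str | Path, check_paths: bool = True) -> CohortManifest:
    """Read a cohort manifest CSV (columns: subject_id, reference_path,
    prediction_path, prediction_kind, parcellation_path, method_label)."""
    path = Path(path)
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "subject_id" not in reader.fieldnames:
            raise ValueError(f"{path}: not a cohort manifest (missing subject_id column)")
        for rec in reader:
            rows.append(
                ManifestRow(
                    subject_id=rec["subject_id"],
                    reference_path=rec["reference_path"],
                    prediction_path=rec["prediction_path"],
                    prediction_kind=(rec.get("prediction_kind") or "mask"),
                    parcellation_path=(rec.get("parcellation_path") or None),
                    method_label=(rec.get("method_label") or "method"),
                )
            )
    manifest = CohortManifest(rows=rows)
    if check_paths:
        manifest.check_paths()
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in manifest.rows:
            writer.writerow(
                [r.subject_id, r.reference_path, r.prediction_path, r.prediction_kind,
                 r.parcellation_path or "", r.method_label]
            )


def configure_logging(verbose: bool = True) -> None:
    """Route per-subject progress lines to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
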