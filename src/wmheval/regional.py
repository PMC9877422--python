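"""Region-stratified evaluation via a user-supplied parcellation.

A parcellation is an integer label volume on the mask grid (0 = outside all
regions) plus a label -> region-name table.  Voxel-level metrics (DSC,
sensitivity, precision) are recomputed inside each region after restricting
both masks; lesion-level metrics are global only.  The minimum-cluster-size
filter is applied to the whole-brain masks *before* restriction, so lesions
straddling a region border are not filtered twice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import BinaryMask, VoxelGrid, load_label_volume, require_compatible
from .volume_metrics import VolumeMetrics, volume_overlap

#: Canonical region ordering for six-ROI reports.
CANONICAL_REGIONS = (
    "frontal",
    "insular",
    "occipital",
    "parietal",
    "temporal",
    "corpus callosum",
)


@dataclass
class Parcellation:
    grid: VoxelGrid
    labels: np.ndarray = field(repr=False)
    region_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("parcellation labels do not match grid shape")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"labels present in volume but absent from region table: {sorted(missing)}")

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.region_table)


def restrict(m: BinaryMask, p: Parcellation, label: int) -> BinaryMask:
    """Foreground of ``m`` intersected with one region of the parcellation."""
    require_compatible(m.grid, p.grid, "mask and parcellation")
    if label not in p.region_table:
        raise KeyError(f"unknown parcellation label {label}")
    return BinaryMask(grid=m.grid, voxels=m.voxels & (p.labels == label))


def regional_report(rs: BinaryMask, as_: BinaryMask, p: Parcellation) -> list[tuple[str, VolumeMetrics]]:
    """Per-region voxel-level metrics.

    Masks must already be cluster-filtered at whole-brain level.  Regions
    where the restricted reference is empty fall under the standard
    missing-value policy of :func:`wmheval.volume_metrics.volume_overlap`.
    """
    require_compatible(rs.grid, as_.grid, "reference and automated masks")
    out: list[tuple[str, VolumeMetrics]] = []
    for label in p.region_labels:
        vm = volume_overlap(restrict(rs, p, label), restrict(as_, p, label))
        out.append((p.region_table[label], vm))
    return out


def read_region_table(path: str | Path) -> dict[int, str]:
    """Read a label table CSV with columns (label, region_name)."""
    table: dict[int, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "label" not in reader.fieldnames:
            raise ValueError(f"{path}: expected columns label, region_name")
        for rec in reader:
            table[int(rec["label"])] = rec["region_name"]
    return table


def write_region_table(table: dict[int, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "region_name"])
        for label in sorted(table):
            writer.writerow([label, table[label]])


def load_parcellation(volume_path: str | Path, table_path: str | Path) -> Parcellation:
    """Load a parcellation from a NIfTI label volume plus a CSV label table."""
    grid, labels = load_label_volume(volume_path)
    return Parcellation(grid=grid, labels=labels, region_table=read_region_table(table_path))
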