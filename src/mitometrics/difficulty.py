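"""Per-instance segmentation-difficulty metrics for labeled 3D volumes.

Two complementary morphological indices quantify how hard an instance is to
segment correctly:

Dilation Collision Index (DCI)
    Dilate the instance mask by a small structuring element (default a
    3x3x3 box, i.e. radius 1 with full 26-neighborhood connectivity) and
    count the number of *distinct other* instances the dilated mask touches.
    High DCI marks crowded objects whose boundary is one small expansion away
    from colliding with neighbors — a proxy for false-merge risk.

Erosion Fragility Index (EFI)
    Erode the instance mask by the same kind of structuring element and count
    the connected components that remain, minus one. High EFI marks
    thin-necked or branched objects that fall apart under a one-voxel inward
    perturbation — a proxy for false-split risk. An instance that erodes to
    nothing creates no fragments and scores 0 (the count is clamped at zero).

Both indices are computed in voxel units: the structuring element is a voxel
box regardless of physical anisotropy. An optional anisotropy-aware footprint
is available for exploration but is off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volume_io import InstanceVolume

__all__ = [
    "StructuringElement",
    "DifficultyRecord",
    "DifficultyReport",
    "dilate_mask",
    "erode_mask",
    "count_components",
    "compute_dci",
    "compute_efi",
    "difficulty_report",
    "export_difficulty_scatter",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class StructuringElement:
    """A cubic (box) structuring element of integer voxel radius.

    Radius 1 yields the 3x3x3 full box (26-neighborhood). The footprint spans
    all voxels within Chebyshev distance <= radius.
    """

    radius: int = 1

    def __post_init__(self) -> None:
        if int(self.radius) != self.radius or self.radius < 1:
            raise ValueError(f"radius must be an integer >= 1, got {self.radius}")

    def footprint(self) -> np.ndarray:
        n = 2 * self.radius + 1
        return np.ones((n, n, n), dtype=bool)

    @staticmethod
    def anisotropic_footprint(
        radius: int, spacing: tuple[float, float, float]
    ) -> np.ndarray:
        """Box footprint whose per-axis extent scales inversely with spacing.

        The finest axis gets the nominal radius; coarser axes get a smaller
        radius so the element is closer to a physical cube. Off by default.
        """
        finest = min(spacing)
        radii = [max(0, round(radius * finest / s)) for s in spacing]
        return np.ones(tuple(2 * r + 1 for r in radii), dtype=bool)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    return ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def dilate_mask(mask: np.ndarray, se: StructuringElement = StructuringElement(1)) -> np.ndarray:
    """Box dilation: all voxels within Chebyshev distance <= radius of the mask.

    Clipped at the volume bounds; always a superset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return ndi.binary_dilation(mask, structure=se.footprint())


def erode_mask(mask: np.ndarray, se: StructuringElement = StructuringElement(1)) -> np.ndarray:
    """Box erosion: voxels whose full box neighborhood lies inside the mask.

    Outside-volume is treated as background, so voxels adjacent to the volume
    border erode away. Always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_erosion(mask, structure=se.footprint(), border_value=0)


def count_components(mask: np.ndarray, connectivity: int = 26) -> int:
    """Number of maximal connected voxel sets under 6/18/26-adjacency."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    _, n = ndi.label(mask, structure=_structure(connectivity))
    return int(n)


def _padded_bbox(vol: InstanceVolume, instance_id: int, pad: int) -> tuple[slice, ...]:
    objs = ndi.find_objects((vol.labels == instance_id).astype(np.int8))
    if not objs or objs[0] is None:
        raise KeyError(f"instance id {instance_id} not present in volume {vol.name!r}")
    return tuple(
        slice(max(0, s.start - pad), min(dim, s.stop + pad))
        for s, dim in zip(objs[0], vol.shape)
    )


def compute_dci(
    vol: InstanceVolume,
    instance_id: int,
    se: StructuringElement = StructuringElement(1),
) -> int:
    """Dilation Collision Index of one instance.

    Counts distinct other positive labels whose masks intersect the dilated
    instance mask; each neighbor counts once regardless of contact area.
    """
    if instance_id <= 0:
        raise KeyError(f"instance id must be positive, got {instance_id}")
    # restricted to the instance bounding box padded by the radius: identical
    # to whole-volume computation because the dilation reaches at most that far
    box = _padded_bbox(vol, instance_id, se.radius)
    sub = vol.labels[box]
    dilated = dilate_mask(sub == instance_id, se)
    touched = np.unique(sub[dilated])
    return int(np.count_nonzero((touched > 0) & (touched != instance_id)))


def compute_efi(
    vol: InstanceVolume,
    instance_id: int,
    se: StructuringElement = StructuringElement(1),
    connectivity: int = 26,
) -> int:
    """Erosion Fragility Index of one instance.

    ``max(0, N_components(erode(mask)) - 1)``: the number of extra fragments a
    mild erosion creates. An instance that erodes to the empty set scores 0.
    """
    if instance_id <= 0:
        raise KeyError(f"instance id must be positive, got {instance_id}")
    box = _padded_bbox(vol, instance_id, 0)
    eroded = erode_mask(vol.labels[box] == instance_id, se)
    return max(0, count_components(eroded, connectivity) - 1)


@dataclass(frozen=True)
class DifficultyRecord:
    """Difficulty indices of a single instance."""

    instance_id: int
    voxel_count: int
    dci: int
    efi: int


@dataclass
class DifficultyReport:
    """Per-instance difficulty records and dataset-level aggregates."""

    volume_name: str
    records: list[DifficultyRecord] = field(default_factory=list)
    radius: int = 1
    connectivity: int = 26

    @property
    def n_instances(self) -> int:
        return len(self.records)

    @property
    def mean_dci(self) -> float | None:
        return float(np.mean([r.dci for r in self.records])) if self.records else None

    @property
    def mean_efi(self) -> float | None:
        return float(np.mean([r.efi for r in self.records])) if self.records else None

    def to_dict(self) -> dict:
        return {
            "volume": self.volume_name,
            "radius": self.radius,
            "connectivity": self.connectivity,
            "n_instances": self.n_instances,
            "mean_dci": self.mean_dci,
            "mean_efi": self.mean_efi,
            "instances": [vars(r) for r in self.records],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def difficulty_report(
    vol: InstanceVolume,
    se: StructuringElement = StructuringElement(1),
    connectivity: int = 26,
) -> DifficultyReport:
    """Compute DCI and EFI for every instance of a volume.

    Returns one record per distinct positive label plus arithmetic-mean
    aggregates (absent for an empty volume).
    """
    counts = vol.voxel_counts()
    records = [
        DifficultyRecord(
            instance_id=i,
            voxel_count=counts[i],
            dci=compute_dci(vol, i, se),
            efi=compute_efi(vol, i, se, connectivity),
        )
        for i in sorted(counts)
    ]
    return DifficultyReport(
        volume_name=vol.name, records=records, radius=se.radius, connectivity=connectivity
    )


SCATTER_COLUMNS = ["dataset", "instance_id", "voxel_count", "dci", "efi"]


def export_difficulty_scatter(
    reports: list[DifficultyReport], path: str | Path
) -> pd.DataFrame:
    """Write a difficulty-plane CSV: one row per instance across reports.

    Columns: ``dataset, instance_id, voxel_count, dci, efi``. Supports
    (DCI, EFI) scatter plots of dataset difficulty.
    """
    rows = [
        (rep.volume_name, r.instance_id, r.voxel_count, r.dci, r.efi)
        for rep in reports
        for r in rep.records
    ]
    df = pd.DataFrame(rows, columns=SCATTER_COLUMNS)
    df.to_csv(path, index=False)
    return df
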