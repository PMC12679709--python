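"""Conjunction analysis and atlas-parcellation coverage reporting.

A conjunction is the voxel-wise product (logical AND) of binarized
significance maps: within one cohort it isolates voxels both *sensitive*
(one-sample test) and *specific* (two-sample test); across cohorts it finds
connections shared between two independently mapped symptom networks.
Coverage reports how much of each named atlas parcel (e.g. the cerebellar
components of canonical functional networks) falls inside a significant
mask. Region tables look up named world-mm coordinates — with "±x" notation
expanding to both hemispheres — in a mask and statistic map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import BinaryMask, ScalarMap, VolumeError, VolumeGrid, resample_labels


@dataclass
class AtlasParcellation:
    """Integer label volume (0 = unassigned) with named parcels."""

    grid: VolumeGrid
    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if self.labels.shape != self.grid.shape:
            raise VolumeError("label volume shape does not match grid")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise VolumeError(f"labels without names: {sorted(missing)}")
        if not present:
            raise VolumeError("atlas has no nonzero labels")

    def to_grid(self, target: VolumeGrid) -> "AtlasParcellation":
        """Nearest-neighbour align the atlas onto the analysis grid."""
        labels = resample_labels(self.labels, self.grid, target)
        return AtlasParcellation(target, labels, dict(self.names))

    @classmethod
    def from_files(cls, label_path, names_path) -> "AtlasParcellation":
        import json

        from .volumes import read_volume

        vol = read_volume(label_path)
        raw = json.loads(open(names_path).read())
        names = {int(k): v for k, v in raw.items()}
        return cls(vol.grid, np.round(vol.data).astype(int), names)


def conjunction(masks: list[BinaryMask]) -> BinaryMask:
    """Voxel-wise AND of binarized maps (their product)."""
    if len(masks) < 2:
        raise VolumeError("conjunction needs at least 2 masks")
    grid = masks[0].grid
    data = np.ones(grid.shape, bool)
    for m in masks:
        if m.grid != grid:
            raise VolumeError("conjunction masks are on different grids")
        data &= m.data
    return BinaryMask(grid, data)


def coverage(mask: BinaryMask, atlas: AtlasParcellation) -> pd.DataFrame:
    """Per-parcel coverage of the atlas by a (significant) mask.

    Columns: label, name, n_label_voxels, n_covered, coverage_fraction.
    """
    if atlas.grid != mask.grid:
        raise VolumeError("atlas and mask grids differ; align the atlas first")
    rows = []
    for label in sorted(atlas.names):
        in_label = atlas.labels == label
        n_label = int(in_label.sum())
        n_cov = int((in_label & mask.data).sum())
        rows.append(
            {
                "label": label,
                "name": atlas.names[label],
                "n_label_voxels": n_label,
                "n_covered": n_cov,
                "coverage_fraction": (n_cov / n_label) if n_label else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _expand_point(name: str, coord) -> list[tuple[str, tuple[float, float, float]]]:
    """Expand a "±x" coordinate into left/right rows; pass plain coords through."""
    x, y, z = coord
    if isinstance(x, str):
        xs = x.strip()
        if xs.startswith(("±", "+-", "-+")):
            mag = float(xs.lstrip("±+-"))
            return [
                (f"{name} (R)" if mag else name, (+mag, float(y), float(z))),
                (f"{name} (L)", (-mag, float(y), float(z))),
            ]
        x = float(xs)
    return [(name, (float(x), float(y), float(z)))]


def region_table(
    mask: BinaryMask,
    stat_map: ScalarMap | None,
    label_points: list[tuple],
) -> pd.DataFrame:
    """Membership and local statistic for named world-mm points.

    ``label_points`` entries are (name, (x, y, z)); x may be written "±6"
    to expand into both hemispheres. Columns: name, x_mm, y_mm, z_mm,
    inside, stat.
    """
    rows = []
    for name, coord in label_points:
        for label, (x, y, z) in _expand_point(name, coord):
            idx = tuple(mask.grid.mm_to_voxel((x, y, z)))
            stat = float(stat_map.data[idx]) if stat_map is not None else np.nan
            rows.append(
                {
                    "name": label,
                    "x_mm": x,
                    "y_mm": y,
                    "z_mm": z,
                    "inside": bool(mask.data[idx]),
                    "stat": stat,
                }
            )
    return pd.DataFrame(rows, columns=["name", "x_mm", "y_mm", "z_mm", "inside", "stat"])
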