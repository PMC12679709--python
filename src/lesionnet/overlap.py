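"""Lesion overlap maps: threshold, binarize, count, and report peaks.

Each lesion's connectivity T-score map is binarized at a stringent symmetric
threshold (default T > +7 / T < -7, strict inequalities); positive and
negative maps are then summed across lesions so that each voxel carries the
number of patients whose lesion is strongly (anti-)connected to it. Peaks
reached by at least a given fraction of the cohort (default 90%) are reported
in world mm coordinates.

The default threshold of 7 corresponds, for a 1000-subject normative
connectome (df = 999) and the standard MNI152 2mm brain mask, to a
Bonferroni-corrected per-tail familywise error rate below 1e-6 — see
:func:`threshold_fwe_equivalence`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import ConnectivityMap
from .volumes import BinaryMask, VolumeError, VolumeGrid

DEFAULT_THRESHOLD = 7.0
MNI152_2MM_BRAIN_VOXELS = 228_483


@dataclass
class OverlapMap:
    grid: VolumeGrid
    counts_pos: np.ndarray
    counts_neg: np.ndarray
    n_lesions: int
    threshold: float

    def __post_init__(self) -> None:
        for name in ("counts_pos", "counts_neg"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != self.grid.shape:
                raise VolumeError(f"{name} shape does not match grid")
            if arr.min() < 0 or arr.max() > self.n_lesions:
                raise VolumeError(f"{name} outside [0, n_lesions]")
            setattr(self, name, arr)


def threshold_binarize(
    cmap: ConnectivityMap, theta: float = DEFAULT_THRESHOLD
) -> tuple[BinaryMask, BinaryMask]:
    """Strictly threshold a T map into positive (t > +theta) and negative (t < -theta) masks."""
    if theta <= 0:
        raise VolumeError("threshold must be positive")
    t = cmap.t_map.data
    defined = cmap.t_map.defined_mask.data
    pos = BinaryMask(cmap.t_map.grid, (t > theta) & defined)
    neg = BinaryMask(cmap.t_map.grid, (t < -theta) & defined)
    return pos, neg


def overlap(maps: list[tuple[BinaryMask, BinaryMask]]) -> OverlapMap:
    """Voxel-wise count of lesions whose binarized maps include each voxel."""
    if not maps:
        raise VolumeError("need at least one lesion's binarized maps")
    grid = maps[0][0].grid
    pos = np.zeros(grid.shape, int)
    neg = np.zeros(grid.shape, int)
    for p, n in maps:
        if p.grid != grid or n.grid != grid:
            raise VolumeError("binarized maps are on different grids")
        pos += p.data
        neg += n.data
    return OverlapMap(grid, pos, neg, n_lesions=len(maps), threshold=np.nan)


def overlap_from_cmaps(
    cmaps: list[ConnectivityMap], theta: float = DEFAULT_THRESHOLD
) -> OverlapMap:
    omap = overlap([threshold_binarize(c, theta) for c in cmaps])
    omap.threshold = theta
    return omap


def percent_of_cohort(count: int, n: int) -> int:
    """Share of the cohort as a rounded percent (round-half-up)."""
    return int(math.floor(100.0 * count / n + 0.5))


def required_count(fraction: float, n: int) -> int:
    """Smallest count reaching ``fraction`` of the cohort: ceil(fraction * n)."""
    return int(math.ceil(fraction * n - 1e-12))


def overlap_peak_report(omap: OverlapMap, fraction: float = 0.9) -> pd.DataFrame:
    """Peaks of the overlap map reached by at least ``fraction`` of lesions.

    Voxels with count >= ceil(fraction * n) are grouped into 26-connected
    components; each component is summarized by its maximal-count voxel
    (ties broken by smallest lexicographic voxel index). Columns: x_mm, y_mm,
    z_mm, count, percent, sign.
    """
    if not 0 < fraction <= 1:
        raise VolumeError("fraction must be in (0, 1]")
    need = required_count(fraction, omap.n_lesions)
    rows = []
    structure = np.ones((3, 3, 3), bool)
    for sign, counts in (("positive", omap.counts_pos), ("negative", omap.counts_neg)):
        supra = counts >= need
        labeled, n_comp = ndimage.label(supra, structure=structure)
        for comp in range(1, n_comp + 1):
            idx = np.argwhere(labeled == comp)
            vals = counts[tuple(idx.T)]
            best = idx[vals == vals.max()]
            # lexicographic tie-break: argwhere is already in C order
            peak = best[0]
            count = int(counts[tuple(peak)])
            mm = omap.grid.voxel_to_mm(peak)
            rows.append(
                {
                    "x_mm": float(mm[0]),
                    "y_mm": float(mm[1]),
                    "z_mm": float(mm[2]),
                    "count": count,
                    "percent": percent_of_cohort(count, omap.n_lesions),
                    "sign": sign,
                }
            )
    return pd.DataFrame(rows, columns=["x_mm", "y_mm", "z_mm", "count", "percent", "sign"])


def threshold_fwe_equivalence(
    theta: float, df: int, n_voxels: int = MNI152_2MM_BRAIN_VOXELS, tails: int = 1
) -> float:
    """Bonferroni familywise error bound implied by a T threshold.

    Returns min(1, n_voxels * P(T_df > theta)) for the per-tail convention
    (``tails=1``, the default: positive and negative maps are thresholded and
    reported separately) or min(1, n_voxels * 2 * P(|T_df| > theta)) for a
    two-sided reading (``tails=2``). Used to sanity-check threshold choices:
    theta = 7 at df = 999 over the 228,483-voxel MNI152 2mm brain mask gives
    a per-tail bound below 1e-6.
    """
    if df < 1 or n_voxels < 1:
        raise VolumeError("df and n_voxels must be >= 1")
    if tails not in (1, 2):
        raise VolumeError("tails must be 1 or 2")
    return float(min(1.0, n_voxels * tails * stats.t.sf(theta, df)))


def smallest_equivalent_threshold(
    target_fwe: float, df: int, n_voxels: int, tails: int = 1
) -> float:
    """Smallest T threshold whose Bonferroni FWE bound is below ``target_fwe``."""
    if not 0 < target_fwe < 1:
        raise VolumeError("target_fwe must be in (0, 1)")
    per_voxel = target_fwe / (n_voxels * tails)
    return float(stats.t.isf(per_voxel, df))
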