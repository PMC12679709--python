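"""Normative lesion connectivity maps.

For each lesion the pipeline computes, across every subject of a normative
resting-state connectome:

1. the seed time course — the unweighted mean preprocessed signal over the
   lesion's in-brain voxels;
2. a whole-brain Pearson r map of that seed against every brain voxel;
3. the Fisher z transform (atanh) of r, which variance-stabilizes the
   correlations for across-subject statistics;
4. the across-subject mean-z map and the voxel-wise one-sample T-score map
   of z against zero (df = N - 1).

The resulting :class:`ConnectivityMap` is the per-lesion "normative lesion
connectivity map": each voxel's value reflects how strongly that voxel was
typically connected to the lesioned tissue in healthy subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import (
    BinaryMask,
    ScalarMap,
    Series4D,
    VolumeError,
    extract,
    insert,
    read_mask,
    read_volume,
    write_volume,
)

logger = logging.getLogger(__name__)

R_CLAMP = 1.0 - 1e-7
DEFAULT_T_CAP = 1e6


@dataclass
class Connectome:
    """N subjects' resting-state series on one grid, stored in-mask.

    ``series[s]`` is the (T, V) matrix of subject ``s``'s time series over
    the ``V`` true cells of ``brain_mask`` in C order.
    """

    series: list[np.ndarray]
    brain_mask: BinaryMask

    def __post_init__(self) -> None:
        if len(self.series) < 2:
            raise VolumeError("a connectome needs at least 2 subjects")
        v = self.brain_mask.require_nonempty("brain mask").n_true
        t = self.series[0].shape[0]
        for s, mat in enumerate(self.series):
            if mat.shape != (t, v):
                raise VolumeError(
                    f"subject {s} series shape {mat.shape} != expected {(t, v)}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_timepoints(self) -> int:
        return int(self.series[0].shape[0])

    @property
    def grid(self):
        return self.brain_mask.grid

    @classmethod
    def from_series_4d(cls, volumes: list[Series4D], brain_mask: BinaryMask) -> "Connectome":
        mats = []
        for vol in volumes:
            if vol.grid != brain_mask.grid:
                raise VolumeError("subject volume grid does not match brain mask grid")
            mats.append(np.ascontiguousarray(vol.data[brain_mask.data].T))
        return cls(mats, brain_mask)

    @classmethod
    def from_files(cls, subject_paths, mask_path) -> "Connectome":
        mask = read_mask(mask_path)
        vols = []
        for p in subject_paths:
            vol = read_volume(p)
            if not isinstance(vol, Series4D):
                raise VolumeError(f"expected a 4D series: {p}")
            vols.append(vol)
        return cls.from_series_4d(vols, mask)

    def lesion_columns(self, lesion: BinaryMask) -> np.ndarray:
        """Indices into the in-mask columns covered by ``lesion``."""
        if lesion.grid != self.grid:
            raise VolumeError("lesion mask grid does not match connectome grid")
        inside = lesion.data[self.brain_mask.data]
        cols = np.flatnonzero(inside)
        if cols.size == 0:
            raise VolumeError("lesion lies entirely outside the brain mask")
        return cols


@dataclass
class ConnectivityMap:
    """Group-level normative connectivity of one lesion: mean Fisher-z and T."""

    lesion_id: str
    mean_z: ScalarMap
    t_map: ScalarMap
    df: int
    n_subjects: int

    def save(self, outdir, stem: str | None = None) -> dict:
        import json

        outdir = Path(outdir)
        stem = stem or self.lesion_id
        zp = write_volume(self.mean_z, outdir / f"{stem}_mean_z.nii.gz")
        tp = write_volume(self.t_map, outdir / f"{stem}_tmap.nii.gz")
        sidecar = {
            "lesion_id": self.lesion_id,
            "n_subjects": self.n_subjects,
            "df": self.df,
            "mean_z": zp.name,
            "t_map": tp.name,
        }
        (outdir / f"{stem}_connectivity.json").write_text(json.dumps(sidecar, indent=2))
        return sidecar


# ---------------------------------------------------------------------------
# Elementary operations


def seed_timecourse(series, lesion: BinaryMask, brain_mask: BinaryMask | None = None) -> np.ndarray:
    """Unweighted mean time course over the lesion's (in-brain) voxels.

    ``series`` is a :class:`Series4D` or an (x, y, z, t) array on the lesion's
    grid. If ``brain_mask`` is given, only lesion voxels inside it contribute.
    """
    data = series.data if isinstance(series, Series4D) else np.asarray(series)
    sel = lesion.data
    if brain_mask is not None:
        sel = sel & brain_mask.data
    if not sel.any():
        raise VolumeError("lesion lies entirely outside the brain mask")
    return data[sel].mean(axis=0)


def subject_r_map(series, seed: np.ndarray, brain_mask: BinaryMask) -> ScalarMap:
    """Pearson correlation of the seed time course with every in-mask voxel.

    Zero-variance voxels get r = 0; a zero-variance seed yields an all-zero
    map with a warning. r is clamped to +/-(1 - 1e-7) so atanh stays finite.
    """
    data = series.data if isinstance(series, Series4D) else np.asarray(series)
    mat = data[brain_mask.data].T  # (T, V)
    seed = np.asarray(seed, dtype=float)
    if seed.shape != (mat.shape[0],):
        raise VolumeError(
            f"seed length {seed.shape} does not match series timepoints {mat.shape[0]}"
        )
    r = _correlate(mat, seed[:, None])[0]
    return insert(r, brain_mask)


def _correlate(mat: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Pearson r of each seed column against each voxel column: (L, V)."""
    t = mat.shape[0]
    xm = mat - mat.mean(axis=0)
    xsd = xm.std(axis=0)
    sm = seeds - seeds.mean(axis=0)
    ssd = sm.std(axis=0)
    zero_seed = ssd == 0
    if np.any(zero_seed):
        warnings.warn("seed time course has zero variance; its r map is all zero")
    denom = np.outer(np.where(zero_seed, 1.0, ssd), np.where(xsd == 0, 1.0, xsd)) * t
    r = (sm.T @ xm) / denom
    r[zero_seed, :] = 0.0
    r[:, xsd == 0] = 0.0
    return np.clip(r, -R_CLAMP, R_CLAMP)


def fisher_z(r_map: ScalarMap) -> ScalarMap:
    """Fisher z transform, z = atanh(r), elementwise on defined voxels."""
    vals = np.clip(r_map.data, -R_CLAMP, R_CLAMP)
    return ScalarMap(r_map.grid, np.arctanh(vals), defined_mask=r_map.defined_mask)


def group_t_map(
    z_maps,
    lesion_id: str = "lesion",
    t_cap: float = DEFAULT_T_CAP,
) -> ConnectivityMap:
    """Across-subject mean-z and one-sample T-score map.

    ``z_maps`` is a list of per-subject :class:`ScalarMap` (shared mask) or an
    (N, V) matrix with an accompanying mask via :func:`group_t_map_matrix`.
    Per voxel, t = mean(z) / (sd(z)/sqrt(N)) with sample sd (ddof=1);
    degenerate voxels (sd = 0) get t = 0 when the mean is also 0, otherwise
    sign(mean) * t_cap with a logged warning.
    """
    if len(z_maps) < 2:
        raise VolumeError("group t map needs at least 2 subjects")
    mask = z_maps[0].defined_mask
    mat = np.stack([extract(m, mask) for m in z_maps])
    return group_t_map_matrix(mat, mask, lesion_id=lesion_id, t_cap=t_cap)


def group_t_map_matrix(
    z_mat: np.ndarray,
    mask: BinaryMask,
    lesion_id: str = "lesion",
    t_cap: float = DEFAULT_T_CAP,
) -> ConnectivityMap:
    """Fast path of :func:`group_t_map` on an (N, V) in-mask matrix."""
    n = z_mat.shape[0]
    if n < 2:
        raise VolumeError("group t map needs at least 2 subjects")
    mean = z_mat.mean(axis=0)
    sd = z_mat.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate & (mean == 0)] = 0.0
    bad = degenerate & (mean != 0)
    if np.any(bad):
        logger.warning(
            "%s: %d voxel(s) with zero across-subject variance and nonzero mean; "
            "t capped at %g",
            lesion_id,
            int(bad.sum()),
            t_cap,
        )
        t[bad] = np.sign(mean[bad]) * t_cap
    return ConnectivityMap(
        lesion_id=lesion_id,
        mean_z=insert(mean, mask),
        t_map=insert(t, mask),
        df=n - 1,
        n_subjects=n,
    )


# ---------------------------------------------------------------------------
# Batch pipeline


def lesion_connectivity_map(
    connectome: Connectome,
    lesion: BinaryMask,
    lesion_id: str = "lesion",
    t_cap: float = DEFAULT_T_CAP,
) -> ConnectivityMap:
    """Full per-lesion pipeline: seed -> r -> Fisher z -> group mean/T map."""
    return connectivity_maps(connectome, {lesion_id: lesion}, t_cap=t_cap)[lesion_id]


def connectivity_maps(
    connectome: Connectome,
    lesions: dict[str, BinaryMask],
    t_cap: float = DEFAULT_T_CAP,
) -> dict[str, ConnectivityMap]:
    """Connectivity maps for many lesions, sharing per-subject standardization."""
    ids = list(lesions)
    cols = [connectome.lesion_columns(lesions[i]) for i in ids]
    z_sum = None
    z_stacks = np.zeros((len(ids), connectome.n_subjects, connectome.brain_mask.n_true))
    for s, mat in enumerate(connectome.series):
        seeds = np.column_stack([mat[:, c].mean(axis=1) for c in cols])
        r = _correlate(mat, seeds)
        z_stacks[:, s, :] = np.arctanh(r)
    out = {}
    for k, lesion_id in enumerate(ids):
        out[lesion_id] = group_t_map_matrix(
            z_stacks[k], connectome.brain_mask, lesion_id=lesion_id, t_cap=t_cap
        )
    return out
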