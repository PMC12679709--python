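"""Volumetric containers, NIfTI I/O, coordinate conventions, and resampling.

All analysis code works on three light containers:

* :class:`VolumeGrid` — a shape plus a 4x4 affine mapping 0-based voxel
  indices to world mm coordinates (MNI convention for real data).
* :class:`BinaryMask` — a boolean volume on a grid (lesion tracings,
  brain masks, thresholded statistic maps).
* :class:`ScalarMap` — a real-valued volume with an explicit defined-mask;
  cells outside the defined mask carry exactly zero so every reduction
  stays finite.

NIfTI reading/writing goes through nibabel; the affine is taken from the
image as nibabel resolves sform/qform precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeError(ValueError):
    """Raised for invalid volumes, grids, masks, or coordinate requests."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D sampling grid: voxel counts per axis plus a voxel-to-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    space_label: str = "unknown"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise VolumeError(f"grid shape must be three positive integers, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise VolumeError(f"affine must be 4x4, got shape {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise VolumeError("affine is not invertible")
        aff = aff.copy()
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(self.affine, other.affine)

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.round(9).tobytes()))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_mm(self, index) -> np.ndarray:
        """World mm coordinates of voxel center(s). ``index`` is (3,) or (N, 3)."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        ints = np.round(idx).astype(int)
        if np.any(ints < 0) or np.any(ints >= np.asarray(self.shape)):
            raise VolumeError(f"voxel index out of range for shape {self.shape}: {index}")
        mm = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm[0] if np.ndim(index) == 1 else mm

    def mm_to_voxel(self, mm) -> np.ndarray:
        """Nearest voxel index for world coordinate(s); inverse of voxel_to_mm."""
        pts = np.atleast_2d(np.asarray(mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        idx = np.round(vox).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise VolumeError(f"mm coordinate outside field of view: {mm}")
        return idx[0] if np.ndim(mm) == 1 else idx


def mni152_2mm_grid() -> VolumeGrid:
    """The standard MNI152 2mm template grid (91x109x91, radiological x-flip)."""
    affine = np.array(
        [
            [-2.0, 0.0, 0.0, 90.0],
            [0.0, 2.0, 0.0, -126.0],
            [0.0, 0.0, 2.0, -72.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return VolumeGrid(shape=(91, 109, 91), affine=affine, space_label="MNI152-2mm")


@dataclass
class BinaryMask:
    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise VolumeError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self, what: str = "mask") -> "BinaryMask":
        if self.n_true == 0:
            raise VolumeError(f"{what} is empty")
        return self

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.data & other.data)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.data | other.data)


@dataclass
class ScalarMap:
    """Real-valued volume; values outside ``defined_mask`` are exactly zero."""

    grid: VolumeGrid
    data: np.ndarray
    defined_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise VolumeError(
                f"map shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.defined_mask is None:
            self.defined_mask = BinaryMask(self.grid, np.ones(self.grid.shape, bool))
        _check_same_grid(self.grid, self.defined_mask.grid)
        self.data = np.where(self.defined_mask.data, self.data, 0.0)

    def values_in_mask(self) -> np.ndarray:
        return self.data[self.defined_mask.data]


@dataclass
class Series4D:
    """Descriptor for a 4D time-series volume (x, y, z, t)."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.shape:
            raise VolumeError(f"4D series shape {self.data.shape} does not match grid")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[3])


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if a != b:
        raise VolumeError("grids do not match (shape or affine differ)")


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path, space_label: str = "unknown"):
    """Read a NIfTI volume; returns :class:`ScalarMap` (3D) or :class:`Series4D` (4D).

    Values are taken as stored (after the format's slope/intercept scaling,
    which nibabel applies). A volume that is entirely NaN is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise VolumeError(f"not a readable NIfTI file: {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if np.all(np.isnan(data)):
        raise VolumeError(f"volume is entirely NaN: {path}")
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim == 3:
        grid = VolumeGrid(data.shape, img.affine, space_label)
        return ScalarMap(grid, data)
    if data.ndim == 4:
        grid = VolumeGrid(data.shape[:3], img.affine, space_label)
        return Series4D(grid, data)
    raise VolumeError(f"unsupported dimensionality {data.ndim} in {path}")


def write_volume(obj, path) -> Path:
    """Write a ScalarMap, BinaryMask, or Series4D as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, BinaryMask):
        data, grid = obj.data.astype(np.uint8), obj.grid
    elif isinstance(obj, (ScalarMap, Series4D)):
        data, grid = obj.data, obj.grid
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    nib.save(img, str(path))
    return path


def read_mask(path, cutoff: float = 0.5, space_label: str = "unknown") -> BinaryMask:
    vol = read_volume(path, space_label)
    if not isinstance(vol, ScalarMap):
        raise VolumeError(f"expected a 3D mask volume, got 4D: {path}")
    return binarize_mask(vol, cutoff=cutoff, name=str(path))


# ---------------------------------------------------------------------------
# Mask operations


def binarize_mask(smap: ScalarMap, cutoff: float = 0.5, name: str = "map") -> BinaryMask:
    """Binarize a scalar map at ``value > cutoff``.

    Handles the 0/1, 0/255 and interpolated dialects of traced lesion files.
    """
    vals = smap.data
    if not np.all(np.isfinite(vals[smap.defined_mask.data])):
        raise VolumeError(f"non-finite values inside defined mask of {name}")
    mask = BinaryMask(smap.grid, (vals > cutoff) & smap.defined_mask.data)
    if mask.n_true == 0:
        raise VolumeError(f"binarizing {name} at cutoff {cutoff} yields an empty mask")
    return mask


def _resample_nearest(data: np.ndarray, source: VolumeGrid, target: VolumeGrid) -> np.ndarray:
    """Nearest-neighbour resample via affine composition (target -> source voxels)."""
    m = np.linalg.inv(source.affine) @ target.affine
    return ndimage.affine_transform(
        data,
        matrix=m[:3, :3],
        offset=m[:3, 3],
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
    )


def resample_to_grid(mask: BinaryMask, target: VolumeGrid) -> BinaryMask:
    """Nearest-neighbour resample a binary mask onto ``target``.

    A mask already on the target grid is returned unchanged; a mask that
    falls entirely outside the target field of view is an error.
    """
    if mask.grid == target:
        return mask
    out = _resample_nearest(mask.data.astype(np.uint8), mask.grid, target) > 0
    result = BinaryMask(target, out)
    if result.n_true == 0:
        raise VolumeError("resampled mask is empty (outside target field of view)")
    return result


def resample_labels(labels: np.ndarray, source: VolumeGrid, target: VolumeGrid) -> np.ndarray:
    """Nearest-neighbour resample an integer label volume onto ``target``."""
    if source == target:
        return labels
    return _resample_nearest(labels.astype(np.int32), source, target)


# ---------------------------------------------------------------------------
# Mask-indexed vector views (used by the statistics modules)


def extract(volume, mask: BinaryMask) -> np.ndarray:
    """1D vector of a volume's values at the mask's true cells (C order)."""
    data = volume.data if isinstance(volume, ScalarMap) else np.asarray(volume)
    _check_same_grid_shapes(data.shape, mask.grid.shape)
    return data[mask.data]


def insert(vec: np.ndarray, mask: BinaryMask, fill: float = 0.0) -> ScalarMap:
    """Scatter a mask-ordered vector back into a full ScalarMap."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (mask.n_true,):
        raise VolumeError(f"vector length {vec.shape} does not match mask n_true {mask.n_true}")
    data = np.full(mask.grid.shape, fill, dtype=float)
    data[mask.data] = vec
    return ScalarMap(mask.grid, data, defined_mask=mask)


def _check_same_grid_shapes(a, b) -> None:
    if tuple(a) != tuple(b):
        raise VolumeError(f"shape mismatch: {a} vs {b}")
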