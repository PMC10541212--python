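"""Gridded-volume domain types and NIfTI / b-value sidecar I/O.

All spatial reasoning in this package uses a single convention: voxel
index ``(i, j, k)`` (0-based) maps to the physical *center*
``origin + (i*sx, j*sy, k*sz)`` in millimetres, with ``(sx, sy, sz)``
the voxel spacing. Distances are always computed between voxel centers
in physical units, so anisotropic grids are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "DwiSeries",
    "RoiMask",
    "read_dwi",
    "read_bvalues",
    "read_mask",
    "read_scalar_volume",
    "average_directions",
    "resample_to_grid",
    "write_volume",
    "write_mask",
]

ROI_LABELS = ("cancer", "control", "tumor_containing", "other")


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3D voxel grid: shape (voxels), spacing (mm), origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid shape, spacing and origin must be length-3")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing entries must be > 0, got {self.spacing}")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm affine (diagonal, no rotation)."""
        aff = np.diag((*self.spacing, 1.0))
        aff[:3, 3] = self.origin
        return aff

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical center coordinates (mm) of an (n, 3) index array."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @property
    def voxel_diagonal_mm(self) -> float:
        return float(np.linalg.norm(self.spacing))

    @classmethod
    def from_affine(cls, shape: Sequence[int], affine: np.ndarray) -> "ImageGrid":
        spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        return cls(tuple(shape[:3]), spacing, tuple(float(v) for v in affine[:3, 3]))


@dataclass
class DwiSeries:
    """Direction-averaged diffusion signal: 4D array indexed (x, y, z, b)."""

    signal: np.ndarray
    bvalues: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DWI signal must be 4D (x, y, z, b)")
        if self.signal.shape[3] != self.bvalues.size:
            raise ValueError(
                f"{self.signal.shape[3]} volumes but {self.bvalues.size} b-values"
            )
        if self.signal.shape[:3] != self.grid.shape:
            raise ValueError("signal spatial shape does not match grid")
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be non-negative")
        if np.unique(self.bvalues).size != self.bvalues.size:
            raise ValueError("b-values must be distinct")
        if np.any(np.diff(self.bvalues) < 0):
            order = np.argsort(self.bvalues)
            self.bvalues = self.bvalues[order]
            self.signal = self.signal[..., order]

    @property
    def n_bvalues(self) -> int:
        return int(self.bvalues.size)

    def volume(self, bvalue: float) -> np.ndarray:
        """The 3D volume acquired at one b-value."""
        idx = np.flatnonzero(np.isclose(self.bvalues, bvalue))
        if idx.size == 0:
            raise KeyError(f"no volume at b={bvalue}")
        return self.signal[..., idx[0]]


@dataclass
class RoiMask:
    """Binary region-of-interest mask on a grid."""

    mask: np.ndarray
    grid: ImageGrid
    label: str = "other"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def read_bvalues(path: str | Path) -> np.ndarray:
    """Parse a whitespace-separated b-value sidecar (FSL ``.bval`` dialect)."""
    text = Path(path).read_text().split()
    if not text:
        raise ValueError(f"empty b-value file: {path}")
    bvals = np.array([float(t) for t in text])
    if np.any(bvals < 0):
        raise ValueError(f"negative b-value in {path}")
    return bvals


def read_dwi(path_volume: str | Path, path_bvalues: str | Path) -> DwiSeries:
    """Load a 4D NIfTI volume plus its b-value sidecar.

    Volumes are re-ordered so b-values ascend; the sidecar count must
    match the fourth dimension.
    """
    img = nib.load(str(path_volume))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D volume, got {data.ndim}D: {path_volume}")
    bvals = read_bvalues(path_bvalues)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"b-value count {bvals.size} != volume count {data.shape[3]}"
        )
    grid = ImageGrid.from_affine(data.shape, img.affine)
    order = np.argsort(bvals)
    return DwiSeries(signal=data[..., order], bvalues=bvals[order], grid=grid)


def read_mask(path: str | Path, label: str = "other") -> RoiMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    grid = ImageGrid.from_affine(data.shape, img.affine)
    return RoiMask(mask=data > 0, grid=grid, label=label)


def read_scalar_volume(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, ImageGrid.from_affine(data.shape, img.affine)


def average_directions(
    groups: Mapping[float, Sequence[np.ndarray]], grid: ImageGrid
) -> DwiSeries:
    """Average per-direction volumes within each b-value shell.

    ``groups`` maps b-value -> sequence of 3D volumes (one per diffusion
    direction). Returns one direction-averaged volume per b-value.
    """
    if not groups:
        raise ValueError("no b-value groups given")
    bvals = np.array(sorted(groups))
    vols = []
    for b in bvals:
        stack = [np.asarray(v, dtype=float) for v in groups[b]]
        if len(stack) == 0:
            raise ValueError(f"empty direction group at b={b}")
        vols.append(np.mean(stack, axis=0))
    return DwiSeries(signal=np.stack(vols, axis=-1), bvalues=bvals, grid=grid)


def resample_to_grid(
    volume: np.ndarray,
    source: ImageGrid,
    target: ImageGrid,
    mode: str = "continuous",
) -> np.ndarray:
    """Resample a 3D volume from one grid to another.

    ``continuous`` uses trilinear interpolation; ``label`` uses
    nearest-neighbour so only values present in the input appear in the
    output (masks, segmentations).
    """
    if mode not in ("continuous", "label"):
        raise ValueError("mode must be 'continuous' or 'label'")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != source.shape:
        raise ValueError("volume shape does not match source grid")
    ii, jj, kk = np.meshgrid(
        *(np.arange(n) for n in target.shape), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    phys = target.voxel_centers(idx)
    src_idx = (phys - np.asarray(source.origin)) / np.asarray(source.spacing)
    order = 1 if mode == "continuous" else 0
    out = ndimage.map_coordinates(
        volume, src_idx.T, order=order, mode="nearest"
    )
    return out.reshape(target.shape)


def write_volume(volume: np.ndarray, grid: ImageGrid, path: str | Path) -> None:
    """Write a 3D or 4D volume as NIfTI with the grid's affine."""
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    img = nib.Nifti1Image(volume.astype(np.float32), grid.affine)
    img.header.set_zooms((*grid.spacing, *([1.0] if volume.ndim == 4 else [])))
    nib.save(img, str(path))


def write_mask(mask: RoiMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit 0/1 NIfTI (lossless round-trip)."""
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))
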