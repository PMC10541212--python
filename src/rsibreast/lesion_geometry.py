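"""Tumor-containing region construction and automated lesion sizing.

The pre-treatment cancer ROI is dilated uniformly by a physical distance
(default 1 cm) to form the "tumor-containing region". Classified
components connected to that region are absorbed into it (to allow for
growth beyond the original margin), the largest connected classified
component inside the region is extracted, and its longest diameter is
the maximum pairwise distance between member voxel centers, reported in
cm. The pre-treatment region is reused at every later time point, so no
manual tumour delineation is needed after baseline.

All distances are physical (mm), respecting anisotropic voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .cancer_classifier import ProbabilityMap, classify_map
from .volumes_io import ImageGrid, RoiMask

__all__ = [
    "LesionMeasurement",
    "expand_roi",
    "attach_connected_growth",
    "largest_component",
    "longest_diameter",
    "measure_timepoint",
]


@dataclass
class LesionMeasurement:
    """Automatic lesion size at one time point."""

    diameter_cm: float
    n_voxels: int
    component_mask: np.ndarray
    region_mask: np.ndarray

    def __post_init__(self) -> None:
        if (self.diameter_cm == 0.0) != (self.n_voxels <= 1):
            raise ValueError("diameter must be 0 exactly for empty/singleton components")
        if np.any(self.component_mask & ~self.region_mask):
            raise ValueError("component must lie inside the tumor-containing region")


def _structure(connectivity: int) -> np.ndarray:
    table = {6: 1, 18: 2, 26: 3}
    if connectivity not in table:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, table[connectivity])


def expand_roi(cancer: RoiMask, distance_mm: float = 10.0) -> RoiMask:
    """Uniform physical dilation of a mask by ``distance_mm``.

    The output contains exactly the voxels whose center lies within the
    Euclidean distance (in mm, anisotropic spacing respected) of some
    input-voxel center; it is always a superset of the input.
    """
    if cancer.n_voxels == 0:
        raise ValueError("cannot expand an empty mask")
    if distance_mm < 0:
        raise ValueError("distance must be non-negative")
    if distance_mm == 0:
        return replace(cancer, mask=cancer.mask.copy(), label="tumor_containing")
    dist = ndimage.distance_transform_edt(
        ~cancer.mask, sampling=cancer.grid.spacing
    )
    return RoiMask(
        mask=dist <= distance_mm + 1e-9, grid=cancer.grid, label="tumor_containing"
    )


def attach_connected_growth(
    region: RoiMask, classified: np.ndarray, connectivity: int = 26
) -> RoiMask:
    """Absorb classified components that touch the region into the region.

    Any connected component of ``classified`` whose voxel set intersects
    the region is included in full, capturing tumour growth that extends
    beyond the dilated margin.
    """
    classified = np.asarray(classified).astype(bool)
    if classified.shape != region.grid.shape:
        raise ValueError("classified mask shape does not match region grid")
    labels, n = ndimage.label(classified, structure=_structure(connectivity))
    if n == 0:
        return replace(region, mask=region.mask.copy())
    touching = np.unique(labels[region.mask & classified])
    touching = touching[touching > 0]
    grown = region.mask | np.isin(labels, touching)
    return RoiMask(mask=grown, grid=region.grid, label="tumor_containing")


def largest_component(
    classified: np.ndarray, region: RoiMask, connectivity: int = 26
) -> np.ndarray:
    """Largest connected component of (classified AND region).

    Returns a boolean mask; all-False when the intersection is empty.
    Ties in size are broken deterministically by the smallest minimum
    linear voxel index.
    """
    classified = np.asarray(classified).astype(bool)
    if classified.shape != region.grid.shape:
        raise ValueError("classified mask shape does not match region grid")
    inter = classified & region.mask
    labels, n = ndimage.label(inter, structure=_structure(connectivity))
    if n == 0:
        return np.zeros(region.grid.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if candidates.size == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        winner = min(
            candidates, key=lambda lab: int(np.flatnonzero(flat == lab)[0])
        )
    return labels == winner


def longest_diameter(component: np.ndarray, grid: ImageGrid) -> float:
    """Longest diameter of a voxel set in cm.

    Maximum pairwise Euclidean distance between voxel centers in
    physical mm, divided by 10. Any 3D chord lies in some plane, so the
    3D maximum realizes the longest diameter in any plane. Empty or
    singleton components measure 0.0 cm, matching a complete response.
    """
    coords = np.argwhere(np.asarray(component).astype(bool))
    if coords.shape[0] <= 1:
        return 0.0
    pts = grid.voxel_centers(coords)
    if pts.shape[0] > 400:
        # max pairwise distance is attained on the convex hull
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: fall through
    return float(pdist(pts).max()) / 10.0


def measure_timepoint(
    prob: ProbabilityMap,
    pre_cancer: RoiMask,
    threshold: float = 0.5,
    expand_mm: float = 10.0,
    connectivity: int = 26,
) -> LesionMeasurement:
    """Full automatic sizing of one time point's probability map.

    ``pre_cancer`` is always the pre-treatment cancer ROI (the same
    region is applied across all registered time points). Composes:
    dilation -> connected-growth attachment -> largest component ->
    longest diameter.
    """
    if prob.grid.shape != pre_cancer.grid.shape:
        raise ValueError("probability map and ROI grids differ")
    classified = classify_map(prob, threshold)
    region = expand_roi(pre_cancer, expand_mm)
    region = attach_connected_growth(region, classified, connectivity)
    component = largest_component(classified, region, connectivity)
    return LesionMeasurement(
        diameter_cm=longest_diameter(component, prob.grid),
        n_voxels=int(component.sum()),
        component_mask=component,
        region_mask=region.mask,
    )
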