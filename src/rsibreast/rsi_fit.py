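"""Three-component fixed-diffusivity signal model fit and normalization.

The diffusion signal at b-value ``b`` is modelled as

    S(b) = C1 * exp(-b * ADC1) + C2 * exp(-b * ADC2) + C3 * exp(-b * ADC3)

with the three apparent diffusion coefficients fixed across voxels and
the non-negative signal contributions ``C1, C2, C3`` estimated per voxel
by least squares. C1 captures restricted / hyper-restricted diffusion
(tumour cells, fatty tissue), C2 hindered diffusion (tumour and
fibroglandular tissue), C3 free and vascular water.

Because the diffusivities are global, the design matrix is shared by
every voxel and the whole volume is fitted with a handful of matrix
products: the non-negativity-constrained solution is found exactly by
enumerating the 2^3 candidate active sets (for a convex problem the
feasible support with the smallest residual is the global optimum).

Fitted maps are normalized per patient to the 95th percentile of the
geometric mean of C1 and C2 inside the contralateral control ROI, which
removes arbitrary scanner scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .volumes_io import DwiSeries, ImageGrid, RoiMask

__all__ = [
    "RsiFixedAdcs",
    "ComponentMaps",
    "fit_components",
    "geometric_mean_map",
    "normalization_factor",
    "normalize_components",
]

#: Example component diffusivities (mm^2/s) used throughout the test
#: phantoms: restricted, hindered, free. These are plausible magnitudes
#: for tissue water, not calibrated values; real analyses must supply
#: the triple in the run configuration.
EXAMPLE_FIXED_ADCS = (1.0e-4, 1.5e-3, 1.0e-2)


@dataclass(frozen=True)
class RsiFixedAdcs:
    """The three fixed component diffusivities in mm^2/s, ascending."""

    adc1: float
    adc2: float
    adc3: float

    def __post_init__(self) -> None:
        if not (0 <= self.adc1 < self.adc2 < self.adc3):
            raise ValueError(
                f"diffusivities must satisfy 0 <= adc1 < adc2 < adc3, "
                f"got ({self.adc1}, {self.adc2}, {self.adc3})"
            )

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.adc1, self.adc2, self.adc3])

    @classmethod
    def example(cls) -> "RsiFixedAdcs":
        return cls(*EXAMPLE_FIXED_ADCS)


@dataclass
class ComponentMaps:
    """Voxel-wise C1/C2/C3 signal-contribution volumes on one grid."""

    c1: np.ndarray
    c2: np.ndarray
    c3: np.ndarray
    fixed_adcs: RsiFixedAdcs
    grid: ImageGrid
    normalization_factor: float | None = None

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            setattr(self, name, arr)
        if self.normalization_factor is not None and self.normalization_factor <= 0:
            raise ValueError("normalization_factor must be positive")

    @property
    def stacked(self) -> np.ndarray:
        """(x, y, z, 3) stack of the three component maps."""
        return np.stack([self.c1, self.c2, self.c3], axis=-1)


def design_matrix(bvalues: np.ndarray, fixed_adcs: RsiFixedAdcs) -> np.ndarray:
    """(n_b, 3) exponential decay design matrix shared by all voxels."""
    b = np.asarray(bvalues, dtype=float)
    return np.exp(-b[:, None] * fixed_adcs.as_array[None, :])


def _nnls_by_support(A: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Exact batched non-negative least squares for a small design matrix.

    A: (m, p) shared design; S: (n, m) signals. Enumerates every support
    subset, solves the unconstrained problem on it, and keeps the
    feasible candidate with the lowest residual — exact for convex NNLS.
    """
    m, p = A.shape
    n = S.shape[0]
    best_coef = np.zeros((n, p))
    best_res = np.einsum("ij,ij->i", S, S)  # empty support residual ||S||^2
    for k in range(1, p + 1):
        for support in combinations(range(p), k):
            As = A[:, support]
            pinv = np.linalg.pinv(As)
            coef = S @ pinv.T  # (n, k)
            feasible = np.all(coef >= 0, axis=1)
            if not np.any(feasible):
                continue
            resid = S - coef @ As.T
            res = np.einsum("ij,ij->i", resid, resid)
            better = feasible & (res < best_res - 1e-12 * (1 + best_res))
            if np.any(better):
                best_res[better] = res[better]
                full = np.zeros((int(better.sum()), p))
                full[:, list(support)] = coef[better]
                best_coef[better] = full
    return best_coef


def fit_components(
    dwi: DwiSeries,
    fixed_adcs: RsiFixedAdcs,
    nonnegative: bool = True,
) -> ComponentMaps:
    """Fit (C1, C2, C3) per voxel by (non-negative) linear least squares.

    Noiseless signals generated by the forward model are recovered
    exactly up to numerical precision. With ``nonnegative`` (default)
    coefficients are constrained to C_i >= 0, reflecting their physical
    meaning as signal fractions; pass ``False`` for the unconstrained
    ordinary least-squares fit.
    """
    if dwi.n_bvalues < 3:
        raise ValueError("at least 3 distinct b-values required to fit 3 components")
    if not np.all(np.isfinite(dwi.signal)):
        raise ValueError("DWI signal contains non-finite values")
    A = design_matrix(dwi.bvalues, fixed_adcs)
    S = dwi.signal.reshape(-1, dwi.n_bvalues)
    coef = S @ np.linalg.pinv(A).T
    if nonnegative:
        bad = np.any(coef < 0, axis=1)
        if np.any(bad):
            coef[bad] = _nnls_by_support(A, S[bad])
        coef = np.maximum(coef, 0.0)
    shape = dwi.grid.shape
    return ComponentMaps(
        c1=coef[:, 0].reshape(shape),
        c2=coef[:, 1].reshape(shape),
        c3=coef[:, 2].reshape(shape),
        fixed_adcs=fixed_adcs,
        grid=dwi.grid,
    )


def geometric_mean_map(maps: ComponentMaps) -> np.ndarray:
    """Voxel-wise sqrt(C1 * C2); the intensity used for normalization."""
    if np.any(maps.c1 < 0) or np.any(maps.c2 < 0):
        raise ValueError("geometric mean requires non-negative C1 and C2")
    return np.sqrt(maps.c1 * maps.c2)


def normalization_factor(gm: np.ndarray, control: RoiMask) -> float:
    """95th percentile of the C1/C2 geometric mean inside the control ROI.

    Percentile convention: sorted-order linear interpolation at rank
    0.95 * (n - 1).
    """
    if control.n_voxels == 0:
        raise ValueError("control mask is empty")
    values = np.asarray(gm, dtype=float)[control.mask]
    factor = float(np.percentile(values, 95.0, method="linear"))
    if factor <= 0:
        raise ValueError("control-ROI geometric mean is zero at the 95th percentile")
    return factor


def normalize_components(maps: ComponentMaps, factor: float) -> ComponentMaps:
    """Divide all three component maps by the patient normalization factor."""
    if not factor > 0:
        raise ValueError("normalization factor must be positive")
    return replace(
        maps,
        c1=maps.c1 / factor,
        c2=maps.c2 / factor,
        c3=maps.c3 / factor,
        normalization_factor=factor,
    )
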