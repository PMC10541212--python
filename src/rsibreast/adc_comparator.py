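"""Conventional ADC map from low b-values and ROI mean ADC.

The apparent diffusion coefficient is the negative slope of the
log-linear fit of signal versus b over the retained b-values
(b < 1000 s/mm^2; with the standard acquisition that is b = 0 and 500,
giving the two-point closed form ADC = ln(S0/S500) / 500). Voxels with
any non-positive retained signal have no defined log-signal and are
flagged undefined. The ROI mean excludes undefined voxels and exact-zero
ADC values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes_io import DwiSeries, ImageGrid, RoiMask

__all__ = ["AdcMap", "compute_adc_map", "mean_adc"]


@dataclass
class AdcMap:
    """ADC volume (mm^2/s) plus the mask of voxels with a valid estimate."""

    adc: np.ndarray
    defined: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.defined = np.asarray(self.defined).astype(bool)
        if self.adc.shape != self.grid.shape or self.defined.shape != self.grid.shape:
            raise ValueError("ADC map shape does not match grid")
        if not np.all(np.isfinite(self.adc[self.defined])):
            raise ValueError("defined voxels must have finite ADC")


def compute_adc_map(dwi: DwiSeries, max_bvalue: float = 1000.0) -> AdcMap:
    """Log-linear ADC fit over b-values below ``max_bvalue``.

    ADC = -slope of the ordinary least-squares line of ln(S) on b; the
    two-retained-b case reduces to the closed-form log ratio. Voxels
    where any retained signal is <= 0 are marked undefined (their ADC is
    NaN).
    """
    keep = dwi.bvalues < max_bvalue
    if keep.sum() < 2:
        raise ValueError(
            f"need at least two b-values below {max_bvalue}, have {int(keep.sum())}"
        )
    b = dwi.bvalues[keep]
    S = dwi.signal[..., keep]
    defined = np.all(S > 0, axis=-1)
    adc = np.full(dwi.grid.shape, np.nan)
    if np.any(defined):
        logS = np.log(S[defined])  # (n_defined, n_b)
        bc = b - b.mean()
        # OLS slope of ln S on b, vectorized over voxels
        slope = (logS * bc).sum(axis=-1) / (bc * bc).sum()
        adc[defined] = -slope
    return AdcMap(adc=adc, defined=defined, grid=dwi.grid)


def mean_adc(
    adc_map: AdcMap, roi: RoiMask, exclude_negative: bool = False
) -> float:
    """Mean ADC over the defined voxels of an ROI.

    Undefined voxels and exact-zero ADC values are excluded; negative
    values (possible under noise) are retained unless
    ``exclude_negative``.
    """
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    use = roi.mask & adc_map.defined
    if not np.any(use):
        raise ValueError("no defined ADC voxels inside the ROI")
    values = adc_map.adc[use]
    values = values[values != 0.0]
    if exclude_negative:
        values = values[values > 0.0]
    if values.size == 0:
        raise ValueError("no usable ADC voxels inside the ROI after exclusions")
    return float(values.mean())
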