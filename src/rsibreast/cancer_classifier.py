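"""Voxel classification: joint (C1, C2) densities -> posterior of cancer.

Training pools normalized (C1, C2) pairs from the pre-treatment cancer
and control ROIs of all patients simultaneously, bins them on a shared
2D histogram, and converts the two class densities into a posterior
probability of cancer per bin via Bayes' rule:

    P(cancer | C1, C2) = f_cancer * pi / (f_cancer * pi + f_control * (1 - pi))

The binned posterior acts as a lookup table: any voxel's (C1, C2) pair
is mapped to the posterior of its bin, producing a probability map per
patient per time point without further training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .rsi_fit import ComponentMaps
from .volumes_io import ImageGrid

__all__ = [
    "ClassifierConfig",
    "PosteriorLookupTable",
    "ProbabilityMap",
    "build_lookup",
    "posterior_map",
    "classify_map",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Density-estimation settings for the lookup table.

    n_bins: histogram resolution per axis.
    prior_cancer: class prior pi; 0.5 makes the posterior a pure
        density ratio.
    smoothing_sigma_bins: optional Gaussian smoothing of each class
        histogram, in bin units (0 disables).
    pseudocount: total uniform probability pseudo-mass mixed into each
        normalized class histogram, so bins with no training data fall
        back exactly to the class prior.
    edge_quantile: the bin edges span [0, q-th pooled quantile] per axis.
    """

    n_bins: int = 128
    prior_cancer: float = 0.5
    smoothing_sigma_bins: float = 0.0
    pseudocount: float = 0.5
    edge_quantile: float = 0.995

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0 < self.prior_cancer < 1):
            raise ValueError("prior_cancer must be in (0, 1)")
        if self.smoothing_sigma_bins < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class PosteriorLookupTable:
    """Binned posterior probability of cancer over the (C1, C2) plane."""

    c1_edges: np.ndarray
    c2_edges: np.ndarray
    posterior: np.ndarray
    prior_cancer: float
    smoothing_sigma_bins: float
    pseudocount: float
    training_counts: tuple[int, int]  # (n cancer voxels, n control voxels)

    def __post_init__(self) -> None:
        self.c1_edges = np.asarray(self.c1_edges, dtype=float)
        self.c2_edges = np.asarray(self.c2_edges, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)
        if np.any(np.diff(self.c1_edges) <= 0) or np.any(np.diff(self.c2_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        expected = (self.c1_edges.size - 1, self.c2_edges.size - 1)
        if self.posterior.shape != expected:
            raise ValueError(
                f"posterior grid {self.posterior.shape} does not match edges {expected}"
            )
        if np.any(self.posterior < 0) or np.any(self.posterior > 1):
            raise ValueError("posterior values must lie in [0, 1]")

    def bin_index(self, values: np.ndarray, axis: int) -> np.ndarray:
        """Bin index per value, clamped to the edge bins for out-of-range."""
        edges = self.c1_edges if axis == 0 else self.c2_edges
        idx = np.searchsorted(edges, np.asarray(values, dtype=float), side="right") - 1
        return np.clip(idx, 0, edges.size - 2)

    def lookup(self, c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
        """Posterior probability of cancer for arrays of (C1, C2) values."""
        i = self.bin_index(np.ravel(c1), axis=0)
        j = self.bin_index(np.ravel(c2), axis=1)
        return self.posterior[i, j].reshape(np.shape(c1))

    def save(self, path: str | Path) -> None:
        payload = {
            "c1_edges": self.c1_edges.tolist(),
            "c2_edges": self.c2_edges.tolist(),
            "posterior": self.posterior.tolist(),
            "prior_cancer": self.prior_cancer,
            "smoothing_sigma_bins": self.smoothing_sigma_bins,
            "pseudocount": self.pseudocount,
            "training_counts": list(self.training_counts),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorLookupTable":
        payload = json.loads(Path(path).read_text())
        payload["training_counts"] = tuple(payload["training_counts"])
        return cls(**payload)


@dataclass
class ProbabilityMap:
    """Voxel-wise posterior probability of cancer on a grid."""

    prob: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != self.grid.shape:
            raise ValueError("probability map shape does not match grid")
        if np.any(self.prob < 0) or np.any(self.prob > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def _class_density(
    pairs: np.ndarray, edges: tuple[np.ndarray, np.ndarray], config: ClassifierConfig
) -> np.ndarray:
    hist, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=edges)
    # smooth in density space: mixing with a uniform pseudo-mass keeps empty
    # bins at the class prior regardless of the two training-pool sizes
    density = hist / max(hist.sum(), 1.0)
    density = density + config.pseudocount / hist.size
    if config.smoothing_sigma_bins > 0:
        density = ndimage.gaussian_filter(density, config.smoothing_sigma_bins)
    return density / density.sum()


def build_lookup(
    cancer_pairs: np.ndarray,
    control_pairs: np.ndarray,
    config: ClassifierConfig | None = None,
) -> PosteriorLookupTable:
    """Build the posterior lookup table from pooled training voxels.

    ``cancer_pairs`` and ``control_pairs`` are (n, 2) arrays of
    normalized (C1, C2) values pooled across all patients'
    pre-treatment ROIs.
    """
    config = config or ClassifierConfig()
    cancer_pairs = np.atleast_2d(np.asarray(cancer_pairs, dtype=float))
    control_pairs = np.atleast_2d(np.asarray(control_pairs, dtype=float))
    for name, arr in (("cancer", cancer_pairs), ("control", control_pairs)):
        if arr.size == 0:
            raise ValueError(f"{name} training set is empty")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{name} pairs must have shape (n, 2)")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} pairs contain non-finite values")

    pooled = np.vstack([cancer_pairs, control_pairs])
    edges = []
    for axis in range(2):
        hi = float(np.quantile(pooled[:, axis], config.edge_quantile))
        if hi <= 0:
            hi = max(float(pooled[:, axis].max()), 1e-6)
        edges.append(np.linspace(0.0, hi, config.n_bins + 1))

    f_cancer = _class_density(cancer_pairs, tuple(edges), config)
    f_control = _class_density(control_pairs, tuple(edges), config)
    pi = config.prior_cancer
    posterior = (f_cancer * pi) / (f_cancer * pi + f_control * (1.0 - pi))
    return PosteriorLookupTable(
        c1_edges=edges[0],
        c2_edges=edges[1],
        posterior=posterior,
        prior_cancer=pi,
        smoothing_sigma_bins=config.smoothing_sigma_bins,
        pseudocount=config.pseudocount,
        training_counts=(cancer_pairs.shape[0], control_pairs.shape[0]),
    )


def posterior_map(maps: ComponentMaps, lookup: PosteriorLookupTable) -> ProbabilityMap:
    """Apply the lookup table voxel-wise to normalized component maps.

    (C1, C2) values beyond the table range are clamped to the edge bins.
    """
    if maps.c1.shape != maps.c2.shape:
        raise ValueError("C1 and C2 grids differ")
    prob = lookup.lookup(maps.c1, maps.c2)
    return ProbabilityMap(prob=prob, grid=maps.grid)


def classify_map(prob: ProbabilityMap, threshold: float = 0.5) -> np.ndarray:
    """Binary cancer mask: probability strictly above the threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return prob.prob > threshold
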