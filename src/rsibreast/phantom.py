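"""Synthetic longitudinal DWI phantom cohorts with known ground truth.

Each phantom patient is a bilateral "breast" geometry on a coarse DWI
grid: two tissue blocks of fatty tissue, each holding an inner
fibroglandular region, plus a tumour ellipsoid in one breast. Tissue
classes carry fixed (C1, C2, C3) signal-contribution triples chosen so
that fat is C1-dominant, fibroglandular tissue C2-dominant and tumour
elevated in both C1 and C2 — the qualitative contrast the voxel
classifier exploits. Forward signals follow the three-exponential decay
model at the standard b-values {0, 500, 1500, 4000} s/mm^2, with
optional Rician noise (the magnitude-MRI noise model).

Longitudinal structure: four time points (pre, early, mid, post) with a
per-timepoint shrinkage fraction scaling the tumour semi-axes. Patients
labelled pCR shrink fully (empty tumour at post-treatment); non-pCR
patients retain most of their tumour. A simulated manual DCE diameter
(true diameter plus small measurement error) accompanies every time
point so the full statistics layer can run on phantom cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .rsi_fit import ComponentMaps, RsiFixedAdcs, design_matrix
from .volumes_io import DwiSeries, ImageGrid, RoiMask

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "PatientStudy",
    "CohortStudies",
    "simulate_signal",
    "generate_patient",
    "generate_cohort",
]

TIMEPOINTS = ("pre", "early", "mid", "post")

#: Default per-tissue (C1, C2, C3) signal contributions.
DEFAULT_TISSUES: dict[str, tuple[float, float, float]] = {
    "fat": (0.80, 0.10, 0.05),
    "fibroglandular": (0.10, 0.70, 0.15),
    "tumor": (0.55, 0.55, 0.10),
}

DEFAULT_GRID = ImageGrid(shape=(64, 64, 16), spacing=(2.5, 2.5, 5.0))
DEFAULT_BVALUES = (0.0, 500.0, 1500.0, 4000.0)


@dataclass
class PhantomConfig:
    """Everything needed to simulate one patient deterministically."""

    grid: ImageGrid = DEFAULT_GRID
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    fixed_adcs: RsiFixedAdcs = field(default_factory=RsiFixedAdcs.example)
    tissue_components: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES)
    )
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_semiaxes_mm: tuple[float, float, float] = (10.0, 6.0, 6.0)
    shrinkage_per_timepoint: dict[str, float] = field(
        default_factory=lambda: {"pre": 0.0, "early": 0.0, "mid": 0.0, "post": 0.0}
    )
    is_pcr: bool = False
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.tumor_semiaxes_mm):
            raise ValueError("tumor semi-axes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        for tp, s in self.shrinkage_per_timepoint.items():
            if tp not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
            if not (0.0 <= s <= 1.0):
                raise ValueError("shrinkage fractions must lie in [0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth underlying one simulated patient."""

    component_maps: dict[str, ComponentMaps]
    tumor_masks: dict[str, np.ndarray]
    control_mask: np.ndarray
    tumor_diameters_cm: dict[str, float]
    noise_sigma: float
    seed: int
    tumor_semiaxes_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class PatientStudy:
    """Simulated inputs for one patient: what the pipeline consumes."""

    patient_id: str
    dwi: dict[str, DwiSeries]
    cancer_roi: RoiMask
    control_roi: RoiMask
    dce_diameters_cm: dict[str, float]
    is_pcr: bool
    truth: PhantomTruth


@dataclass
class CohortStudies:
    studies: list[PatientStudy]

    @property
    def pcr_labels(self) -> dict[str, bool]:
        return {s.patient_id: s.is_pcr for s in self.studies}


def _voxel_center_axes(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(
        grid.origin[a] + np.arange(grid.shape[a]) * grid.spacing[a] for a in range(3)
    )


def _box_mask(grid: ImageGrid, lo_mm, hi_mm) -> np.ndarray:
    x, y, z = _voxel_center_axes(grid)
    return (
        ((x >= lo_mm[0]) & (x <= hi_mm[0]))[:, None, None]
        & ((y >= lo_mm[1]) & (y <= hi_mm[1]))[None, :, None]
        & ((z >= lo_mm[2]) & (z <= hi_mm[2]))[None, None, :]
    )


def _ellipsoid_mask(grid: ImageGrid, center_mm, semiaxes_mm) -> np.ndarray:
    if min(semiaxes_mm) < 1e-9:
        return np.zeros(grid.shape, dtype=bool)
    x, y, z = _voxel_center_axes(grid)
    qx = ((x - center_mm[0]) / semiaxes_mm[0]) ** 2
    qy = ((y - center_mm[1]) / semiaxes_mm[1]) ** 2
    qz = ((z - center_mm[2]) / semiaxes_mm[2]) ** 2
    q = qx[:, None, None] + qy[None, :, None] + qz[None, None, :]
    return q <= 1.0


def _snap_to_voxel_center(grid: ImageGrid, point_mm) -> tuple[float, float, float]:
    idx = np.round(
        (np.asarray(point_mm) - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    )
    return tuple(grid.voxel_centers(idx[None, :])[0])


def _breast_extents(grid: ImageGrid):
    """Physical extents (mm) of the two breast blocks and the control box."""
    fov = np.asarray(grid.shape) * np.asarray(grid.spacing)
    mx, my, mz = 0.06 * fov[0], 0.12 * fov[1], 0.12 * fov[2]
    left = ((mx, my, mz), (0.5 * fov[0] - mx, fov[1] - my, fov[2] - mz))
    right = ((0.5 * fov[0] + mx, my, mz), (fov[0] - mx, fov[1] - my, fov[2] - mz))
    return left, right


def build_truth_maps(
    config: PhantomConfig, tumor_scale: float
) -> tuple[ComponentMaps, np.ndarray, np.ndarray]:
    """Assemble tissue component maps for one time point.

    Returns (maps, tumor_mask, control_mask). ``tumor_scale`` in [0, 1]
    multiplies the tumour semi-axes (0 -> tumour fully resolved).
    """
    grid = config.grid
    left, right = _breast_extents(grid)
    breasts = _box_mask(grid, *left) | _box_mask(grid, *right)

    def inner(extent):
        lo, hi = np.asarray(extent[0]), np.asarray(extent[1])
        c = (lo + hi) / 2
        semi = (hi - lo) / 2 * 0.55
        return _ellipsoid_mask(grid, c, semi)

    fibro = inner(left) | inner(right)
    center = config.tumor_center_mm
    if center is None:
        lo, hi = np.asarray(left[0]), np.asarray(left[1])
        center = tuple((lo + hi) / 2)
    center = _snap_to_voxel_center(grid, center)
    tumor = _ellipsoid_mask(
        grid, center, tuple(a * tumor_scale for a in config.tumor_semiaxes_mm)
    )

    shape = grid.shape
    comp = np.zeros((*shape, 3))
    comp[breasts] = config.tissue_components["fat"]
    comp[fibro & breasts] = config.tissue_components["fibroglandular"]
    comp[tumor] = config.tissue_components["tumor"]

    # control region: a box inside the contralateral breast spanning both
    # fatty and fibroglandular tissue
    lo, hi = np.asarray(right[0]), np.asarray(right[1])
    c = (lo + hi) / 2
    half = (hi - lo) / 2 * np.array([0.8, 0.8, 0.8])
    control = _box_mask(grid, c - half, c + half) & breasts & ~tumor

    maps = ComponentMaps(
        c1=comp[..., 0], c2=comp[..., 1], c3=comp[..., 2],
        fixed_adcs=config.fixed_adcs, grid=grid,
    )
    return maps, tumor, control


def simulate_signal(
    truth: ComponentMaps,
    bvalues,
    noise_sigma: float,
    seed: int,
    noise_model: str = "rician",
) -> DwiSeries:
    """Forward-simulate the DWI signal from component maps.

    Noiseless signal is the exact three-exponential forward model.
    Rician noise: observed = sqrt((S + g1)^2 + g2^2) with g1, g2
    independent N(0, sigma^2) — the magnitude of a complex Gaussian
    perturbation. ``noise_model='gaussian'`` adds g1 only (clipped at 0).
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    bvalues = np.asarray(bvalues, dtype=float)
    A = design_matrix(bvalues, truth.fixed_adcs)  # (n_b, 3)
    signal = truth.stacked @ A.T  # (x, y, z, n_b)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0.0, noise_sigma, signal.shape)
        if noise_model == "rician":
            g2 = rng.normal(0.0, noise_sigma, signal.shape)
            signal = np.sqrt((signal + g1) ** 2 + g2**2)
        elif noise_model == "gaussian":
            signal = np.maximum(signal + g1, 0.0)
        else:
            raise ValueError("noise_model must be 'rician' or 'gaussian'")
    return DwiSeries(signal=signal, bvalues=bvalues, grid=truth.grid)


def _true_diameter_cm(mask: np.ndarray, grid: ImageGrid) -> float:
    from .lesion_geometry import longest_diameter

    return longest_diameter(mask, grid)


def generate_patient(config: PhantomConfig, patient_id: str = "p00") -> PatientStudy:
    """Simulate one patient's four-timepoint study from a config."""
    rng = np.random.default_rng(config.seed)
    component_maps: dict[str, ComponentMaps] = {}
    tumor_masks: dict[str, np.ndarray] = {}
    diameters: dict[str, float] = {}
    dwi: dict[str, DwiSeries] = {}
    dce: dict[str, float] = {}
    control_mask = None
    for i, tp in enumerate(TIMEPOINTS):
        shrink = config.shrinkage_per_timepoint.get(tp, 0.0)
        if config.is_pcr and tp == "post":
            shrink = 1.0
        scale = 1.0 - shrink
        maps, tumor, control = build_truth_maps(config, scale)
        if tp == "pre" and not tumor.any():
            raise ValueError("tumor ellipsoid lies outside the grid")
        component_maps[tp] = maps
        tumor_masks[tp] = tumor
        control_mask = control
        diameters[tp] = _true_diameter_cm(tumor, config.grid)
        dwi[tp] = simulate_signal(
            maps, config.bvalues, config.noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        # manual DCE measurement emulation: truth plus small reader error
        err = rng.normal(0.0, 0.1) if diameters[tp] > 0 else 0.0
        dce[tp] = max(0.0, diameters[tp] + err)

    truth = PhantomTruth(
        component_maps=component_maps,
        tumor_masks=tumor_masks,
        control_mask=control_mask,
        tumor_diameters_cm=diameters,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
        tumor_semiaxes_mm=config.tumor_semiaxes_mm,
    )
    return PatientStudy(
        patient_id=patient_id,
        dwi=dwi,
        cancer_roi=RoiMask(tumor_masks["pre"], config.grid, "cancer"),
        control_roi=RoiMask(control_mask, config.grid, "control"),
        dce_diameters_cm=dce,
        is_pcr=config.is_pcr,
        truth=truth,
    )


def generate_cohort(
    n_patients: int = 27,
    pcr_fraction: float = 10 / 27,
    template: PhantomConfig | None = None,
    seed: int = 0,
    noise_sigma: float | None = None,
) -> CohortStudies:
    """Simulate a longitudinal cohort with a known pCR prevalence.

    Exactly ``round(n_patients * pcr_fraction)`` patients are labelled
    pCR (full shrinkage by post-treatment); the rest shrink by at most
    20%. Tumour semi-axes vary per patient. Per-patient seeds derive
    deterministically from the master seed, so permuting generation
    order cannot change any individual patient.
    """
    if not (0.0 <= pcr_fraction <= 1.0):
        raise ValueError("pcr_fraction must lie in [0, 1]")
    if n_patients < 2:
        raise ValueError("need at least two patients")
    template = template or PhantomConfig()
    if noise_sigma is None:
        noise_sigma = template.noise_sigma
    master = np.random.default_rng(seed)
    patient_seeds = master.integers(0, 2**31 - 1, size=n_patients)
    n_pcr = int(round(n_patients * pcr_fraction))
    labels = np.zeros(n_patients, dtype=bool)
    labels[master.permutation(n_patients)[:n_pcr]] = True

    studies = []
    for i in range(n_patients):
        prng = np.random.default_rng(patient_seeds[i])
        a = prng.uniform(8.0, 16.0)
        bc = prng.uniform(5.0, min(10.0, a), size=2)
        if labels[i]:
            schedule = {
                "pre": 0.0,
                "early": float(prng.uniform(0.3, 0.5)),
                "mid": float(prng.uniform(0.6, 0.9)),
                "post": 1.0,
            }
        else:
            schedule = {
                "pre": 0.0,
                "early": float(prng.uniform(0.0, 0.1)),
                "mid": float(prng.uniform(0.05, 0.15)),
                "post": float(prng.uniform(0.05, 0.2)),
            }
        config = replace(
            template,
            tumor_semiaxes_mm=(float(a), float(bc[0]), float(bc[1])),
            shrinkage_per_timepoint=schedule,
            is_pcr=bool(labels[i]),
            noise_sigma=float(noise_sigma),
            seed=int(patient_seeds[i]),
        )
        studies.append(generate_patient(config, patient_id=f"p{i:02d}"))
    return CohortStudies(studies=studies)
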