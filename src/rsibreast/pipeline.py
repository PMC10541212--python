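"""Workflow orchestration: library functions plus the ``rsibreast`` CLI.

The multi-stage study workflow is::

    simulate -> fit -> train -> measure -> evaluate

Each stage exists both as a plain function operating on in-memory
objects (used by the test suite and by scripted analyses) and as a
click subcommand operating on an on-disk study layout (NIfTI volumes,
.bval sidecars, cohort CSV, JSON reports). Every stage is deterministic
given its config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import yaml

from . import adc_comparator, cancer_classifier, lesion_geometry, rsi_fit
from .cancer_classifier import ClassifierConfig, PosteriorLookupTable
from .phantom import PatientStudy, CohortStudies, PhantomConfig, generate_cohort
from .response_stats import (
    CohortDataset,
    TimepointRecord,
    evaluate_cohort,
    results_to_jsonable,
)
from .rsi_fit import RsiFixedAdcs
from .volumes_io import (
    DwiSeries,
    RoiMask,
    read_dwi,
    read_mask,
    write_mask,
    write_volume,
)

log = logging.getLogger("rsibreast")

TIMEPOINTS = ("pre", "early", "mid", "post")


@dataclass
class RunConfig:
    """All tunables of the analysis pipeline with study defaults."""

    fixed_adcs: RsiFixedAdcs = field(default_factory=RsiFixedAdcs.example)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    threshold: float = 0.5
    expand_mm: float = 10.0
    connectivity: int = 26
    alpha: float = 0.025
    min_specificity: float = 0.90
    nonnegative_fit: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "fixed_adcs" in raw:
            kwargs["fixed_adcs"] = RsiFixedAdcs(*raw.pop("fixed_adcs"))
        if "classifier" in raw:
            kwargs["classifier"] = ClassifierConfig(**raw.pop("classifier"))
        kwargs.update(raw)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# In-memory pipeline stages


def fit_and_normalize(
    dwi: DwiSeries, control: RoiMask, config: RunConfig
) -> rsi_fit.ComponentMaps:
    """Fit the three-component model and normalize to the control ROI."""
    maps = rsi_fit.fit_components(dwi, config.fixed_adcs, config.nonnegative_fit)
    gm = rsi_fit.geometric_mean_map(maps)
    factor = rsi_fit.normalization_factor(gm, control)
    return rsi_fit.normalize_components(maps, factor)


def train_classifier(
    studies: list[PatientStudy], config: RunConfig
) -> PosteriorLookupTable:
    """Pool pre-treatment (C1, C2) pairs across all patients and train."""
    if not studies:
        raise ValueError("no training studies given")
    cancer_pairs, control_pairs = [], []
    for study in studies:
        maps = fit_and_normalize(study.dwi["pre"], study.control_roi, config)
        pairs = np.stack([maps.c1, maps.c2], axis=-1)
        cancer_pairs.append(pairs[study.cancer_roi.mask])
        control_pairs.append(pairs[study.control_roi.mask])
    return cancer_classifier.build_lookup(
        np.vstack(cancer_pairs), np.vstack(control_pairs), config.classifier
    )


def measure_study(
    study: PatientStudy, lookup: PosteriorLookupTable, config: RunConfig
) -> list[TimepointRecord]:
    """Automatic RSI diameter and mean ADC at every available time point."""
    records = []
    for tp in TIMEPOINTS:
        if tp not in study.dwi:
            continue
        dwi = study.dwi[tp]
        maps = fit_and_normalize(dwi, study.control_roi, config)
        prob = cancer_classifier.posterior_map(maps, lookup)
        measurement = lesion_geometry.measure_timepoint(
            prob,
            study.cancer_roi,
            threshold=config.threshold,
            expand_mm=config.expand_mm,
            connectivity=config.connectivity,
        )
        adc_map = adc_comparator.compute_adc_map(dwi)
        records.append(
            TimepointRecord(
                patient_id=study.patient_id,
                timepoint=tp,
                rsi_diameter_cm=measurement.diameter_cm,
                dce_diameter_cm=study.dce_diameters_cm.get(tp),
                mean_adc=adc_comparator.mean_adc(adc_map, study.cancer_roi),
            )
        )
    return records


def run_cohort_pipeline(
    cohort: CohortStudies, config: RunConfig | None = None
) -> CohortDataset:
    """Full pipeline on an in-memory cohort: train, measure, assemble."""
    config = config or RunConfig()
    lookup = train_classifier(cohort.studies, config)
    records = []
    for study in cohort.studies:
        records.extend(measure_study(study, lookup, config))
    return CohortDataset(records=records, pcr_labels=cohort.pcr_labels)


# ---------------------------------------------------------------------------
# On-disk study layout helpers


def write_study(study: PatientStudy, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for tp, dwi in study.dwi.items():
        write_volume(dwi.signal, dwi.grid, d / f"dwi_{tp}.nii.gz")
        (d / f"dwi_{tp}.bval").write_text(
            " ".join(f"{b:g}" for b in dwi.bvalues) + "\n"
        )
    write_mask(study.cancer_roi, d / "cancer_roi.nii.gz")
    write_mask(study.control_roi, d / "control_roi.nii.gz")
    meta = {
        "patient_id": study.patient_id,
        "is_pcr": study.is_pcr,
        "timepoints": sorted(study.dwi, key=TIMEPOINTS.index),
        "dce_diameters_cm": study.dce_diameters_cm,
        "true_diameters_cm": study.truth.tumor_diameters_cm,
        "noise_sigma": study.truth.noise_sigma,
        "seed": study.truth.seed,
    }
    (d / "patient.json").write_text(json.dumps(meta, indent=2))


def read_study(directory: str | Path) -> PatientStudy:
    d = Path(directory)
    meta = json.loads((d / "patient.json").read_text())
    dwi = {
        tp: read_dwi(d / f"dwi_{tp}.nii.gz", d / f"dwi_{tp}.bval")
        for tp in meta["timepoints"]
    }
    from .phantom import PhantomTruth  # local import to avoid cycle at module load

    truth = PhantomTruth(
        component_maps={},
        tumor_masks={},
        control_mask=None,
        tumor_diameters_cm=meta.get("true_diameters_cm", {}),
        noise_sigma=meta.get("noise_sigma", 0.0),
        seed=meta.get("seed", 0),
    )
    return PatientStudy(
        patient_id=meta["patient_id"],
        dwi=dwi,
        cancer_roi=read_mask(d / "cancer_roi.nii.gz", "cancer"),
        control_roi=read_mask(d / "control_roi.nii.gz", "control"),
        dce_diameters_cm=meta["dce_diameters_cm"],
        is_pcr=meta["is_pcr"],
        truth=truth,
    )


def _study_dirs(root: Path) -> list[Path]:
    dirs = sorted(p for p in root.iterdir() if (p / "patient.json").exists())
    if not dirs:
        raise click.ClickException(f"no studies found under {root}")
    return dirs


def _upsert_rows(csv_path: Path, rows: list[dict]) -> None:
    import pandas as pd

    new = pd.DataFrame(rows)
    if csv_path.exists():
        old = pd.read_csv(csv_path)
        keys = set(zip(new["patient_id"].astype(str), new["timepoint"]))
        keep = ~old.apply(
            lambda r: (str(r["patient_id"]), r["timepoint"]) in keys, axis=1
        )
        new = pd.concat([old[keep], new], ignore_index=True)
    new.sort_values(["patient_id", "timepoint"]).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("--verbose", is_flag=True, help="Log progress to stderr.")
def main(verbose: bool) -> None:
    """Automated DWI-based breast-tumor response assessment."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


def _load_config(config_path: str | None) -> RunConfig:
    return RunConfig.from_yaml(config_path) if config_path else RunConfig()


@main.command()
@click.option("--out", "out_dir", required=True, type=click.Path())
@click.option("--patients", default=27, show_default=True)
@click.option("--pcr-fraction", default=10 / 27, show_default=True)
@click.option("--noise-sigma", default=0.0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--grid-shape", nargs=3, type=int, default=(64, 64, 16))
def simulate(out_dir, patients, pcr_fraction, noise_sigma, seed, grid_shape):
    """Write a synthetic longitudinal cohort to OUT_DIR."""
    from .volumes_io import ImageGrid

    template = PhantomConfig(grid=ImageGrid(tuple(grid_shape), (2.5, 2.5, 5.0)))
    cohort = generate_cohort(
        n_patients=patients,
        pcr_fraction=pcr_fraction,
        template=template,
        seed=seed,
        noise_sigma=noise_sigma,
    )
    root = Path(out_dir)
    for study in cohort.studies:
        write_study(study, root / study.patient_id)
    labels = {s.patient_id: s.is_pcr for s in cohort.studies}
    (root / "labels.json").write_text(json.dumps(labels, indent=2))
    log.info("wrote %d studies to %s", patients, root)


@main.command()
@click.option("--study", "study_dir", required=True, type=click.Path(exists=True))
@click.option("--timepoint", default="pre", type=click.Choice(TIMEPOINTS))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_dir", type=click.Path())
def fit(study_dir, timepoint, config_path, out_dir):
    """Fit component maps for one study time point and write them."""
    config = _load_config(config_path)
    study = read_study(study_dir)
    if timepoint not in study.dwi:
        raise click.ClickException(f"no {timepoint} acquisition in {study_dir}")
    if study.control_roi.n_voxels == 0:
        raise click.ClickException(f"empty control mask in {study_dir}")
    maps = fit_and_normalize(study.dwi[timepoint], study.control_roi, config)
    out = Path(out_dir or Path(study_dir) / "derived")
    out.mkdir(parents=True, exist_ok=True)
    for name in ("c1", "c2", "c3"):
        write_volume(getattr(maps, name), maps.grid, out / f"{timepoint}_{name}.nii.gz")
    report = {
        "timepoint": timepoint,
        "normalization_factor": maps.normalization_factor,
        "fixed_adcs": list(config.fixed_adcs.as_array),
        "mean_c1": float(maps.c1.mean()),
        "mean_c2": float(maps.c2.mean()),
    }
    (out / f"{timepoint}_fit_report.json").write_text(json.dumps(report, indent=2))
    click.echo(json.dumps(report))


@main.command()
@click.option("--studies", "studies_root", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def train(studies_root, config_path, out_path):
    """Train the pooled posterior lookup table from pre-treatment studies."""
    config = _load_config(config_path)
    studies = [read_study(d) for d in _study_dirs(Path(studies_root))]
    lookup = train_classifier(studies, config)
    lookup.save(out_path)
    log.info(
        "trained on %d cancer / %d control voxels", *lookup.training_counts
    )


@main.command()
@click.option("--study", "study_dir", required=True, type=click.Path(exists=True))
@click.option("--lookup", "lookup_path", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--cohort-csv", required=True, type=click.Path())
def measure(study_dir, lookup_path, config_path, cohort_csv):
    """Measure RSI diameter and mean ADC for every time point of a study."""
    config = _load_config(config_path)
    study = read_study(study_dir)
    lookup = PosteriorLookupTable.load(lookup_path)
    records = measure_study(study, lookup, config)
    rows = [
        {
            "patient_id": r.patient_id,
            "timepoint": r.timepoint,
            "rsi_diameter_cm": r.rsi_diameter_cm,
            "dce_diameter_cm": r.dce_diameter_cm,
            "mean_adc": r.mean_adc,
            "pcr": study.is_pcr,
        }
        for r in records
    ]
    _upsert_rows(Path(cohort_csv), rows)
    click.echo(f"measured {len(rows)} timepoints for {study.patient_id}")


@main.command()
@click.option("--cohort-csv", required=True, type=click.Path(exists=True))
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def evaluate(cohort_csv, config_path, out_path):
    """Evaluate endpoint statistics from a cohort CSV."""
    config = _load_config(config_path)
    dataset = CohortDataset.from_csv(cohort_csv)
    blocks = evaluate_cohort(
        dataset, alpha=config.alpha, min_specificity=config.min_specificity
    )
    payload = results_to_jsonable(blocks)
    Path(out_path).write_text(json.dumps(payload, indent=2))
    post = payload["absolute_post"]["modalities"]
    for modality, entry in post.items():
        s = entry["summary"]
        click.echo(
            f"{modality}: AUC={s['auc']:.2f} "
            f"sens={s['best']['sensitivity']:.2f} spec={s['best']['specificity']:.2f}"
        )


if __name__ == "__main__":
    main()
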