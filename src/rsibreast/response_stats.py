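"""Endpoint statistics for longitudinal response assessment.

The clinical endpoint is binary pathology at surgery: non-pCR (residual
invasive disease; the positive class) versus pCR. Per-patient imaging
measurements — automatic RSI-classifier diameter, manual DCE diameter,
mean ADC — enter either as absolute post-treatment values or as relative
change from pre-treatment. The layer provides:

* Mann-Whitney ROC AUC with DeLong variance and Wald CI,
* operating points: maximum accuracy, and maximum sensitivity subject
  to specificity >= 90%,
* exact (Clopper-Pearson) binomial CIs for sensitivity/specificity/
  accuracy,
* paired comparisons: exact McNemar on discordant classifications and
  DeLong's test on correlated AUCs, at alpha 0.025 (two primary
  outcomes),
* a cohort evaluator assembling all of the above per time point and
  modality.

Directionality is explicit per modality: a larger residual size is
evidence of non-pCR, while for change in mean ADC the a-priori
assumption is that an ADC *increase* marks response, so a smaller
change is evidence of non-pCR.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIMEPOINTS",
    "TimepointRecord",
    "CohortDataset",
    "ConfusionCounts",
    "OperatingPoint",
    "RocSummary",
    "PairedTestResult",
    "relative_change",
    "roc_auc",
    "auc_ci",
    "best_accuracy_operating_point",
    "spec_constrained_operating_point",
    "confusion_metrics",
    "clopper_pearson_ci",
    "mcnemar_exact",
    "delong_test",
    "evaluate_cohort",
]

TIMEPOINTS = ("pre", "early", "mid", "post")
MODALITIES = ("rsi", "dce", "adc")

#: Predicted-positive direction per modality. Absolute sizes and
#: absolute mean ADC: higher value -> non-pCR. Relative changes: less
#: shrinkage (higher Delta-size) -> non-pCR; an ADC increase marks
#: response, so a *lower* Delta-ADC -> non-pCR.
ABSOLUTE_DIRECTIONS = {"rsi": "higher", "dce": "higher", "adc": "higher"}
DELTA_DIRECTIONS = {"rsi": "higher", "dce": "higher", "adc": "lower"}


@dataclass(frozen=True)
class TimepointRecord:
    patient_id: str
    timepoint: str
    rsi_diameter_cm: float | None = None
    dce_diameter_cm: float | None = None
    mean_adc: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        for name in ("rsi_diameter_cm", "dce_diameter_cm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    def value(self, modality: str) -> float | None:
        return {
            "rsi": self.rsi_diameter_cm,
            "dce": self.dce_diameter_cm,
            "adc": self.mean_adc,
        }[modality]


@dataclass
class CohortDataset:
    """Per-patient per-timepoint measurements plus pathology labels.

    ``pcr_labels`` maps patient id -> True for pCR. The positive class
    throughout the statistics is non-pCR.
    """

    records: list[TimepointRecord]
    pcr_labels: dict[str, bool]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.patient_id, rec.timepoint)
            if key in seen:
                raise ValueError(f"duplicate record for {key}")
            seen.add(key)
            if rec.patient_id not in self.pcr_labels:
                raise ValueError(f"no pCR label for patient {rec.patient_id}")

    @property
    def patients(self) -> list[str]:
        return sorted(self.pcr_labels)

    def record(self, patient_id: str, timepoint: str) -> TimepointRecord | None:
        for rec in self.records:
            if rec.patient_id == patient_id and rec.timepoint == timepoint:
                return rec
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "timepoint": r.timepoint,
                "rsi_diameter_cm": r.rsi_diameter_cm,
                "dce_diameter_cm": r.dce_diameter_cm,
                "mean_adc": r.mean_adc,
                "pcr": self.pcr_labels[r.patient_id],
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortDataset":
        records = []
        labels: dict[str, bool] = {}
        for _, row in frame.iterrows():
            pid = str(row["patient_id"])
            labels[pid] = bool(row["pcr"])
            records.append(
                TimepointRecord(
                    patient_id=pid,
                    timepoint=str(row["timepoint"]),
                    rsi_diameter_cm=_optional(row.get("rsi_diameter_cm")),
                    dce_diameter_cm=_optional(row.get("dce_diameter_cm")),
                    mean_adc=_optional(row.get("mean_adc")),
                )
            )
        return cls(records=records, pcr_labels=labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortDataset":
        return cls.from_frame(pd.read_csv(path))


def _optional(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or pd.isna(v):
        return None
    return float(v)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]


@dataclass(frozen=True)
class RocSummary:
    auc: float
    auc_ci: tuple[float, float]
    n_positive: int
    n_negative: int
    best: OperatingPoint
    spec_constrained: OperatingPoint


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.025

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def relative_change(value_t: float, value_pre: float) -> float:
    """(value_t - value_pre) / value_pre; -1.0 marks a lesion that vanished."""
    if value_pre == 0:
        raise ValueError("relative change undefined for zero pre-treatment value")
    return (value_t - value_pre) / value_pre


def _validated(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1D sequences")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "higher":
        return scores
    if direction == "lower":
        return -scores
    raise ValueError("direction must be 'higher' or 'lower'")


def roc_auc(scores, labels, direction: str = "higher") -> float:
    """ROC AUC as the Mann-Whitney probability, ties counted half.

    ``direction='lower'`` means a lower score is evidence for the
    positive class (used for change in mean ADC).
    """
    scores, labels = _validated(scores, labels)
    s = _oriented(scores, direction)
    ranks = stats.rankdata(s)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: V10 (per positive), V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, var(AUC)) via the DeLong estimator for a single curve."""
    v10, v01 = _placements(scores[labels], scores[~labels])
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_ci(
    scores, labels, direction: str = "higher", alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong-variance Wald interval, clipped to [0, 1]."""
    scores, labels = _validated(scores, labels)
    s = _oriented(scores, direction)
    auc, var = _delong_variance(s, labels)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _counts_at(scores: np.ndarray, labels: np.ndarray, thr: float) -> ConfusionCounts:
    pred = scores > thr
    return ConfusionCounts(
        tp=int((pred & labels).sum()),
        fn=int((~pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()),
    )


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) from a confusion table."""
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("both class margins must be non-empty")
    return (
        c.tp / (c.tp + c.fn),
        c.tn / (c.tn + c.fp),
        (c.tp + c.tn) / c.total,
    )


def clopper_pearson_ci(
    successes: int, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval."""
    if n < 1 or not (0 <= successes <= n):
        raise ValueError("require 0 <= successes <= n and n >= 1")
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return lo, hi


def _operating_point(
    counts: ConfusionCounts, threshold: float, direction: str, alpha: float = 0.05
) -> OperatingPoint:
    sens, spec, acc = confusion_metrics(counts)
    # report the threshold on the original score scale
    thr = threshold if direction == "higher" else -threshold
    return OperatingPoint(
        threshold=float(thr),
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=clopper_pearson_ci(counts.tp, counts.tp + counts.fn, alpha),
        specificity_ci=clopper_pearson_ci(counts.tn, counts.tn + counts.fp, alpha),
        accuracy_ci=clopper_pearson_ci(counts.tp + counts.tn, counts.total, alpha),
    )


def best_accuracy_operating_point(
    scores, labels, direction: str = "higher"
) -> OperatingPoint:
    """Threshold maximizing accuracy over midpoint candidates.

    Accuracy ties are broken towards higher specificity, then towards
    fewer predicted positives (the more conservative rule).
    """
    scores, labels = _validated(scores, labels)
    s = _oriented(scores, direction)
    best: tuple | None = None
    for thr in _candidate_thresholds(s):
        c = _counts_at(s, labels, thr)
        sens, spec, acc = confusion_metrics(c)
        key = (acc, spec, -(c.tp + c.fp))
        if best is None or key > best[0]:
            best = (key, c, thr)
    return _operating_point(best[1], best[2], direction)


def spec_constrained_operating_point(
    scores, labels, direction: str = "higher", min_specificity: float = 0.90
) -> OperatingPoint:
    """Maximum-sensitivity threshold among those with specificity >= bound.

    Sensitivity ties are broken towards higher specificity. The
    classify-nothing threshold always satisfies the constraint, so the
    degenerate fallback is sensitivity 0.
    """
    scores, labels = _validated(scores, labels)
    s = _oriented(scores, direction)
    best: tuple | None = None
    for thr in _candidate_thresholds(s):
        c = _counts_at(s, labels, thr)
        sens, spec, acc = confusion_metrics(c)
        if spec < min_specificity:
            continue
        key = (sens, spec)
        if best is None or key > best[0]:
            best = (key, c, thr)
    return _operating_point(best[1], best[2], direction)


def mcnemar_exact(
    discordant_b: int, discordant_c: int, alpha: float = 0.025
) -> PairedTestResult:
    """Exact two-sided McNemar test on discordant pair counts.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    no discordant pairs gives p = 1.
    """
    if discordant_b < 0 or discordant_c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = discordant_b + discordant_c
    k = min(discordant_b, discordant_c)
    p = 1.0 if n == 0 else min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
    return PairedTestResult(
        test_name="mcnemar_exact", statistic=float(k), p_value=p, alpha=alpha
    )


def delong_test(
    scores_a,
    scores_b,
    labels,
    direction_a: str = "higher",
    direction_b: str = "higher",
    alpha: float = 0.025,
) -> PairedTestResult:
    """DeLong's test for two correlated ROC curves on the same subjects.

    The covariance of the two AUCs is estimated from the paired
    structural components (placement values); the statistic is the
    normal z for the AUC difference.
    """
    labels = np.asarray(labels, dtype=bool)
    sa, labels = _validated(scores_a, labels)
    sb, _ = _validated(scores_b, labels)
    sa = _oriented(sa, direction_a)
    sb = _oriented(sb, direction_b)
    v10a, v01a = _placements(sa[labels], sa[~labels])
    v10b, v01b = _placements(sb[labels], sb[~labels])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = auc_a - auc_b
    if var_diff <= 0:
        if abs(delta) > 1e-12:
            raise ValueError("zero DeLong variance with unequal AUCs")
        z, p = 0.0, 1.0
    else:
        z = delta / math.sqrt(var_diff)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return PairedTestResult(
        test_name="delong", statistic=float(z), p_value=min(p, 1.0), alpha=alpha
    )


# ---------------------------------------------------------------------------
# Cohort-level evaluation


def _modality_scores(
    dataset: CohortDataset, modality: str, timepoint: str, delta: bool
) -> tuple[list[str], np.ndarray]:
    """Patients with a usable score for one modality/time point block."""
    pids, values = [], []
    for pid in dataset.patients:
        rec = dataset.record(pid, timepoint)
        if rec is None or rec.value(modality) is None:
            continue
        if delta:
            pre = dataset.record(pid, "pre")
            if pre is None or pre.value(modality) in (None, 0):
                continue
            values.append(relative_change(rec.value(modality), pre.value(modality)))
        else:
            values.append(rec.value(modality))
        pids.append(pid)
    return pids, np.asarray(values, dtype=float)


def _block(
    dataset: CohortDataset,
    timepoint: str,
    delta: bool,
    alpha: float,
    min_specificity: float,
) -> dict:
    directions = DELTA_DIRECTIONS if delta else ABSOLUTE_DIRECTIONS
    per_modality: dict[str, dict] = {}
    scores_by_modality: dict[str, tuple[list[str], np.ndarray]] = {}
    for modality in MODALITIES:
        pids, scores = _modality_scores(dataset, modality, timepoint, delta)
        if len(pids) == 0:
            continue
        labels = np.array([not dataset.pcr_labels[p] for p in pids])
        if labels.all() or not labels.any():
            continue
        direction = directions[modality]
        auc, ci = auc_ci(scores, labels, direction)
        summary = RocSummary(
            auc=auc,
            auc_ci=ci,
            n_positive=int(labels.sum()),
            n_negative=int((~labels).sum()),
            best=best_accuracy_operating_point(scores, labels, direction),
            spec_constrained=spec_constrained_operating_point(
                scores, labels, direction, min_specificity
            ),
        )
        scores_by_modality[modality] = (pids, scores)
        per_modality[modality] = {"direction": direction, "summary": summary}

    comparisons = []
    for ma, mb in itertools.combinations(sorted(scores_by_modality), 2):
        pids_a, sa = scores_by_modality[ma]
        pids_b, sb = scores_by_modality[mb]
        shared = [p for p in pids_a if p in set(pids_b)]
        if len(shared) < 3:
            continue
        ia = [pids_a.index(p) for p in shared]
        ib = [pids_b.index(p) for p in shared]
        labels = np.array([not dataset.pcr_labels[p] for p in shared])
        if labels.all() or not labels.any():
            continue
        da, db = directions[ma], directions[mb]
        sa_s, sb_s = sa[ia], sb[ib]
        pred_a = _oriented(sa_s, da) > _oriented(
            np.full_like(sa_s, per_modality[ma]["summary"].best.threshold), da
        )
        pred_b = _oriented(sb_s, db) > _oriented(
            np.full_like(sb_s, per_modality[mb]["summary"].best.threshold), db
        )
        correct_a = pred_a == labels
        correct_b = pred_b == labels
        mc_sens = mcnemar_exact(
            int((correct_a & ~correct_b & labels).sum()),
            int((~correct_a & correct_b & labels).sum()),
            alpha,
        )
        mc_spec = mcnemar_exact(
            int((correct_a & ~correct_b & ~labels).sum()),
            int((~correct_a & correct_b & ~labels).sum()),
            alpha,
        )
        try:
            delong = delong_test(sa_s, sb_s, labels, da, db, alpha)
        except ValueError:
            delong = None  # degenerate: zero DeLong variance with unequal AUCs
        comparisons.append(
            {
                "modalities": (ma, mb),
                "mcnemar_sensitivity": mc_sens,
                "mcnemar_specificity": mc_spec,
                "delong": delong,
            }
        )
    return {"timepoint": timepoint, "delta": delta,
            "modalities": per_modality, "comparisons": comparisons}


def evaluate_cohort(
    dataset: CohortDataset,
    alpha: float = 0.025,
    min_specificity: float = 0.90,
) -> dict:
    """Full endpoint evaluation of a cohort.

    Produces the absolute post-treatment block plus relative-change
    blocks at the early, mid and post time points: per modality the AUC
    with CI, the maximum-accuracy operating point and the
    specificity-constrained operating point (each with exact binomial
    CIs), and pairwise McNemar / DeLong comparisons at ``alpha``.
    """
    if True not in dataset.pcr_labels.values() or False not in dataset.pcr_labels.values():
        raise ValueError("cohort must contain both pCR and non-pCR patients")
    blocks = {"absolute_post": _block(dataset, "post", False, alpha, min_specificity)}
    for tp in ("early", "mid", "post"):
        blocks[f"delta_{tp}"] = _block(dataset, tp, True, alpha, min_specificity)
    return blocks


def results_to_jsonable(blocks: Mapping) -> dict:
    """Recursively convert an evaluate_cohort result to JSON-safe types."""

    def conv(obj):
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (RocSummary, OperatingPoint, PairedTestResult, ConfusionCounts)):
            return conv(vars(obj))
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return obj

    return conv(dict(blocks))
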