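import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsibreast.response_stats import (
    CohortDataset,
    ConfusionCounts,
    TimepointRecord,
    auc_ci,
    best_accuracy_operating_point,
    clopper_pearson_ci,
    confusion_metrics,
    delong_test,
    evaluate_cohort,
    mcnemar_exact,
    relative_change,
    roc_auc,
    spec_constrained_operating_point,
)


def pairwise_auc_oracle(scores, labels):
    """Brute-force Mann-Whitney probability with half-weight ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, n_max=30, tie_prone=True):
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    if tie_prone:
        scores = rng.integers(0, 6, n).astype(float)
    else:
        scores = rng.normal(size=n)
    return scores, labels


class TestRelativeChange:
    @pytest.mark.parametrize(
        "vt,vpre,expected", [(5.0, 5.0, 0.0), (0.0, 4.0, -1.0), (3.0, 2.0, 0.5)]
    )
    def test_values(self, vt, vpre, expected):
        assert relative_change(vt, vpre) == pytest.approx(expected)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            relative_change(1.0, 0.0)


class TestRocAuc:
    def test_separated_and_tied(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [1, 0, 1, 0]) == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(50):
            scores, labels = random_instance(rng)
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels)
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores, labels = random_instance(rng, tie_prone=False)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_lower_direction_flips(self, rng):
        scores, labels = random_instance(rng, tie_prone=False)
        a = roc_auc(scores, labels, "higher")
        b = roc_auc(scores, labels, "lower")
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestOperatingPoints:
    def exhaustive_scan(self, scores, labels, direction):
        s = scores if direction == "higher" else -np.asarray(scores, float)
        results = []
        for thr in np.concatenate(
            [[-np.inf], np.unique(s)[:-1] / 2 + np.unique(s)[1:] / 2, [np.inf]]
        ):
            pred = s > thr
            tp = int((pred & labels).sum())
            fp = int((pred & ~labels).sum())
            tn = int((~pred & ~labels).sum())
            fn = int((~pred & labels).sum())
            results.append((thr, tp, fn, fp, tn))
        return results

    def test_separable_reaches_perfect_accuracy(self):
        op = best_accuracy_operating_point([1, 2, 8, 9], [0, 0, 1, 1])
        assert op.accuracy == 1.0
        sp = spec_constrained_operating_point([1, 2, 8, 9], [0, 0, 1, 1])
        assert sp.sensitivity == 1.0 and sp.specificity == 1.0

    def test_all_tied_scores_fall_back_to_majority(self):
        op = best_accuracy_operating_point([3, 3, 3, 3, 3], [1, 1, 1, 0, 0])
        assert op.accuracy == pytest.approx(3 / 5)
        assert op.counts.tp + op.counts.fp in (0, 5)

    def test_constrained_degenerate_gives_zero_sensitivity(self):
        # positives strictly below negatives: no useful high-spec threshold
        op = spec_constrained_operating_point([1, 2, 8, 9], [1, 1, 0, 0], "higher")
        assert op.specificity >= 0.9
        assert op.sensitivity == 0.0

    def test_best_accuracy_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng)
            op = best_accuracy_operating_point(scores, labels)
            accs = [
                (tp + tn) / len(scores)
                for _, tp, fn, fp, tn in self.exhaustive_scan(scores, labels, "higher")
            ]
            assert op.accuracy == pytest.approx(max(accs))

    def test_spec_constrained_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            scores, labels = random_instance(rng)
            op = spec_constrained_operating_point(scores, labels)
            best_sens = 0.0
            for _, tp, fn, fp, tn in self.exhaustive_scan(scores, labels, "higher"):
                if tn + fp and tn / (tn + fp) >= 0.9 and tp + fn:
                    best_sens = max(best_sens, tp / (tp + fn))
            assert op.sensitivity == pytest.approx(best_sens)

    def test_accuracy_at_least_majority_rate(self, rng):
        for _ in range(20):
            scores, labels = random_instance(rng)
            prev = labels.mean()
            op = best_accuracy_operating_point(scores, labels)
            assert op.accuracy >= max(prev, 1 - prev) - 1e-12


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((12, 5, 1, 9), (0.71, 0.90, 0.78)),
            ((15, 2, 3, 7), (0.88, 0.70, 0.81)),
            ((5, 0, 0, 5), (1.0, 1.0, 1.0)),
        ],
    )
    def test_reference_tables(self, counts, expected):
        got = confusion_metrics(ConfusionCounts(*counts))
        assert tuple(round(v, 2) for v in got) == expected

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(0, 0, 2, 3))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestClopperPearson:
    def test_matches_statsmodels_beta_interval(self, rng):
        from statsmodels.stats.proportion import proportion_confint

        for _ in range(25):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(float(slo), abs=1e-10)
            assert hi == pytest.approx(float(shi), abs=1e-10)

    def test_boundaries(self):
        assert clopper_pearson_ci(0, 10)[0] == 0.0
        assert clopper_pearson_ci(10, 10)[1] == 1.0

    @given(k=st.integers(0, 30), n=st.integers(1, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_contains_point_estimate_and_widens_with_confidence(self, k, n):
        if k > n:
            return
        lo, hi = clopper_pearson_ci(k, n, alpha=0.05)
        lo2, hi2 = clopper_pearson_ci(k, n, alpha=0.01)
        assert lo - 1e-12 <= k / n <= hi + 1e-12
        assert lo2 <= lo + 1e-12 and hi2 >= hi - 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(5, 4)


class TestMcNemar:
    def test_symmetric_and_empty(self):
        assert mcnemar_exact(4, 4).p_value == 1.0
        assert mcnemar_exact(0, 0).p_value == 1.0

    def test_hand_computed_tail(self):
        """b=0, c=6: 2 * P(X <= 0), X ~ Bin(6, 1/2) = 2/64."""
        assert mcnemar_exact(0, 6).p_value == pytest.approx(0.03125)

    def test_matches_statsmodels_exact(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for _ in range(20):
            b, c = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            if b + c == 0 or b == c:
                continue  # convention differences only matter off-diagonal
            table = [[0, b], [c, 0]]
            sm_p = float(sm_mcnemar(table, exact=True).pvalue)
            assert mcnemar_exact(b, c).p_value == pytest.approx(sm_p, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_exact(-1, 2)


class TestDeLong:
    def make_paired(self, rng, n=40, rho=0.6, shift=0.8):
        labels = np.zeros(n, bool)
        labels[: n // 2] = True
        base = rng.normal(size=n)
        a = base + rng.normal(scale=0.8, size=n) + shift * labels
        b = rho * base + rng.normal(scale=0.8, size=n) + 0.5 * shift * labels
        return a, b, labels

    def test_identical_scores_give_unit_p(self, rng):
        s, _, labels = self.make_paired(rng)
        res = delong_test(s, s, labels)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_auc_equals_roc_auc_exactly(self, rng):
        s, t, labels = self.make_paired(rng)
        res_auc, _ = auc_ci(s, labels)
        assert res_auc == roc_auc(s, labels)

    def test_variance_matches_naive_enumeration(self, rng):
        """DeLong single-curve variance vs an explicit double-loop oracle."""
        from rsibreast.response_stats import _delong_variance

        for _ in range(10):
            n_tot = int(rng.integers(6, 16))
            labels = np.zeros(n_tot, bool)
            labels[: int(rng.integers(2, n_tot - 1))] = True
            rng.shuffle(labels)
            scores = rng.integers(0, 6, n_tot).astype(float)
            pos, neg = scores[labels], scores[~labels]
            m, n = len(pos), len(neg)
            psi = lambda p, q: 1.0 if p > q else 0.5 if p == q else 0.0
            v10 = np.array([np.mean([psi(p, q) for q in neg]) for p in pos])
            v01 = np.array([np.mean([psi(p, q) for p in pos]) for q in neg])
            expected_var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
            got_auc, got = _delong_variance(scores, labels)
            assert got_auc == pytest.approx(v10.mean())
            assert got == pytest.approx(expected_var, abs=1e-12)

    def test_p_value_tracks_bootstrap_difference(self, rng):
        """Small-scale sanity check against a paired bootstrap of dAUC."""
        a, b, labels = self.make_paired(rng, n=40)
        res = delong_test(a, b, labels)
        boot = []
        idx = np.arange(len(labels))
        for _ in range(2000):
            take = rng.choice(idx, size=len(idx), replace=True)
            if labels[take].all() or not labels[take].any():
                continue
            boot.append(roc_auc(a[take], labels[take]) - roc_auc(b[take], labels[take]))
        boot = np.asarray(boot)
        p_boot = 2 * min((boot <= 0).mean(), (boot >= 0).mean())
        assert abs(res.p_value - min(p_boot, 1.0)) < 0.15

    def test_zero_variance_mismatch_rejected(self):
        labels = np.array([1, 1, 0, 0], bool)
        with pytest.raises(ValueError):
            delong_test([1, 1, 1, 1], [5, 6, 1, 2], labels)


def build_reference_cohort():
    """27-patient cohort whose post-treatment RSI diameters cross 0.75 cm
    with counts TP=12, FN=5, FP=1, TN=9 at the accuracy-optimal threshold."""
    records, labels = [], {}
    rsi_post = {}
    k = 0
    for i in range(12):  # non-pCR, detected (large residual)
        rsi_post[f"n{k}"] = 1.0 + 0.125 * i
        labels[f"n{k}"] = False
        k += 1
    for i in range(5):  # non-pCR, missed (small residual)
        rsi_post[f"n{k}"] = 0.15 + 0.1 * i
        labels[f"n{k}"] = False
        k += 1
    labels["f0"] = True  # pCR, false positive (large spurious measurement)
    rsi_post["f0"] = 3.0
    for i in range(9):  # pCR, correctly negative
        rsi_post[f"t{i}"] = (0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.04, 0.03)[i]
        labels[f"t{i}"] = True
    for pid, v in rsi_post.items():
        records.append(
            TimepointRecord(pid, "pre", rsi_diameter_cm=4.0, dce_diameter_cm=4.5, mean_adc=1.1e-3)
        )
        records.append(
            TimepointRecord(
                pid, "post", rsi_diameter_cm=v, dce_diameter_cm=v, mean_adc=1.1e-3 + v * 1e-4
            )
        )
    return CohortDataset(records=records, pcr_labels=labels)


class TestEvaluateCohort:
    def test_separable_cohort_has_unit_auc_everywhere(self):
        records, labels = [], {}
        for i in range(6):
            pid = f"p{i}"
            labels[pid] = i < 3  # 3 pCR, 3 non-pCR
            sizes = {True: (4.0, 2.0, 1.0, 0.0), False: (4.0, 3.9, 3.8, 3.7)}[labels[pid]]
            for tp, v in zip(("pre", "early", "mid", "post"), sizes):
                records.append(
                    TimepointRecord(
                        pid, tp, rsi_diameter_cm=v, dce_diameter_cm=v,
                        mean_adc=2e-3 - v * 1e-4,
                    )
                )
        blocks = evaluate_cohort(CohortDataset(records, labels))
        for name, block in blocks.items():
            for modality in ("rsi", "dce"):
                assert block["modalities"][modality]["summary"].auc == 1.0

    def test_reference_confusion_counts_reproduced(self):
        ds = build_reference_cohort()
        blocks = evaluate_cohort(ds)
        summary = blocks["absolute_post"]["modalities"]["rsi"]["summary"]
        c = summary.best.counts
        assert (c.tp, c.fn, c.fp, c.tn) == (12, 5, 1, 9)
        sens, spec, acc = confusion_metrics(c)
        assert (round(sens, 2), round(spec, 2), round(acc, 2)) == (0.71, 0.90, 0.78)
        # the constrained point keeps specificity >= 0.9 with the same sensitivity
        assert summary.spec_constrained.specificity >= 0.9
        assert summary.spec_constrained.sensitivity == pytest.approx(12 / 17)

    def test_patient_order_invariance(self):
        ds = build_reference_cohort()
        shuffled = CohortDataset(list(reversed(ds.records)), dict(ds.pcr_labels))
        a = evaluate_cohort(ds)
        b = evaluate_cohort(shuffled)
        sa = a["absolute_post"]["modalities"]["rsi"]["summary"]
        sb = b["absolute_post"]["modalities"]["rsi"]["summary"]
        assert sa.auc == sb.auc and sa.best.counts == sb.best.counts

    def test_single_class_cohort_rejected(self):
        records = [TimepointRecord("a", "post", rsi_diameter_cm=1.0)]
        with pytest.raises(ValueError):
            evaluate_cohort(CohortDataset(records, {"a": False}))

    def test_csv_roundtrip(self, tmp_path):
        ds = build_reference_cohort()
        ds.to_csv(tmp_path / "cohort.csv")
        back = CohortDataset.from_csv(tmp_path / "cohort.csv")
        assert back.pcr_labels == ds.pcr_labels
        assert len(back.records) == len(ds.records)


class TestAucProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_auc_complement_for_tie_free_scores(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng, tie_prone=False)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)
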