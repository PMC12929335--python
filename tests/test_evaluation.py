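"""Confusion metrics, threshold sweeps, trapezoidal AUROC, DeLong, Spearman."""

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from hepafat.correction import PUBLISHED_MODELS, correct
from hepafat.evaluation import (
    ConfusionCounts,
    confusion_from_predictions,
    delong_compare,
    metrics,
    roc_auc,
    round_percent,
    spearman,
    threshold_sweep,
)
from hepafat.synthetic import CohortSimConfig, simulate_cohort

FIXTURE = Path(__file__).parent / "data" / "threshold_table_counts.csv"


def _concordance_brute_force(scores, truth):
    """Pairwise concordance probability with tie credit 1/2 (oracle)."""
    pos = scores[truth]
    neg = scores[~truth]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_worked_confusion_example(self):
        m = metrics(ConfusionCounts(tp=71, fp=13, fn=4, tn=109))
        r = m.rounded()
        assert r == {
            "sensitivity": 94.7,
            "specificity": 89.3,
            "balanced_accuracy": 92.0,
            "ppv": 84.5,
            "npv": 96.5,
        }

    def test_second_worked_example(self):
        m = metrics(ConfusionCounts(tp=76, fp=5, fn=2, tn=128))
        assert round_percent(m.sensitivity) == 97.4
        assert round_percent(m.specificity) == 96.2

    def test_zero_denominator_undefined_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=7))
        assert m.sensitivity is None
        assert m.balanced_accuracy is None
        assert m.specificity is not None

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=1)
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, fn=0, tn=0)

    def test_reference_table_regression(self):
        # every fixture row: metrics recomputed from counts match the
        # independently tabulated percents to rounding precision
        df = pd.read_csv(FIXTURE)
        for row in df.itertuples(index=False):
            counts = ConfusionCounts(
                tp=row.sens_num,
                fn=row.sens_den - row.sens_num,
                tn=row.spec_num,
                fp=row.spec_den - row.spec_num,
            )
            m = metrics(counts)
            assert m.sensitivity == pytest.approx(row.sens, abs=0.051)
            assert m.specificity == pytest.approx(row.spec, abs=0.051)
            assert m.balanced_accuracy == pytest.approx(row.ba, abs=0.051)
            assert m.ppv == pytest.approx(row.ppv, abs=0.051)
            assert m.npv == pytest.approx(row.npv, abs=0.051)
            # denominators implied by the counts must agree with the table
            assert counts.tp + counts.fp == row.ppv_den
            assert counts.tn + counts.fn == row.npv_den


class TestThresholdSweep:
    def test_perfect_separation(self):
        scores = np.array([10.0, 20.0, 30.0, 80.0, 90.0, 100.0])
        truth = np.array([True, True, True, False, False, False])
        sweep = threshold_sweep(scores, truth, [50.0], "less_than")
        assert sweep.optimal.metrics.balanced_accuracy == pytest.approx(100.0)

    def test_constant_scores_degenerate(self):
        scores = np.zeros(10)
        truth = np.array([True] * 4 + [False] * 6)
        sweep = threshold_sweep(scores, truth, [-1.0, 0.0, 1.0], "less_than")
        for row in sweep.rows:
            assert row.metrics.sensitivity + row.metrics.specificity == pytest.approx(100.0)
            assert 0.0 in (row.metrics.sensitivity, row.metrics.specificity)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            threshold_sweep([1.0, 2.0], [True, True], [1.5], "less_than")

    def test_optimum_stable_across_seeds(self):
        # venous corrected values on a derivation-like cohort: the
        # balanced-accuracy optimum moves by at most one 5-HU step
        grid = list(range(40, 105, 5))
        optima = []
        for seed in (21, 22):
            cfg = CohortSimConfig(
                n_subjects=10_000, seed=seed, phases=("non-contrast", "venous")
            )
            df = simulate_cohort(cfg)
            sub = df[df.phase == "venous"]
            sweep = threshold_sweep(
                sub.nc_observed_hu.to_numpy(),
                sub.steatosis_truth.to_numpy(),
                grid,
                "less_than",
            )
            optima.append(sweep.optimal.threshold)
        assert abs(optima[0] - optima[1]) <= 5.0

    def test_ba_tie_breaks_to_higher_specificity(self):
        # both thresholds reach BA = 75 but with opposite sens/spec balance
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        truth = np.array([True, False, True, False])
        sweep = threshold_sweep(scores, truth, [1.5, 3.5], "less_than")
        bas = [r.metrics.balanced_accuracy for r in sweep.rows]
        assert bas[0] == bas[1] == pytest.approx(75.0)
        assert sweep.optimal.threshold == 1.5
        assert sweep.optimal.metrics.specificity == pytest.approx(100.0)


class TestRocAuc:
    def test_all_tied_scores_give_half(self):
        res = roc_auc(np.ones(8), np.array([True] * 3 + [False] * 5))
        assert res.auroc == pytest.approx(0.5, abs=1e-12)

    def test_small_hand_example(self):
        # positives {0.9, 0.4}, negatives {0.8, 0.1}: 3 of 4 pairs concordant
        scores = np.array([0.9, 0.4, 0.8, 0.1])
        truth = np.array([True, True, False, False])
        assert roc_auc(scores, truth).auroc == pytest.approx(0.75, abs=1e-12)

    def test_perfect_ranking(self):
        scores = np.array([5.0, 4.0, 1.0, 0.0])
        truth = np.array([True, True, False, False])
        assert roc_auc(scores, truth).auroc == pytest.approx(1.0, abs=1e-12)

    def test_equals_concordance_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            scores = rng.integers(0, 6, n).astype(float)  # heavy ties
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            assert roc_auc(scores, truth).auroc == pytest.approx(
                _concordance_brute_force(scores, truth), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        truth = rng.random(60) < 0.4
        a = roc_auc(scores, truth).auroc
        b = roc_auc(np.exp(scores) * 3 + 1, truth).auroc
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=200) + rng.random(200).round()  # some ties
        truth = rng.random(200) < 0.3
        assert roc_auc(scores, truth).auroc == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12
        )

    def test_curve_is_monotone(self, rng):
        scores = rng.integers(0, 10, 50).astype(float)
        truth = rng.random(50) < 0.5
        pts = np.array(roc_auc(scores, truth).points)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        assert tuple(pts[0]) == (0.0, 0.0) and tuple(pts[-1]) == (1.0, 1.0)


def _jackknife_var_diff(scores_a, scores_b, truth):
    """Delete-one jackknife of the AUC difference (independent oracle)."""
    n = len(truth)
    thetas = []
    for i in range(n):
        keep = np.arange(n) != i
        t = truth[keep]
        if t.all() or not t.any():
            return None
        thetas.append(
            roc_auc(scores_a[keep], t).auroc - roc_auc(scores_b[keep], t).auroc
        )
    thetas = np.asarray(thetas)
    return (n - 1) / n * float(((thetas - thetas.mean()) ** 2).sum())


class TestDelong:
    def test_identical_scores(self, rng):
        s = rng.normal(size=30)
        truth = rng.random(30) < 0.5
        res = delong_compare(s, s, truth)
        assert res.z == 0.0
        assert res.p == 1.0

    def test_variance_matches_bootstrap(self, rng):
        n = 40
        truth = np.array([True] * 16 + [False] * 24)
        scores_a = truth * 1.2 + rng.normal(size=n)
        scores_b = truth * 0.5 + rng.normal(size=n)
        res = delong_compare(scores_a, scores_b, truth)

        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            t = truth[idx]
            if t.all() or not t.any():
                continue
            boot.append(
                roc_auc(scores_a[idx], t).auroc - roc_auc(scores_b[idx], t).auroc
            )
        boot_var = float(np.var(boot, ddof=1))
        assert res.var_diff == pytest.approx(boot_var, rel=0.10)

    def test_small_paired_example_vs_jackknife(self, rng):
        truth = np.array([True, True, True, False, False, False])
        scores_a = np.array([3.1, 2.0, 2.6, 1.9, 0.5, 1.1])
        scores_b = np.array([2.2, 0.8, 2.9, 1.6, 1.4, 0.2])
        res = delong_compare(scores_a, scores_b, truth)
        jk = _jackknife_var_diff(scores_a, scores_b, truth)
        # DeLong's estimator is the U-statistic jackknife up to small-sample
        # scaling; at n=6 they should agree to well within a factor of two
        assert res.var_diff == pytest.approx(jk, rel=0.5)
        assert res.var_diff > 0

    def test_power_on_strong_vs_weak_marker(self):
        rejections = 0
        n = 2000
        for seed in range(200):
            rng = np.random.default_rng(30_000 + seed)
            truth = rng.random(n) < 0.3
            strong = truth * 1.0 + rng.normal(size=n)
            weak = truth * 0.3 + rng.normal(size=n)
            res = delong_compare(strong, weak, truth)
            if res.p is not None and res.p < 0.01:
                rejections += 1
        assert rejections / 200 > 0.90

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1.0, 2.0], [1.0], [True, False])


class TestSpearman:
    def test_strictly_increasing(self):
        r, _ = spearman([1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_hand_rank_example(self):
        r, p = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)
        # t-approximation with n-2 df
        t = 0.8 * math.sqrt(3 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, df=3), abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_roi_vs_volumetric_simulation(self, rng):
        # two noisy reads of the same underlying liver attenuation should be
        # strongly rank-correlated, mirroring manual-vs-automated agreement
        signal = rng.normal(55.0, 10.0, 200)
        roi_read = signal + rng.normal(0, 2.0, 200)
        vol_read = signal + rng.normal(0, 2.0, 200)
        r, p = spearman(roi_read, vol_read)
        assert r > 0.9
        assert p < 1e-10


def test_confusion_from_predictions_counts():
    counts = confusion_from_predictions(
        [True, True, False, False, True], [True, False, False, True, True]
    )
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 1, 1, 1)


def test_corrected_attenuation_auroc_on_simulated_cohort():
    # discrimination of corrected post-contrast attenuation vs latent truth
    cfg = CohortSimConfig(n_subjects=4000, seed=17)
    df = simulate_cohort(cfg)
    for phase in ("arterial", "venous", "delayed"):
        sub = df[df.phase == phase]
        res = roc_auc(-sub.nc_observed_hu.to_numpy(), sub.steatosis_truth.to_numpy())
        assert res.auroc > 0.9
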