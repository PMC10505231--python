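"""Metrics (R^2, AUC, bootstrap CI, Youden cutoff, confusion matrix) and
the repeated-split protocol."""

import numpy as np
import pytest
from helpers import auc_pair_counting_oracle

from milfc.estimator import TrainConfig
from milfc.evaluation import (
    ProtocolConfig,
    best_cutoff,
    bootstrap_ci,
    confusion_metrics,
    r_squared,
    roc_auc,
    run_protocol,
)
from milfc.synthetic import simulate_cohort


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([0.5, 0.7, 0.9])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([0.5, 0.7, 0.9])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_matches_longhand_oracle(self, rng):
        y, p = rng.normal(size=50), rng.normal(size=50)
        ss_res = sum((a - b) ** 2 for a, b in zip(y, p))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        assert r_squared(y, p) == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        y, p = rng.normal(size=30), rng.normal(size=30)
        assert r_squared(3 * y + 2, 3 * p + 2) == pytest.approx(r_squared(y, p), abs=1e-10)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [0.9, 1.1])




class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_anti_ordered(self):
        assert roc_auc([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # ties likely
            assert roc_auc(labels, scores) == pytest.approx(
                auc_pair_counting_oracle(labels, scores), abs=1e-12
            )

    def test_complement_under_score_negation(self, rng):
        labels = np.array([0, 1] * 15)
        scores = rng.normal(size=30)  # ties have measure zero
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestBootstrapCI:
    def test_degenerate_metric_gives_zero_width_interval(self):
        lo, hi = bootstrap_ci([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9], n_boot=100, seed=0)
        assert lo == hi == 1.0

    def test_default_replicate_count_is_1000(self):
        import inspect

        assert inspect.signature(bootstrap_ci).parameters["n_boot"].default == 1000

    def test_deterministic_in_seed(self, rng):
        labels = np.array([0, 1] * 30)
        scores = rng.normal(size=60) + labels
        a = bootstrap_ci(labels, scores, n_boot=200, seed=7)
        b = bootstrap_ci(labels, scores, n_boot=200, seed=7)
        assert a == b

    def test_interval_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(0)
        widths = {}
        for n in (50, 500):
            labels = np.array([0, 1] * (n // 2))
            scores = rng.normal(size=n) + 1.2 * labels
            lo, hi = bootstrap_ci(labels, scores, n_boot=300, seed=1)
            widths[n] = hi - lo
        assert widths[500] < widths[50]


class TestBestCutoff:
    def test_separated_scores_return_gap_midpoint(self):
        c = best_cutoff([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert c == pytest.approx(0.5)  # midpoint of the 0.2-0.8 gap

    def test_identical_scores_single_candidate(self):
        assert best_cutoff([0, 1, 0, 1], [0.4, 0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 2)
            uniq = np.unique(scores)
            cands = [uniq[0]] if uniq.size == 1 else list((uniq[:-1] + uniq[1:]) / 2)
            best_j, oracle_c = -np.inf, None
            for c in cands:
                calls = scores >= c
                sens = np.mean(calls[labels == 1])
                spec = np.mean(~calls[labels == 0])
                j = sens + spec - 1
                if j > best_j:
                    best_j, oracle_c = j, c
            assert best_cutoff(labels, scores) == pytest.approx(oracle_c)


class TestConfusionMetrics:
    def test_all_correct(self):
        assert confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1]) == (1.0, 1.0, 1.0, 1.0)

    def test_symmetric_example(self):
        labels = [1] * 10 + [0] * 10
        calls = [1] * 9 + [0] + [1] + [0] * 9  # TP=9 FN=1 FP=1 TN=9
        acc, prec, rec, f1 = confusion_metrics(labels, calls)
        assert (acc, prec, rec, f1) == (0.9, 0.9, 0.9, pytest.approx(0.9))

    def test_no_positive_calls_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            acc, prec, rec, f1 = confusion_metrics([0, 1], [0, 0])
        assert prec == 0.0 and f1 == 0.0


class TestRunProtocol:
    @pytest.fixture(scope="class")
    def tiny_report(self):
        cohort = simulate_cohort(30, n_patches_range=(60, 100), seed=21)
        cfg = ProtocolConfig(
            n_splits=2,
            n_bootstrap=50,
            seed=4,
            train_config=TrainConfig(N=8, max_epochs=10, n_restarts=1),
        )
        return cohort, cfg, run_protocol(cohort, cfg)

    def test_one_row_per_split(self, tiny_report):
        _, cfg, report = tiny_report
        assert len(report.splits) == cfg.n_splits
        assert set(report.mean) >= {"r2_1p", "auc_fused", "accuracy", "f1"}

    def test_metrics_in_natural_ranges(self, tiny_report):
        _, _, report = tiny_report
        for key in ("auc_1p", "auc_19q", "auc_fused", "accuracy", "precision", "recall", "f1"):
            assert 0.0 <= report.mean[key] <= 1.0
        assert report.mean["r2_1p"] <= 1.0
        assert (report.splits["auc_fused_ci_low"] <= report.splits["auc_fused"]).all()
        assert (report.splits["auc_fused"] <= report.splits["auc_fused_ci_high"]).all()

    def test_same_seed_reproduces_report(self, tiny_report):
        cohort, cfg, report = tiny_report
        again = run_protocol(cohort, cfg)
        assert report.splits.equals(again.splits)
        assert report.to_json() == again.to_json()

    def test_too_small_cohort_rejected(self):
        cohort = simulate_cohort(4, n_patches_range=(20, 30), seed=0)
        with pytest.raises(ValueError):
            run_protocol(cohort, ProtocolConfig(n_splits=1))
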