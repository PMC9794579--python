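"""ROC AUC, diagnostic likelihood ratios, and the repeated-test algorithm."""

import numpy as np
import pytest

from tdprisk.biomarkers import PoolEntry, VariabilityPool
from tdprisk.classifier import CnnConfig, TrainedModel, build_cnn
from tdprisk.evaluation import roc_auc_ovr, confusion_metrics, run_repeated_test


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array(["high", "high", "low", "low"])
        assert roc_auc_ovr(labels, [0.9, 0.8, 0.2, 0.1], "high") == 1.0

    def test_all_ties_half(self):
        labels = np.array(["high", "high", "low", "low"])
        assert roc_auc_ovr(labels, [0.5] * 4, "high") == 0.5

    def test_hand_counted_pairs(self):
        # positives 0.9, 0.4 vs negatives 0.6, 0.2: 3 of 4 pairs won
        labels = np.array(["h", "h", "n", "n"])
        assert roc_auc_ovr(labels, [0.9, 0.4, 0.6, 0.2], "h") == 0.75

    def test_single_class_returns_missing(self):
        assert np.isnan(roc_auc_ovr(np.array(["h", "h"]), [0.1, 0.2], "h"))

    def test_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        labels = rng.choice(["a", "b"], size=50)
        scores = rng.random(50).round(1)  # rounding forces ties
        assert roc_auc_ovr(labels, scores, "a") == pytest.approx(
            roc_auc_score(labels == "a", scores)
        )


class TestConfusionMetrics:
    def test_all_correct_degenerate(self):
        labels = np.array(["high"] * 4 + ["intermediate"] * 7 + ["low"] * 5)
        m = confusion_metrics(labels, labels)
        assert m["accuracy"] == 1.0
        for cls in ("high", "intermediate", "low"):
            assert m["per_class"][cls].lr_neg == 0.0
            assert m["per_class"][cls].lr_pos == np.inf

    def test_hand_computed_confusion(self):
        # rows true high/(int)/(low): (4,0,0) / (1,5,1) / (0,2,3)
        labels = np.array(
            ["high"] * 4 + ["intermediate"] * 7 + ["low"] * 5
        )
        preds = np.array(
            ["high"] * 4
            + ["high"] + ["intermediate"] * 5 + ["low"]
            + ["intermediate"] * 2 + ["low"] * 3
        )
        m = confusion_metrics(labels, preds)
        # high: sens 4/4, spec 11/12
        h = m["per_class"]["high"]
        assert h.sensitivity == 1.0
        assert h.lr_pos == pytest.approx(1.0 / (1 - 11 / 12))
        assert h.lr_neg == 0.0
        # intermediate: sens 5/7, spec 7/9
        i = m["per_class"]["intermediate"]
        assert i.sensitivity == pytest.approx(5 / 7)
        assert i.lr_pos == pytest.approx((5 / 7) / (2 / 9))
        assert i.lr_neg == pytest.approx((2 / 7) / (7 / 9))
        # low: sens 3/5, spec 10/11
        l = m["per_class"]["low"]
        assert l.lr_pos == pytest.approx((3 / 5) / (1 / 11))
        assert m["accuracy"] == pytest.approx(12 / 16)
        # macro F1 from per-class precision/recall
        f1_h = 2 * (4 / 5) * 1.0 / (4 / 5 + 1.0)
        f1_i = 2 * (5 / 7) * (5 / 7) / (5 / 7 + 5 / 7)
        f1_l = 2 * (3 / 4) * (3 / 5) / (3 / 4 + 3 / 5)
        assert m["f1_macro"] == pytest.approx((f1_h + f1_i + f1_l) / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array(["a"]), np.array(["a", "b"]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([]), np.array([]))


@pytest.fixture(scope="module")
def tiny_model():
    return TrainedModel(config=CnnConfig(seed=2), net=build_cnn(CnnConfig(seed=2)))


def make_pool(n_per_drug, seed=0, n_drugs_per_class=2):
    rng = np.random.default_rng(seed)
    pool = VariabilityPool()
    i = 0
    for risk, mu in (("high", 1.0), ("intermediate", 0.0), ("low", -1.0)):
        for _ in range(n_drugs_per_class):
            pool.add(
                PoolEntry(
                    drug=f"drug{i}",
                    risk=risk,
                    values=mu + 0.1 * rng.normal(size=(n_per_drug, 500)),
                    sample_ids=np.arange(n_per_drug),
                    multipliers=np.ones(n_per_drug),
                )
            )
            i += 1
    return pool


class TestRunRepeatedTest:
    def test_single_series_pool_collapses_summary(self, tiny_model):
        pool = make_pool(1)
        summary = run_repeated_test(tiny_model, pool, n_iter=25, seed=0)
        for cls in ("high", "intermediate", "low"):
            med, lo, hi = summary.auc[cls]
            assert med == lo == hi
        assert summary.accuracy[0] == summary.accuracy[1] == summary.accuracy[2]

    def test_seeded_run_reproducible(self, tiny_model):
        pool = make_pool(10)
        a = run_repeated_test(tiny_model, pool, n_iter=50, seed=3)
        b = run_repeated_test(tiny_model, pool, n_iter=50, seed=3)
        assert a.auc == b.auc
        assert a.accuracy == b.accuracy

    def test_medians_within_min_max(self, tiny_model):
        pool = make_pool(20)
        s = run_repeated_test(tiny_model, pool, n_iter=40, seed=1)
        for per_cls in (s.auc, s.lr_pos, s.lr_neg):
            for med, lo, hi in per_cls.values():
                if not np.isnan(med):
                    assert lo <= med <= hi

    def test_iteration_count_recorded(self, tiny_model):
        pool = make_pool(3)
        s = run_repeated_test(tiny_model, pool, n_iter=17, seed=0)
        assert s.n_iterations == 17
        assert len(s.per_iteration) == 17

    def test_invalid_iteration_count_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            run_repeated_test(tiny_model, make_pool(2), n_iter=0, seed=0)

    def test_perfectly_informative_pool_perfect_scores(self):
        """An oracle model on a separable pool yields AUC 1 and accuracy 1."""

        class OracleModel:
            class config:
                input_length = 500

            class net:
                @staticmethod
                def forward(x, train=False):
                    # P(high) increases with the mean level, P(low) decreases
                    level = x.mean(axis=1)
                    logits = np.stack(
                        [level, 1.0 - np.abs(level), -level], axis=1
                    )
                    e = np.exp(logits)
                    return e / e.sum(axis=1, keepdims=True)

        pool = make_pool(10, seed=4)
        s = run_repeated_test(OracleModel(), pool, n_iter=30, seed=5)
        assert all(s.auc[c][0] == 1.0 for c in ("high", "intermediate", "low"))
        assert s.accuracy[0] == 1.0
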