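"""Metric formulas, ranking oracles and interpretability contracts."""

import numpy as np
import pytest

from conftest import tiny_run_config
from methylcl.evaluation import (
    ConfusionCounts,
    auprc,
    auroc,
    confusion,
    cross_modification_matrix,
    feature_t_stats,
    full_report,
    gradient_importance,
    metrics,
    perturbation_importance,
    repeated_runs,
    top_features,
)
from methylcl.pipeline import build_model, prepare_features, run_experiment
from methylcl.synthetic import SyntheticConfig, generate_dataset
from methylcl.training import TrainConfig


def pairwise_auroc(scores, labels):
    """Exhaustive concordance oracle: P(pos > neg) + 0.5 P(tie)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions(self):
        labels = [1, 1, 1, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.1, 0.2, 0.3]
        c = confusion(labels, scores)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 3, 0, 0)

    def test_inverted_predictions(self):
        labels = [1, 1, 0, 0]
        scores = [0.1, 0.2, 0.9, 0.8]
        c = confusion(labels, scores)
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_threshold_above_all_scores_predicts_negative(self):
        c = confusion([1, 0], [0.9, 0.9], threshold=1.0)
        assert c.tp == 0 and c.fp == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])


class TestMetrics:
    def test_worked_example_from_balanced_86_split(self):
        rep = metrics(ConfusionCounts(tp=72, tn=67, fp=19, fn=14))
        assert rep.acc == pytest.approx(0.8081, abs=5e-5)
        assert rep.mcc == pytest.approx(0.6173, abs=5e-5)
        assert rep.pre == pytest.approx(0.7912, abs=5e-5)
        assert rep.f1 == pytest.approx(0.8136, abs=5e-5)
        assert rep.sn == pytest.approx(0.8372, abs=5e-5)
        assert rep.sp == pytest.approx(0.7791, abs=5e-5)
        assert not rep.degenerate

    def test_no_association_gives_zero_mcc(self):
        rep = metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert rep.mcc == 0.0
        assert rep.acc == 0.5

    def test_degenerate_denominator_flagged_zero(self):
        rep = metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=5))
        assert rep.degenerate
        assert rep.sp == 0.0 and rep.pre == 0.0

    def test_agrees_with_direct_recomputation(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=200)
        scores = rng.uniform(size=200)
        c = confusion(labels, scores)
        rep = metrics(c)
        pred = (scores >= 0.5).astype(int)
        assert rep.acc == pytest.approx(np.mean(pred == labels))
        assert rep.sn == pytest.approx(np.mean(pred[labels == 1] == 1))


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_three_of_four_concordant(self):
        assert auroc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_trapezoid_equals_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            labels = np.zeros(n, dtype=int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            # ties are common under quantized scores
            scores = np.round(rng.uniform(size=n), 1)
            assert auroc(scores, labels) == pytest.approx(
                pairwise_auroc(scores, labels), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.5, 0.6], [1, 1])
        with pytest.raises(ValueError):
            auprc([0.5, 0.6], [0, 0])

    def test_auprc_perfect_ranking_is_one(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_full_report_keys(self):
        rep = full_report([0.9, 0.2, 0.8, 0.1], [1, 0, 1, 0])
        assert set(rep) == {"Sn", "Sp", "Acc", "Pre", "F1", "MCC", "AUROC", "AUPRC"}


class TestFeatureTStats:
    def test_identical_groups_give_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 4))
        labels = np.array([0, 1] * 20)
        t = feature_t_stats(X, labels)
        assert np.all(np.abs(t) < 3.0)

    def test_textbook_two_sample_value(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [2.0], [3.0], [4.0], [5.0]])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        t = feature_t_stats(X, labels)
        assert t[0] == pytest.approx(-1.0954, abs=1e-4)

    def test_output_length_is_dimension_count(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 7))
        labels = np.array([0, 1] * 5)
        assert feature_t_stats(X, labels).shape == (7,)

    def test_zero_variance_dimension_is_nan_sentinel(self):
        X = np.ones((8, 2))
        X[:, 1] = np.arange(8)
        labels = np.array([0, 1] * 4)
        t = feature_t_stats(X, labels)
        assert np.isnan(t[0])
        assert np.isfinite(t[1])

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            feature_t_stats(np.ones((3, 2)), [1, 0, 0])

    def test_top_features_ranked_by_magnitude(self):
        t = np.array([0.1, -5.0, 2.0, np.nan])
        top = top_features(t, k=3)
        assert [i for i, _ in top] == [1, 2, 0]


class TestImportanceProfiles:
    def test_gradient_profile_length_and_nonnegativity(self, tiny_dataset, tiny_config):
        train_recs, _ = tiny_dataset
        model = build_model(tiny_config)
        profile = gradient_importance(model, train_recs[:4], tiny_config)
        assert profile.shape == (41,)
        assert np.all(profile >= 0)

    def test_constant_model_gives_zero_gradient_profile(self, tiny_dataset, tiny_config):
        train_recs, _ = tiny_dataset
        model = build_model(tiny_config)
        # zeroing the classifier output stage makes probs constant (0.5, 0.5)
        model.cls_out.W.data[:] = 0.0
        model.cls_out.b.data[:] = 0.0
        profile = gradient_importance(model, train_recs[:3], tiny_config)
        assert np.allclose(profile, 0.0)

    def test_constant_model_gives_zero_perturbation_profile(
        self, tiny_dataset, tiny_config
    ):
        train_recs, _ = tiny_dataset
        model = build_model(tiny_config)
        model.cls_out.W.data[:] = 0.0
        model.cls_out.b.data[:] = 0.0
        profile = perturbation_importance(model, train_recs[:2], tiny_config)
        assert np.allclose(profile, 0.0)

    def test_trained_model_concentrates_on_motif_region(self, tiny_dataset):
        # perturbation importance of a trained model peaks inside the planted
        # motif window (positions 20-24) rather than in the background
        train_recs, test_recs = tiny_dataset
        cfg = tiny_run_config(
            training=TrainConfig(epochs=10, batch_size=16, seed=0)
        )
        model, _ = run_experiment(train_recs, test_recs, cfg)
        profile = perturbation_importance(model, test_recs[:8], cfg)
        motif = profile[20:25].mean()
        background = np.concatenate([profile[:15], profile[30:]]).mean()
        assert motif > background


class TestRepeatedRuns:
    def test_single_run_and_reproducibility(self, tiny_dataset, tiny_config):
        train_recs, test_recs = tiny_dataset
        one = repeated_runs(train_recs, test_recs, tiny_config, n_runs=1, master_seed=7)
        assert one["auroc"].shape == (1,)
        two = repeated_runs(train_recs, test_recs, tiny_config, n_runs=1, master_seed=7)
        assert np.array_equal(one["auroc"], two["auroc"])

    def test_runs_are_finite_and_in_range(self, tiny_dataset, tiny_config):
        train_recs, test_recs = tiny_dataset
        out = repeated_runs(train_recs, test_recs, tiny_config, n_runs=2, master_seed=1)
        assert np.all((out["auroc"] >= 0) & (out["auroc"] <= 1))

    def test_zero_runs_rejected(self, tiny_dataset, tiny_config):
        train_recs, test_recs = tiny_dataset
        with pytest.raises(ValueError):
            repeated_runs(train_recs, test_recs, tiny_config, n_runs=0)


class TestCrossModification:
    def test_shared_motif_transfers_and_diagonal_consistent(self, tiny_config):
        a = generate_dataset(SyntheticConfig(n_pos=30, n_neg=30, motif="GGACU", seed=1))
        b = generate_dataset(SyntheticConfig(n_pos=30, n_neg=30, motif="GGACU", seed=2))
        df = cross_modification_matrix({"a": a, "b": b}, tiny_config)
        assert df.shape == (2, 2)
        assert np.all(df.values >= 0) and np.all(df.values <= 1)
        # shared planted signal: training on a should transfer to b
        assert df.loc["b", "a"] > 0.5

    def test_fewer_than_two_datasets_rejected(self, tiny_config, tiny_dataset):
        with pytest.raises(ValueError):
            cross_modification_matrix({"only": tiny_dataset}, tiny_config)
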