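"""Fold assignment, boosted-tree training, tuning, additivity, attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from guidescore.model import (
    GuideScorer,
    Hyperparams,
    SEQUENCE_HP,
    TARGET_HP,
    cv_spearman,
    explain,
    grouped_stratified_folds,
    sequence_residuals,
    train_gbrt,
    tune,
)
from guidescore.sequence import SchemaError

SMALL_HP = Hyperparams(num_leaves=15, min_child_samples=20, learning_rate=0.1,
                       n_estimators=100)


def linear_dataset(rng, n=2000, n_features=5, noise=0.1):
    X = pd.DataFrame(
        rng.standard_normal((n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    y = 2.0 * X["f0"].to_numpy() + rng.normal(0, noise, n)
    return X, y


class TestFoldAssignment:
    def test_partition_and_gene_exclusivity(self, rng):
        genes = rng.choice([f"g{i}" for i in range(10)], 200)
        folds = grouped_stratified_folds(genes, k=5, seed=0)
        assert set(folds) == set(range(5))
        for gene in np.unique(genes):
            assert len(np.unique(folds[genes == gene])) == 1

    def test_single_source_reduces_to_grouped_kfold(self, rng):
        genes = np.repeat([f"g{i}" for i in range(10)], 5)
        folds = grouped_stratified_folds(genes, sources=None, k=5, seed=1)
        # each fold holds exactly two genes' rows
        for fold in range(5):
            assert len(np.unique(genes[folds == fold])) == 2

    def test_source_proportions_balanced(self, rng):
        genes = np.repeat([f"g{i}" for i in range(100)], 10)
        sources = np.repeat(np.where(np.arange(100) < 50, "a", "b"), 10)
        folds = grouped_stratified_folds(genes, sources, k=5, seed=0)
        global_prop = (sources == "a").mean()
        for fold in range(5):
            prop = (sources[folds == fold] == "a").mean()
            assert abs(prop - global_prop) <= 0.15

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            grouped_stratified_folds(["g1", "g2"], k=5)


class TestTrainGbrt:
    def test_recovers_planted_linear_signal(self, rng):
        X, y = linear_dataset(rng)
        train = np.arange(len(X)) < 1500
        model = train_gbrt(X.loc[train], y[train], SMALL_HP, seed=0)
        pred = model.predict(X.loc[~train])
        assert spearmanr(pred, y[~train]).statistic >= 0.9

    def test_constant_target_predicts_mean(self, rng):
        X, _ = linear_dataset(rng, n=200)
        y = np.full(200, 3.5)
        model = train_gbrt(X, y, SMALL_HP, seed=0)
        np.testing.assert_allclose(model.predict(X), 3.5, atol=1e-9)

    def test_seed_reproducibility(self, rng):
        X, y = linear_dataset(rng, n=500)
        a = train_gbrt(X, y, SMALL_HP, seed=3).predict(X)
        b = train_gbrt(X, y, SMALL_HP, seed=3).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_nonfinite_targets_rejected(self, rng):
        X, y = linear_dataset(rng, n=100)
        y[0] = np.nan
        with pytest.raises(ValueError):
            train_gbrt(X, y, SMALL_HP)

    def test_default_hyperparameters(self):
        assert (SEQUENCE_HP.num_leaves, SEQUENCE_HP.min_child_samples) == (111, 199)
        assert (TARGET_HP.num_leaves, TARGET_HP.min_child_samples) == (8, 137)
        assert SEQUENCE_HP.learning_rate == 0.01
        assert SEQUENCE_HP.n_estimators == 5000


class TestTune:
    def test_single_trial_returns_that_trial(self, rng):
        X, y = linear_dataset(rng, n=300)
        genes = np.repeat([f"g{i}" for i in range(30)], 10)
        best, log = tune(
            X, y, genes, n_trials=1, k=3, seed=0,
            learning_rate=0.1, n_estimators=20,
        )
        assert len(log) == 1
        assert best.num_leaves == log.loc[0, "num_leaves"]

    def test_small_trees_selected_for_simple_signal(self, rng):
        """On data a stump can fit, the search should not favor huge trees."""
        X, y = linear_dataset(rng, n=600, noise=0.5)
        genes = np.repeat([f"g{i}" for i in range(60)], 10)
        best, log = tune(
            X, y, genes, n_trials=8, k=3, seed=0,
            learning_rate=0.1, n_estimators=30,
        )
        assert best.num_leaves <= (8 + 256) / 2
        assert log["cv_spearman"].max() == log.loc[
            log["num_leaves"] == best.num_leaves, "cv_spearman"
        ].max()

    def test_invalid_range_rejected(self, rng):
        X, y = linear_dataset(rng, n=100)
        with pytest.raises(ValueError):
            tune(X, y, np.arange(100), search_range=(64, 8))


class TestResidualStage:
    def test_residual_definition(self):
        np.testing.assert_allclose(
            sequence_residuals([1.0, 2.0], [1.0, 2.0]), [0.0, 0.0]
        )
        with pytest.raises(ValueError):
            sequence_residuals(np.ones(3), np.ones(4))

    def test_training_residuals_near_zero_mean(self, rng):
        X, y = linear_dataset(rng, n=800)
        scorer = GuideScorer(sequence_hp=SMALL_HP, seed=0).fit_sequence(X, y)
        assert abs(scorer.residuals_.mean()) < 0.05

    def test_combined_additivity_exact(self, rng):
        X_seq, y = linear_dataset(rng, n=600)
        X_tgt = pd.DataFrame(
            rng.standard_normal((600, 3)), columns=["t0", "t1", "t2"]
        )
        y = y + 0.5 * (X_tgt["t0"] > 0).to_numpy()
        scorer = GuideScorer(sequence_hp=SMALL_HP, target_hp=SMALL_HP, seed=0)
        scorer.fit(X_seq, y, X_tgt)
        combined = scorer.predict(X_seq, X_tgt)
        seq_only = scorer.predict(X_seq)
        residual = scorer.predict_target_residual(X_tgt)
        np.testing.assert_allclose(combined - seq_only, residual, atol=1e-9)

    def test_target_stage_improves_on_planted_target_effect(self, rng):
        X_seq, y_seq = linear_dataset(rng, n=2000, noise=0.2)
        flag = (rng.random(2000) > 0.5).astype(float)
        X_tgt = pd.DataFrame({"domain_flag": flag, "noise": rng.standard_normal(2000)})
        y = y_seq + 1.0 * flag
        train = np.arange(2000) < 1500
        scorer = GuideScorer(sequence_hp=SMALL_HP, target_hp=SMALL_HP, seed=0)
        scorer.fit(X_seq.loc[train], y[train], X_tgt.loc[train])
        seq_rho = spearmanr(scorer.predict(X_seq.loc[~train]), y[~train]).statistic
        both_rho = spearmanr(
            scorer.predict(X_seq.loc[~train], X_tgt.loc[~train]), y[~train]
        ).statistic
        assert both_rho > seq_rho

    def test_schema_mismatch_rejected(self, rng):
        X, y = linear_dataset(rng, n=200)
        scorer = GuideScorer(sequence_hp=SMALL_HP, seed=0).fit_sequence(X, y)
        with pytest.raises(SchemaError):
            scorer.predict(X.rename(columns={"f0": "other"}))


class TestExplain:
    def test_constant_model_zero_attributions(self, rng):
        X, _ = linear_dataset(rng, n=200)
        model = train_gbrt(X, np.full(200, 2.0), SMALL_HP, seed=0)
        attributions, base = explain(model, X.head(20))
        np.testing.assert_allclose(attributions.to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(base, 2.0, atol=1e-9)

    def test_single_feature_concentration(self, rng):
        """A signal carried by one feature gets essentially all attribution."""
        X, y = linear_dataset(rng, n=1000, noise=0.01)
        model = train_gbrt(X, y, SMALL_HP, seed=0)
        attributions, _ = explain(model, X.head(100))
        mass = attributions.abs().sum()
        assert mass["f0"] / mass.sum() > 0.95

    def test_local_accuracy_on_random_rows(self, rng):
        X, y = linear_dataset(rng, n=500)
        model = train_gbrt(X, y, SMALL_HP, seed=0)
        rows = X.iloc[rng.choice(500, 100, replace=False)]
        attributions, base = explain(model, rows)
        reconstructed = base + attributions.sum(axis=1).to_numpy()
        np.testing.assert_allclose(reconstructed, model.predict(rows), atol=1e-6)


class TestSerialization:
    def test_bundle_round_trip_identical_predictions(self, tmp_path, rng):
        X_seq, y = linear_dataset(rng, n=400)
        X_tgt = pd.DataFrame(rng.standard_normal((400, 2)), columns=["a", "b"])
        scorer = GuideScorer(sequence_hp=SMALL_HP, target_hp=SMALL_HP, seed=0)
        scorer.fit(X_seq, y, X_tgt)
        scorer.save(tmp_path / "bundle")
        loaded = GuideScorer.load(tmp_path / "bundle")
        np.testing.assert_array_equal(
            scorer.predict(X_seq, X_tgt), loaded.predict(X_seq, X_tgt)
        )
        np.testing.assert_array_equal(scorer.predict(X_seq), loaded.predict(X_seq))

    def test_bundle_files_are_text(self, tmp_path, rng):
        X, y = linear_dataset(rng, n=200)
        scorer = GuideScorer(sequence_hp=SMALL_HP, seed=0).fit_sequence(X, y)
        scorer.save(tmp_path / "bundle")
        for path in (tmp_path / "bundle").iterdir():
            path.read_text()  # raises if binary


class TestCvSpearman:
    def test_cv_positive_on_learnable_signal(self, rng):
        X, y = linear_dataset(rng, n=500, noise=0.3)
        genes = np.repeat([f"g{i}" for i in range(50)], 10)
        score = cv_spearman(X, y, genes, None, SMALL_HP, k=5, seed=0)
        assert score > 0.8
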