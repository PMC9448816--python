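"""Paired tracr deltas, G/T binning, junction terminator, capture regression."""

import numpy as np
import pandas as pd
import pytest

from guidescore.model import Hyperparams
from guidescore.sequence import SequenceFeaturizer
from guidescore.simulate import (
    EffectConfig,
    gen_capture_counts,
    gen_contexts,
    gen_paired_screens,
)
from guidescore.tracr import (
    GTBin,
    bin_contrasts,
    capture_regression,
    gt_bins,
    junction_features,
    pair_spacers,
    train_delta_model,
)


class TestGtBins:
    @pytest.mark.parametrize(
        "tail,presence,n_t,n_g",
        [
            ("GTTT", "G&T", 3, 1),
            ("AACA", "neither", 0, 0),
            ("TTTT", "T only", 4, 0),
            ("GGCG", "G only", 0, 3),
        ],
    )
    def test_bin_classes(self, tail, presence, n_t, n_g):
        spacer = "A" * 16 + tail
        assert gt_bins(spacer) == GTBin(presence=presence, n_t=n_t, n_g=n_g)

    def test_counts_bounded(self, rng):
        for _ in range(50):
            spacer = "".join(rng.choice(list("ACGT"), 20))
            b = gt_bins(spacer)
            assert 0 <= b.n_t + b.n_g <= 4


class TestPairSpacers:
    def make_screen(self, spacers, z):
        return pd.DataFrame({"spacer": spacers, "z": z})

    def test_identical_screens_zero_delta(self):
        screen = self.make_screen(["AAAA", "CCCC"], [0.5, -0.5])
        paired = pair_spacers(screen, screen)
        np.testing.assert_allclose(paired["delta"], 0.0)

    def test_join_cardinality_and_unpaired_counts(self):
        a = self.make_screen(["s1", "s2", "s3"], [1.0, 2.0, 3.0])
        b = self.make_screen(["s2", "s3", "s4"], [0.0, 0.0, 0.0])
        paired = pair_spacers(a, b)
        assert len(paired) == 2
        assert paired.attrs["unpaired_a"] == 1
        assert paired.attrs["unpaired_b"] == 1

    def test_disjoint_screens_warn(self):
        a = self.make_screen(["s1"], [1.0])
        b = self.make_screen(["s2"], [1.0])
        with pytest.warns(UserWarning):
            paired = pair_spacers(a, b)
        assert paired.empty

    def test_delta_antisymmetry(self, rng):
        spacers = [f"s{i}" for i in range(100)]
        a = self.make_screen(spacers, rng.standard_normal(100))
        b = self.make_screen(spacers, rng.standard_normal(100))
        forward = pair_spacers(a, b)["delta"]
        backward = pair_spacers(b, a)["delta"]
        np.testing.assert_allclose(forward, -backward)


class TestBinContrasts:
    def test_all_zero_deltas(self, rng):
        spacers = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(400)]
        result = bin_contrasts(np.zeros(400), spacers)
        assert result["contrast_gt_vs_t_only"] == pytest.approx(0.0)
        assert result["contrast_g_only_vs_neither"] == pytest.approx(0.0)

    def test_planted_t_only_penalty_recovered(self, rng):
        spacers = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(2000)]
        bins = [gt_bins(s) for s in spacers]
        deltas = np.array(
            [-0.5 if b.presence == "T only" else 0.0 for b in bins]
        ) + rng.normal(0, 0.2, 2000)
        result = bin_contrasts(deltas, spacers)
        assert result["contrast_gt_vs_t_only"] == pytest.approx(0.5, abs=0.06)
        assert result["p_gt_vs_t_only"] < 1e-6

    def test_empty_cell_marked_missing(self):
        spacers = ["A" * 20, "A" * 20]  # only 'neither'
        result = bin_contrasts(np.array([0.1, -0.1]), spacers)
        assert np.isnan(result["presence_means"]["G&T"])
        assert np.isnan(result["contrast_gt_vs_t_only"])

    def test_antisymmetry_under_role_swap(self, rng):
        spacers = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(500)]
        deltas = rng.standard_normal(500)
        fwd = bin_contrasts(deltas, spacers)
        rev = bin_contrasts(-deltas, spacers)
        assert fwd["contrast_gt_vs_t_only"] == pytest.approx(
            -rev["contrast_gt_vs_t_only"]
        )


class TestJunctionFeatures:
    def test_hsu_scaffold_always_terminator(self, rng):
        for _ in range(20):
            spacer = "".join(rng.choice(list("ACGT"), 20))
            features = junction_features(spacer, "Hsu")
            assert features["max_t_run"] >= 4
            assert features["terminator"]

    def test_chen_scaffold_without_spacer_ts(self):
        features = junction_features("C" * 16 + "AAAA", "Chen")
        assert features["max_t_run"] == 3
        assert not features["terminator"]

    def test_threshold_boundary(self):
        # spacer-tail runs of length 3 vs 4 straddle the threshold
        three = junction_features("C" * 17 + "TTT", "DeWeirdt")
        assert three["max_t_run"] == 3 and not three["terminator"]
        four = junction_features("C" * 16 + "TTTT", "DeWeirdt")
        assert four["max_t_run"] == 4 and four["terminator"]

    def test_flag_monotone_in_spacer_t_run(self):
        runs = []
        for k in range(5):
            spacer = "C" * (20 - k) + "T" * k
            runs.append(junction_features(spacer, "Chen")["max_t_run"])
        assert runs == sorted(runs)

    def test_window_contract(self):
        with pytest.raises(ValueError):
            junction_features("A" * 20, "Hsu", window=8, scaffold_share=6)
        with pytest.raises(ValueError):
            junction_features("A" * 20, "Hsu", window=30, scaffold_share=20)


class TestDeltaModel:
    HP = Hyperparams(num_leaves=31, min_child_samples=20, learning_rate=0.05,
                     n_estimators=150)

    def featurize(self, contexts):
        frame = pd.DataFrame(
            {"context_30nt": [c.full for c in contexts], "tracr": "Hsu"}
        )
        X = SequenceFeaturizer().fit_transform(frame)
        return X.drop(columns=["tracr_Hsu", "tracr_Chen"])

    def test_pure_noise_deltas_uncorrelated(self, rng):
        contexts = gen_contexts(1000, seed=11)
        X = self.featurize(contexts)
        deltas = rng.standard_normal(1000)
        _, pearsons = train_delta_model(X, deltas, k=5, seed=0, hp=self.HP)
        assert abs(pearsons.mean()) < 0.1

    def test_planted_t_count_effect_recovered(self, rng):
        contexts = gen_contexts(3000, seed=12)
        X = self.featurize(contexts)
        n_t = np.array([gt_bins(c.spacer).n_t for c in contexts])
        deltas = -0.3 * n_t + rng.normal(0, 0.3, 3000)
        _, pearsons = train_delta_model(X, deltas, k=5, seed=0, hp=self.HP)
        assert pearsons.mean() >= 0.5

    def test_small_sample_warns(self, rng):
        contexts = gen_contexts(30, seed=13)
        X = self.featurize(contexts)
        with pytest.warns(UserWarning):
            train_delta_model(X, rng.standard_normal(30), k=3, seed=0, hp=self.HP)


class TestCaptureRegression:
    def test_planted_slope_recovered_with_ci_coverage(self):
        """Planted per-T slope -0.5: CI excludes 0 in >= 90/100 seeded runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_t = rng.integers(0, 4, 200)
            n_g = rng.integers(0, 4, 200)
            y = -0.5 * n_t + 0.1 * n_g + rng.normal(0, 0.3, 200)
            result = capture_regression(y, n_t, n_g)
            row = result.loc["n_t"]
            covered = row["ci_low"] <= -0.5 <= row["ci_high"]
            excludes_zero = row["ci_high"] < 0
            hits += covered and excludes_zero
        assert hits >= 90

    def test_zero_effect_coverage(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n_t = rng.integers(0, 4, 100)
            n_g = rng.integers(0, 4, 100)
            y = rng.normal(0, 1.0, 100)
            row = capture_regression(y, n_t, n_g).loc["n_t"]
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert 88 <= covered <= 100

    def test_constant_predictor_rank_error(self, rng):
        with pytest.raises(ValueError):
            capture_regression(rng.standard_normal(50), np.ones(50), np.ones(50))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            capture_regression([0.1, 0.2], [1, 2], [0, 1])


class TestSyntheticDeltaRecovery:
    def test_fig_pattern_bin_ordering(self, default_config):
        """Paired synthetic screens reproduce the termination-attenuation
        ordering: mean delta T-only < neither <= G&T."""
        hsu, chen = gen_paired_screens(n_guides=4000, cfg=default_config, seed=5)
        paired = pair_spacers(hsu, chen)
        result = bin_contrasts(paired["delta"], paired["spacer"])
        means = result["presence_means"]
        assert means["T only"] < means["neither"]
        assert means["neither"] <= means["G&T"] + 0.05
        assert result["contrast_gt_vs_t_only"] > 0.3
        assert result["p_gt_vs_t_only"] < 0.01

    def test_capture_generator_recovers_planted_gamma(self, default_config):
        spacers = [c.spacer for c in gen_contexts(400, seed=21)]
        counts = gen_capture_counts(spacers, default_config, seed=22)
        lfc = np.log2(counts["capture_count"] + 1) - np.log2(counts["gdna_count"] + 1)
        result = capture_regression(lfc, counts["n_t"], counts["n_g"])
        row = result.loc["n_t"]
        gamma_log2 = default_config.gamma_capture / np.log(2)
        assert row["ci_low"] <= gamma_log2 <= row["ci_high"]

    def test_zero_capture_effects_give_zero_lfc(self):
        cfg = EffectConfig(gamma_capture=0.0, delta_capture=0.0)
        spacers = [c.spacer for c in gen_contexts(600, seed=23)]
        counts = gen_capture_counts(spacers, cfg, seed=24)
        lfc = np.log2(counts["capture_count"] + 1) - np.log2(counts["gdna_count"] + 1)
        assert abs(lfc.mean()) < 0.1
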