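import numpy as np
import pytest

from guidescore.activity import process_screen, standardize_activity
from guidescore.model import GuideScorer, Hyperparams, grouped_stratified_folds
from guidescore.sequence import SequenceFeaturizer
from guidescore.simulate import EffectConfig, gen_screen_dataset


@pytest.fixture(scope="session")
def small_screen():
    """A small synthetic screen shared across tests (40 genes x 10 guides)."""
    return gen_screen_dataset(n_genes=40, guides_per_gene=10, seed=7)


@pytest.fixture(scope="session")
def processed_small_screen(small_screen):
    return process_screen(small_screen["counts"])


@pytest.fixture(scope="session")
def recovery_pipeline():
    """Full-scale recovery run: 200 genes x 25 guides, EffectConfig defaults,
    seed 0, 500 trees — used by the pipeline-recovery and explanation tests.

    Trains the sequence model on standardized generated activities with one
    gene-grouped fold held out; also carries the count-layer run (counts ->
    processed activities -> model) for the contrast checks.
    """
    ds = gen_screen_dataset(n_genes=200, guides_per_gene=25, seed=0)
    act = ds["activities"]
    y = standardize_activity(-act["activity"], orient="dropout")
    X = SequenceFeaturizer().fit_transform(act)
    folds = grouped_stratified_folds(act["gene"], k=5, seed=0)
    test = folds == 0
    hp = Hyperparams(num_leaves=111, min_child_samples=199, n_estimators=500)
    scorer = GuideScorer(sequence_hp=hp, seed=0).fit_sequence(X.loc[~test], y[~test])
    pred = scorer.predict(X.loc[test])
    return {
        "dataset": ds,
        "X": X,
        "y": y,
        "folds": folds,
        "test_mask": test,
        "scorer": scorer,
        "pred": pred,
    }


@pytest.fixture(scope="session")
def default_config():
    return EffectConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
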