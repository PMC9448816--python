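"""Two-stage gradient-boosted activity model.

Stage one (sequence model) predicts z-scored activity from sequence
features; stage two (target model) predicts the *residual* of stage one
from target-site features, so the combined score is exactly
``sequence_score + target_residual_score`` — additive by construction,
which also makes per-stage attributions additive.

Cross-validation groups guides by gene (no gene straddles train/test) and
stratifies folds by dataset source.  Training is deterministic given the
seed under the single-threaded contract used here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.model_selection import StratifiedGroupKFold

from guidescore.sequence import SCHEMA_VERSION, TRACR_CATEGORIES, SchemaError


@dataclass(frozen=True)
class Hyperparams:
    """LightGBM hyperparameters for one stage."""

    num_leaves: int
    min_child_samples: int
    learning_rate: float = 0.01
    n_estimators: int = 5000

    def __post_init__(self) -> None:
        if self.num_leaves < 2 or self.min_child_samples < 1:
            raise ValueError("invalid hyperparameters")


#: tuned defaults for the production-scale training compendium
SEQUENCE_HP = Hyperparams(num_leaves=111, min_child_samples=199)
TARGET_HP = Hyperparams(num_leaves=8, min_child_samples=137)

#: tuning search range for num_leaves and min_child_samples
SEARCH_RANGE = (8, 256)


def grouped_stratified_folds(
    genes, sources=None, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign rows to k folds, gene-grouped and source-stratified.

    Every guide targeting a given gene lands in the same fold; dataset
    sources are represented approximately proportionally in each fold.
    Returns an integer fold index per row.
    """
    genes = np.asarray(genes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(genes)) < k:
        raise ValueError(f"need at least k={k} distinct genes")
    if sources is None:
        sources = np.zeros(len(genes), dtype=int)
    sources = np.asarray(sources)
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(genes), -1, dtype=int)
    X_dummy = np.zeros((len(genes), 1))
    for fold, (_, test_idx) in enumerate(
        splitter.split(X_dummy, sources, groups=genes)
    ):
        folds[test_idx] = fold
    assert (folds >= 0).all()
    return folds


def _validate_xy(X: pd.DataFrame, y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if not np.isfinite(y).all():
        raise ValueError("targets contain non-finite values")
    return y


def train_gbrt(
    X: pd.DataFrame, y, hp: Hyperparams, seed: int = 0
) -> lgb.LGBMRegressor:
    """Fit one boosted regression-tree ensemble (deterministic, 1 thread)."""
    y = _validate_xy(X, y)
    model = lgb.LGBMRegressor(
        num_leaves=hp.num_leaves,
        min_child_samples=hp.min_child_samples,
        learning_rate=hp.learning_rate,
        n_estimators=hp.n_estimators,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )
    model.fit(X, y)
    return model


def cv_spearman(
    X: pd.DataFrame, y, genes, sources, hp: Hyperparams, k: int = 5, seed: int = 0
) -> float:
    """Mean held-out Spearman over gene-grouped stratified folds."""
    y = _validate_xy(X, y)
    folds = grouped_stratified_folds(genes, sources, k=k, seed=seed)
    scores = []
    for fold in range(k):
        test = folds == fold
        model = train_gbrt(X.loc[~test], y[~test], hp, seed=seed)
        pred = model.predict(X.loc[test])
        scores.append(spearmanr(pred, y[test]).statistic)
    return float(np.mean(scores))


def tune(
    X: pd.DataFrame,
    y,
    genes,
    sources=None,
    n_trials: int = 50,
    k: int = 5,
    seed: int = 0,
    search_range: tuple[int, int] = SEARCH_RANGE,
    learning_rate: float = 0.01,
    n_estimators: int = 5000,
) -> tuple[Hyperparams, pd.DataFrame]:
    """Search num_leaves / min_child_samples maximizing CV Spearman.

    A seeded random sampler draws both integers log-uniformly from
    ``search_range``; returns the best hyperparameters and the trial log.
    """
    lo, hi = search_range
    if lo > hi or lo < 2:
        raise ValueError(f"invalid search range {search_range}")
    rng = np.random.default_rng(seed)
    trials = []
    for trial in range(n_trials):
        leaves, child = np.exp(
            rng.uniform(np.log(lo), np.log(hi + 1), size=2)
        ).astype(int)
        hp = Hyperparams(
            num_leaves=int(np.clip(leaves, lo, hi)),
            min_child_samples=int(np.clip(child, lo, hi)),
            learning_rate=learning_rate,
            n_estimators=n_estimators,
        )
        score = cv_spearman(X, y, genes, sources, hp, k=k, seed=seed)
        trials.append(
            {
                "trial": trial,
                "num_leaves": hp.num_leaves,
                "min_child_samples": hp.min_child_samples,
                "cv_spearman": score,
            }
        )
    log = pd.DataFrame(trials)
    best = log.loc[log["cv_spearman"].idxmax()]
    best_hp = Hyperparams(
        num_leaves=int(best["num_leaves"]),
        min_child_samples=int(best["min_child_samples"]),
        learning_rate=learning_rate,
        n_estimators=n_estimators,
    )
    return best_hp, log


def sequence_residuals(activities, sequence_scores) -> np.ndarray:
    """Residual activity left unexplained by the sequence model."""
    activities = np.asarray(activities, dtype=float)
    sequence_scores = np.asarray(sequence_scores, dtype=float)
    if activities.shape != sequence_scores.shape:
        raise ValueError("shape mismatch between activities and sequence scores")
    return activities - sequence_scores


def explain(model: lgb.LGBMRegressor, X: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-row additive feature attributions (TreeSHAP) + base values.

    Local accuracy: base + row-sum of attributions equals the prediction.
    """
    contrib = model.predict(X, pred_contrib=True)
    attributions = pd.DataFrame(contrib[:, :-1], index=X.index, columns=X.columns)
    base = contrib[:, -1]
    return attributions, base


class GuideScorer:
    """Two-stage sgRNA activity model (sequence + residual target stages).

    Parameters follow sklearn conventions; fitted attributes carry a
    trailing underscore.  ``fit`` takes the sequence feature table and
    activity vector, plus an optional target feature table to train the
    residual stage.  ``predict`` returns the sequence score alone or the
    additive combination when target features are supplied.
    """

    def __init__(
        self,
        sequence_hp: Hyperparams = SEQUENCE_HP,
        target_hp: Hyperparams = TARGET_HP,
        seed: int = 0,
    ):
        self.sequence_hp = sequence_hp
        self.target_hp = target_hp
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "sequence_hp": self.sequence_hp,
            "target_hp": self.target_hp,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "GuideScorer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting ---------------------------------------------------------

    def fit(
        self, X_sequence: pd.DataFrame, y, X_target: pd.DataFrame | None = None
    ) -> "GuideScorer":
        y = _validate_xy(X_sequence, y)
        self.sequence_model_ = train_gbrt(X_sequence, y, self.sequence_hp, self.seed)
        self.sequence_schema_ = list(X_sequence.columns)
        self.sequence_scores_ = self.sequence_model_.predict(X_sequence)
        self.residuals_ = sequence_residuals(y, self.sequence_scores_)
        self.target_model_ = None
        self.target_schema_ = None
        if X_target is not None:
            if len(X_target) != len(X_sequence):
                raise ValueError("sequence and target tables differ in length")
            self.target_model_ = train_gbrt(
                X_target, self.residuals_, self.target_hp, self.seed
            )
            self.target_schema_ = list(X_target.columns)
        return self

    def fit_sequence(self, X_sequence: pd.DataFrame, y) -> "GuideScorer":
        return self.fit(X_sequence, y, X_target=None)

    def fit_target(self, X_target: pd.DataFrame) -> "GuideScorer":
        """Train the residual target stage after ``fit_sequence``."""
        self._check_fitted()
        if len(X_target) != len(self.residuals_):
            raise ValueError("target table length does not match training rows")
        self.target_model_ = train_gbrt(
            X_target, self.residuals_, self.target_hp, self.seed
        )
        self.target_schema_ = list(X_target.columns)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "sequence_model_"):
            raise RuntimeError("model is not fitted")

    @staticmethod
    def _check_schema(X: pd.DataFrame, schema: list[str], stage: str) -> None:
        if list(X.columns) != schema:
            raise SchemaError(
                f"{stage} features do not match the trained schema "
                f"({len(X.columns)} vs {len(schema)} columns)"
            )

    # -- scoring ---------------------------------------------------------

    def predict(
        self, X_sequence: pd.DataFrame, X_target: pd.DataFrame | None = None
    ) -> np.ndarray:
        self._check_fitted()
        self._check_schema(X_sequence, self.sequence_schema_, "sequence")
        scores = self.sequence_model_.predict(X_sequence)
        if X_target is not None:
            if self.target_model_ is None:
                raise RuntimeError("no target stage was trained")
            self._check_schema(X_target, self.target_schema_, "target")
            scores = scores + self.target_model_.predict(X_target)
        return scores

    def predict_target_residual(self, X_target: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        if self.target_model_ is None:
            raise RuntimeError("no target stage was trained")
        self._check_schema(X_target, self.target_schema_, "target")
        return self.target_model_.predict(X_target)

    def explain_sequence(self, X_sequence: pd.DataFrame):
        self._check_fitted()
        self._check_schema(X_sequence, self.sequence_schema_, "sequence")
        return explain(self.sequence_model_, X_sequence)

    def explain_target(self, X_target: pd.DataFrame):
        self._check_fitted()
        if self.target_model_ is None:
            raise RuntimeError("no target stage was trained")
        self._check_schema(X_target, self.target_schema_, "target")
        return explain(self.target_model_, X_target)

    # -- persistence -----------------------------------------------------

    def save(self, bundle_dir: str | Path) -> None:
        """Persist the bundle as a directory of text files."""
        self._check_fitted()
        bundle_dir = Path(bundle_dir)
        bundle_dir.mkdir(parents=True, exist_ok=True)
        self.sequence_model_.booster_.save_model(
            str(bundle_dir / "sequence_model.txt")
        )
        if self.target_model_ is not None:
            self.target_model_.booster_.save_model(
                str(bundle_dir / "target_model.txt")
            )
        meta = {
            "schema_version": SCHEMA_VERSION,
            "tracr_vocabulary": list(TRACR_CATEGORIES),
            "seed": self.seed,
            "sequence_hp": asdict(self.sequence_hp),
            "target_hp": asdict(self.target_hp),
            "sequence_schema": self.sequence_schema_,
            "target_schema": self.target_schema_,
        }
        (bundle_dir / "bundle.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "GuideScorer":
        bundle_dir = Path(bundle_dir)
        meta = json.loads((bundle_dir / "bundle.json").read_text())
        scorer = cls(
            sequence_hp=Hyperparams(**meta["sequence_hp"]),
            target_hp=Hyperparams(**meta["target_hp"]),
            seed=meta["seed"],
        )
        scorer.sequence_model_ = _loaded_regressor(bundle_dir / "sequence_model.txt")
        scorer.sequence_schema_ = meta["sequence_schema"]
        scorer.target_model_ = None
        scorer.target_schema_ = meta["target_schema"]
        target_path = bundle_dir / "target_model.txt"
        if target_path.exists():
            scorer.target_model_ = _loaded_regressor(target_path)
        scorer.sequence_scores_ = None
        scorer.residuals_ = None
        return scorer


class _LoadedBooster:
    """Minimal predict/pred_contrib wrapper around a deserialized booster."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict(self, X, **kwargs):
        return self.booster_.predict(
            X.to_numpy() if isinstance(X, pd.DataFrame) else X, **kwargs
        )


def _loaded_regressor(path: Path) -> _LoadedBooster:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _LoadedBooster(lgb.Booster(model_file=str(path)))


def fit_sequence_model(X_sequence, y, hp=SEQUENCE_HP, seed: int = 0) -> GuideScorer:
    return GuideScorer(sequence_hp=hp, seed=seed).fit_sequence(X_sequence, y)


def fit_target_model(scorer: GuideScorer, X_target) -> GuideScorer:
    return scorer.fit_target(X_target)
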