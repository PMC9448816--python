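"""Evaluation statistics for pooled screens and scoring models.

Essential genes provide positive controls (their guides should deplete) and
non-essential genes negative controls; separation statistics (ROC-AUC,
SSMD), per-gene rank agreement, quintile calibration and a compact-library
simulation quantify screen and model quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import roc_auc_score


def roc_auc(scores, labels, greater_is_active: bool = True) -> float:
    """ROC-AUC for separating essential (label 1) from non-essential guides.

    ``greater_is_active=False`` is for dropout LFCs, where more negative
    means more active; scores are negated internally so depletion ranks
    positive.  Equals P(random positive > random negative) with ties half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both positive and negative labels")
    if not greater_is_active:
        scores = -scores
    return float(roc_auc_score(labels, scores))


def ssmd(essential_lfcs, nonessential_lfcs) -> float:
    """Strictly standardized mean difference, non-essential minus essential.

    (mu_ne - mu_e) / sqrt(sigma_ne^2 + sigma_e^2) with sample SDs (ddof=1).
    Larger values mean stronger separation in a dropout screen.
    """
    e = np.asarray(essential_lfcs, dtype=float)
    ne = np.asarray(nonessential_lfcs, dtype=float)
    if e.size < 2 or ne.size < 2:
        raise ValueError("each group needs at least 2 values")
    denom = np.sqrt(ne.var(ddof=1) + e.var(ddof=1))
    if denom == 0:
        raise ValueError("zero pooled variance")
    return float((ne.mean() - e.mean()) / denom)


def per_gene_spearman(
    predicted, observed, genes, min_guides: int = 3
) -> pd.Series:
    """Within-gene Spearman correlation of predicted vs observed activity.

    Genes with fewer than ``min_guides`` guides are excluded.
    """
    frame = pd.DataFrame(
        {
            "pred": np.asarray(predicted, dtype=float),
            "obs": np.asarray(observed, dtype=float),
            "gene": np.asarray(genes),
        }
    )
    out = {}
    for gene, group in frame.groupby("gene"):
        if len(group) < min_guides:
            continue
        out[gene] = spearmanr(group["pred"], group["obs"]).statistic
    return pd.Series(out, name="spearman", dtype=float)


def quintile_calibration(
    observed_lfcs,
    predicted_scores,
    genes,
    n_pred_bins: int = 5,
    min_guides: int = 20,
    dropout: bool = True,
) -> pd.DataFrame:
    """Prediction-bin x observed-quintile percentage table.

    Within each gene (with >= ``min_guides`` guides) observed LFCs are
    average-ranked and cut into five equal-count quintiles (quintile 5 =
    most active; for dropout screens, most depleted).  Predicted scores are
    cut globally into ``n_pred_bins`` equal-count bins (bin ``n`` = highest
    predicted activity).  Rows (prediction bins) sum to 100.
    """
    frame = pd.DataFrame(
        {
            "lfc": np.asarray(observed_lfcs, dtype=float),
            "pred": np.asarray(predicted_scores, dtype=float),
            "gene": np.asarray(genes),
        }
    )
    frame = frame.groupby("gene").filter(lambda g: len(g) >= min_guides)
    if frame.empty:
        raise ValueError(f"no gene has >= {min_guides} guides")

    def gene_quintiles(group: pd.Series) -> np.ndarray:
        oriented = -group if dropout else group
        ranks = rankdata(oriented, method="average")
        # fixed-boundary cut of average ranks into 5 equal-count bins
        return np.ceil(ranks / len(ranks) * 5).astype(int)

    frame["quintile"] = (
        frame.groupby("gene")["lfc"].transform(lambda g: gene_quintiles(g))
    )
    pred_ranks = rankdata(frame["pred"], method="average")
    frame["pred_bin"] = np.ceil(pred_ranks / len(pred_ranks) * n_pred_bins).astype(int)

    table = pd.crosstab(frame["pred_bin"], frame["quintile"], normalize="index") * 100
    table = table.reindex(
        index=range(1, n_pred_bins + 1), columns=range(1, 6), fill_value=0.0
    )
    table.index.name = "pred_bin"
    table.columns.name = "quintile"
    return table


def simulate_library(
    scores,
    observed_lfcs,
    genes,
    essential,
    n_guides: int = 4,
    strategy: str = "top_score",
    seed: int = 0,
) -> dict:
    """Simulate a compact library by picking ``n_guides`` guides per gene.

    ``strategy="top_score"`` picks the highest-scoring guides; ``"random"``
    picks uniformly with the given seed.  Returns per-gene mean LFCs and
    the essential/non-essential SSMD of those means.
    """
    if strategy not in ("top_score", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")
    frame = pd.DataFrame(
        {
            "score": np.asarray(scores, dtype=float),
            "lfc": np.asarray(observed_lfcs, dtype=float),
            "gene": np.asarray(genes),
            "essential": np.asarray(essential, dtype=bool),
        }
    )
    rng = np.random.default_rng(seed)
    records = []
    for gene, group in frame.groupby("gene"):
        if strategy == "top_score":
            picked = group.nlargest(min(n_guides, len(group)), "score")
        else:
            take = min(n_guides, len(group))
            picked = group.iloc[rng.choice(len(group), size=take, replace=False)]
        records.append(
            {
                "gene": gene,
                "mean_lfc": picked["lfc"].mean(),
                "essential": bool(group["essential"].iloc[0]),
            }
        )
    per_gene = pd.DataFrame(records).set_index("gene")
    value = ssmd(
        per_gene.loc[per_gene["essential"], "mean_lfc"],
        per_gene.loc[~per_gene["essential"], "mean_lfc"],
    )
    return {"per_gene": per_gene, "ssmd": value, "strategy": strategy}
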