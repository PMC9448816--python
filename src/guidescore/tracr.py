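"""tracrRNA-dependent activity differences and Pol III termination analysis.

Pol III terminates transcription at runs of >= 4 T's on the non-template
strand.  The Hsu scaffold carries a 4-T run at positions 2-5, so spacers
ending in T's are prone to premature termination when paired with it; G's
in the spacer 3' end attenuate this.  The analyses here quantify that
signal: paired z-score differences between screens, G/T presence binning
over spacer positions 17-20, junction terminator detection, a
sequence-based difference model, and the direct-capture vs gDNA regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu, pearsonr, ttest_ind
from sklearn.model_selection import KFold

from guidescore.model import Hyperparams, train_gbrt
from guidescore.sequence import TracrVariant, longest_runs

#: minimum T-run length treated as a Pol III termination signal
TERMINATOR_RUN = 4

PRESENCE_CLASSES = ("G&T", "G only", "T only", "neither")


@dataclass(frozen=True)
class GTBin:
    """G/T content of spacer positions 17-20 (the scaffold-proximal end)."""

    presence: str
    n_t: int
    n_g: int


def gt_bins(spacer: str) -> GTBin:
    """Bin a spacer by G/T presence and counts in its last four nucleotides."""
    tail = spacer.upper()[-4:]
    if len(tail) < 4:
        raise ValueError("spacer shorter than 4 nt")
    n_t = tail.count("T")
    n_g = tail.count("G")
    if n_g and n_t:
        presence = "G&T"
    elif n_g:
        presence = "G only"
    elif n_t:
        presence = "T only"
    else:
        presence = "neither"
    return GTBin(presence=presence, n_t=n_t, n_g=n_g)


def pair_spacers(
    screen_a: pd.DataFrame,
    screen_b: pd.DataFrame,
    spacer_column: str = "spacer",
    z_column: str = "z",
) -> pd.DataFrame:
    """Inner-join two screens on spacer; delta = z_a - z_b.

    Inputs must already be z-scored per screen.  Returns the paired table
    with ``z_a``/``z_b``/``delta`` and records unpaired counts in
    ``frame.attrs``.
    """
    a = screen_a[[spacer_column, z_column]].rename(columns={z_column: "z_a"})
    b = screen_b[[spacer_column, z_column]].rename(columns={z_column: "z_b"})
    paired = a.merge(b, on=spacer_column, how="inner")
    paired["delta"] = paired["z_a"] - paired["z_b"]
    paired.attrs["unpaired_a"] = len(a) - len(paired)
    paired.attrs["unpaired_b"] = len(b) - len(paired)
    if paired.empty:
        warnings.warn("no spacers shared between the two screens")
    return paired


def bin_contrasts(
    deltas, spacers, test: str = "welch"
) -> dict:
    """Mean paired delta per G/T bin, with the two key contrasts.

    Contrasts: mean(G&T) - mean(T only) — the G-attenuation effect — and
    mean(G only) - mean(neither) — any T-independent G effect.  P-values
    from a two-sided Welch t-test (or Mann-Whitney with ``test="mwu"``).
    """
    frame = pd.DataFrame({"delta": np.asarray(deltas, dtype=float)})
    bins = [gt_bins(s) for s in spacers]
    frame["presence"] = [b.presence for b in bins]
    frame["n_t"] = [b.n_t for b in bins]
    frame["n_g"] = [b.n_g for b in bins]

    presence_means = {
        cls: (
            float(frame.loc[frame["presence"] == cls, "delta"].mean())
            if (frame["presence"] == cls).any()
            else float("nan")
        )
        for cls in PRESENCE_CLASSES
    }
    count_means = (
        frame.groupby(["n_t", "n_g"])["delta"].mean().rename("mean_delta")
    )

    def contrast(cls_a: str, cls_b: str):
        a = frame.loc[frame["presence"] == cls_a, "delta"].to_numpy()
        b = frame.loc[frame["presence"] == cls_b, "delta"].to_numpy()
        if a.size < 2 or b.size < 2:
            return float("nan"), float("nan")
        if test == "welch":
            result = ttest_ind(a, b, equal_var=False)
        elif test == "mwu":
            result = mannwhitneyu(a, b, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        return float(a.mean() - b.mean()), float(result.pvalue)

    gt_vs_t, p_gt_vs_t = contrast("G&T", "T only")
    g_vs_none, p_g_vs_none = contrast("G only", "neither")
    return {
        "presence_means": presence_means,
        "count_means": count_means,
        "contrast_gt_vs_t_only": gt_vs_t,
        "p_gt_vs_t_only": p_gt_vs_t,
        "contrast_g_only_vs_neither": g_vs_none,
        "p_g_only_vs_neither": p_g_vs_none,
    }


def junction_features(
    spacer: str,
    tracr: TracrVariant | str,
    window: int = 10,
    scaffold_share: int = 6,
) -> dict:
    """T-run features across the spacer-3'/scaffold-5' junction.

    The transcript window concatenates the last ``window - scaffold_share``
    spacer nucleotides with the first ``scaffold_share`` scaffold
    nucleotides; the terminator flag fires when the window contains a T-run
    of length >= 4.
    """
    if isinstance(tracr, str):
        tracr = TracrVariant.parse(tracr)
    spacer_share = window - scaffold_share
    if spacer_share < 4 or scaffold_share < 6:
        raise ValueError("window must cover >= 4 spacer nt and >= 6 scaffold nt")
    if len(tracr.scaffold_5prime) < scaffold_share:
        raise ValueError(
            f"scaffold constant shorter than {scaffold_share} nt"
        )
    if len(spacer) < spacer_share:
        raise ValueError(f"spacer shorter than {spacer_share} nt")
    transcript = spacer.upper()[-spacer_share:] + tracr.scaffold_5prime[:scaffold_share]
    max_run = longest_runs(transcript)["T"]
    return {
        "window": transcript,
        "max_t_run": max_run,
        "t_count": transcript.count("T"),
        "terminator": max_run >= TERMINATOR_RUN,
    }


DELTA_HP = Hyperparams(num_leaves=31, min_child_samples=20, learning_rate=0.05,
                       n_estimators=200)


def train_delta_model(
    X: pd.DataFrame,
    deltas,
    k: int = 5,
    seed: int = 0,
    hp: Hyperparams = DELTA_HP,
):
    """Predict paired activity differences from sequence features.

    Trains on k shuffled folds and reports the held-out Pearson correlation
    per fold, then refits on all rows.  Returns (model, fold_pearsons).
    """
    deltas = np.asarray(deltas, dtype=float)
    if len(X) != len(deltas):
        raise ValueError("X and deltas length mismatch")
    if len(deltas) < 50:
        warnings.warn("fewer than 50 paired spacers; fold estimates unstable")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    pearsons = []
    for train_idx, test_idx in splitter.split(X):
        model = train_gbrt(X.iloc[train_idx], deltas[train_idx], hp, seed=seed)
        pred = model.predict(X.iloc[test_idx])
        if np.ptp(pred) == 0:
            pearsons.append(0.0)
        else:
            pearsons.append(float(pearsonr(pred, deltas[test_idx]).statistic))
    final = train_gbrt(X, deltas, hp, seed=seed)
    return final, np.array(pearsons)


def capture_regression(lfc_direct_minus_gdna, n_t, n_g, alpha: float = 0.05) -> pd.DataFrame:
    """OLS of direct-capture vs gDNA log-fold-change on 3'-end T and G counts.

    Models expression attenuation: coefficients give the per-T and per-G
    change in the paired LFC, with normal-theory confidence intervals.
    Returns a frame indexed const/n_t/n_g with coef, ci_low, ci_high, pvalue.
    """
    y = np.asarray(lfc_direct_minus_gdna, dtype=float)
    X = pd.DataFrame({"n_t": np.asarray(n_t, float), "n_g": np.asarray(n_g, float)})
    if len(y) <= 3:
        raise ValueError("need more than 3 observations")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear predictors)")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=alpha)
    out = pd.DataFrame(
        {
            "coef": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "pvalue": fit.pvalues,
        }
    )
    return out
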