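"""Screen read counts -> model-ready activity scores.

Processing chain (mirroring standard pooled-screen practice): reads per
million -> log2(rpm + 1) -> pDNA abundance filters -> log2 fold change vs
pDNA -> replicate averaging -> Yeo-Johnson power transform + z-scoring ->
sign orientation so the most active guides score most positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import PowerTransformer


@dataclass
class ScreenCounts:
    """sgRNA x condition count matrix with a designated pDNA column.

    ``replicates`` groups sample columns by screen, e.g.
    ``{"screenA": ["rep1", "rep2", "rep3"]}``.
    """

    counts: pd.DataFrame
    pdna_column: str
    replicates: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.pdna_column not in self.counts.columns:
            raise ValueError(f"pDNA column {self.pdna_column!r} missing")
        if (self.counts < 0).any().any():
            raise ValueError("negative read counts")
        for screen, cols in self.replicates.items():
            missing = [c for c in cols if c not in self.counts.columns]
            if missing:
                raise ValueError(f"screen {screen!r}: missing columns {missing}")


def lognorm(counts) -> pd.Series | np.ndarray:
    """log2(reads-per-million + 1) for one condition column."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("condition has zero total reads")
    values = np.log2(arr / total * 1e6 + 1.0)
    if isinstance(counts, pd.Series):
        return pd.Series(values, index=counts.index, name=counts.name)
    return values


def _zscores(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; z-scores undefined, treating all as 0")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def filter_low_abundance(pdna_lognorms, z_cut: float = -3.0) -> np.ndarray:
    """Keep mask dropping guides under-represented in the plasmid pool.

    Guides whose pDNA lognorm z-score is below ``z_cut`` are removed.
    """
    arr = np.asarray(pdna_lognorms, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 guides")
    keep = _zscores(arr) >= z_cut
    return keep


def filter_outlier_pdna(pdna_lognorms: pd.DataFrame, sd_cut: float = 4.0) -> np.ndarray:
    """Keep mask removing guides >``sd_cut`` SD from the pDNA mean in any screen."""
    z = np.column_stack([_zscores(pdna_lognorms[c].to_numpy(float))
                         for c in pdna_lognorms.columns])
    return (np.abs(z) <= sd_cut).all(axis=1)


def lfc(sample_lognorm, pdna_lognorm):
    """log2 fold change of a condition relative to pDNA."""
    sample = np.asarray(sample_lognorm, dtype=float)
    pdna = np.asarray(pdna_lognorm, dtype=float)
    if sample.shape != pdna.shape:
        raise ValueError("sample and pDNA lognorms differ in shape")
    values = sample - pdna
    if isinstance(sample_lognorm, pd.Series):
        return pd.Series(values, index=sample_lognorm.index)
    return values


def average_replicates(lfcs: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Mean LFC across replicate columns + replicate Pearson matrix."""
    if lfcs.shape[1] < 1:
        raise ValueError("no replicate columns")
    return lfcs.mean(axis=1), lfcs.corr(method="pearson")


def standardize_activity(values, orient: str = "dropout") -> np.ndarray:
    """Yeo-Johnson transform + z-score + sign orientation.

    ``orient="dropout"`` flips the sign so the most depleted (most negative
    LFC) guides receive the most positive activity; ``"enrichment"`` keeps
    the sign.  Rank order is preserved up to the flip.
    """
    arr = np.asarray(values, dtype=float).reshape(-1, 1)
    if arr.shape[0] < 10:
        raise ValueError("need at least 10 values to fit the power transform")
    if np.ptp(arr) == 0:
        raise ValueError("constant input; activity standardization undefined")
    if orient not in ("dropout", "enrichment"):
        raise ValueError(f"unknown orientation {orient!r}")
    transformer = PowerTransformer(method="yeo-johnson", standardize=True)
    z = transformer.fit_transform(arr).ravel()
    if orient == "dropout":
        z = -z
    return z


def process_screen(
    screen: ScreenCounts,
    z_cut: float = -3.0,
    sd_cut: float = 4.0,
    orient: str = "dropout",
) -> pd.DataFrame:
    """Counts -> per-screen averaged LFC and standardized activity.

    Returns a frame indexed by sgRNA with one ``lfc_<screen>`` and
    ``activity_<screen>`` column per screen, after pDNA abundance filtering
    (filters are applied jointly across screens on the shared pDNA column).
    """
    lognorms = screen.counts.apply(lognorm, axis=0)
    pdna = lognorms[screen.pdna_column]
    keep = filter_low_abundance(pdna, z_cut=z_cut)
    keep &= filter_outlier_pdna(pdna.to_frame(), sd_cut=sd_cut)
    lognorms = lognorms.loc[keep]
    pdna = pdna.loc[keep]

    out = pd.DataFrame(index=lognorms.index)
    for name, cols in screen.replicates.items():
        rep_lfcs = pd.DataFrame(
            {c: lfc(lognorms[c], pdna) for c in cols}, index=lognorms.index
        )
        mean_lfc, _ = average_replicates(rep_lfcs)
        out[f"lfc_{name}"] = mean_lfc
        out[f"activity_{name}"] = standardize_activity(mean_lfc, orient=orient)
    return out


def build_training_table(
    records: pd.DataFrame,
    phenotype_genes,
    max_matches: int = 1,
    gene_column: str = "gene",
    match_column: str = "match_count",
) -> pd.DataFrame:
    """Harmonize per-dataset activity records into one training table.

    Keeps only guides targeting genes expected to show a phenotype and drops
    promiscuous guides (more than ``max_matches`` perfect genomic matches).
    Per-dataset standardization must already have been applied; no
    re-scaling happens across datasets.
    """
    phenotype_genes = set(phenotype_genes)
    mask = records[gene_column].isin(phenotype_genes)
    if match_column in records.columns:
        mask &= records[match_column] <= max_matches
    return records.loc[mask].copy()
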