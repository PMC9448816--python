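"""Seeded synthetic-data generators with the structure the method assumes.

The generators emulate a tiling knockout screen: 30-mer NGG contexts,
activities with planted sequence effects (a tracr-dependent G bonus at
spacer position 20, a Hsu-specific poly-T termination penalty at spacer
positions 17-20 attenuated by G's, and a folding-energy penalty), gene
effects, negative-binomial read counts for a pDNA pool plus three
replicates, toy annotation bundles, and paired gDNA/direct-capture counts
with T-dependent expression attenuation.  Every generator is a pure
function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from guidescore.activity import ScreenCounts
from guidescore.folding import spacer_mfe
from guidescore.sequence import ContextSequence, SCORING_ALIAS
from guidescore.target import (
    DOMAIN_SOURCES,
    AnnotationBundle,
    write_bundle,
)
from guidescore.tracr import gt_bins

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class EffectConfig:
    """Planted effect sizes for the activity generator.

    ``beta_polyt`` is the per-T penalty over spacer positions 17-20, active
    only with the Hsu scaffold and attenuated by a factor
    ``(1 - g_attenuation)`` per G in the same window (G's interrupt the
    Pol III termination signal).  ``gamma_capture``/``delta_capture`` give
    the log expression attenuation per T / per G for direct capture.
    """

    beta_g20_hsu: float = 0.5
    beta_g20_chen: float = 0.15
    beta_polyt: float = -0.3
    g_attenuation: float = 0.8
    beta_mfe: float = 0.1
    gene_effect_sd: float = 0.5
    noise_sd: float = 0.3
    gamma_capture: float = -0.5
    delta_capture: float = 0.19

    def __post_init__(self) -> None:
        if self.beta_polyt > 0:
            raise ValueError("beta_polyt must be <= 0")
        if not 0 <= self.g_attenuation <= 1:
            raise ValueError("g_attenuation must be in [0, 1]")
        for name, value in asdict(self).items():
            if not np.isfinite(value):
                raise ValueError(f"{name} is not finite")


def gen_contexts(n: int, seed: int = 0, gc_content: float = 0.5) -> list[ContextSequence]:
    """Random 30-mer contexts with an NGG PAM and the given GC content."""
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2
    p_at = (1 - gc_content) / 2
    bases = rng.choice(list("ACGT"), size=(n, 30), p=[p_at, p_gc, p_gc, p_at])
    contexts = []
    for row in bases:
        row[25] = "G"
        row[26] = "G"
        contexts.append(ContextSequence.from_full("".join(row)))
    return contexts


def sequence_effect(
    spacer: str, tracr_label: str, cfg: EffectConfig
) -> float:
    """Deterministic planted sequence effect for one guide."""
    alias = SCORING_ALIAS[tracr_label]
    beta_g20 = cfg.beta_g20_hsu if alias == "Hsu" else cfg.beta_g20_chen
    effect = beta_g20 * (spacer[19] == "G")
    gtbin = gt_bins(spacer)
    if tracr_label == "Hsu":
        effect += (
            cfg.beta_polyt * gtbin.n_t * (1 - cfg.g_attenuation) ** gtbin.n_g
        )
    effect += cfg.beta_mfe * spacer_mfe(spacer)
    return float(effect)


def gen_activity(
    contexts: list[ContextSequence],
    tracrs: list[str],
    cfg: EffectConfig,
    genes: list[str],
    seed: int = 0,
    gene_effects: dict[str, float] | None = None,
) -> pd.DataFrame:
    """True + noisy activities with planted sequence and gene effects.

    activity = G20 bonus (tracr-dependent) + attenuated poly-T penalty
    (Hsu only) + beta_mfe * folding MFE + gene effect + Gaussian noise.
    ``gene_effects`` may be supplied to share gene effects across screens
    of the same genes (e.g. paired tracr screens).
    """
    if not len(contexts) == len(tracrs) == len(genes):
        raise ValueError("contexts, tracrs and genes must have equal length")
    rng = np.random.default_rng(seed)
    unique_genes = pd.unique(np.asarray(genes))
    if gene_effects is None:
        gene_effects = dict(
            zip(unique_genes, rng.normal(0, cfg.gene_effect_sd, len(unique_genes)))
        )
    seq_effects = np.array(
        [sequence_effect(c.spacer, t, cfg) for c, t in zip(contexts, tracrs)]
    )
    # activities live on a z-like scale: plant effects around zero mean so a
    # library is not globally depleted or enriched
    seq_effects = seq_effects - seq_effects.mean()
    true = seq_effects + np.array([gene_effects[g] for g in genes])
    noisy = true + rng.normal(0, cfg.noise_sd, len(contexts))
    return pd.DataFrame(
        {
            "context_30nt": [c.full for c in contexts],
            "spacer": [c.spacer for c in contexts],
            "tracr": list(tracrs),
            "gene": list(genes),
            "sequence_effect": seq_effects,
            "true_activity": true,
            "activity": noisy,
        }
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_screen_counts(
    activities: pd.DataFrame,
    essential: np.ndarray,
    depth: float = 1000.0,
    seed: int = 0,
    n_replicates: int = 3,
    dispersion: float = 10.0,
    pdna_column: str = "pdna",
    screen_name: str = "screen",
) -> ScreenCounts:
    """Negative-binomial counts for a pDNA pool + replicate dropout samples.

    Guide abundance in the pool is lognormal; the expected dropout LFC of a
    guide is ``-activity`` for essential-gene guides and 0 otherwise.
    ``depth`` is the mean reads per guide; ``dispersion`` is the NB size.
    """
    rng = np.random.default_rng(seed)
    n = len(activities)
    essential = np.asarray(essential, dtype=bool)
    rel = rng.lognormal(0.0, 0.5, n)
    rel /= rel.mean()
    pdna_mean = depth * rel
    true_lfc = np.where(essential, -activities["activity"].to_numpy(), 0.0)
    data = {pdna_column: _nb_counts(rng, pdna_mean, dispersion)}
    for rep in range(1, n_replicates + 1):
        data[f"{screen_name}_rep{rep}"] = _nb_counts(
            rng, pdna_mean * 2.0**true_lfc, dispersion
        )
    counts = pd.DataFrame(data, index=activities.index)
    return ScreenCounts(
        counts=counts,
        pdna_column=pdna_column,
        replicates={screen_name: [f"{screen_name}_rep{rep}" for rep in range(1, n_replicates + 1)]},
    )


def gen_annotation_bundle(genes: list[str], seed: int = 0) -> AnnotationBundle:
    """Toy proteins (50-500 aa), domain intervals, conservation tracks.

    Conservation is elevated inside domain intervals; ~5% of positions are
    missing from the track.
    """
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    cds_lengths: dict[str, int] = {}
    domains: dict[str, list[tuple[str, int, int]]] = {}
    conservation: dict[str, np.ndarray] = {}
    for gene in genes:
        n_aa = int(rng.integers(50, 501))
        proteins[gene] = "".join(rng.choice(list(_AA), n_aa))
        cds = 3 * n_aa + 3
        cds_lengths[gene] = cds
        gene_domains = []
        n_sources = int(rng.integers(2, 7))
        for source in rng.choice(DOMAIN_SOURCES, n_sources, replace=False):
            length = int(rng.integers(30, max(31, cds // 3)))
            start = int(rng.integers(1, cds - length + 1))
            gene_domains.append((str(source), start, start + length))
        domains[gene] = gene_domains
        in_domain = np.zeros(cds, dtype=bool)
        for _, start, end in gene_domains:
            in_domain[start - 1: end - 1] = True
        track = rng.normal(np.where(in_domain, 0.8, 0.2), 0.1)
        track[rng.random(cds) < 0.05] = np.nan
        conservation[gene] = track
    return AnnotationBundle(
        proteins=proteins,
        cds_lengths=cds_lengths,
        domains=domains,
        conservation=conservation,
    )


def gen_capture_counts(
    spacers: list[str],
    cfg: EffectConfig,
    seed: int = 0,
    depth: float = 1000.0,
    dispersion: float = 10.0,
) -> pd.DataFrame:
    """Paired gDNA / direct-capture counts with 3'-end G/T attenuation.

    Capture abundance is gDNA abundance times
    exp(gamma_capture * nT + delta_capture * nG) over spacer positions
    17-20 (Hsu-scaffold expression attenuation read out directly).
    """
    rng = np.random.default_rng(seed)
    n = len(spacers)
    bins = [gt_bins(s) for s in spacers]
    n_t = np.array([b.n_t for b in bins])
    n_g = np.array([b.n_g for b in bins])
    rel = rng.lognormal(0.0, 0.5, n)
    rel /= rel.mean()
    gdna_mean = depth * rel
    capture_mean = gdna_mean * np.exp(cfg.gamma_capture * n_t + cfg.delta_capture * n_g)
    return pd.DataFrame(
        {
            "spacer": list(spacers),
            "gdna_count": _nb_counts(rng, gdna_mean, dispersion),
            "capture_count": _nb_counts(rng, capture_mean, dispersion),
            "n_t": n_t,
            "n_g": n_g,
        }
    )


def gen_design(
    n_genes: int,
    guides_per_gene: int,
    seed: int = 0,
    tracr_labels: tuple[str, ...] = ("Hsu", "Chen"),
    essential_fraction: float = 0.5,
    gc_content: float = 0.5,
) -> pd.DataFrame:
    """A guide design table: contexts, random tracr labels, genes, flags."""
    rng = np.random.default_rng(seed)
    n = n_genes * guides_per_gene
    contexts = gen_contexts(n, seed=int(rng.integers(2**31)), gc_content=gc_content)
    genes = [f"gene{g:04d}" for g in range(n_genes) for _ in range(guides_per_gene)]
    n_essential = int(round(n_genes * essential_fraction))
    essential_genes = {f"gene{g:04d}" for g in range(n_essential)}
    tracrs = rng.choice(tracr_labels, n)
    frame = pd.DataFrame(
        {
            "sgrna": [f"sg{i:05d}" for i in range(n)],
            "context_30nt": [c.full for c in contexts],
            "spacer": [c.spacer for c in contexts],
            "tracr": tracrs,
            "gene": genes,
            "essential": [g in essential_genes for g in genes],
            "match_count": 1,
        }
    ).set_index("sgrna")
    return frame


def gen_screen_dataset(
    n_genes: int = 200,
    guides_per_gene: int = 25,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    depth: float = 1000.0,
) -> dict:
    """A complete synthetic screen: design, activities, and read counts."""
    cfg = cfg or EffectConfig()
    rng = np.random.default_rng(seed)
    design = gen_design(n_genes, guides_per_gene, seed=int(rng.integers(2**31)))
    contexts = [ContextSequence.from_full(s) for s in design["context_30nt"]]
    activities = gen_activity(
        contexts,
        list(design["tracr"]),
        cfg,
        list(design["gene"]),
        seed=int(rng.integers(2**31)),
    )
    activities.index = design.index
    screen = gen_screen_counts(
        activities,
        design["essential"].to_numpy(),
        depth=depth,
        seed=int(rng.integers(2**31)),
    )
    return {"design": design, "activities": activities, "counts": screen, "config": cfg}


def gen_paired_screens(
    n_guides: int = 4000,
    cfg: EffectConfig | None = None,
    seed: int = 0,
    tracr_a: str = "Hsu",
    tracr_b: str = "Chen",
    n_genes: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two screens of the same spacers with different scaffolds.

    Returns per-screen frames with spacer and z-scored activity, sharing
    gene effects but with independent measurement noise — the input shape
    for paired-delta analysis.
    """
    cfg = cfg or EffectConfig()
    rng = np.random.default_rng(seed)
    contexts = gen_contexts(n_guides, seed=int(rng.integers(2**31)))
    genes = [f"gene{i % n_genes:04d}" for i in range(n_guides)]
    unique_genes = sorted(set(genes))
    # same genes in both screens: gene effects are shared, noise is not
    gene_effects = dict(
        zip(unique_genes, rng.normal(0, cfg.gene_effect_sd, len(unique_genes)))
    )
    frames = []
    for label in (tracr_a, tracr_b):
        activity = gen_activity(
            contexts, [label] * n_guides, cfg, genes,
            seed=int(rng.integers(2**31)), gene_effects=gene_effects,
        )
        z = activity["activity"].to_numpy()
        activity["z"] = (z - z.mean()) / z.std(ddof=1)
        frames.append(activity[["spacer", "gene", "z"]])
    return frames[0], frames[1]


def write_fixture_dir(
    out_dir: str | Path,
    n_genes: int = 20,
    guides_per_gene: int = 10,
    cfg: EffectConfig | None = None,
    seed: int = 0,
) -> Path:
    """Emit a complete fixture directory (design, counts, bundle, lists)."""
    cfg = cfg or EffectConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = gen_screen_dataset(n_genes, guides_per_gene, cfg=cfg, seed=seed)
    data["design"].to_csv(out_dir / "design.tsv", sep="\t")
    data["counts"].counts.to_csv(out_dir / "counts.tsv", sep="\t")
    genes = data["design"][["gene", "essential"]].drop_duplicates("gene")
    (out_dir / "essential_genes.txt").write_text(
        "\n".join(genes.loc[genes["essential"], "gene"]) + "\n"
    )
    (out_dir / "nonessential_genes.txt").write_text(
        "\n".join(genes.loc[~genes["essential"], "gene"]) + "\n"
    )
    bundle = gen_annotation_bundle(sorted(genes["gene"]), seed=seed + 1)
    write_bundle(bundle, out_dir / "bundle")
    manifest = {
        "seed": seed,
        "n_genes": n_genes,
        "guides_per_gene": guides_per_gene,
        "effect_config": asdict(cfg),
        "pdna_column": data["counts"].pdna_column,
        "replicates": data["counts"].replicates,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
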