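"""Target-site (protein-level) features for guide activity scoring.

Cut-site position within the CDS, amino-acid composition around the cut,
evolutionary conservation, and protein-domain membership all modulate the
phenotypic consequence of a Cas9 cut.  Annotations are consumed from a
file-based bundle (protein FASTA, domain interval TSV, per-nucleotide
conservation TSV) rather than live database queries.

Coordinate conventions: CDS nucleotide positions and amino-acid indices are
1-based; domain intervals are half-open ``[start, end)`` in CDS nucleotide
coordinates; windows are cut-centered and truncated at CDS/protein bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

#: the annotation sources whose domain calls become binary features
DOMAIN_SOURCES = (
    "Pfam",
    "Smart",
    "PROSITE",
    "Gene3D",
    "MobiDB-lite",
    "PANTHER",
    "Superfamily",
    "PRINTS",
    "CDD",
    "TIGRFAM",
    "HAMAP",
    "PIRSF",
    "SFLD",
    "ProSitePatterns",
    "Seg",
    "Coils",
)

#: residues preferentially found in alpha-helices
HELIX_RESIDUES = frozenset("VIYFWL")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy (optional biochemical summary)
_KD_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}


class UnknownGeneError(KeyError):
    def __init__(self, genes):
        self.genes = sorted(set(genes))
        super().__init__(f"genes missing from annotation bundle: {self.genes}")


@dataclass
class AnnotationBundle:
    """Per-gene annotations backing the target features.

    ``domains`` maps gene -> list of (source, start, end) half-open CDS-nt
    intervals; ``conservation`` maps gene -> float array over the CDS with
    NaN marking missing values.
    """

    proteins: dict[str, str]
    cds_lengths: dict[str, int]
    domains: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    conservation: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, protein in self.proteins.items():
            cds = self.cds_lengths.get(gene)
            if cds is None:
                raise ValueError(f"gene {gene!r} has a protein but no CDS length")
            if abs(len(protein) * 3 - cds) > 3:
                raise ValueError(
                    f"gene {gene!r}: protein length {len(protein)} aa inconsistent "
                    f"with CDS length {cds} nt"
                )
            for source, start, end in self.domains.get(gene, []):
                if not (1 <= start < end <= cds + 1):
                    raise ValueError(
                        f"gene {gene!r}: domain {source} [{start},{end}) outside CDS"
                    )
            track = self.conservation.get(gene)
            if track is not None and len(track) != cds:
                raise ValueError(
                    f"gene {gene!r}: conservation track length {len(track)} != CDS {cds}"
                )

    def genes(self) -> list[str]:
        return sorted(self.proteins)


def read_bundle(bundle_dir: str | Path) -> AnnotationBundle:
    """Read an annotation bundle directory.

    Expected files: ``proteins.fasta``; ``domains.tsv`` with columns
    gene/source/start/end; ``conservation.tsv`` with columns gene/pos/value
    (1-based positions; absent positions are missing).
    """
    bundle_dir = Path(bundle_dir)
    proteins = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(bundle_dir / "proteins.fasta"), "fasta")
    }
    cds_lengths = {gene: 3 * len(seq) + 3 for gene, seq in proteins.items()}

    domains: dict[str, list[tuple[str, int, int]]] = {}
    domains_path = bundle_dir / "domains.tsv"
    if domains_path.exists():
        table = pd.read_csv(domains_path, sep="\t")
        for row in table.itertuples():
            domains.setdefault(row.gene, []).append(
                (row.source, int(row.start), int(row.end))
            )

    conservation: dict[str, np.ndarray] = {}
    cons_path = bundle_dir / "conservation.tsv"
    if cons_path.exists():
        table = pd.read_csv(cons_path, sep="\t")
        for gene, group in table.groupby("gene"):
            track = np.full(cds_lengths[str(gene)], np.nan)
            track[group["pos"].to_numpy(dtype=int) - 1] = group["value"].to_numpy()
            conservation[str(gene)] = track

    return AnnotationBundle(
        proteins=proteins,
        cds_lengths=cds_lengths,
        domains=domains,
        conservation=conservation,
    )


def write_bundle(bundle: AnnotationBundle, bundle_dir: str | Path) -> None:
    bundle_dir = Path(bundle_dir)
    bundle_dir.mkdir(parents=True, exist_ok=True)
    with open(bundle_dir / "proteins.fasta", "w") as handle:
        for gene in bundle.genes():
            handle.write(f">{gene}\n{bundle.proteins[gene]}\n")
    rows = [
        {"gene": gene, "source": src, "start": start, "end": end}
        for gene, intervals in sorted(bundle.domains.items())
        for src, start, end in intervals
    ]
    pd.DataFrame(rows, columns=["gene", "source", "start", "end"]).to_csv(
        bundle_dir / "domains.tsv", sep="\t", index=False
    )
    cons_rows = []
    for gene, track in sorted(bundle.conservation.items()):
        present = np.flatnonzero(~np.isnan(track))
        cons_rows.append(
            pd.DataFrame(
                {"gene": gene, "pos": present + 1, "value": track[present]}
            )
        )
    (
        pd.concat(cons_rows, ignore_index=True)
        if cons_rows
        else pd.DataFrame(columns=["gene", "pos", "value"])
    ).to_csv(bundle_dir / "conservation.tsv", sep="\t", index=False)


@dataclass(frozen=True)
class CutSite:
    """Location of the Cas9 blunt cut within a gene's CDS."""

    gene: str
    cut_nt: int
    cds_len_nt: int

    def __post_init__(self) -> None:
        if self.cds_len_nt <= 0:
            raise ValueError("CDS length must be positive")
        if not 1 <= self.cut_nt <= self.cds_len_nt:
            raise ValueError(
                f"cut position {self.cut_nt} outside CDS [1, {self.cds_len_nt}]"
            )

    @property
    def cut_aa(self) -> int:
        return math.ceil(self.cut_nt / 3)

    @property
    def fraction_of_cds(self) -> float:
        return self.cut_nt / self.cds_len_nt


def locate_cut(spacer_cds_end_nt: int, cds_len_nt: int, gene: str = "") -> CutSite:
    """Place the blunt cut 3 nt 5' of the PAM (between spacer positions 17/18).

    ``spacer_cds_end_nt`` is the CDS coordinate of spacer position 20 (the
    PAM-proximal end, protospacer on the sense strand).
    """
    return CutSite(gene=gene, cut_nt=spacer_cds_end_nt - 3, cds_len_nt=cds_len_nt)


def aa_window_features(
    protein: str, cut_aa: int, width: int = 16, include_biochem: bool = False
) -> dict[str, float]:
    """Residue composition of a cut-centered window of ``width`` residues.

    ``width``/2 residues are taken each side of the cut (truncated at the
    termini).  Returns 20 relative abundances (summing to 1), the fraction
    of helix-prone residues {V, I, Y, F, W, L}, and optionally mean
    Kyte-Doolittle hydropathy.
    """
    if width % 2 or width < 2:
        raise ValueError("width must be a positive even integer")
    if not 1 <= cut_aa <= len(protein):
        raise ValueError(f"cut_aa {cut_aa} outside protein [1, {len(protein)}]")
    half = width // 2
    window = protein[max(0, cut_aa - half): cut_aa + half].upper()
    if not window:
        raise ValueError("empty amino-acid window")
    n = len(window)
    features = {f"aa_{a}": window.count(a) / n for a in AMINO_ACIDS}
    features["helix_fraction"] = sum(r in HELIX_RESIDUES for r in window) / n
    if include_biochem:
        features["mean_hydropathy"] = (
            sum(_KD_HYDROPATHY.get(r, 0.0) for r in window) / n
        )
    return features


def conservation_features(
    track: np.ndarray, cut_nt: int, small: int = 4, large: int = 32
) -> dict[str, float]:
    """Mean conservation over small/large cut-centered windows.

    Windows are half-open nt ranges of the given width centered on the cut,
    truncated at CDS bounds; missing (NaN) positions are excluded from the
    mean.  An all-missing window yields NaN plus a missing indicator of 1.
    """
    out: dict[str, float] = {}
    for name, width in (("cons_small", small), ("cons_large", large)):
        start = max(0, cut_nt - width // 2)
        end = min(len(track), cut_nt + width // 2)
        window = track[start:end]
        valid = window[~np.isnan(window)]
        if valid.size:
            out[name] = float(valid.mean())
            out[f"{name}_missing"] = 0.0
        else:
            out[name] = float("nan")
            out[f"{name}_missing"] = 1.0
    return out


def domain_flags(
    bundle: AnnotationBundle, gene: str, cut_nt: int
) -> dict[str, int]:
    """Per-source binary membership: cut inside any half-open interval."""
    flags = {f"domain_{src}": 0 for src in DOMAIN_SOURCES}
    for source, start, end in bundle.domains.get(gene, []):
        if start <= cut_nt < end and f"domain_{source}" in flags:
            flags[f"domain_{source}"] = 1
    return flags


def target_feature_names(include_biochem: bool = False) -> list[str]:
    names = ["fraction_of_cds"]
    names += [f"aa_{a}" for a in AMINO_ACIDS] + ["helix_fraction"]
    if include_biochem:
        names.append("mean_hydropathy")
    names += ["cons_small", "cons_small_missing", "cons_large", "cons_large_missing"]
    names += [f"domain_{src}" for src in DOMAIN_SOURCES]
    return names


def featurize_target(
    sites: list[CutSite],
    bundle: AnnotationBundle,
    aa_width: int = 16,
    cons_small: int = 4,
    cons_large: int = 32,
    include_biochem: bool = False,
    index=None,
) -> pd.DataFrame:
    """Target feature table: cut position, aa window, conservation, domains."""
    missing = [s.gene for s in sites if s.gene not in bundle.proteins]
    if missing:
        raise UnknownGeneError(missing)
    names = target_feature_names(include_biochem)
    if not sites:
        return pd.DataFrame(columns=names, dtype=float)
    rows = []
    for site in sites:
        row: dict[str, float] = {"fraction_of_cds": site.fraction_of_cds}
        row.update(
            aa_window_features(
                bundle.proteins[site.gene], site.cut_aa, aa_width, include_biochem
            )
        )
        track = bundle.conservation.get(site.gene)
        if track is None:
            track = np.full(site.cds_len_nt, np.nan)
        row.update(conservation_features(track, site.cut_nt, cons_small, cons_large))
        row.update(domain_flags(bundle, site.gene, site.cut_nt))
        rows.append(row)
    return pd.DataFrame(rows, index=index, columns=names, dtype=float)


class TargetFeaturizer:
    """sklearn-style transformer from cut sites to target features."""

    def __init__(
        self,
        aa_width: int = 16,
        cons_small: int = 4,
        cons_large: int = 32,
        include_biochem: bool = False,
    ):
        self.aa_width = aa_width
        self.cons_small = cons_small
        self.cons_large = cons_large
        self.include_biochem = include_biochem

    def get_params(self, deep: bool = True) -> dict:
        return {
            "aa_width": self.aa_width,
            "cons_small": self.cons_small,
            "cons_large": self.cons_large,
            "include_biochem": self.include_biochem,
        }

    def set_params(self, **params) -> "TargetFeaturizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "TargetFeaturizer":
        self.feature_names_ = target_feature_names(self.include_biochem)
        return self

    def transform(self, sites: list[CutSite], bundle: AnnotationBundle) -> pd.DataFrame:
        return featurize_target(
            sites,
            bundle,
            aa_width=self.aa_width,
            cons_small=self.cons_small,
            cons_large=self.cons_large,
            include_biochem=self.include_biochem,
        )
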