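"""30-nt context sequences, tracrRNA variants, and sequence featurization.

The target context is a 30-mer laid out as 4 nt upstream + 20-nt spacer +
3-nt PAM (NGG) + 3 nt downstream.  Spacer positions are 1-based with
position 20 adjacent to the scaffold; full-context positions are 1-based
(spacer occupies 5..24, PAM 25..27).

Feature schema (version 1.0), in fixed column order:

1. position one-hots         p{i}_{N}   for i in 1..30, N in ACGT   (120)
2. position dinucleotide     p{i}_{NN}  for i in 1..29              (464)
3. nucleotide counts         n_{N} over the 30-mer                  (4)
4. dinucleotide counts       n_{NN} over the 30-mer, overlapping    (16)
5. spacer GC count + GC>10 indicator                                (2)
6. longest run of each nucleotide in the spacer                     (4)
7. melting temperatures: RNA:DNA heteroduplex of the full spacer,
   plus DNA-duplex Tm of the 30-mer and three spacer subsegments
   (spacer positions 16-20, 8-15, 3-7)                              (5)
8. spacer folding minimum free energy (kcal/mol)                    (1)
9. tracrRNA category one-hot (scoring alias Hsu / Chen)             (2)
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guidescore.folding import spacer_mfe
from guidescore.thermo import heteroduplex_tm, segment_tms

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]

CONTEXT_LEN = 30
UPSTREAM_LEN = 4
SPACER_LEN = 20
PAM_LEN = 3
DOWNSTREAM_LEN = 3

SCHEMA_VERSION = "1.0"

#: 5' ends (first 12 nt) of the scaffold constants.  The Hsu scaffold carries
#: a run of four T's in positions 2-5 (a Pol III termination signal); the
#: Chen and DeWeirdt scaffolds disrupt it, leaving a three-T run in 2-4.
TRACR_SCAFFOLDS: dict[str, str] = {
    "Hsu": "GTTTTAGAGCTA",
    "Chen": "GTTTAAGAGCTA",
    "DeWeirdt": "GTTTGAGAGCTA",
}

#: tracrRNA label used for scoring.  The DeWeirdt scaffold behaves like the
#: Chen scaffold for activity prediction (both disrupt the poly-T signal),
#: so it is scored under the Chen category.
SCORING_ALIAS: dict[str, str] = {"Hsu": "Hsu", "Chen": "Chen", "DeWeirdt": "Chen"}

TRACR_CATEGORIES = ("Hsu", "Chen")

_BSMBI_SITES = ("CGTCTC", "GAGACG")


class SequenceError(ValueError):
    """Invalid guide sequence input."""


class SchemaError(ValueError):
    """Feature table does not match the expected schema."""


def _check_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceError(f"{name} must be non-empty")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise SequenceError(f"{name} contains non-ACGT symbols: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class ContextSequence:
    """A 30-nt target context: upstream + spacer + PAM + downstream."""

    upstream: str
    spacer: str
    pam: str
    downstream: str

    def __post_init__(self) -> None:
        for attr, expected in (
            ("upstream", UPSTREAM_LEN),
            ("spacer", SPACER_LEN),
            ("pam", PAM_LEN),
            ("downstream", DOWNSTREAM_LEN),
        ):
            value = _check_dna(getattr(self, attr), attr)
            if len(value) != expected:
                raise SequenceError(
                    f"{attr} must be {expected} nt, got {len(value)}"
                )
            object.__setattr__(self, attr, value)

    @property
    def full(self) -> str:
        return self.upstream + self.spacer + self.pam + self.downstream

    @classmethod
    def from_full(cls, seq: str, allow_non_ngg: bool = False) -> "ContextSequence":
        seq = _check_dna(seq, "context")
        if len(seq) != CONTEXT_LEN:
            raise SequenceError(f"context must be {CONTEXT_LEN} nt, got {len(seq)}")
        ctx = cls(
            upstream=seq[:4], spacer=seq[4:24], pam=seq[24:27], downstream=seq[27:]
        )
        ctx.check_pam(allow_non_ngg=allow_non_ngg)
        return ctx

    def check_pam(self, allow_non_ngg: bool = False) -> None:
        """Require an NGG PAM (full-context positions 26-27 = GG)."""
        if self.pam[1:] != "GG":
            if allow_non_ngg:
                warnings.warn(
                    f"non-NGG PAM {self.pam!r}; scoring was developed on NGG sites",
                    stacklevel=2,
                )
            else:
                raise SequenceError(f"PAM {self.pam!r} is not NGG")


def assemble_context(
    upstream: str, spacer: str, pam: str, downstream: str, allow_non_ngg: bool = True
) -> ContextSequence:
    """Assemble and validate a 30-nt context from its four segments."""
    ctx = ContextSequence(upstream=upstream, spacer=spacer, pam=pam, downstream=downstream)
    if not allow_non_ngg:
        ctx.check_pam(allow_non_ngg=False)
    return ctx


@dataclass(frozen=True)
class TracrVariant:
    """A tracrRNA scaffold variant (Hsu, Chen, or DeWeirdt)."""

    label: str
    scaffold_5prime: str = field(init=False)
    scoring_alias: str = field(init=False)

    def __post_init__(self) -> None:
        if self.label not in TRACR_SCAFFOLDS:
            raise KeyError(
                f"unknown tracrRNA label {self.label!r}; "
                f"known: {sorted(TRACR_SCAFFOLDS)}"
            )
        object.__setattr__(self, "scaffold_5prime", TRACR_SCAFFOLDS[self.label])
        object.__setattr__(self, "scoring_alias", SCORING_ALIAS[self.label])

    @classmethod
    def parse(cls, label: str, strict: bool = False) -> "TracrVariant":
        """Resolve a (possibly unnormalized) label to a variant.

        In strict mode only the canonical capitalized labels are accepted.
        """
        if strict:
            return cls(label)
        normalized = label.strip().lower()
        for known in TRACR_SCAFFOLDS:
            if normalized == known.lower():
                return cls(known)
        raise KeyError(
            f"unknown tracrRNA label {label!r}; known: {sorted(TRACR_SCAFFOLDS)}"
        )


def tracr_feature(variant: TracrVariant | str) -> str:
    """Categorical tracr encoding used by the model (scoring alias)."""
    if isinstance(variant, str):
        variant = TracrVariant.parse(variant)
    return variant.scoring_alias


def longest_runs(seq: str) -> dict[str, int]:
    """Length of the longest maximal run of each nucleotide (0 if absent)."""
    seq = _check_dna(seq, "sequence")
    runs = dict.fromkeys(NUCLEOTIDES, 0)
    for base, group in itertools.groupby(seq):
        n = sum(1 for _ in group)
        if n > runs[base]:
            runs[base] = n
    return runs


def has_polyt(spacer: str, min_run: int = 4) -> bool:
    return "T" * min_run in spacer.upper()


def has_bsmbi(seq: str) -> bool:
    seq = seq.upper()
    return any(site in seq for site in _BSMBI_SITES)


def library_filter_mask(contexts: list[ContextSequence], min_polyt_run: int = 4) -> np.ndarray:
    """Design-stage exclusion mask: True = keep.

    Drops spacers containing a poly-T run (Pol III terminator) or contexts
    containing a BsmBI recognition site (cloning incompatibility).
    """
    return np.array(
        [
            not (has_polyt(c.spacer, min_polyt_run) or has_bsmbi(c.full))
            for c in contexts
        ],
        dtype=bool,
    )


# ---------------------------------------------------------------------------
# feature blocks
# ---------------------------------------------------------------------------

def _onehot_names() -> list[str]:
    names = [f"p{i}_{n}" for i in range(1, CONTEXT_LEN + 1) for n in NUCLEOTIDES]
    names += [f"p{i}_{d}" for i in range(1, CONTEXT_LEN) for d in DINUCLEOTIDES]
    return names


def _composition_names() -> list[str]:
    return (
        [f"n_{n}" for n in NUCLEOTIDES]
        + [f"n_{d}" for d in DINUCLEOTIDES]
        + ["spacer_gc_count", "spacer_gc_gt_10"]
    )


def _thermo_names() -> list[str]:
    return [
        "tm_heteroduplex",
        "tm_context_30",
        "tm_spacer_16_20",
        "tm_spacer_8_15",
        "tm_spacer_3_7",
    ]


def feature_names() -> list[str]:
    """The full, ordered sequence feature schema (version 1.0)."""
    return (
        _onehot_names()
        + _composition_names()
        + [f"longest_run_{n}" for n in NUCLEOTIDES]
        + _thermo_names()
        + ["spacer_mfe"]
        + [f"tracr_{c}" for c in TRACR_CATEGORIES]
    )


def onehot_features(ctx: ContextSequence) -> dict[str, int]:
    """Position-specific order-1 and order-2 indicator block (584 columns)."""
    seq = ctx.full
    values = {name: 0 for name in _onehot_names()}
    for i, base in enumerate(seq, start=1):
        values[f"p{i}_{base}"] = 1
    for i in range(1, CONTEXT_LEN):
        values[f"p{i}_{seq[i - 1:i + 1]}"] = 1
    return values


def composition_features(ctx: ContextSequence) -> dict[str, int]:
    """Position-independent counts over the 30-mer plus spacer GC features."""
    seq = ctx.full
    values: dict[str, int] = {f"n_{n}": seq.count(n) for n in NUCLEOTIDES}
    dinuc_counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(CONTEXT_LEN - 1):
        dinuc_counts[seq[i:i + 2]] += 1
    values.update({f"n_{d}": c for d, c in dinuc_counts.items()})
    gc = ctx.spacer.count("G") + ctx.spacer.count("C")
    values["spacer_gc_count"] = gc
    values["spacer_gc_gt_10"] = int(gc > 10)
    return values


def _thermo_features(ctx: ContextSequence) -> dict[str, float]:
    tm_block = segment_tms(ctx.full)
    return {
        "tm_heteroduplex": heteroduplex_tm(ctx.spacer),
        "tm_context_30": tm_block["context_30"],
        "tm_spacer_16_20": tm_block["spacer_16_20"],
        "tm_spacer_8_15": tm_block["spacer_8_15"],
        "tm_spacer_3_7": tm_block["spacer_3_7"],
    }


def _featurize_one(
    ctx: ContextSequence, tracr: TracrVariant | str, mfe_engine: str
) -> dict[str, float]:
    row: dict[str, float] = {}
    row.update(onehot_features(ctx))
    row.update(composition_features(ctx))
    runs = longest_runs(ctx.spacer)
    row.update({f"longest_run_{n}": runs[n] for n in NUCLEOTIDES})
    row.update(_thermo_features(ctx))
    row["spacer_mfe"] = spacer_mfe(ctx.spacer, engine=mfe_engine)
    alias = tracr_feature(tracr)
    for cat in TRACR_CATEGORIES:
        row[f"tracr_{cat}"] = int(alias == cat)
    return row


def featurize_sequence(
    contexts: list[ContextSequence],
    tracrs: list[TracrVariant | str],
    index=None,
    mfe_engine: str = "builtin",
) -> pd.DataFrame:
    """Featurize contexts + tracr labels into the fixed 618-column schema.

    Pure and row-independent: identical inputs yield an identical table;
    training and scoring must share this schema.
    """
    if len(contexts) != len(tracrs):
        raise ValueError(
            f"{len(contexts)} contexts but {len(tracrs)} tracr labels"
        )
    names = feature_names()
    if not contexts:
        return pd.DataFrame(columns=names, dtype=float)
    rows = [_featurize_one(c, t, mfe_engine) for c, t in zip(contexts, tracrs)]
    table = pd.DataFrame(rows, index=index, columns=names, dtype=float)
    table.attrs["schema_version"] = SCHEMA_VERSION
    return table


class SequenceFeaturizer:
    """sklearn-style transformer from design tables to sequence features.

    Parameters
    ----------
    context_column, tracr_column:
        Column names in the input frame.  Alternatively the frame may carry
        the four segment columns ``upstream``/``spacer``/``pam``/``downstream``.
    mfe_engine:
        ``"builtin"`` (dynamic-programming fold under the packaged simplified
        energy model) or ``"vienna"`` (ViennaRNA, if importable).
    allow_non_ngg:
        Accept (with a warning) contexts whose PAM is not NGG.
    """

    def __init__(
        self,
        context_column: str = "context_30nt",
        tracr_column: str = "tracr",
        mfe_engine: str = "builtin",
        allow_non_ngg: bool = False,
    ):
        self.context_column = context_column
        self.tracr_column = tracr_column
        self.mfe_engine = mfe_engine
        self.allow_non_ngg = allow_non_ngg

    def get_params(self, deep: bool = True) -> dict:
        return {
            "context_column": self.context_column,
            "tracr_column": self.tracr_column,
            "mfe_engine": self.mfe_engine,
            "allow_non_ngg": self.allow_non_ngg,
        }

    def set_params(self, **params) -> "SequenceFeaturizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X=None, y=None) -> "SequenceFeaturizer":
        self.feature_names_ = feature_names()
        return self

    def _contexts(self, X: pd.DataFrame) -> list[ContextSequence]:
        if self.context_column in X.columns:
            return [
                ContextSequence.from_full(s, allow_non_ngg=self.allow_non_ngg)
                for s in X[self.context_column]
            ]
        segments = ("upstream", "spacer", "pam", "downstream")
        if all(c in X.columns for c in segments):
            return [
                assemble_context(r.upstream, r.spacer, r.pam, r.downstream)
                for r in X.itertuples()
            ]
        raise SchemaError(
            f"input needs a {self.context_column!r} column or the four "
            "segment columns upstream/spacer/pam/downstream"
        )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.tracr_column not in X.columns:
            raise SchemaError(f"input lacks tracr column {self.tracr_column!r}")
        contexts = self._contexts(X)
        return featurize_sequence(
            contexts, list(X[self.tracr_column]), index=X.index,
            mfe_engine=self.mfe_engine,
        )

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
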