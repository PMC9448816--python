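# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `guidescore`, in the spirit of a statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence features

A target context is 30 nt: 4 nt upstream, the 20-nt spacer-matching
sequence, the 3-nt NGG PAM, and 3 nt downstream. Spacer positions are
1-based with position 20 adjacent to the scaffold; all interval logic is
half-open `[start, end)`. Contexts with a non-NGG PAM are rejected by
default (the scoring scheme was developed on NGG sites) and accepted with a
warning behind `allow_non_ngg`.

The feature schema (version 1.0, 618 columns, fixed order) comprises:
position-specific order-1 (30×4) and order-2 (29×16) indicators;
position-independent mono- and dinucleotide counts over the 30-mer; spacer
GC count and a GC>10 indicator; the longest run of each nucleotide in the
spacer; five melting temperatures; the spacer folding MFE; and a two-column
tracr category one-hot. The exact composition of older sequence-only
schemes is not published as a formal specification, so the schema is
versioned: alternates can be slotted in without breaking stored models
(scoring refuses schema-mismatched inputs with an explicit error).

**Melting temperatures.** The primary thermodynamic feature is the Tm of
the RNA spacer hybridized to its complementary DNA strand, computed by
nearest-neighbor summation with the packaged Sugimoto RNA/DNA hybrid
ΔH/ΔS table (via biopython). Conditions are fixed package-wide — 50 mM
Na⁺, 25 nM per strand, Schildkraut-Lifson salt correction — so the feature
is deterministic; the constants live in `thermo.TM_CONDITIONS`. A legacy
block adds DNA-duplex Tms of the full 30-mer and of spacer subsegments
16–20, 8–15 and 3–7 (the segment temperatures used by earlier scoring
schemes). Whether the original heteroduplex feature used the full 20-nt
duplex or subsegments is not documented; we compute the full duplex and
keep the subsegment block separately.

**Folding MFE.** The spacer (read as RNA) is folded with a
dynamic-programming algorithm under a deliberately simple energy model:
Watson-Crick plus G·U pairs; pair energies G-C −2.1, A-U −1.1, G-U −0.6
kcal/mol; a −1.0 kcal/mol bonus per stacked pair; a minimum hairpin loop of
3; no pseudoknots. Because the model is additive over pairs and stacks,
the DP minimum is exact and verifiable by exhaustive enumeration of all
secondary structures at short lengths — the test suite checks equality for
1000 random sequences of length ≤ 12. The model intentionally omits loop
entropies, so its magnitudes are larger than Turner-model values (random
20-mers average around −11 kcal/mol rather than −1 to −3); the feature is
used as a relative structure-propensity score, which is all a tree
ensemble consumes. ViennaRNA can be swapped in (`engine="vienna"`) where
calibrated physical energies are wanted.

**tracrRNA variants.** Three scaffolds are supported via their 5′-end
constants (first 12 nt): Hsu `GTTTTAGAGCTA`, Chen `GTTTAAGAGCTA`, DeWeirdt
`GTTTGAGAGCTA`. The Hsu scaffold carries a 4-T run at positions 2–5 (a
Pol III terminator); Chen and DeWeirdt disrupt it (3-T run at 2–4) by an
A or G substitution respectively. For scoring, DeWeirdt aliases to Chen —
both lack the intact terminator, and their activity profiles match —
giving a two-level model category. Full-scaffold sequence parity (stem
extension etc.) is out of scope; only the 5′ constant matters for the
junction analyses here.

## Target features

Annotations are consumed from a file bundle (protein FASTA; TSV domain
intervals `gene/source/start/end` in half-open CDS-nt coordinates; TSV
conservation `gene/pos/value`) rather than live REST queries, for
reproducibility. The blunt Cas9 cut is placed 3 nt 5′ of the PAM (between
spacer positions 17/18). Features: cut position as a fraction of the CDS;
amino-acid relative abundances and the fraction of helix-prone residues
{V, I, Y, F, W, L} in a cut-centered window of 16 residues (width/2 per
side, truncated at the termini — "width w around the cut" is interpreted
symmetrically); mean conservation in cut-centered windows of 4 and 32 nt
(truncated at CDS bounds, missing positions excluded; an all-missing
window produces NaN plus an explicit `_missing` indicator column, which
the tree model handles natively); and 16 binary domain-source flags. A cut
exactly at an interval's `end` is outside it (half-open convention).
Additional residue-level biochemistry (mean Kyte-Doolittle hydropathy) is
available behind `include_biochem`, off by default. Isoform selection is
out of scope: one canonical protein per gene, conservation indexed
linearly along the CDS.

## Activity processing

Counts → reads-per-million → log2(rpm + 1) (the only pseudocount in the
chain) → abundance filters on the pDNA column (drop z < −3; drop |z| > 4
in any screen) → LFC vs pDNA → replicate averaging (with the replicate
Pearson matrix reported) → Yeo-Johnson power transform fit by maximum
likelihood, z-scoring, and a sign flip for dropout screens so the most
depleted guides score most positive. Standardization is applied per
dataset before merging (assay scales differ; no re-scaling across
datasets), and the orientation flag is recorded per dataset. Training
tables keep only guides targeting genes expected to show a phenotype and
drop guides with more than one perfect genomic match (match counts are an
input).

## The two-stage model

Stage one fits a LightGBM regressor on sequence features (defaults: 111
leaves, min 199 samples per leaf, learning rate 0.01, 5000 trees — the
hyperparameters tuned at production scale). Stage two fits a second
ensemble (8 leaves, min 137 samples) on the stage-one *residuals* using
target features, making combined scores exactly additive:
`predict(seq, tgt) = predict(seq) + residual_model(tgt)`. No early
stopping is used (fixed tree count). Training is single-threaded and
deterministic given the seed (`deterministic=True, n_jobs=1`); multi-
threaded training is possible but not used by the tests.

Cross-validation groups rows by gene (no gene straddles train and test —
asserted) and stratifies by dataset source via
`StratifiedGroupKFold(shuffle=True)`. Hyperparameter search draws
`num_leaves` and `min_child_samples` log-uniformly from [8, 256] over 50
trials by default, scoring each trial by mean cross-validated Spearman
(the evaluation metric used throughout); the sampler is a seeded random
sampler and the full trial log is returned. Attributions use LightGBM's
native TreeSHAP (`pred_contrib`), which satisfies local accuracy
(base + Σ attributions = prediction) to machine precision.

Model bundles persist as a directory of text files (two LightGBM model
dumps plus a JSON with schemas, hyperparameters, tracr vocabulary, and
seed); a round-trip reproduces predictions bit-identically.

## tracrRNA difference analysis

Screens of the same spacers with different scaffolds are paired by exact
spacer match; the difference is Δz = z_Hsu − z_other on per-screen
z-scores. Spacers are binned by G/T content of positions 17–20 into
{G&T, G only, T only, neither} and by (nT, nG) counts. Contrasts
mean(G&T) − mean(T only) and mean(G only) − mean(neither) are tested with
a two-sided Welch t-test by default (Mann-Whitney behind a flag) — the
test family is a package choice. Junction features scan the concatenated
transcript window (last 4 spacer nt + first 6 scaffold nt by default) for
the maximum T-run; the terminator flag fires at runs ≥ 4. The capture
regression is OLS of the direct-capture vs gDNA log2 fold change on nT
and nG with an intercept and normal-theory 95% CIs; a rank-deficient
design raises an error.

## Synthetic-data generator

The generator defines the study conditions for all end-to-end tests.
Planted activity for guide *i*:

  a_i = β_G20(tracr)·1[G at spacer pos 20]
      + β_polyT · nT₁₇₋₂₀ · (1 − g)^{nG₁₇₋₂₀} · 1[scaffold = Hsu]
      + β_MFE · ΔG_MFE + gene effect + ε

with defaults β_G20 = 0.5 (Hsu) / 0.15 (Chen), β_polyT = −0.3 per T,
attenuation g = 0.8 per G, β_MFE = 0.1 (kcal/mol)⁻¹, gene effects
N(0, 0.5²), ε ~ N(0, 0.3²). The (1 − g)^{nG} factor implements the
mechanism the difference analysis is designed to detect — G's interrupt
the T-dependent termination signal; setting g = 0 recovers a plain per-T
penalty (used when testing slope recovery). With these defaults the
closed-form presence-bin contrasts are G&T − T-only = 0.55 and
G-only − neither = 0.15 on the raw activity scale, i.e. the generator
plants a difference structure of realistic magnitude. Sequence effects
are centered across the library (activities are z-like; a designed
library is not globally depleted). Paired screens share gene effects (the
same genes are screened) but draw independent measurement noise.

Counts: guide abundance in the pool is lognormal (σ = 0.5, normalized to
mean 1); expected dropout LFC is −a_i for essential-gene guides and 0
otherwise; pDNA and three replicate samples are negative-binomial with
size 10 (typical screen overdispersion; configurable) at a default depth
of 1000 reads per guide. Annotation bundles use random 50–500 aa
proteins, 2–6 domain intervals per gene, and conservation tracks elevated
inside domains with ~5% missing positions. Direct-capture counts multiply
gDNA abundance by exp(γ·nT + δ·nG), defaults γ = −0.5, δ = 0.19 (natural
log), emulating T-dependent expression attenuation.

What the generator does **not** emulate: off-target effects, copy-number
artifacts, guide-level toxicity unrelated to the target, position-specific
base preferences beyond the planted terms, batch effects, or read-level
error. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes, not that the defaults match any particular
laboratory dataset.

## Problem sizes and evaluation choices

End-to-end recovery runs use 200 genes × 25 guides with the default
effect sizes and 500 boosted trees — large enough for stable per-gene
rank statistics while keeping the full suite fast on a laptop-class
machine. Recovery is measured on the generated activity records (the
conditions the effect-size defaults define); the count layer is exercised
separately, where NB overdispersion (size 10) adds roughly 0.5 log2 units
of LFC noise per guide and correspondingly caps within-gene
prediction-observation correlation — the G20-by-tracr interaction
contrast survives that layer and is asserted on both paths. Whole-library
ROC-AUC is not a meaningful statistic under the centered-activity LFC
link (half the essential guides sit near zero effect), so screen-level
detection is reported for essential guides with positive planted
activity, alongside compact-library SSMDs (top-score vs random picking).

## Known limitations

- The builtin folding energies are ordinal, not calibrated physical
  free energies.
- The Rule-set-2-era feature block is a reconstruction behind a versioned
  schema, not a byte-exact replica of any published feature vector.
- Quintile calibration uses global prediction bins against per-gene
  observed quintiles; with few genes the diagonal is not exactly 100%
  even for perfect predictions (bin boundaries differ by sampling).
- Tie handling in rank-based statistics uses average ranks with
  fixed-boundary cuts throughout.
- Hyperparameter search uses a seeded random sampler; a TPE-style sampler
  can be plugged in but is not bundled.
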