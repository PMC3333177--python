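# Methods

This note documents the models, conventions and numerical choices behind
`exomotif`, and what the synthetic-data experiments do and do not demonstrate.

## ECER stratification

The exosome-to-cell expression ratio of a transcript is the ratio of its
compartment means across the two technical replicates (mean-then-ratio; the
alternative ratio-then-mean is sensitive to a single low cell replicate).
Filtering keeps transcripts with mean exosomal intensity strictly above 100
intensity units and with *concordant* replicates. Concordance is not uniquely
defined by a replicate pair; we operationalize it as the two replicate-wise
ratios `exo_i / cell_i` lying within a configurable fold of each other
(default 2). Transcripts whose cellular mean falls below a detection
threshold (default 1.0 intensity unit, configurable) while they pass the
exosomal filter are *exosome-specific*; concordance is vacuous for them.

Bins are half-open `[low, high)` with edges 0.75, 1.5, 2, 3, 5, 9, 17, 33, ∞.
The listed boundaries touch, so half-openness is required for a disjoint
cover; the ">33" bin is `[33, ∞)`. ECER below 0.75 is `unassigned`.
Exosome-specific transcripts form their own partition and are excluded from
bin-ordered correlation statistics by default; a flag merges them into ">33".

## Motif statistics

Motifs are unambiguous strings over {A,C,G,U}; IUPAC ambiguity codes in a
sequence never match any motif position (conservative). Occurrences are
counted with overlaps — necessary for homopolymer and repeat analysis — and a
non-overlapping mode exists as a config alternative.

The relative position of an occurrence is `start / (L − k)`, so the first and
last possible starts map exactly to 0 and 1; a sequence of length `k` maps to
0.5. Location skewness is the population Fisher–Pearson `g1` over the
*pooled* relative positions of all occurrences in a partition (0 when there
are none or the variance vanishes); per-transcript-then-averaged skewness is
a possible alternative that we did not adopt because it weights transcripts
with single occurrences equally with dense repeats. Under this convention
positive skewness means 5′-clustered sites and negative means 3′-clustered.

Counting is vectorized: each sequence is integer-encoded once, rolling k-mer
codes (with an ambiguity validity mask) feed `numpy.bincount` accumulators of
size `4^k` for counts, containment, mRNA containment and the first three
raw moments of relative position, from which fraction, skewness and mRNA
share for all `4^k` motifs are derived at once. A reference per-motif scan
path (`motif_partition_stats`) implements the same definitions independently
and the two are cross-checked in the test suite.

### Enrichment (Pm / Ps)

The chance of a motif at a single window under a background composition
`(p_A, p_C, p_G, p_U)` is the product of its base frequencies. Expected
occurrences are `Σ_seq (L − k + 1) · p_motif`; expected containing counts are
`Σ_seq [1 − (1 − p_motif)^(L − k + 1)]`. Observed and expected (rounded
half-up — Fisher needs integer tables) enter two-sided Fisher tests against
the window and sequence totals respectively; p-values across a tested family
are BH-FDR corrected. The background defaults to the pooled composition of
the analyzed partition; per-sequence composition is a config alternative.

### Correlations with secretion and half-life

Secretion association is Kendall `τ_b` between the 8 ordered bins and a
motif's per-bin containing fraction (bin-level). Half-life association is, by
default, also bin-level: `τ_b` between the per-bin containing fraction and
the per-bin median half-life of a cell type. A transcript-level variant
(binary presence against per-transcript half-life) is provided, but note its
tie correction bounds |τ| by `sqrt(n_present·n_absent / C(n,2))` — about 0.45
even under perfect separation for a minority motif — so threshold chains in
the 0.4–0.7 range are only meaningful on the bin-level statistic.

### Rank-change selection

Both reference partitions rank all motifs by descending occurrence count;
the rank delta (control minus enriched) flags the strongest risers. Ties take
average ranks: with competition or lexicographic tie-breaking the rank of
never-observed motifs would depend on their alphabet position, and at desk
scale most of the `4^8` universe is unobserved. Output ties in delta are
broken lexicographically for determinism.

## Selection chains

Defaults, all configurable: short-motif classes need location-skewness
magnitude > 0.6 and containing fraction > 15 % in a reference partition plus
enrichment over the opposite reference. Secretion-specific stage 1 needs
|τ_secretion| ≥ 0.7 and |τ_half-life| ≥ 0.4 in at least one cell type (the
"significant in one cell type" reading is a deliberate choice — divergent
cell-type behaviour is itself informative and is reported per cell type).
Stage 2 adds τ_secretion > 0, eRNA occupancy > 10 % and |skewness| > 0.2,
with the skew direction annotated 5′/3′ at the ±0.2 cutoff.

Co-occurrence is an exact Venn decomposition over the selected motifs'
containment sets. The combination-enrichment null fixes each motif's
single-containment count and draws the sets as independent uniform subsets of
the partition, which reduces the joint intersection to a chain of
hypergeometric draws; the add-one Monte-Carlo estimate
`(1 + hits) / (1 + draws)` is conservative and never returns 0.

## Profiles

The 100-bin identity function follows a three-step procedure: residues of
each sequence are binned on that sequence's *ungapped* span
(`bin = floor(100·i/L)`, residue `L−1` clamped into bin 99); each residue
scores the fraction of the other sequences aligned to its column (coverage
mode: any non-gap; identity mode: the same nucleotide — both are emitted,
identity ≤ coverage bin-wise); per-sequence bin means are then stacked and
averaged. Bins with no residues for a short sequence are excluded from the
stack rather than zero-filled. The alignment itself is an input file; no
aligner is bundled.

Motif density is a Gaussian kernel mixture over occurrence relative
positions, each kernel truncated to [0, 1] and renormalized by its truncated
mass, evaluated at the 100 bin midpoints and discretely normalized so the bin
mean is exactly 1. The default bandwidth 0.05 (5 % of transcript length)
smooths adjacent-bin noise without erasing the 5′/3′ asymmetry; it is a
config knob, not an assertion about any prior analysis.

## Structure windows

Each 8-mer occurrence is expanded by 46-nt flanks into a 100-nt window;
occurrences closer than a flank to a transcript end are skipped by default
(clipping is available, with the true length recorded). Windows whose region
midpoint lies in the relative span 0.7–1.0 — where the secretion motifs
concentrate — are ranked by free energy.

Folding uses the ViennaRNA bindings when requested (dangle model 2, MFE and
partition-function centroid structures), but the default engine is a
deterministic Nussinov-style maximum-base-pairing dynamic program
(Watson–Crick plus G·U, minimum hairpin loop of 3, energy = −pairs, ties
broken toward leaving the 3′ base unpaired then the smallest pairing
partner). Thermodynamics is not this package's contribution; the fallback
keeps every code path testable and is verified against exhaustive structure
enumeration on short sequences. "Predominant structure" replaces by-eye
inspection with exact grouping of the dot-bracket pattern over the motif ± 2
positions — a deliberately strict surrogate: with it, pattern frequencies are
reproducible but lower than a human's tolerant visual clustering would give.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
ground truth for every planted feature:

* **Sizes.** Default 400 transcripts per bin (plus 50 exosome-specific) —
  comparable to the per-bin sizes of a real stratified microarray set while
  keeping the full pipeline in the tens of seconds on one CPU.
* **Lengths** log-normal, median 800 nt (σ_log 0.45): short enough for fast
  exhaustive scans, long enough for 100-nt structure windows and meaningful
  relative-position statistics.
* **Composition.** G/C excess 0.15 over the 5′ third, A excess 0.12 over the
  3′ third; poly(A) tails (geometric length, mean 50 nt) on 65 % of mRNAs.
  mRNA fraction declines linearly 0.95 → 0.80 across the bins.
* **Expression.** True ECER is drawn inside the bin bounds (log-uniform on
  [33, 330] for the top bin), cellular intensity log-normal (median 500), the
  exosomal intensity derived as `cell × ECER`, and both duplicated with
  multiplicative noise of CV 0.1 — so true bins are known by construction and
  measured bins differ only through replicate noise.
* **Half-life** log-normal (median 8 h, σ_log 0.8) with scale declining
  log-linearly across the bin index so that the cell-reference /
  eRNA-reference mean ratio equals the configured secretion factor (1.8 for
  B-cells, 1.3 for fibroblasts); 90 % of transcripts carry half-life records.
  The graded decline (rather than a single offset on the top bin) encodes a
  monotone secretion–decay association, which is what the bin-level τ
  statistic detects.
* **Planting** overwrites bases in place (no insertion), keeping lengths and
  gradients intact, at a uniform position inside a relative interval
  (default [0.7, 1.0]) with collision-free placement. A motif may carry a
  linear plant-probability ramp across the bins (peak in >33) — modelling
  occupancy that tracks secretion, which is the signal the τ-based selection
  is designed to detect; a single-bin planting caps bin-level τ at 0.5
  because the seven background bins are mutually tied. An `exclusive` flag
  scrubs chance occurrences outside planted sites for clean rank-change
  recovery. A joint-plant rule inserts several motifs into the same
  transcripts of one bin to create a known Venn overlap.
* **Determinism.** All randomness flows from one seed through named
  substreams (class, length, sequence, planting, expression, half-life);
  identical config + seed reproduce byte-identical files.

### What passing the synthetic experiments shows — and what it does not

Recovery of the planted motifs demonstrates that the statistics and threshold
chains detect a secretion-tracking, 3′-clustered, co-occurring motif signal
of the configured effect size at desk scale, and that every stage composes
correctly. It does not validate the biological claim on real measurements:
the generator has no probe-level effects, cross-hybridization, shared
transcript families/paralogy, UTR/CDS architecture, or dependence between
composition and class beyond the modelled gradients, and its noise is purely
multiplicative log-normal. Real microarray data also require the
accession-specific loaders (supported, but consumed as-is — no normalization
or background correction is applied).

## Numerical conventions and degenerate inputs

* Zero-variance skewness, constant-variable Kendall τ, and empty-occurrence
  densities all return 0 (or a zero profile) rather than NaN.
* Fisher's exact test is two-sided by the probability-mass criterion; an
  all-zero table is an error, a zero margin gives p = 1.
* Exact Mann-Whitney enumeration is used for pooled sizes ≤ 12 (midranks for
  ties), the tie-corrected normal approximation beyond. The bootstrap
  stopping rule starts checking at round 3 (the SD is undefined at one round
  and degenerate at two) and uses the sample SD of all rounds so far;
  subsampling is without replacement by default.
* Expected counts are rounded half-up for Fisher tables; q-values are
  monotone step-up BH.
* The bootstrap "fixed 100" rule uses the full sample when it is smaller
  than 100.

## Problem sizes

Test-suite and acceptance runs use 400 transcripts per bin (the generator
default), the full 4^8 motif universe for selection statistics, k ≤ 5 for
exhaustive short-motif tables, 10 000 Monte-Carlo draws for combination
enrichment, and up to 400 folded windows per run. Oracle equivalence tests
run exhaustively where enumeration is tractable (all 2×2 tables with small
totals, all structures of short windows) and on seeded random instances
beyond that.

## Known limitations

* The identity function's interaction of very short sequences with 100 bins
  leaves some bins empty per sequence; they are excluded from the stack,
  which slightly biases profiles of alignments with drastically different
  ungapped lengths.
* The combination-enrichment null conditions on single-motif counts only;
  correlated containment through composition (e.g. two GC-rich motifs) is not
  part of the null and can inflate significance.
* The pair-maximization fallback ignores stacking energetics; its energies
  are comparable only within the fallback, never against kcal/mol values.
* Transcript-level half-life τ is reported but, as noted, bounded well below
  the default thresholds for minority motifs; use the bin-level statistic for
  selection.
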