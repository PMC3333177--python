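# exomotif

Exhaustive discovery of short linear sequence motifs enriched in
exosome-secreted RNAs (eRNAs) — candidate *cis*-acting "secretory zipcode"
elements that may target transcripts to exosome nano-vesicles.

Cells load a selective subset of their transcriptome into exosomes, and some
transcripts are found only in the vesicles, implying sequence-encoded sorting.
`exomotif` implements the full analysis chain used to look for that signal in
expression data from paired exosome/cell microarray measurements:

1. **ECER stratification.** For each transcript the exosome-to-cell expression
   ratio `ECER = mean(exosome replicates) / mean(cell replicates)` is
   computed; transcripts with mean exosomal intensity above 100 and concordant
   replicates are stratified into eight half-open bins
   (0.75–1.5, 1.5–2, 2–3, 3–5, 5–9, 9–17, 17–33, >33) whose span doubles from
   bin to bin, plus an *exosome-specific* group (detected in exosomes only).
   The 0.75–1.5 bin is the cell-enriched reference, >33 the eRNA reference.
2. **Exhaustive k-mer statistics.** Every motif over {A,C,G,U} of length 1–8
   (87 380 in total) is scored per bin: occurrence count, fraction of
   transcripts containing it, mRNA share among carriers, and the skewness
   `g1 = m3 / m2^{3/2}` of its relative-position distribution
   (`rel_pos = start / (L − k)`; positive g1 = 5′-clustered). Enrichment over
   a composition-matched random motif is tested with Fisher's exact test
   (occurrence-level *Pm* and transcript-level *Ps*), BH-FDR corrected.
3. **Secretion-specific selection.** Kendall `τ_b` between a motif's per-bin
   containing fraction and the bin order (secretion), and between that
   fraction and the per-bin median RNA half-life, feed a two-stage filter:
   stage 1 keeps |τ_secretion| ≥ 0.7 and |τ_half-life| ≥ 0.4; stage 2 adds
   τ_secretion > 0, eRNA occupancy > 10 % and |skewness| > 0.2. Rank-change
   between the eRNA and reference occurrence rankings flags the strongest
   risers, and the co-occurrence of selected motifs is quantified as an exact
   Venn decomposition with a Monte-Carlo enrichment p-value.
4. **Profiles and structure.** Motif positions are smoothed into a 100-bin
   density on the relative axis; a precomputed multiple alignment can be
   summarized by the 100-bin identity function; and 100-nt motif-centered
   windows (46-nt flanks) are folded — by ViennaRNA when available, or by a
   built-in base-pair-maximization fallback — to find the predominant local
   fold of each motif.

A first-class synthetic data generator emulates the assumed statistics
(declining mRNA fraction, secretion-associated half-life decline, 5′-GC /
3′-poly(A) composition gradients) and plants motifs with known positions and
co-occurrence, so the entire chain is testable against ground truth.

## Worked example

```python
from exomotif import pipeline

cfg = pipeline.PipelineConfig(
    seed=7,
    simulate={"recovery_scenario": True, "n_per_bin": 150},
    structure_enabled=False,
)
pipeline.run_all(cfg, "scratch/example_selection")
print(open("scratch/example_selection/summary.txt").read())
```

prints (abridged):

```
ECER partition sizes:
            0.75-1.5: 150
               1.5-2: 139
                 ...
                 >33: 158
    exosome_specific: 18

secretion-specific selection: 763 stage-1, 4 stage-2 motifs
  UAAUCCCA  tau_ecer=+0.857  frac(eRNA)=0.272  skew=-2.693
  ACCAGCCU  tau_ecer=+0.909  frac(eRNA)=0.215  skew=-2.562
  CCAGCCUA  tau_ecer=+0.857  frac(eRNA)=0.120  skew=-1.426
  AACCAGCC  tau_ecer=+0.786  frac(eRNA)=0.114  skew=-1.586

co-occurrence of UAAUCCCA, ACCAGCCU, CCAGCCUA: 7 transcripts with all,
62 with any (enrichment p=9.999e-05)
```

The three planted secretion motifs rise with the ECER bins
(τ_secretion ≈ +0.9), anti-correlate with half-life, sit in the 3′ tract of
their carriers, and overlap in the same transcripts far more often than
independent sets of the same sizes would (Monte-Carlo p ≈ 1e-4) — the
signature of a combinatorial secretion signal.

The `examples/` directory holds one short script per capability
(simulation, partitioning, exhaustive scan, selection/co-occurrence,
profiles/folding); each prints the numbers it computes with a line on what
they mean. A thin CLI mirrors the stages:
`exomotif run-all -c config.yaml -w workdir`, plus `simulate`, `partition`,
`scan`, `select`, `profile`, `structure` and `report` subcommands.

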