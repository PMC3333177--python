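"""Stratify transcripts by exosome-to-cell expression ratio (ECER).

Transcripts with mean exosomal intensity above 100 and concordant replicates
are binned into 0.75-1.5 ... >33; the first bin is the cell-enriched
reference, the last the exosome-enriched (eRNA) reference.
"""

from exomotif import simulate
from exomotif.ecer import assign_partitions, compute_ecer, filter_transcripts

ds = simulate.generate(simulate.default_recovery_config(seed=7, n_per_bin=50))

results = [compute_ecer(p) for p in ds.profiles.values()]
kept, report = filter_transcripts(results)
print(f"kept {report.n_kept}/{report.n_input} transcripts "
      f"({report.n_low_expression} below the expression cutoff, "
      f"{report.n_discordant} replicate-discordant)")

for part in assign_partitions(kept):
    if part.size == 0:
        continue
    mrna = sum(
        1 for t in part.members if ds.records[t].txclass.value == "mRNA"
    )
    print(f"  ECER {part.label:>18}: {part.size:4d} transcripts, "
          f"{100 * mrna / part.size:5.1f}% mRNA")

print("\nThe mRNA share declines toward the secreted bins: long noncoding "
      "RNAs are over-represented among exosome-enriched transcripts.")
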