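"""Exhaustive 8-mer statistics: occupancy, positional skewness, rank change.

Every 8-mer is counted in the cell-enriched and exosome-enriched reference
partitions; motifs rising most in the eRNA occurrence ranking are candidate
secretion signals.
"""

import numpy as np

from exomotif import simulate
from exomotif.kmers import build_kmer_table, index_to_motif, rank_change_selection

ds = simulate.generate(simulate.default_recovery_config(seed=7, n_per_bin=50))

cell_ids = ds.true_members("0.75-1.5")
erna_ids = ds.true_members(">33")
cell = build_kmer_table([ds.records[t] for t in sorted(cell_ids)], k=8)
erna = build_kmer_table([ds.records[t] for t in sorted(erna_ids)], k=8)

names = np.array([index_to_motif(i, 8) for i in range(4**8)])
frac = erna.frac_containing
order = np.argsort(-frac)[:5]
print("most common 8-mers in the eRNA reference (fraction containing, skewness):")
for i in order:
    print(f"  {names[i]}: {frac[i]:.2f}  skew={erna.skewness[i]:+.2f}")
print("(poly(A) tracts dominate raw occupancy; skewness <0 marks 3'-clustered sites)")

rank = rank_change_selection(
    dict(zip(names, erna.counts.astype(float))),
    dict(zip(names, cell.counts.astype(float))),
    top_n=5,
)
print("\ntop rank-change risers (enriched in eRNAs relative to cell-bound RNAs):")
for m, delta in rank:
    print(f"  {m}: rank delta {delta:+.0f}")
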