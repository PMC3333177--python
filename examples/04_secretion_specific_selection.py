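"""Select secretion-specific 8-mers and analyze their co-occurrence.

Runs the pipeline end to end on a synthetic dataset with the three planted
secretion motifs, then shows the two-stage threshold chain
(|tau_secretion| >= 0.7 and |tau_halflife| >= 0.4; then positive secretion
correlation, >10% eRNA occupancy, |skewness| > 0.2) and the Venn overlap of
the selected motifs.
"""

import json
from pathlib import Path

import pandas as pd

from exomotif import pipeline

workdir = Path("scratch/example_selection")
cfg = pipeline.PipelineConfig(
    seed=7,
    simulate={"recovery_scenario": True, "n_per_bin": 150},
    structure_enabled=False,
)
pipeline.run_all(cfg, workdir)

sel = pd.read_csv(workdir / "selection.tsv", sep="\t")
print(f"{int(sel.stage1.sum())} 8-mers pass stage 1, "
      f"{int(sel.stage2.sum())} pass all four stage-2 criteria:")
for r in sel[sel.stage2].itertuples(index=False):
    print(f"  {r.motif}: tau_secretion={r.tau_ecer:+.2f}, "
          f"tau_halflife(fibro)={r.tau_halflife_fibroblast:+.2f}, "
          f"eRNA fraction={r.frac_erna:.2f}, skew={r.skew_erna:+.2f}")

venn = json.loads((workdir / "venn.json").read_text())
print(f"\nco-occurrence in the >33 partition ({venn['partition_size']} transcripts):")
print(f"  any of {', '.join(venn['motifs'])}: {venn['n_any']}")
print(f"  all three jointly: {venn['n_all']} "
      f"(Monte-Carlo enrichment p = {venn['combination_enrichment_p']:.2g})")
print("A joint overlap far above the independent-sets expectation indicates "
      "a combinatorial secretion signal.")
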