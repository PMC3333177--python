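"""Threshold chains for motif classification, secretion-specific selection,
and motif co-occurrence (Venn) analysis.

Two chains are implemented:

* short-motif classification against the two reference partitions — a motif is
  *eRNA-associated* when its location skewness magnitude exceeds 0.6, the
  fraction of eRNA-partition transcripts containing it exceeds 15%, and that
  fraction is higher than in the cell-enriched reference (mirrored for
  *intracellular-associated*);
* secretion-specific 8-mer selection — stage 1 keeps motifs whose bin-level
  secretion correlation magnitude is at least 0.7 and whose half-life
  correlation magnitude is at least 0.4 in at least one cell type; stage 2
  additionally requires a positive secretion correlation, a containing
  fraction above 10% in the eRNA partition, and a location skewness magnitude
  above 0.2 there.  Skew direction is annotated as 5' (> +0.2) or 3' (< -0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SelectionThresholds:
    min_abs_skewness: float = 0.6
    min_frac_containing: float = 0.15
    min_abs_tau_secretion: float = 0.7
    min_abs_tau_halflife: float = 0.4
    skew_5prime_cutoff: float = 0.2
    min_frac_final: float = 0.10


def classify_short_motifs(
    stats: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.Series:
    """Label motifs as eRNA_associated / intracellular_associated / unclassified.

    ``stats`` is indexed by motif with columns ``frac_erna, skew_erna,
    frac_cell, skew_cell`` holding the containing fraction and location
    skewness in the exosome-enriched (>33) and cell-enriched (0.75-1.5)
    reference partitions.
    """
    required = {"frac_erna", "skew_erna", "frac_cell", "skew_cell"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing reference-partition columns: {sorted(missing)}")
    t = thresholds
    erna = (
        (stats["skew_erna"].abs() > t.min_abs_skewness)
        & (stats["frac_erna"] > t.min_frac_containing)
        & (stats["frac_erna"] > stats["frac_cell"])
    )
    intra = (
        (stats["skew_cell"].abs() > t.min_abs_skewness)
        & (stats["frac_cell"] > t.min_frac_containing)
        & (stats["frac_cell"] > stats["frac_erna"])
    )
    labels = pd.Series("unclassified", index=stats.index, name="label")
    labels[erna] = "eRNA_associated"
    labels[intra] = "intracellular_associated"
    return labels


def _skew_direction(skew: float, cutoff: float) -> str:
    if skew > cutoff:
        return "5prime"
    if skew < -cutoff:
        return "3prime"
    return "none"


def select_secretion_specific(
    stats: pd.DataFrame,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Two-stage secretion-specific motif selection.

    ``stats`` is indexed by motif with columns ``tau_ecer``, one or more
    ``tau_halflife_*`` columns, ``frac_erna`` and ``skew_erna``.  Returns a
    copy with boolean ``stage1``/``stage2`` columns and a ``skew_direction``
    annotation; stage-2 passers are always a subset of stage-1 passers.
    """
    t = thresholds
    hl_cols = [c for c in stats.columns if c.startswith("tau_halflife")]
    if "tau_ecer" not in stats.columns or not hl_cols:
        raise ValueError("stats must carry tau_ecer and tau_halflife_* columns")
    out = stats.copy()
    hl_ok = (
        out[hl_cols].abs().max(axis=1).fillna(0.0) >= t.min_abs_tau_halflife
    )
    out["stage1"] = (out["tau_ecer"].abs() >= t.min_abs_tau_secretion) & hl_ok
    out["skew_direction"] = [
        _skew_direction(s, t.skew_5prime_cutoff) for s in out["skew_erna"]
    ]
    out["stage2"] = (
        out["stage1"]
        & (out["tau_ecer"] > 0)
        & (out["frac_erna"] > t.min_frac_final)
        & (out["skew_erna"].abs() > t.skew_5prime_cutoff)
    )
    return out


@dataclass
class CooccurrenceReport:
    """Exact Venn decomposition of motif-containing transcript sets."""

    motif_set: list[str]
    region_counts: dict[frozenset[str], int]
    n_any: int
    n_all: int
    single_counts: dict[str, int] = field(default_factory=dict)
    all_members: set[str] = field(default_factory=set)


def cooccurrence(
    motifs: Sequence[str], containment: Mapping[str, set[str]]
) -> CooccurrenceReport:
    """Venn region counts for 2-6 motif-containing transcript sets.

    ``region_counts`` maps every nonempty motif subset to the number of
    transcripts contained by exactly that subset; regions are disjoint and sum
    to the union size ``n_any``.
    """
    motifs = list(motifs)
    if not 2 <= len(motifs) <= 6:
        raise ValueError("cooccurrence expects 2-6 motifs")
    sets = {m: set(containment.get(m, set())) for m in motifs}
    union = set().union(*sets.values())
    regions: dict[frozenset[str], int] = {
        frozenset(sub): 0
        for r in range(1, len(motifs) + 1)
        for sub in combinations(motifs, r)
    }
    for tid in union:
        key = frozenset(m for m in motifs if tid in sets[m])
        regions[key] += 1
    inter = set.intersection(*sets.values()) if sets else set()
    return CooccurrenceReport(
        motif_set=motifs,
        region_counts=regions,
        n_any=len(union),
        n_all=len(inter),
        single_counts={m: len(s) for m, s in sets.items()},
        all_members=inter,
    )


def combination_enrichment(
    report: CooccurrenceReport,
    partition_size: int,
    seed: int = 0,
    n_draws: int = 10000,
) -> float:
    """Monte-Carlo p-value for an excess full-overlap count.

    The null fixes each motif's single-containment count and draws the motif
    sets as independent uniform subsets of ``partition_size`` transcripts; the
    joint intersection then follows a chain of hypergeometric draws.  The
    returned p is ``(1 + #draws with intersection >= observed) / (1 + n_draws)``
    and is deterministic for a given seed.
    """
    if partition_size < report.n_any:
        raise ValueError("partition_size smaller than observed union")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    sizes = [report.single_counts[m] for m in report.motif_set]
    rng = np.random.default_rng(seed)
    cur = np.full(n_draws, sizes[0], dtype=np.int64)
    for s in sizes[1:]:
        cur = rng.hypergeometric(cur, partition_size - cur, s)
    hits = int(np.count_nonzero(cur >= report.n_all))
    return (1 + hits) / (1 + n_draws)
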