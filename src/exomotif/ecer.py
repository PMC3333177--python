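"""Exosome-to-cell expression ratio (ECER) computation and stratification.

The ECER of a transcript is its mean exosomal intensity divided by its mean
cellular intensity across the two technical replicates (mean-then-ratio, not
ratio-then-mean).  Transcripts whose cellular signal falls below a detection
threshold while they still pass the exosomal expression filter are labelled
*exosome-specific*.  Filtered transcripts are stratified into eight half-open
ECER bins — 0.75-1.5, 1.5-2, 2-3, 3-5, 5-9, 9-17, 17-33 and >33 — whose span
doubles from bin to bin; 0.75-1.5 serves as the cell-enriched reference and
>33 as the exosome-enriched (eRNA) reference set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dataio import ExpressionProfile

logger = logging.getLogger("exomotif.ecer")

#: Ordered labels of the eight numeric ECER bins, ascending.
BIN_LABELS: tuple[str, ...] = (
    "0.75-1.5", "1.5-2", "2-3", "3-5", "5-9", "9-17", "17-33", ">33",
)
#: Half-open bin edges; ">33" is [33, inf).
BIN_EDGES: tuple[float, ...] = (0.75, 1.5, 2.0, 3.0, 5.0, 9.0, 17.0, 33.0, math.inf)

EXOSOME_SPECIFIC = "exosome_specific"
UNASSIGNED = "unassigned"

#: Reference partitions: cell-enriched and exosome-enriched (eRNA).
CELL_REFERENCE = BIN_LABELS[0]
ERNA_REFERENCE = BIN_LABELS[-1]


class UndefinedRatioError(ValueError):
    """Both compartment means are zero; the ECER is undefined."""


@dataclass(frozen=True)
class EcerResult:
    id: str
    ecer: float | None  # None == exosome-specific
    mean_exo: float
    mean_cell: float
    concordant: bool

    @property
    def exosome_specific(self) -> bool:
        return self.ecer is None


@dataclass
class EcerPartition:
    label: str
    bounds: tuple[float, float]  # [low, high) on the ECER axis
    members: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_kept: int
    n_low_expression: int
    n_discordant: int


def compute_ecer(
    profile: ExpressionProfile,
    detection_threshold: float = 1.0,
    concordance_fold: float = 2.0,
) -> EcerResult:
    """Compute the ECER of one expression profile.

    ``ecer`` is ``mean_exo / mean_cell`` when the cellular mean reaches
    ``detection_threshold`` and ``None`` (exosome-specific) otherwise.
    Concordance requires the two replicate-wise ratios ``exo_i / cell_i`` to be
    within ``concordance_fold`` of each other; it is vacuously true for
    exosome-specific transcripts and false when exactly one cellular replicate
    is zero (the replicate ratios then disagree maximally).
    """
    mean_exo, mean_cell = profile.mean_exo, profile.mean_cell
    if mean_exo == 0 and mean_cell == 0:
        raise UndefinedRatioError(f"{profile.id}: both compartment means are zero")
    if mean_cell < detection_threshold:
        return EcerResult(profile.id, None, mean_exo, mean_cell, concordant=True)
    if min(profile.cell) <= 0:
        concordant = False
    else:
        r1 = profile.exo[0] / profile.cell[0]
        r2 = profile.exo[1] / profile.cell[1]
        if min(r1, r2) <= 0:
            concordant = r1 == r2
        else:
            concordant = max(r1, r2) / min(r1, r2) <= concordance_fold
    return EcerResult(profile.id, mean_exo / mean_cell, mean_exo, mean_cell, concordant)


def filter_transcripts(
    results: Iterable[EcerResult],
    min_exo_expression: float = 100.0,
) -> tuple[list[EcerResult], FilterReport]:
    """Keep transcripts with mean exosomal expression above the cutoff and
    concordant replicate-wise ratios; report counts dropped by reason."""
    results = list(results)
    if not results:
        raise ValueError("empty ECER collection")
    kept: list[EcerResult] = []
    n_low = n_disc = 0
    for r in results:
        if not r.mean_exo > min_exo_expression:
            n_low += 1
        elif not r.concordant:
            n_disc += 1
        else:
            kept.append(r)
    report = FilterReport(len(results), len(kept), n_low, n_disc)
    logger.info(
        "filter_transcripts: kept %d/%d (low expression %d, discordant %d)",
        report.n_kept, report.n_input, n_low, n_disc,
    )
    return kept, report


def bin_label(ecer: float) -> str:
    """Map a numeric ECER onto its half-open bin label (``unassigned`` < 0.75)."""
    if ecer < BIN_EDGES[0]:
        return UNASSIGNED
    for label, low, high in zip(BIN_LABELS, BIN_EDGES[:-1], BIN_EDGES[1:]):
        if low <= ecer < high:
            return label
    return UNASSIGNED  # unreachable for finite ecer

def assign_partitions(
    results: Iterable[EcerResult],
    merge_exosome_specific: bool = False,
) -> list[EcerPartition]:
    """Stratify filtered ECER results into the eight numeric bins plus the
    ``exosome_specific`` and ``unassigned`` labels.

    With ``merge_exosome_specific`` the exosome-specific transcripts are folded
    into the ">33" bin instead of forming their own partition.
    """
    partitions = {
        label: EcerPartition(label, (low, high))
        for label, low, high in zip(BIN_LABELS, BIN_EDGES[:-1], BIN_EDGES[1:])
    }
    partitions[EXOSOME_SPECIFIC] = EcerPartition(EXOSOME_SPECIFIC, (math.inf, math.inf))
    partitions[UNASSIGNED] = EcerPartition(UNASSIGNED, (0.0, BIN_EDGES[0]))
    for r in results:
        if r.exosome_specific:
            label = ERNA_REFERENCE if merge_exosome_specific else EXOSOME_SPECIFIC
        else:
            label = bin_label(r.ecer)
        partitions[label].members.add(r.id)
    sizes = {p.label: p.size for p in partitions.values()}
    logger.info("assign_partitions: sizes %s", sizes)
    return list(partitions.values())


def partition_map(partitions: Sequence[EcerPartition]) -> dict[str, EcerPartition]:
    return {p.label: p for p in partitions}
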