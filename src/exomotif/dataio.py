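"""Input readers, sequence normalization and transcript classification.

All downstream stages work on RNA-alphabet sequences (``A C G U`` plus IUPAC
ambiguity codes) keyed by an opaque transcript identifier.  Four tabular/sequence
inputs are supported:

* expression TSV with header ``id, exo_1, exo_2, cell_1, cell_2`` — duplicate
  microarray intensities for the exosomal and cellular compartments;
* transcript FASTA (DNA or RNA alphabet; the ID is the first whitespace-delimited
  header token);
* annotation TSV ``id, class`` with class in ``{mRNA, ncRNA, unknown}``;
* optional half-life TSV ``id, half_life_h, cell_type``.

Coordinates are 0-based and half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("exomotif.dataio")

#: IUPAC nucleotide one-letter codes (RNA alphabet after normalization).
IUPAC_CODES = frozenset("ACGUNRYSWKMBDHV")

_WHITESPACE = str.maketrans("", "", " \t\r\n\v\f")


class MalformedSequenceError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide codes."""


class DuplicateIdError(ValueError):
    """An input table or FASTA contains the same transcript ID twice."""


class TxClass(str, Enum):
    MRNA = "mRNA"
    NCRNA = "ncRNA"
    UNKNOWN = "unknown"


def normalize_sequence(raw: str) -> str:
    """Uppercase, strip whitespace and convert to the RNA alphabet (T -> U).

    Ambiguity codes are preserved verbatim.  Raises
    :class:`MalformedSequenceError` naming the first offending position when a
    non-IUPAC character is present.  Idempotent.
    """
    if not raw:
        raise MalformedSequenceError("empty sequence")
    seq = raw.translate(_WHITESPACE).upper().replace("T", "U")
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_CODES:
            raise MalformedSequenceError(
                f"non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


def classify_transcript(accession: str) -> TxClass:
    """RefSeq-prefix classification: NM_/XM_ -> mRNA, NR_/XR_ -> ncRNA."""
    if not accession:
        raise ValueError("empty accession")
    if accession.startswith(("NM_", "XM_")):
        return TxClass.MRNA
    if accession.startswith(("NR_", "XR_")):
        return TxClass.NCRNA
    return TxClass.UNKNOWN


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    sequence: str
    txclass: TxClass = TxClass.UNKNOWN

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be nonempty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionProfile:
    """Duplicate intensities for one transcript in both compartments."""

    id: str
    exo: tuple[float, float]
    cell: tuple[float, float]

    def __post_init__(self) -> None:
        for v in (*self.exo, *self.cell):
            if not (v == v and v >= 0 and v != float("inf")):
                raise ValueError(f"{self.id}: intensities must be finite and >= 0")

    @property
    def mean_exo(self) -> float:
        return (self.exo[0] + self.exo[1]) / 2.0

    @property
    def mean_cell(self) -> float:
        return (self.cell[0] + self.cell[1]) / 2.0


@dataclass(frozen=True)
class HalfLifeRecord:
    id: str
    half_life: float  # hours
    cell_type: str  # "b_cell" | "fibroblast" | other

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError(f"{self.id}: half-life must be > 0")


@dataclass
class Dataset:
    """Joined inputs keyed by transcript ID.

    ``records`` only contains transcripts with a sequence; profiles without a
    sequence stay usable for expression-only stages and are listed in
    ``missing_sequence``.
    """

    profiles: dict[str, ExpressionProfile]
    records: dict[str, TranscriptRecord]
    half_lives: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_sequence: set[str] = field(default_factory=set)

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)


def _check_unique(ids: Iterable[str], source: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DuplicateIdError(f"duplicate transcript id {i!r} in {source}")
        seen.add(i)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: normalized RNA sequence}``."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateIdError(f"duplicate transcript id {rec.id!r} in {path}")
        out[rec.id] = normalize_sequence(str(rec.seq))
    return out


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_expression(path: str | Path) -> dict[str, ExpressionProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if df.empty:
        raise ValueError(f"empty expression table: {path}")
    _check_unique(df["id"], f"expression table {path}")
    return {
        row.id: ExpressionProfile(
            id=row.id,
            exo=(float(row.exo_1), float(row.exo_2)),
            cell=(float(row.cell_1), float(row.cell_2)),
        )
        for row in df.itertuples(index=False)
    }


def read_annotation(path: str | Path) -> dict[str, TxClass]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_unique(df["id"], f"annotation table {path}")
    return {
        tid: TxClass(cls) for tid, cls in zip(df["id"], df["class"])
    }


def read_halflife(path: str | Path) -> dict[str, dict[str, float]]:
    """Return ``{cell_type: {id: half_life_hours}}``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "cell_type": str})
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        rec = HalfLifeRecord(row.id, float(row.half_life_h), row.cell_type)
        table = out.setdefault(rec.cell_type, {})
        if rec.id in table:
            raise DuplicateIdError(
                f"duplicate half-life for {rec.id!r} / {rec.cell_type}"
            )
        table[rec.id] = rec.half_life
    return out


def load_inputs(
    expression: str | Path,
    fasta: str | Path | None = None,
    annotation: str | Path | None = None,
    halflife: str | Path | None = None,
) -> Dataset:
    """Read and join the four inputs on transcript ID.

    The explicit annotation column, when present, overrides accession-prefix
    inference so synthetic datasets can set classes directly.  Join statistics
    are logged; the join is order-independent.
    """
    profiles = read_expression(expression)
    seqs = read_fasta(fasta) if fasta is not None else {}
    classes = read_annotation(annotation) if annotation is not None else {}
    half_lives = read_halflife(halflife) if halflife is not None else {}

    records: dict[str, TranscriptRecord] = {}
    missing: set[str] = set()
    for tid in profiles:
        if tid in seqs:
            txc = classes.get(tid, classify_transcript(tid))
            records[tid] = TranscriptRecord(tid, seqs[tid], txc)
        else:
            missing.add(tid)
    n_orphan_seqs = len(set(seqs) - set(profiles))
    logger.info(
        "load_inputs: %d profiles, %d with sequence, %d sequence-missing, "
        "%d orphan sequences",
        len(profiles), len(records), len(missing), n_orphan_seqs,
    )
    return Dataset(
        profiles=profiles,
        records=records,
        half_lives=half_lives,
        missing_sequence=missing,
    )
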