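"""Motif-centered secondary-structure windows.

Each occurrence of an 8-mer (or any k-mer) is expanded into a window of
``flank`` nt upstream and downstream (default 46, i.e. 100-nt windows for
8-mers).  Windows are folded either by the ViennaRNA thermodynamic engine
(optional; MFE and centroid structures with free energies in kcal/mol, dangle
model d2 and partition function as in classic RNAfold ``-p -d2`` usage) or by
a built-in base-pair-maximization fallback: a Nussinov-style dynamic program
over Watson-Crick plus G·U wobble pairs with a minimum hairpin loop of 3
unpaired bases, reporting ``energy = -(number of pairs)``.  The fallback keeps
the whole module testable without the external engine.

"Predominant structure" summaries group folds by the exact dot-bracket pattern
over the motif plus two flanking positions on each side — an algorithmic
surrogate for by-eye structure comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .dataio import TranscriptRecord
from .kmers import MotifOccurrence

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3  # unpaired bases required inside a hairpin

ENGINE_FALLBACK = "pair_max_fallback"
ENGINE_THERMO = "external_thermo"


class EngineNotAvailableError(RuntimeError):
    pass


@dataclass(frozen=True)
class StructureWindow:
    transcript_id: str
    motif: str
    window_seq: str
    motif_offset: int  # index of the motif's first base within the window
    start: int  # window start on the transcript (0-based)
    region: tuple[float, float]  # relative start/end of the window on the transcript

    @property
    def region_midpoint(self) -> float:
        return (self.region[0] + self.region[1]) / 2.0


@dataclass(frozen=True)
class FoldResult:
    window: StructureWindow
    dot_bracket: str
    energy: float  # kcal/mol (thermo) or -(pair count) (fallback)
    engine: str
    structure_kind: str  # "mfe" | "centroid" | "maxpair"
    local_pattern: str  # dot-bracket over motif +- 2 positions


def extract_windows(
    occurrences: Iterable[MotifOccurrence],
    records: Mapping[str, TranscriptRecord],
    flank: int = 46,
    edge_policy: str = "skip",
) -> tuple[list[StructureWindow], int]:
    """Cut flank+k+flank windows around motif occurrences.

    Occurrences too close to a transcript end are skipped (default) or clipped
    to the available span; the number skipped is returned alongside.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if edge_policy not in {"skip", "clip"}:
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    windows: list[StructureWindow] = []
    n_skipped = 0
    for occ in occurrences:
        rec = records[occ.transcript_id]
        k = len(occ.motif)
        lo, hi = occ.start - flank, occ.start + k + flank
        if lo < 0 or hi > rec.length:
            if edge_policy == "skip":
                n_skipped += 1
                continue
            lo, hi = max(lo, 0), min(hi, rec.length)
        windows.append(
            StructureWindow(
                transcript_id=occ.transcript_id,
                motif=occ.motif,
                window_seq=rec.sequence[lo:hi],
                motif_offset=occ.start - lo,
                start=lo,
                region=(lo / rec.length, hi / rec.length),
            )
        )
    return windows, n_skipped


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def max_pair_fold(seq: str) -> tuple[str, int]:
    """Nussinov maximum base-pairing fold with loop >= 3; deterministic.

    Returns the dot-bracket string and the pair count.  Ties are broken by
    preferring to leave the right end unpaired, then the smallest pairing
    partner, which makes the traceback order-independent.
    """
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - MIN_LOOP):
                if _can_pair(seq[k], seq[j]):
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + dp[k + 1][j - 1] + 1
                    if cand > best:
                        best = cand
            dp[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        if dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            if _can_pair(seq[k], seq[j]):
                left = dp[i][k - 1] if k > i else 0
                if left + dp[k + 1][j - 1] + 1 == dp[i][j]:
                    structure[k], structure[j] = "(", ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return "".join(structure), dp[0][n - 1] if n else 0


def local_pattern(window: StructureWindow, dot_bracket: str, margin: int = 2) -> str:
    lo = max(window.motif_offset - margin, 0)
    hi = min(window.motif_offset + len(window.motif) + margin, len(dot_bracket))
    return dot_bracket[lo:hi]


def _thermo_fold(seq: str, kind: str) -> tuple[str, float]:
    try:
        import RNA  # ViennaRNA python binding
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise EngineNotAvailableError(
            "the ViennaRNA python binding is not installed; "
            "use engine='fallback' for the built-in pair-maximization fold"
        ) from exc
    md = RNA.md()
    md.dangles = 2
    fc = RNA.fold_compound(seq, md)
    struct, mfe = fc.mfe()
    if kind == "mfe":
        return struct, float(mfe)
    fc.exp_params_rescale(mfe)
    fc.pf()
    cstruct, _ = fc.centroid()
    return cstruct, float(fc.eval_structure(cstruct))


def fold_window(
    window: StructureWindow,
    engine: str = "fallback",
    kind: str = "mfe",
) -> FoldResult:
    """Fold one window; ``engine`` is ``"fallback"`` or ``"thermo"``.

    With the fallback engine ``kind`` is ignored and the structure kind is
    reported as ``"maxpair"``.
    """
    seq = window.window_seq
    if engine == "fallback":
        db, pairs = max_pair_fold(seq)
        return FoldResult(window, db, -float(pairs), ENGINE_FALLBACK, "maxpair",
                          local_pattern(window, db))
    if engine == "thermo":
        if kind not in {"mfe", "centroid"}:
            raise ValueError(f"unknown structure kind {kind!r}")
        db, energy = _thermo_fold(seq, kind)
        return FoldResult(window, db, energy, ENGINE_THERMO, kind,
                          local_pattern(window, db))
    raise ValueError(f"unknown engine {engine!r}")


@dataclass(frozen=True)
class PredominantPattern:
    motif: str
    pattern: str
    count: int
    frequency: float


@dataclass
class StructureSummary:
    ranked: list[FoldResult]  # ascending free energy within the region filter
    predominant: dict[str, PredominantPattern]  # per motif


def rank_and_summarize(
    folds: Sequence[FoldResult],
    region_filter: tuple[float, float] = (0.7, 1.0),
) -> StructureSummary:
    """Rank folds by free energy within a relative region and summarize the
    most frequent local motif pattern per motif.

    Only windows whose region midpoint lies inside ``region_filter`` are kept
    (default [0.7, 1.0], the 3'-proximal span where the secretion-specific
    motifs concentrate).  Ties are broken by transcript ID then window start,
    making the ranking stable under permutation of the input.
    """
    if not folds:
        raise ValueError("rank_and_summarize requires at least one fold")
    lo, hi = region_filter
    kept = [f for f in folds if lo <= f.window.region_midpoint <= hi]
    ranked = sorted(
        kept, key=lambda f: (f.energy, f.window.transcript_id, f.window.start)
    )
    predominant: dict[str, PredominantPattern] = {}
    by_motif: dict[str, dict[str, int]] = {}
    for f in kept:
        by_motif.setdefault(f.window.motif, {}).setdefault(f.local_pattern, 0)
        by_motif[f.window.motif][f.local_pattern] += 1
    for motif, patterns in by_motif.items():
        total = sum(patterns.values())
        pattern, count = sorted(patterns.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        predominant[motif] = PredominantPattern(motif, pattern, count, count / total)
    return StructureSummary(ranked=ranked, predominant=predominant)


def write_dot_bracket(folds: Iterable[FoldResult], path) -> None:
    """Vienna-style output: header, sequence line, structure line with energy."""
    with open(path, "w") as fh:
        for f in folds:
            w = f.window
            fh.write(f">{w.transcript_id}|{w.motif}|start={w.start}|{f.structure_kind}\n")
            fh.write(w.window_seq + "\n")
            fh.write(f"{f.dot_bracket} ({f.energy:.2f})\n")
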