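"""Relative-scale profiles: 100-bin alignment identity and motif density.

The identity profile summarizes a precomputed multiple sequence alignment on a
per-transcript relative axis in three steps: (1) each ungapped residue ``i`` of
a sequence of ungapped length ``L`` is assigned to bin ``floor(100*i/L)``
(clamped to 99); (2) the residue's value is the fraction of the *other*
sequences that are aligned to its column (``coverage`` mode: any non-gap;
``identity`` mode: the same nucleotide), and per-sequence per-bin means are
taken; (3) the per-sequence bin vectors are stacked and averaged into a single
100-value function.  The aligner itself is out of scope — any aligned FASTA or
Clustal file can be consumed.

The motif density profile is a Gaussian kernel density of occurrence relative
positions on [0, 1], each kernel truncated to the unit interval and
renormalized, evaluated at the 100 bin midpoints and discretely normalized so
that ``sum(bins) / 100 == 1`` whenever any occurrence exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from scipy.stats import norm

N_BINS = 100
GAP = "-"


@dataclass(frozen=True)
class IdentityProfile:
    bins: np.ndarray  # 100 values in [0, 1]
    n_sequences: int
    mode: str  # "coverage" | "identity"


@dataclass(frozen=True)
class DensityProfile:
    bins: np.ndarray  # 100 non-negative values, mean 1 when nonempty
    motif: str
    bandwidth: float


def read_alignment(path: str | Path) -> list[str]:
    """Read an aligned FASTA or Clustal (.aln/.clustal) file into row strings.

    Rows are uppercased with T converted to U; gaps stay ``-``.
    """
    path = Path(path)
    fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq).upper().replace("T", "U") for rec in aln]


def identity_profile(
    msa: Sequence[str], mode: str = "coverage"
) -> IdentityProfile:
    """100-bin identity function of an alignment (see module docstring)."""
    if mode not in {"coverage", "identity"}:
        raise ValueError(f"unknown mode {mode!r}")
    rows = [r.upper().replace("T", "U") for r in msa]
    n = len(rows)
    if n < 2:
        raise ValueError("identity_profile requires >= 2 sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("aligned sequences must have equal length")
    mat = np.array([list(r) for r in rows])
    nongap = mat != GAP
    all_gap = ~nongap.any(axis=1)
    if all_gap.any():
        raise ValueError(f"sequence {int(np.flatnonzero(all_gap)[0])} is all gaps")
    col_nongap = nongap.sum(axis=0)

    per_seq_bins = np.full((n, N_BINS), np.nan)
    for s in range(n):
        cols = np.flatnonzero(nongap[s])
        L = cols.size
        bins = np.minimum((N_BINS * np.arange(L)) // L, N_BINS - 1)
        if mode == "coverage":
            vals = (col_nongap[cols] - 1) / (n - 1)
        else:
            same = (mat[:, cols] == mat[s, cols]).sum(axis=0)
            vals = (same - 1) / (n - 1)
        sums = np.bincount(bins, weights=vals, minlength=N_BINS)
        cnts = np.bincount(bins, minlength=N_BINS)
        with np.errstate(invalid="ignore"):
            per_seq_bins[s] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    profile = np.nanmean(per_seq_bins, axis=0)
    profile = np.nan_to_num(profile, nan=0.0)
    return IdentityProfile(bins=profile, n_sequences=n, mode=mode)


def motif_density(
    rel_positions: Sequence[float],
    bandwidth: float = 0.05,
    motif: str = "",
) -> DensityProfile:
    """Truncated-Gaussian kernel density of relative positions on [0, 1]."""
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    x = np.asarray(rel_positions, dtype=float)
    mid = (np.arange(N_BINS) + 0.5) / N_BINS
    if x.size == 0:
        return DensityProfile(np.zeros(N_BINS), motif, bandwidth)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative positions must lie in [0, 1]")
    # each kernel renormalized by its truncated mass on [0, 1]
    mass = norm.cdf((1.0 - x) / bandwidth) - norm.cdf((0.0 - x) / bandwidth)
    kern = norm.pdf((mid[:, None] - x[None, :]) / bandwidth) / (bandwidth * mass)
    dens = kern.mean(axis=1)
    dens = dens / dens.mean()  # discrete normalization: sum(bins)/100 == 1
    return DensityProfile(dens, motif, bandwidth)
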