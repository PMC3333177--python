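"""Statistical primitives shared by all analysis stages.

Conventions
-----------
* ``skewness`` is the Fisher-Pearson *population* coefficient
  ``g1 = m3 / m2**1.5`` (central moments), with ``g1 = 0`` for zero-variance
  input; the small-sample adjusted variant is available via ``adjusted=True``.
* ``kendall_tau`` is tau-b (tie-corrected); a constant variable yields 0.
* ``fisher_exact`` is the two-sided probability-mass definition.
* ``mwu_pvalue`` enumerates all arrangements exactly for pooled size <= 12 and
  falls back to the tie-corrected normal approximation otherwise.
* ``mwu_bootstrap`` implements a resampled Mann-Whitney comparison that stops
  when the running standard deviation of the p-values drops to 10% of their
  running mean (checked from round 3), or both fall below 1e-15.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats as sps


class ContingencyTable2x2(NamedTuple):
    """Row 1 = observed (containing / not), row 2 = expected (containing / not)."""

    a: int
    b: int
    c: int
    d: int


def skewness(values: Sequence[float], adjusted: bool = False) -> float:
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("skewness of empty input is undefined")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    g1 = float(np.mean((x - m) ** 3) / m2**1.5)
    if adjusted:
        n = x.size
        if n < 3:
            raise ValueError("adjusted skewness requires n >= 3")
        g1 *= math.sqrt(n * (n - 1)) / (n - 2)
    return g1


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("kendall_tau: length mismatch")
    if x.size < 2:
        raise ValueError("kendall_tau requires n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    tau = sps.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("fisher_exact entries must be non-negative integers")
    return ContingencyTable2x2(*(int(v) for v in arr.ravel()))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value (probability-mass criterion)."""
    t = _as_table(table)
    if t.a + t.b + t.c + t.d == 0:
        raise ValueError("fisher_exact: all-zero table")
    p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return float(min(p, 1.0))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in sps.false_discovery_control(p, method="bh")]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rx = ranks[: x.size].sum()
    return rx - x.size * (x.size + 1) / 2.0


def mwu_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact enumeration of all C(n+m, n) group assignments (ties handled via
    midranks) when n + m <= 12; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mwu_pvalue requires nonempty samples")
    n, m = x.size, y.size
    if n + m <= 12:
        u_obs = _u_statistic(x, y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = n * (n + 1) / 2.0
        us = np.array(
            [ranks[list(idx)].sum() - offset for idx in combinations(range(n + m), n)]
        )
        total = us.size
        eps = 1e-9
        p_le = np.count_nonzero(us <= u_obs + eps) / total
        p_ge = np.count_nonzero(us >= u_obs - eps) / total
        return min(1.0, 2.0 * min(p_le, p_ge))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


@dataclass(frozen=True)
class BootstrapMwuResult:
    p_mean: float
    p_sd: float
    n_rounds: int
    converged: bool
    seed: int


def mwu_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    sample_size_rule: str = "fixed_100",
    max_rounds: int = 200,
    seed: int = 0,
    replace: bool = False,
) -> BootstrapMwuResult:
    """Bootstrap-stabilized Mann-Whitney comparison of two samples.

    Each round subsamples (without replacement by default) either 100 values
    (``fixed_100``) or the size of the smaller sample (``min_sample``) from each
    input, records the two-sided Mann-Whitney p-value, and stops when the
    running SD of the recorded p-values is at most 10% of their running mean,
    or both mean and SD have dropped to 1e-15, or ``max_rounds`` is reached
    (``converged=False`` then).  Deterministic for a given seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("mwu_bootstrap requires samples of size >= 2")
    if max_rounds < 2:
        raise ValueError("max_rounds must be >= 2")
    if sample_size_rule == "fixed_100":
        size = 100
    elif sample_size_rule == "min_sample":
        size = int(min(x.size, y.size))
    else:
        raise ValueError(f"unknown sample_size_rule {sample_size_rule!r}")

    rng = np.random.default_rng(seed)
    ps: list[float] = []
    converged = False
    for _ in range(max_rounds):
        sx = rng.choice(x, size=min(size, x.size), replace=replace)
        sy = rng.choice(y, size=min(size, y.size), replace=replace)
        ps.append(mwu_pvalue(sx, sy))
        if len(ps) >= 3:
            mean = float(np.mean(ps))
            sd = float(np.std(ps, ddof=1))
            if sd <= 0.10 * mean or (mean <= 1e-15 and sd <= 1e-15):
                converged = True
                break
    mean = float(np.mean(ps))
    sd = float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0
    return BootstrapMwuResult(mean, sd, len(ps), converged, seed)
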