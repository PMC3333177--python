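"""Synthetic transcriptome + expression + half-life generator with ground truth.

The generator emulates the statistical structure the analysis assumes:

* transcripts stratified into the eight ECER bins (plus an optional
  exosome-specific group), with the true ECER drawn inside the bin bounds and
  duplicate intensities derived from it under multiplicative replicate noise;
* an mRNA fraction that declines with secretion (default 0.95 -> 0.80 across
  the bins), mirrored in the annotation table;
* a positional base-composition gradient (G/C enriched over the 5' third, A
  enriched over the 3' third) and poly(A) tails on a fraction of mRNAs;
* half-lives log-normal per transcript whose scale declines log-linearly with
  the bin index so that the cell-enriched / exosome-enriched reference-bin
  mean ratio equals the configured secretion factor (1.8 for B-cells, 1.3 for
  fibroblasts by default);
* planted motifs, overwriting the underlying bases (lengths and gradients stay
  intact) at a uniform position inside a relative-position interval.  A planted
  motif may carry a monotone plant-probability ramp across the bins (its
  occupancy then tracks secretion, the signature the selection stage looks
  for), and a joint-plant rule inserts several motifs into the same transcripts
  of one bin to create a known co-occurrence overlap.

All randomness flows from a single seed through named substreams; identical
config + seed reproduce byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .dataio import Dataset, ExpressionProfile, TranscriptRecord, TxClass
from .ecer import BIN_EDGES, BIN_LABELS, ERNA_REFERENCE, EXOSOME_SPECIFIC

_BASES = "ACGU"
_STREAMS = {"class": 0, "length": 1, "sequence": 2, "plant": 3,
            "expression": 4, "halflife": 5}


@dataclass(frozen=True)
class PlantedMotif:
    motif: str
    plant_prob: float
    target_bins: tuple[str, ...] = (ERNA_REFERENCE,)
    rel_pos_interval: tuple[float, float] = (0.7, 1.0)
    #: with ramp=True the plant probability rises linearly across the eight
    #: numeric bins, reaching plant_prob in the >33 bin (target_bins ignored)
    ramp: bool = False
    #: with exclusive=True chance occurrences outside planted sites are
    #: scrubbed (one base mutated), so the motif is truly absent elsewhere
    exclusive: bool = False

    def bin_prob(self, bin_idx: int, label: str) -> float:
        if self.ramp:
            return self.plant_prob * (bin_idx + 1) / len(BIN_LABELS)
        return self.plant_prob if label in self.target_bins else 0.0


@dataclass(frozen=True)
class JointPlant:
    """Plant all ``motifs`` together in a fraction of one bin's transcripts."""

    motifs: tuple[str, ...]
    prob: float
    bin_label: str = ERNA_REFERENCE
    rel_pos_interval: tuple[float, float] = (0.7, 1.0)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_per_bin: int = 400
    n_exosome_specific: int = 0
    length_lognormal: tuple[float, float] = (math.log(800.0), 0.45)
    gc5_bias: float = 0.15
    a3_bias: float = 0.12
    polyA_prob_mrna: float = 0.65
    polyA_len_geom_p: float = 0.02
    mrna_frac_by_bin: tuple[float, ...] = tuple(
        0.95 - 0.15 * i / 7 for i in range(8)
    )
    planted_motifs: tuple[PlantedMotif, ...] = ()
    joint_plant: JointPlant | None = None
    halflife_lognormal: tuple[float, float] = (math.log(8.0), 0.8)
    halflife_secretion_factor: Mapping[str, float] = field(
        default_factory=lambda: {"b_cell": 1.8, "fibroblast": 1.3}
    )
    halflife_coverage: float = 0.9
    cell_intensity_lognormal: tuple[float, float] = (math.log(500.0), 0.6)
    erna_ecer_max: float = 330.0  # >33 bin sampled log-uniform on [33, this]
    replicate_cv: float = 0.1

    def __post_init__(self) -> None:
        if len(self.mrna_frac_by_bin) != len(BIN_LABELS):
            raise ValueError("mrna_frac_by_bin must have one entry per bin")
        min_len = math.exp(self.length_lognormal[0] - 4 * self.length_lognormal[1])
        for pm in self.planted_motifs:
            if len(pm.motif) >= 50:
                raise ValueError(f"planted motif {pm.motif!r} too long")
        _ = min_len


@dataclass
class GroundTruthRecord:
    id: str
    bin: str
    txclass: str
    length: int
    ecer: float | None
    planted: list[tuple[str, int]]
    half_life: dict[str, float]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    records: dict[str, TranscriptRecord]
    profiles: dict[str, ExpressionProfile]
    half_lives: dict[str, dict[str, float]]  # cell_type -> id -> hours
    truth: dict[str, GroundTruthRecord]

    def as_dataset(self) -> Dataset:
        return Dataset(
            profiles=self.profiles,
            records=self.records,
            half_lives=self.half_lives,
        )

    def true_members(self, label: str) -> set[str]:
        return {tid for tid, gt in self.truth.items() if gt.bin == label}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        return write_dataset(self, outdir)


def _segment_probs(cfg: SyntheticConfig) -> list[np.ndarray]:
    b, a = cfg.gc5_bias, cfg.a3_bias
    p5 = np.array([0.25 - b / 2, 0.25 + b / 2, 0.25 + b / 2, 0.25 - b / 2])
    pm = np.full(4, 0.25)
    p3 = np.array([0.25 + a, 0.25 - a / 3, 0.25 - a / 3, 0.25 - a / 3])
    return [p5 / p5.sum(), pm, p3 / p3.sum()]


def _draw_sequence(rng: np.random.Generator, L: int, probs: list[np.ndarray]) -> np.ndarray:
    thirds = [L // 3, L // 3, L - 2 * (L // 3)]
    parts = [rng.choice(4, size=n, p=p) for n, p in zip(thirds, probs)]
    return np.concatenate(parts).astype(np.int8)


def _plant(
    rng: np.random.Generator,
    seq: np.ndarray,
    motif: str,
    interval: tuple[float, float],
    occupied: list[tuple[int, int]],
) -> int | None:
    """Overwrite the bases of one motif at a uniform position inside the
    relative interval, avoiding previously planted spans; None if no room."""
    k = len(motif)
    L = seq.size
    if L <= k:
        return None
    lo = math.ceil(interval[0] * (L - k))
    hi = math.floor(interval[1] * (L - k))
    if hi < lo:
        return None
    codes = np.array([_BASES.index(c) for c in motif], dtype=np.int8)
    for _ in range(100):
        start = int(rng.integers(lo, hi + 1))
        if all(start + k <= s or start >= e for s, e in occupied):
            seq[start : start + k] = codes
            occupied.append((start, start + k))
            return start
    return None


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[c] for c in seq)


def _scrub(
    rng: np.random.Generator,
    seq: np.ndarray,
    motif: str,
    keep_starts: set[int],
    occupied: list[tuple[int, int]],
) -> None:
    """Mutate one base inside every chance occurrence of ``motif`` that is not
    a recorded planted site, without touching planted spans."""
    k = len(motif)
    codes = np.array([_BASES.index(c) for c in motif], dtype=np.int8)
    for _ in range(20):
        text = _decode(seq)
        stray = [
            s
            for s in range(len(text) - k + 1)
            if text.startswith(motif, s) and s not in keep_starts
        ]
        if not stray:
            return
        for s in stray:
            free = [
                p
                for p in range(s, s + k)
                if all(p < a or p >= b for a, b in occupied)
            ]
            if not free:
                continue
            p = free[len(free) // 2]
            old = seq[p]
            seq[p] = (old + 1 + int(rng.integers(3))) % 4


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full synthetic dataset bundle with ground truth."""
    rngs = {
        name: np.random.default_rng([config.seed, sid])
        for name, sid in _STREAMS.items()
    }
    probs = _segment_probs(config)
    mu_l, sd_l = config.length_lognormal
    mu_c, sd_c = config.cell_intensity_lognormal
    mu_h, sd_h = config.halflife_lognormal
    cv = config.replicate_cv

    bins: list[tuple[str, int]] = [(lbl, i) for i, lbl in enumerate(BIN_LABELS)]
    if config.n_exosome_specific > 0:
        bins.append((EXOSOME_SPECIFIC, len(BIN_LABELS) - 1))

    records: dict[str, TranscriptRecord] = {}
    profiles: dict[str, ExpressionProfile] = {}
    half_lives: dict[str, dict[str, float]] = {
        ct: {} for ct in config.halflife_secretion_factor
    }
    truth: dict[str, GroundTruthRecord] = {}

    counter = 0
    for label, bin_idx in bins:
        n = (
            config.n_exosome_specific
            if label == EXOSOME_SPECIFIC
            else config.n_per_bin
        )
        for _ in range(n):
            tid = f"TX{counter:05d}"
            counter += 1
            is_mrna = rngs["class"].random() < config.mrna_frac_by_bin[bin_idx]
            txclass = TxClass.MRNA if is_mrna else TxClass.NCRNA
            L = max(50, int(round(rngs["length"].lognormal(mu_l, sd_l))))
            seq = _draw_sequence(rngs["sequence"], L, probs)
            if is_mrna and rngs["sequence"].random() < config.polyA_prob_mrna:
                tail = min(int(rngs["sequence"].geometric(config.polyA_len_geom_p)),
                           L // 3)
                if tail > 0:
                    seq[-tail:] = 0  # poly(A)

            planted: list[tuple[str, int]] = []
            occupied: list[tuple[int, int]] = []
            joint = config.joint_plant
            jointly_planted = False
            if joint is not None and label == joint.bin_label:
                if rngs["plant"].random() < joint.prob:
                    jointly_planted = True
                    for m in joint.motifs:
                        start = _plant(rngs["plant"], seq, m,
                                       joint.rel_pos_interval, occupied)
                        if start is not None:
                            planted.append((m, start))
            for pm in config.planted_motifs:
                p = pm.bin_prob(bin_idx, label)
                if (
                    joint is not None
                    and label == joint.bin_label
                    and pm.motif in joint.motifs
                ):
                    if jointly_planted:
                        continue  # already carries the motif via the joint rule
                    p = max(0.0, (p - joint.prob) / (1.0 - joint.prob))
                if p > 0 and rngs["plant"].random() < p:
                    start = _plant(rngs["plant"], seq, pm.motif,
                                   pm.rel_pos_interval, occupied)
                    if start is not None:
                        planted.append((pm.motif, start))
            for pm in config.planted_motifs:
                if pm.exclusive:
                    keep = {s for m, s in planted if m == pm.motif}
                    _scrub(rngs["plant"], seq, pm.motif, keep, occupied)

            if label == EXOSOME_SPECIFIC:
                ecer: float | None = None
                cell_base = 0.0
                exo_base = float(rngs["expression"].lognormal(mu_c, sd_c)) + 120.0
            elif label == ERNA_REFERENCE:
                lo, hi = BIN_EDGES[-2], config.erna_ecer_max
                ecer = float(np.exp(rngs["expression"].uniform(np.log(lo), np.log(hi))))
                cell_base = float(rngs["expression"].lognormal(mu_c, sd_c))
                exo_base = cell_base * ecer
            else:
                lo, hi = BIN_EDGES[bin_idx], BIN_EDGES[bin_idx + 1]
                ecer = float(rngs["expression"].uniform(lo, hi))
                cell_base = float(rngs["expression"].lognormal(mu_c, sd_c))
                exo_base = cell_base * ecer

            if cv > 0:
                noise = rngs["expression"].lognormal(-cv**2 / 2, cv, size=4)
            else:
                noise = np.ones(4)
            exo = (exo_base * noise[0], exo_base * noise[1])
            cell = (cell_base * noise[2], cell_base * noise[3])

            hls: dict[str, float] = {}
            has_hl = rngs["halflife"].random() < config.halflife_coverage
            for ct, factor in config.halflife_secretion_factor.items():
                z = rngs["halflife"].normal()
                hl = float(
                    np.exp(mu_h - math.log(factor) * bin_idx / 7 + sd_h * z)
                )
                if has_hl:
                    hls[ct] = hl
                    half_lives[ct][tid] = hl

            records[tid] = TranscriptRecord(tid, _decode(seq), txclass)
            profiles[tid] = ExpressionProfile(tid, exo, cell)
            truth[tid] = GroundTruthRecord(
                id=tid, bin=label, txclass=txclass.value, length=L,
                ecer=ecer, planted=planted, half_life=hls,
            )

    return SyntheticDataset(config, records, profiles, half_lives, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as the same plain-text formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "expression": outdir / "expression.tsv",
        "annotation": outdir / "annotation.tsv",
        "halflife": outdir / "halflife.tsv",
        "truth": outdir / "ground_truth.json",
    }
    ids = sorted(ds.records)
    with open(paths["fasta"], "w") as fh:
        for tid in ids:
            fh.write(f">{tid}\n")
            seq = ds.records[tid].sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["expression"], "w") as fh:
        fh.write("id\texo_1\texo_2\tcell_1\tcell_2\n")
        for tid in ids:
            p = ds.profiles[tid]
            fh.write(
                f"{tid}\t{p.exo[0]:.4f}\t{p.exo[1]:.4f}"
                f"\t{p.cell[0]:.4f}\t{p.cell[1]:.4f}\n"
            )
    with open(paths["annotation"], "w") as fh:
        fh.write("id\tclass\n")
        for tid in ids:
            fh.write(f"{tid}\t{ds.records[tid].txclass.value}\n")
    with open(paths["halflife"], "w") as fh:
        fh.write("id\thalf_life_h\tcell_type\n")
        for ct in sorted(ds.half_lives):
            for tid in sorted(ds.half_lives[ct]):
                fh.write(f"{tid}\t{ds.half_lives[ct][tid]:.4f}\t{ct}\n")
    truth_obj = {
        tid: {
            "bin": gt.bin, "txclass": gt.txclass, "length": gt.length,
            "ecer": gt.ecer, "planted": gt.planted, "half_life": gt.half_life,
        }
        for tid, gt in sorted(ds.truth.items())
    }
    with open(paths["truth"], "w") as fh:
        json.dump({"config_seed": ds.config.seed, "transcripts": truth_obj},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


#: The three 8-mers previously reported as enriched in exosome-secreted RNAs;
#: used as the default planted ground truth for recovery experiments.
SECRETION_MOTIFS = ("ACCAGCCU", "CAGUGAGC", "UAAUCCCA")


def default_recovery_config(seed: int, n_per_bin: int = 400) -> SyntheticConfig:
    """The standard parameter-recovery scenario: the three secretion motifs
    planted with a ramped probability peaking at 0.2 in the >33 bin, with 10%
    of >33 transcripts carrying all three jointly at relative positions
    [0.7, 1.0]."""
    return SyntheticConfig(
        seed=seed,
        n_per_bin=n_per_bin,
        n_exosome_specific=max(2, n_per_bin // 8),
        planted_motifs=tuple(
            PlantedMotif(m, plant_prob=0.2, ramp=True) for m in SECRETION_MOTIFS
        ),
        joint_plant=JointPlant(motifs=SECRETION_MOTIFS, prob=0.10),
    )


#: Miniature fixed-seed dataset shared across the test suite.
FIXTURE_CONFIG = SyntheticConfig(
    seed=20113,
    n_per_bin=12,
    n_exosome_specific=6,
    length_lognormal=(math.log(260.0), 0.25),
    planted_motifs=(
        PlantedMotif("ACCAGCCU", plant_prob=0.75, target_bins=(ERNA_REFERENCE,)),
    ),
    halflife_coverage=1.0,
    replicate_cv=0.05,
)


def regenerate_reference_fixture(dest: str | Path) -> dict[str, Path]:
    """Regenerate the committed miniature fixture into ``dest``.

    The committed copy must match byte-for-byte; a drift check in the test
    suite compares the two file sets.
    """
    return write_dataset(generate(FIXTURE_CONFIG), dest)
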