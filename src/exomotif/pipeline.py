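"""End-to-end orchestration: partition -> exhaustive scan -> selection ->
profiles -> structure windows, with a machine-readable run manifest.

Each stage is a standalone function operating on the files in a working
directory, so the stages can be re-run individually on a previous stage's
outputs and reproduce the same digests.  All outputs are plain TSV/JSON/FASTA;
writes are atomic (temp file + rename) and a failed stage leaves its partial
outputs behind with a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import kmers, profiles, selection as sel, simulate, stats, structure
from .dataio import Dataset, load_inputs
from .ecer import (
    BIN_LABELS,
    CELL_REFERENCE,
    ERNA_REFERENCE,
    EXOSOME_SPECIFIC,
    UNASSIGNED,
    assign_partitions,
    compute_ecer,
    filter_transcripts,
)

logger = logging.getLogger("exomotif.pipeline")


@dataclass
class PipelineConfig:
    """YAML-mappable configuration with one section per stage."""

    seed: int = 0
    # inputs (either explicit paths or a simulate section)
    expression: str | None = None
    fasta: str | None = None
    annotation: str | None = None
    halflife: str | None = None
    msa: str | None = None
    simulate: dict[str, Any] | None = None
    # partition stage
    min_expression: float = 100.0
    concordance_fold: float = 2.0
    detection_threshold: float = 1.0
    merge_exosome_specific: bool = False
    # scan stage
    ks_short: tuple[int, ...] = (1, 2, 3, 4, 5)
    k_long: int = 8
    top_rank_change: int = 100
    # selection stage
    thresholds: sel.SelectionThresholds = field(default_factory=sel.SelectionThresholds)
    venn_motifs: tuple[str, ...] | None = None  # None -> top stage-2 motifs
    n_venn: int = 3
    enrichment_draws: int = 10000
    # profile stage
    bandwidth: float = 0.05
    # structure stage
    structure_enabled: bool = True
    engine: str = "fallback"
    flank: int = 46
    region: tuple[float, float] = (0.7, 1.0)
    max_windows: int = 400

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = sel.SelectionThresholds(**raw["thresholds"])
        for key in ("ks_short", "venn_motifs", "region"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict[str, Any]:
        d = asdict(self)
        return d


# ---------------------------------------------------------------------------
# small IO helpers


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(path, df.to_csv(sep="\t", index=False, float_format="%.6g"))


def _json_dump(obj: Any, path: Path) -> None:
    _atomic_write(path, json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _load_dataset(cfg: PipelineConfig, workdir: Path) -> Dataset:
    exp = cfg.expression
    if exp is None:
        indir = workdir / "inputs"
        if not (indir / "expression.tsv").exists():
            raise FileNotFoundError(
                "no expression table configured and no simulated inputs found"
            )
        return load_inputs(
            indir / "expression.tsv",
            indir / "transcripts.fasta",
            indir / "annotation.tsv",
            indir / "halflife.tsv",
        )
    return load_inputs(exp, cfg.fasta, cfg.annotation, cfg.halflife)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, workdir: Path) -> dict[str, Path]:
    """Generate synthetic inputs into ``workdir/inputs`` when configured."""
    if cfg.simulate is None:
        raise ValueError("config has no simulate section")
    raw = dict(cfg.simulate)
    raw.setdefault("seed", cfg.seed)
    if raw.pop("recovery_scenario", False):
        sim_cfg = simulate.default_recovery_config(
            seed=raw["seed"], n_per_bin=raw.get("n_per_bin", 400)
        )
    else:
        if "planted_motifs" in raw:
            raw["planted_motifs"] = tuple(
                simulate.PlantedMotif(**pm) if isinstance(pm, dict) else pm
                for pm in raw["planted_motifs"]
            )
        if isinstance(raw.get("joint_plant"), dict):
            raw["joint_plant"] = simulate.JointPlant(**raw["joint_plant"])
        sim_cfg = simulate.SyntheticConfig(**raw)
    ds = simulate.generate(sim_cfg)
    return ds.write(workdir / "inputs")


def stage_partition(cfg: PipelineConfig, workdir: Path) -> pd.DataFrame:
    """ECER computation, filtering and stratification -> partitions.tsv."""
    data = _load_dataset(cfg, workdir)
    results = [
        compute_ecer(p, cfg.detection_threshold, cfg.concordance_fold)
        for p in data.profiles.values()
        if p.mean_exo > 0 or p.mean_cell > 0
    ]
    kept, report = filter_transcripts(results, cfg.min_expression)
    parts = assign_partitions(kept, cfg.merge_exosome_specific)
    label_of = {tid: p.label for p in parts for tid in p.members}
    rows = sorted(
        (
            r.id,
            r.mean_exo,
            r.mean_cell,
            "" if r.exosome_specific else f"{r.ecer:.6g}",
            label_of[r.id],
        )
        for r in kept
    )
    df = pd.DataFrame(rows, columns=["id", "mean_exo", "mean_cell", "ecer", "partition"])
    _write_df(df, workdir / "partitions.tsv")
    _json_dump(
        {
            "filter": asdict(report),
            "sizes": {p.label: p.size for p in parts},
            "settings": {
                "min_expression": cfg.min_expression,
                "concordance_fold": cfg.concordance_fold,
                "detection_threshold": cfg.detection_threshold,
                "merge_exosome_specific": cfg.merge_exosome_specific,
            },
        },
        workdir / "partition_summary.json",
    )
    return df


def _read_partitions(workdir: Path) -> pd.DataFrame:
    return pd.read_csv(workdir / "partitions.tsv", sep="\t", dtype={"id": str})


def _bin_members(part_df: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {lbl: [] for lbl in BIN_LABELS}
    out[EXOSOME_SPECIFIC] = []
    out[UNASSIGNED] = []
    for tid, lbl in zip(part_df["id"], part_df["partition"]):
        out.setdefault(lbl, []).append(tid)
    return out


def _bin_halflife_medians(
    data: Dataset, members: Mapping[str, Sequence[str]]
) -> dict[str, np.ndarray]:
    """Per-cell-type median half-life over each of the 8 numeric bins."""
    out: dict[str, np.ndarray] = {}
    for ct, table in sorted(data.half_lives.items()):
        med = np.full(len(BIN_LABELS), np.nan)
        for i, lbl in enumerate(BIN_LABELS):
            vals = [table[t] for t in members[lbl] if t in table]
            if vals:
                med[i] = float(np.median(vals))
        out[ct] = med
    return out


def stage_scan(cfg: PipelineConfig, workdir: Path) -> pd.DataFrame:
    """Exhaustive k-mer statistics per partition.

    Emits ``short_motif_stats.tsv`` (all motifs for the short lengths, per
    bin), ``rank_change.tsv`` (top enriched-set rank risers among k_long-mers)
    and ``selection_stats.tsv`` (per k_long-mer secretion/half-life
    correlations plus reference-partition statistics, trimmed to motifs seen
    in at least one reference partition).
    """
    data = _load_dataset(cfg, workdir)
    part_df = _read_partitions(workdir)
    members = _bin_members(part_df)
    encoded = {
        tid: kmers.encode_sequence(rec.sequence) for tid, rec in data.records.items()
    }

    def bin_records(lbl: str):
        return [data.records[t] for t in members[lbl] if t in data.records]

    tables: dict[tuple[str, int], kmers.KmerPartitionTable] = {}
    for lbl in BIN_LABELS:
        recs = bin_records(lbl)
        for k in (*cfg.ks_short, cfg.k_long):
            tables[(lbl, k)] = kmers.build_kmer_table(recs, k, encoded)

    # short-motif table, one row per motif x bin
    short_rows = []
    for k in cfg.ks_short:
        motif_names = [kmers.index_to_motif(i, k) for i in range(4**k)]
        for lbl in BIN_LABELS:
            t = tables[(lbl, k)]
            frac = t.frac_containing
            skew = t.skewness
            mf = t.mrna_frac
            for i, m in enumerate(motif_names):
                short_rows.append(
                    (m, k, lbl, int(t.counts[i]), int(t.containing[i]),
                     frac[i], skew[i], mf[i])
                )
    short_df = pd.DataFrame(
        short_rows,
        columns=["motif", "k", "partition", "n_occurrences", "n_containing",
                 "frac_containing", "skewness", "mrna_frac"],
    )
    _write_df(short_df, workdir / "short_motif_stats.tsv")

    # long-motif (k_long) secretion statistics
    k = cfg.k_long
    size = 4**k
    frac_matrix = np.stack([tables[(lbl, k)].frac_containing for lbl in BIN_LABELS])
    tau_ecer = kmers.tau_matrix_vs_bins(frac_matrix)
    hl_medians = _bin_halflife_medians(data, members)
    tau_hl: dict[str, np.ndarray] = {}
    for ct, med in hl_medians.items():
        ok = np.isfinite(med)
        if ok.sum() >= 2:
            tau_hl[ct] = kmers.tau_matrix_vs_bins(frac_matrix[ok], ref=med[ok])
        else:
            tau_hl[ct] = np.full(size, np.nan)

    erna = tables[(ERNA_REFERENCE, k)]
    cell = tables[(CELL_REFERENCE, k)]
    motif_names = np.array([kmers.index_to_motif(i, k) for i in range(size)])
    keep = (erna.containing > 0) | (cell.containing > 0)
    sel_df = pd.DataFrame(
        {
            "motif": motif_names[keep],
            "tau_ecer": tau_ecer[keep],
            **{f"tau_halflife_{ct}": v[keep] for ct, v in tau_hl.items()},
            "frac_erna": erna.frac_containing[keep],
            "skew_erna": erna.skewness[keep],
            "mrna_frac_erna": erna.mrna_frac[keep],
            "n_occ_erna": erna.counts[keep],
            "n_containing_erna": erna.containing[keep],
            "frac_cell": cell.frac_containing[keep],
            "skew_cell": cell.skewness[keep],
        }
    )
    _write_df(sel_df, workdir / "selection_stats.tsv")

    rank = kmers.rank_change_selection(
        dict(zip(motif_names, erna.counts.astype(float))),
        dict(zip(motif_names, cell.counts.astype(float))),
        top_n=cfg.top_rank_change,
    )
    _write_df(
        pd.DataFrame(rank, columns=["motif", "rank_delta"]),
        workdir / "rank_change.tsv",
    )
    _json_dump(
        {
            "k_long": k,
            "n_bins": len(BIN_LABELS),
            "bin_sizes": {lbl: tables[(lbl, k)].n_members for lbl in BIN_LABELS},
            "halflife_bin_medians": {
                ct: [None if not np.isfinite(v) else round(float(v), 4) for v in med]
                for ct, med in hl_medians.items()
            },
        },
        workdir / "scan_summary.json",
    )
    return sel_df


def stage_select(cfg: PipelineConfig, workdir: Path) -> pd.DataFrame:
    """Threshold chains, co-occurrence Venn and enrichment tests."""
    data = _load_dataset(cfg, workdir)
    part_df = _read_partitions(workdir)
    members = _bin_members(part_df)
    sel_df = pd.read_csv(workdir / "selection_stats.tsv", sep="\t").set_index("motif")
    short_df = pd.read_csv(workdir / "short_motif_stats.tsv", sep="\t")

    # short-motif classification against the two reference partitions
    ref = short_df[short_df["partition"].isin([ERNA_REFERENCE, CELL_REFERENCE])]
    pivot = ref.pivot(index="motif", columns="partition",
                      values=["frac_containing", "skewness"])
    short_stats = pd.DataFrame(
        {
            "frac_erna": pivot[("frac_containing", ERNA_REFERENCE)],
            "skew_erna": pivot[("skewness", ERNA_REFERENCE)],
            "frac_cell": pivot[("frac_containing", CELL_REFERENCE)],
            "skew_cell": pivot[("skewness", CELL_REFERENCE)],
        }
    )
    labels = sel.classify_short_motifs(short_stats, cfg.thresholds)
    classes = short_stats.assign(label=labels).reset_index()
    classes = classes.sort_values("motif").reset_index(drop=True)
    _write_df(classes, workdir / "short_motif_classes.tsv")

    selected = sel.select_secretion_specific(sel_df, cfg.thresholds)
    selected = selected.sort_values(
        ["stage2", "stage1", "frac_erna", "motif"],
        ascending=[False, False, False, True],
    )

    # composition-matched enrichment for the stage-1 candidates
    erna_records = [data.records[t] for t in members[ERNA_REFERENCE]
                    if t in data.records]
    base = kmers.pooled_base_freqs(erna_records)
    lengths = [r.length for r in erna_records]
    cand = selected.index[selected["stage1"]].tolist()
    pm_p = {}
    ps_p = {}
    for m in cand:
        pm_p[m], ps_p[m] = kmers.enrichment_tests(
            m,
            int(selected.loc[m, "n_occ_erna"]),
            int(selected.loc[m, "n_containing_erna"]),
            lengths,
            base,
        )
    selected["pm_p"] = [pm_p.get(m, np.nan) for m in selected.index]
    selected["ps_p"] = [ps_p.get(m, np.nan) for m in selected.index]
    if cand:
        pm_q = stats.bh_fdr([pm_p[m] for m in cand])
        ps_q = stats.bh_fdr([ps_p[m] for m in cand])
        selected["pm_q"] = pd.Series(dict(zip(cand, pm_q)))
        selected["ps_q"] = pd.Series(dict(zip(cand, ps_q)))
    else:
        selected["pm_q"] = np.nan
        selected["ps_q"] = np.nan
    _write_df(selected.reset_index(), workdir / "selection.tsv")

    # co-occurrence of the headline motifs within the eRNA partition
    if cfg.venn_motifs is not None:
        venn_motifs = list(cfg.venn_motifs)
    else:
        venn_motifs = selected.index[selected["stage2"]].tolist()[: cfg.n_venn]
    venn_obj: dict[str, Any] = {"motifs": venn_motifs}
    if len(venn_motifs) >= 2:
        containment = {
            m: {
                t for t in members[ERNA_REFERENCE]
                if t in data.records and m in data.records[t].sequence
            }
            for m in venn_motifs
        }
        report = sel.cooccurrence(venn_motifs, containment)
        n_erna = sum(1 for t in members[ERNA_REFERENCE] if t in data.records)
        p_comb = sel.combination_enrichment(
            report, n_erna, seed=cfg.seed, n_draws=cfg.enrichment_draws
        )
        venn_obj.update(
            {
                "partition": ERNA_REFERENCE,
                "partition_size": n_erna,
                "regions": {
                    "+".join(sorted(key)): count
                    for key, count in report.region_counts.items()
                },
                "single_counts": report.single_counts,
                "n_any": report.n_any,
                "n_all": report.n_all,
                "all_members": sorted(report.all_members),
                "combination_enrichment_p": p_comb,
            }
        )
    _json_dump(venn_obj, workdir / "venn.json")
    return selected


def _venn_motifs(workdir: Path) -> list[str]:
    with open(workdir / "venn.json") as fh:
        return list(json.load(fh)["motifs"])


def stage_profile(cfg: PipelineConfig, workdir: Path) -> pd.DataFrame:
    """Motif density profiles (plus MSA identity profiles when provided)."""
    data = _load_dataset(cfg, workdir)
    members = _bin_members(_read_partitions(workdir))
    motifs = _venn_motifs(workdir)
    cols: dict[str, np.ndarray] = {"bin": np.arange(profiles.N_BINS)}
    for m in motifs:
        rel = [
            occ.rel_pos
            for t in members[ERNA_REFERENCE]
            if t in data.records
            for occ in kmers.scan_occurrences(data.records[t], m)
        ]
        cols[f"density_{m}"] = profiles.motif_density(rel, cfg.bandwidth, m).bins
    if cfg.msa:
        rows = profiles.read_alignment(cfg.msa)
        cols["identity_coverage"] = profiles.identity_profile(rows, "coverage").bins
        cols["identity_match"] = profiles.identity_profile(rows, "identity").bins
    df = pd.DataFrame(cols)
    _write_df(df, workdir / "profiles.tsv")
    return df


def stage_structure(cfg: PipelineConfig, workdir: Path) -> dict[str, Any]:
    """Motif-window extraction, folding, ranking and predominant patterns."""
    data = _load_dataset(cfg, workdir)
    members = _bin_members(_read_partitions(workdir))
    motifs = _venn_motifs(workdir)
    occurrences = [
        occ
        for m in motifs
        for t in sorted(members[ERNA_REFERENCE])
        if t in data.records
        for occ in kmers.scan_occurrences(data.records[t], m)
    ]
    windows, n_skipped = structure.extract_windows(
        occurrences, data.records, flank=cfg.flank
    )
    lo, hi = cfg.region
    windows = [w for w in windows if lo <= w.region_midpoint <= hi]
    windows = windows[: cfg.max_windows]
    folds = [structure.fold_window(w, engine=cfg.engine) for w in windows]
    summary_obj: dict[str, Any] = {
        "engine": cfg.engine,
        "n_windows": len(windows),
        "n_skipped_edge": n_skipped,
        "region": list(cfg.region),
        "predominant": {},
    }
    if folds:
        summary = structure.rank_and_summarize(folds, cfg.region)
        structure.write_dot_bracket(summary.ranked, workdir / "structures.dbn")
        summary_obj["predominant"] = {
            m: {"pattern": p.pattern, "count": p.count,
                "frequency": round(p.frequency, 4)}
            for m, p in sorted(summary.predominant.items())
        }
        summary_obj["best_energy"] = summary.ranked[0].energy if summary.ranked else None
    else:
        _atomic_write(workdir / "structures.dbn", "")
    _json_dump(summary_obj, workdir / "structure_summary.json")
    return summary_obj


STAGE_OUTPUTS = {
    "partition": ["partitions.tsv", "partition_summary.json"],
    "scan": ["short_motif_stats.tsv", "selection_stats.tsv", "rank_change.tsv",
             "scan_summary.json"],
    "select": ["short_motif_classes.tsv", "selection.tsv", "venn.json"],
    "profile": ["profiles.tsv"],
    "structure": ["structures.dbn", "structure_summary.json"],
}


def run_all(config: PipelineConfig | str | Path, outdir: str | Path) -> dict[str, Any]:
    """Execute every enabled stage and write ``manifest.json`` + summary.

    Returns the manifest dictionary.  A stage failure renames that stage's
    outputs to ``*.partial`` and re-raises.
    """
    cfg = (
        config
        if isinstance(config, PipelineConfig)
        else PipelineConfig.from_yaml(config)
    )
    workdir = Path(outdir)
    workdir.mkdir(parents=True, exist_ok=True)

    stage_fns = []
    if cfg.simulate is not None:
        stage_fns.append(("simulate", stage_simulate))
    stage_fns += [
        ("partition", stage_partition),
        ("scan", stage_scan),
        ("select", stage_select),
        ("profile", stage_profile),
    ]
    if cfg.structure_enabled:
        stage_fns.append(("structure", stage_structure))

    timings: dict[str, float] = {}
    for name, fn in stage_fns:
        t0 = time.perf_counter()
        try:
            fn(cfg, workdir)
        except Exception:
            for rel in STAGE_OUTPUTS.get(name, []):
                p = workdir / rel
                if p.exists():
                    os.replace(p, p.with_suffix(p.suffix + ".partial"))
            raise
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timings[name])

    outputs = {}
    for name, _ in stage_fns:
        for rel in STAGE_OUTPUTS.get(name, []):
            p = workdir / rel
            if p.exists():
                outputs[rel] = _digest(p)
    if cfg.simulate is not None:
        for p in sorted((workdir / "inputs").iterdir()):
            outputs[f"inputs/{p.name}"] = _digest(p)

    manifest = {
        "config": cfg.to_jsonable(),
        "seed": cfg.seed,
        "stage_timings_s": timings,
        "outputs_sha256": outputs,
        "input_files": {
            key: _digest(Path(val))
            for key, val in (
                ("expression", cfg.expression), ("fasta", cfg.fasta),
                ("annotation", cfg.annotation), ("halflife", cfg.halflife),
                ("msa", cfg.msa),
            )
            if val
        },
    }
    _json_dump(manifest, workdir / "manifest.json")
    report_summary(workdir)
    return manifest


def report_summary(workdir: str | Path) -> dict[str, Any]:
    """Deterministic human-readable summary of a finished run."""
    workdir = Path(workdir)
    summary: dict[str, Any] = {}
    psum = workdir / "partition_summary.json"
    if psum.exists():
        summary["partitions"] = json.loads(psum.read_text())["sizes"]
    sel_path = workdir / "selection.tsv"
    if sel_path.exists():
        df = pd.read_csv(sel_path, sep="\t")
        summary["n_stage1"] = int(df["stage1"].sum())
        summary["n_stage2"] = int(df["stage2"].sum())
        top = df[df["stage2"]].head(10)
        summary["top_stage2"] = [
            {
                "motif": r.motif,
                "tau_ecer": round(float(r.tau_ecer), 3),
                "frac_erna": round(float(r.frac_erna), 3),
                "skew_erna": round(float(r.skew_erna), 3),
            }
            for r in top.itertuples(index=False)
        ]
    venn = workdir / "venn.json"
    if venn.exists():
        v = json.loads(venn.read_text())
        summary["cooccurrence"] = {
            key: v[key]
            for key in ("motifs", "n_any", "n_all", "combination_enrichment_p")
            if key in v
        }
    ssum = workdir / "structure_summary.json"
    if ssum.exists():
        summary["structure"] = json.loads(ssum.read_text())
    _json_dump(summary, workdir / "summary.json")

    lines = ["exomotif run summary", "====================", ""]
    if "partitions" in summary:
        lines.append("ECER partition sizes:")
        for lbl in (*BIN_LABELS, EXOSOME_SPECIFIC, UNASSIGNED):
            if lbl in summary["partitions"]:
                lines.append(f"  {lbl:>18}: {summary['partitions'][lbl]}")
    else:
        lines.append("partition stage output absent")
    if "n_stage1" in summary:
        lines.append("")
        lines.append(
            f"secretion-specific selection: {summary['n_stage1']} stage-1, "
            f"{summary['n_stage2']} stage-2 motifs"
        )
        for row in summary.get("top_stage2", []):
            lines.append(
                f"  {row['motif']}  tau_ecer={row['tau_ecer']:+.3f}  "
                f"frac(eRNA)={row['frac_erna']:.3f}  skew={row['skew_erna']:+.3f}"
            )
    else:
        lines.append("selection stage output absent")
    if "cooccurrence" in summary and "n_any" in summary["cooccurrence"]:
        c = summary["cooccurrence"]
        lines.append("")
        lines.append(
            f"co-occurrence of {', '.join(c['motifs'])}: "
            f"{c['n_all']} transcripts with all, {c['n_any']} with any "
            f"(enrichment p={c['combination_enrichment_p']:.4g})"
        )
    _atomic_write(workdir / "summary.txt", "\n".join(lines) + "\n")
    return summary
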