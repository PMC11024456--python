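"""End-to-end orchestration: simulated or on-disk tables through all stages.

Stage order::

    merge_runs -> filter_global -> replicate_qc -> average_replicates
    -> filter_min_proportion -> filter_taxonomic_scope -> fusion
    -> metrics -> statistics

Each stage logs the surviving number of MOTUs / replicates / samples, and a
machine-readable manifest records every threshold, seed and version so that
two manifests differing only in seed explain any output difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tables_io import (MarkerSpec, MotuRecord, ReplicateTable, ValidationError,
                        default_markers, merge_runs, read_metadata,
                        read_motu_records, read_replicate_table,
                        write_profile, write_sample_table)
from .replicate_qc import QcReport, average_replicates, filter_replicates_iterative
from .motu_filtering import (ControlReport, filter_global, filter_min_proportion,
                             filter_taxonomic_scope, screen_controls)
from .marker_fusion import DietProfile, category_proportions, fuse_markers, occurrence_union
from .diet_metrics import (aggregate, diversity_table, rra, summary_mean_se,
                           wpoo, wpoo_per_sample)
from .composition_stats import hellinger, pca, permanova, permutation_anova, rda

STAGES = ["merge_runs", "filter_global", "replicate_qc", "average_replicates",
          "filter_min_proportion", "filter_taxonomic_scope", "fusion",
          "metrics", "statistics"]

SCAFFOLD_MARKER = "Euka02"
CATEGORY_MARKER = {"plant": "Sper01", "bryophyte": "Bryo01",
                   "mushroom": "Fung01", "lichen": "Fung01", "arthropod": "ZBJ"}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineOutput:
    """In-memory results of a full pipeline run."""

    profile: DietProfile
    occurrence: pd.DataFrame
    sample_tables: dict[str, pd.DataFrame]
    qc_reports: dict[str, QcReport]
    control_reports: dict[str, ControlReport]
    diversity: pd.DataFrame
    wpoo: pd.Series
    wpoo_samples: pd.DataFrame
    anova: dict[str, Any] = field(default_factory=dict)
    permanova: dict[str, Any] = field(default_factory=dict)
    ordination: dict[str, Any] = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)
    metadata: pd.DataFrame | None = None


def _log(log: list[dict], stage: str, **info) -> None:
    log.append({"stage": stage, **info})


def run_stages(study,
               extra_runs: Mapping[str, list[ReplicateTable]] | None = None,
               min_len: int = 10, min_total_reads: int = 10,
               min_prop: float = 0.01, occurrence_threshold: float = 0.01,
               qc_max_iter: int = 20, n_perm: int = 999,
               stats_seed: int | None = None,
               run_statistics: bool = True) -> PipelineOutput:
    """Run every stage on an in-memory study (simulated or loaded).

    ``study`` needs ``tables`` (marker -> ReplicateTable), ``records``
    (marker -> {motu: MotuRecord}) and ``metadata``; ``SimStudy`` fits.
    """
    tables: dict[str, ReplicateTable] = dict(study.tables)
    records: dict[str, dict[str, MotuRecord]] = study.records
    metadata: pd.DataFrame = study.metadata
    markers: Mapping[str, MarkerSpec] = getattr(getattr(study, "config", None),
                                                "markers", None) or default_markers()
    log: list[dict] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # 1. merge sequencing runs
    @stage("merge_runs")
    def _merge():
        if extra_runs:
            for m, runs in extra_runs.items():
                for other in runs:
                    tables[m] = merge_runs(tables[m], other)
        for m, t in tables.items():
            _log(log, "merge_runs", marker=m, replicates=len(t.replicate_ids),
                 motus=len(t.motu_ids), reads=int(t.counts.to_numpy().sum()))

    # 2. global length / total-read filter
    @stage("filter_global")
    def _global():
        for m in list(tables):
            tables[m] = filter_global(tables[m], records[m],
                                      min_len=min_len, min_total_reads=min_total_reads)
            _log(log, "filter_global", marker=m, motus=len(tables[m].motu_ids))

    # 3. replicate QC (+ advisory control screening)
    qc_reports: dict[str, QcReport] = {}
    control_reports: dict[str, ControlReport] = {}

    @stage("replicate_qc")
    def _qc():
        for m in list(tables):
            control_reports[m] = screen_controls(tables[m], records=records[m])
            tables[m], qc_reports[m] = filter_replicates_iterative(tables[m], qc_max_iter)
            _log(log, "replicate_qc", marker=m,
                 replicates=len(tables[m].noncontrol().replicate_ids),
                 removed=len(qc_reports[m].removed),
                 iterations=qc_reports[m].n_iterations,
                 samples_dropped=len(qc_reports[m].samples_dropped))

    # 4. average replicates per sample
    sample_tables: dict[str, pd.DataFrame] = {}

    @stage("average_replicates")
    def _avg():
        for m in list(tables):
            sample_tables[m] = average_replicates(tables[m])
            _log(log, "average_replicates", marker=m, samples=len(sample_tables[m]))

    # 5. per-sample 1% tag-jump filter
    @stage("filter_min_proportion")
    def _minprop():
        for m in list(sample_tables):
            sample_tables[m], emptied = filter_min_proportion(sample_tables[m], min_prop)
            _log(log, "filter_min_proportion", marker=m,
                 motus=sample_tables[m].shape[1], emptied_samples=len(emptied))

    # 6. taxonomic scope per marker
    @stage("filter_taxonomic_scope")
    def _scope():
        for m in list(sample_tables):
            scoped = filter_taxonomic_scope(sample_tables[m], records[m], markers[m])
            sample_tables[m] = rra(scoped)   # renormalize after dropping columns
            _log(log, "filter_taxonomic_scope", marker=m, motus=sample_tables[m].shape[1])

    # 7. fusion onto the eukaryote scaffold + occurrence union
    result: dict[str, Any] = {}

    @stage("fusion")
    def _fusion():
        if SCAFFOLD_MARKER not in sample_tables:
            raise ValidationError(f"scaffold marker {SCAFFOLD_MARKER} missing")
        cat_props = category_proportions(sample_tables[SCAFFOLD_MARKER],
                                         records[SCAFFOLD_MARKER])
        cat_tables: dict[str, pd.DataFrame] = {}
        all_records: dict[str, MotuRecord] = {}
        for recs in records.values():
            all_records.update(recs)
        for cat, m in CATEGORY_MARKER.items():
            if m not in sample_tables:
                continue
            tbl = sample_tables[m]
            cols = [c for c in tbl.columns
                    if records[m].get(c) and records[m][c].dietary_category == cat]
            if cols:
                cat_tables[cat] = tbl[cols]
        profile = fuse_markers(cat_props, cat_tables,
                               marker_of_category=CATEGORY_MARKER, records=all_records)
        occ = occurrence_union(
            {m: t for m, t in sample_tables.items() if m != SCAFFOLD_MARKER},
            threshold=occurrence_threshold)
        result["profile"], result["occurrence"] = profile, occ
        _log(log, "fusion", samples=profile.matrix.shape[0],
             taxa=profile.matrix.shape[1], unfusable=len(profile.unfusable),
             scaffold_conflicts=len(profile.scaffold_conflicts))

    # 8. metrics
    @stage("metrics")
    def _metrics():
        profile: DietProfile = result["profile"]
        genus_taxa = [t for t in profile.matrix.columns
                      if not t.endswith("_unresolved")]
        result["diversity"] = diversity_table(profile.matrix, q=1.0, genus_taxa=genus_taxa)
        result["wpoo_samples"] = wpoo_per_sample(result["occurrence"])
        result["wpoo"] = wpoo(result["occurrence"])
        _log(log, "metrics", samples=len(result["diversity"]))

    # 9. statistics per vole species
    anova_res, perma_res, ordi_res = {}, {}, {}

    @stage("statistics")
    def _stats():
        if not run_statistics:
            _log(log, "statistics", skipped=True)
            return
        profile: DietProfile = result["profile"]
        common = [s for s in profile.matrix.index if s in metadata.index]
        for sp in sorted(metadata.loc[common, "vole_species"].unique()):
            idx = [s for s in common if metadata.at[s, "vole_species"] == sp]
            if len(idx) < 6:
                continue
            X = hellinger(profile.matrix.loc[idx])
            design = metadata.loc[idx, ["phase", "season", "site_id"]].reset_index(drop=True)
            interaction_ok = (design.groupby(["phase", "season"]).size().min() >= 2
                              and design[["phase", "season"]].nunique().min() > 1)
            terms = ["phase", "season"] + (["phase:season"] if interaction_ok else [])
            seed = stats_seed
            try:
                perma_res[sp] = permanova(X.to_numpy(), design, terms=terms,
                                          n_perm=n_perm, seed=seed)
            except ValueError:
                pass
            div = result["diversity"].loc[idx, "all_motus"]
            try:
                anova_res[sp] = permutation_anova(div.to_numpy(), design, terms=terms,
                                                  n_perm=n_perm, seed=seed)
            except ValueError:
                pass
            ordi_res[f"{sp}_pca"] = pca(X)
            try:
                if interaction_ok and design["site_id"].nunique() > 1:
                    ordi_res[f"{sp}_rda"] = rda(X, design, terms=["phase:season"],
                                                condition=["site_id"])
                else:
                    ordi_res[f"{sp}_rda"] = rda(X, design, terms=["phase", "season"])
            except ValueError:
                pass
        _log(log, "statistics", species=sorted(perma_res))

    return PipelineOutput(
        profile=result["profile"], occurrence=result["occurrence"],
        sample_tables=sample_tables, qc_reports=qc_reports,
        control_reports=control_reports, diversity=result["diversity"],
        wpoo=result["wpoo"], wpoo_samples=result["wpoo_samples"],
        anova=anova_res, permanova=perma_res, ordination=ordi_res,
        stage_log=log, metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Config-driven run with on-disk outputs


@dataclass
class _LoadedStudy:
    tables: dict[str, ReplicateTable]
    records: dict[str, dict[str, MotuRecord]]
    metadata: pd.DataFrame
    config: Any = None


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg


def _study_from_config(cfg: dict) -> Any:
    from .synthetic_data import SimConfig, simulate_study
    if "simulate" in cfg:
        sim = cfg.get("simulate") or {}
        if "seed" not in sim and "seed" in cfg:
            sim["seed"] = cfg["seed"]
        return simulate_study(SimConfig(**sim))
    inputs = cfg.get("inputs")
    if not inputs:
        raise ValidationError("config needs either a 'simulate' or an 'inputs' section")
    markers = default_markers()
    tables, records = {}, {}
    for m, entry in inputs.get("markers", {}).items():
        if m not in markers:
            raise ValidationError(f"unknown marker {m!r}")
        tables[m] = read_replicate_table(entry["table"], markers[m], entry.get("map"))
        records[m] = read_motu_records(entry["records"], m)
        for extra in entry.get("extra_runs", []):
            tables[m] = merge_runs(tables[m],
                                   read_replicate_table(extra, markers[m], entry.get("map")))
    if SCAFFOLD_MARKER not in tables:
        raise ValidationError(f"config must provide the scaffold marker {SCAFFOLD_MARKER}")
    for cat, m in CATEGORY_MARKER.items():
        declared = cfg.get("categories")
        if declared and cat in declared and m not in tables:
            raise ValidationError(f"category {cat!r} declared but marker {m} table missing")
    metadata = read_metadata(inputs["metadata"])
    return _LoadedStudy(tables=tables, records=records, metadata=metadata)


_FMT = "%.12g"


def _write_tsv(df: pd.DataFrame, path: Path, index_label="sample_id") -> None:
    df.to_csv(path, sep="\t", float_format=_FMT, index_label=index_label)


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> Path:
    """Execute the full pipeline from a YAML config; write all outputs.

    Deterministic: identical config (including seed) gives byte-identical
    numeric outputs.  Returns the run directory.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    thresholds = cfg.get("thresholds", {})
    stats_cfg = cfg.get("stats", {})
    seed = cfg.get("seed")
    study = _study_from_config(cfg)
    res = run_stages(
        study,
        min_len=int(thresholds.get("min_len", 10)),
        min_total_reads=int(thresholds.get("min_reads", 10)),
        min_prop=float(thresholds.get("min_prop", 0.01)),
        occurrence_threshold=float(thresholds.get("occurrence", 0.01)),
        qc_max_iter=int(cfg.get("qc", {}).get("max_iter", 20)),
        n_perm=int(stats_cfg.get("n_perm", 999)),
        stats_seed=int(stats_cfg.get("seed", seed if seed is not None else 0)),
    )

    write_profile(res.profile, out / "diet_profile.tsv")
    _write_tsv(res.occurrence, out / "occurrence.tsv")
    _write_tsv(res.diversity, out / "diversity.tsv")
    _write_tsv(res.wpoo.to_frame("wpoo"), out / "wpoo.tsv", index_label="taxon")
    _write_tsv(res.wpoo_samples, out / "wpoo_samples.tsv")
    if res.metadata is not None:
        res.metadata.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
    for m, t in res.sample_tables.items():
        _write_tsv(t, out / f"sample_table_{m}.tsv")
    qc_rows = []
    for m, rep in res.qc_reports.items():
        for it, rid, dw in rep.removed:
            qc_rows.append({"marker": m, "iteration": it, "replicate_id": rid, "dw": dw})
    pd.DataFrame(qc_rows, columns=["marker", "iteration", "replicate_id", "dw"]) \
        .to_csv(out / "qc_removals.tsv", sep="\t", index=False, float_format=_FMT)

    stats_json: dict[str, Any] = {}
    for sp, r in res.permanova.items():
        stats_json.setdefault("permanova", {})[sp] = json.loads(
            r.summary().to_json(orient="index", double_precision=12))
    for sp, r in res.anova.items():
        stats_json.setdefault("anova", {})[sp] = json.loads(
            r.summary().to_json(orient="index", double_precision=12))
    for key, r in res.ordination.items():
        stats_json.setdefault("ordination", {})[key] = {
            "eigenvalues": [round(float(v), 12) for v in r.eigenvalues],
            "percent_explained": [round(float(v), 12) for v in r.percent_explained],
            "constrained": bool(r.constrained),
            "adjusted_r2": None if r.adjusted_r2 is None else round(float(r.adjusted_r2), 12),
        }
        _write_tsv(r.site_scores, out / f"ordination_{key}_scores.tsv")
        _write_tsv(r.loadings, out / f"ordination_{key}_loadings.tsv", index_label="taxon")
    with open(out / "statistics.json", "w") as fh:
        json.dump(stats_json, fh, indent=1, sort_keys=True)

    manifest = {
        "version": __version__,
        "stages": STAGES,
        "stage_log": res.stage_log,
        "thresholds": {"min_len": int(thresholds.get("min_len", 10)),
                       "min_reads": int(thresholds.get("min_reads", 10)),
                       "min_prop": float(thresholds.get("min_prop", 0.01)),
                       "occurrence": float(thresholds.get("occurrence", 0.01))},
        "qc": {"max_iter": int(cfg.get("qc", {}).get("max_iter", 20))},
        "stats": {"n_perm": int(stats_cfg.get("n_perm", 999)),
                  "seed": int(stats_cfg.get("seed", seed if seed is not None else 0))},
        "seed": seed,
        "qc_summary": {m: {"removed": len(r.removed), "iterations": r.n_iterations,
                           "thresholds": [round(t, 12) for t in r.thresholds],
                           "samples_dropped": r.samples_dropped,
                           "converged": r.converged}
                       for m, r in res.qc_reports.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


# ---------------------------------------------------------------------------
# Figure-style summaries


def summarize_figures(run_dir: str | Path,
                      rra_threshold: float = 0.01,
                      detection_fraction: float = 0.05) -> dict[str, pd.DataFrame]:
    """Summary tables of a completed run: per-taxon mean +/- SE of RRA and
    wPOO for common taxa, and plant functional-group means by phase/season.

    A taxon enters the per-taxon summary when it contributed more than
    ``rra_threshold`` of the sequences in at least one sample AND was
    detected (above the same threshold) in strictly more than
    ``detection_fraction`` of the samples.
    """
    run = Path(run_dir)
    out: dict[str, pd.DataFrame] = {}
    profile_path = run / "diet_profile.tsv"
    if not profile_path.exists():
        import warnings
        warnings.warn(f"{run} has no pipeline outputs; summaries are empty")
        return out
    from .tables_io import read_profile, read_sample_table
    profile = read_profile(profile_path)
    matrix = profile.matrix

    detected = matrix > rra_threshold
    frac = detected.mean(axis=0)
    keep = [t for t in matrix.columns
            if detected[t].any() and frac[t] > detection_fraction]
    rra_sum = summary_mean_se(matrix[keep])
    out["rra_summary"] = rra_sum

    wpoo_samples = read_sample_table(run / "wpoo_samples.tsv")
    keep_w = [t for t in keep if t in wpoo_samples.columns]
    out["wpoo_summary"] = summary_mean_se(wpoo_samples.reindex(columns=keep_w, fill_value=0.0))

    meta_path = run / "metadata.tsv"
    if meta_path.exists():
        metadata = pd.read_csv(meta_path, sep="\t", index_col=0)
        fg = aggregate(matrix, by="functional_group", annotations=profile.annotations)
        fg = fg[[c for c in ("graminoid", "forb", "shrub") if c in fg.columns]]
        common = [s for s in fg.index if s in metadata.index]
        fg = fg.loc[common]
        groups = []
        for key in ("phase", "season"):
            g = fg.groupby(metadata.loc[common, key]).agg(["mean", "sem"])
            g.index.name = key
            groups.append(g)
        out["functional_groups"] = pd.concat(groups, keys=["phase", "season"])

    for name, df in out.items():
        df.to_csv(run / f"summary_{name}.tsv", sep="\t", float_format=_FMT)
    return out
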