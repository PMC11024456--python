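"""Synthetic multi-marker metabarcoding studies with known ground truth.

The generator emulates the post-clustering stage of a faecal-DNA diet study
of two boreal vole species sampled over two seasons and two phases of a
population cycle: per-marker MOTU count tables at the PCR-replicate level,
a replicate -> sample map, per-sample metadata, and MOTU taxonomy records.
Because the true per-sample diet proportions are retained, every pipeline
stage (replicate QC, filtering, fusion, metrics, statistics) can be tested
for recovery rather than merely for plumbing.

Generative model
----------------
* Each vole species has a base diet: a mixture over dietary categories
  (plants, bryophytes, arthropods, lichens, mushrooms) with a within-
  category Dirichlet over a fixed taxon pool.
* A sample's true diet is a Dirichlet draw around its species base
  (concentration = diet breadth); phase and season effects multiply chosen
  taxa and the profile is renormalized, so effects are compositional.
* Each marker sees the truth restricted to its categories, renormalized and
  multiplied by per-taxon detection biases (lognormal, fixed per study).
* Replicate counts are Dirichlet-multinomial around the marker truth: PCR
  replicates are overdispersed relative to multinomial sampling, which is
  exactly what makes the dw/db replicate filter non-trivial.
* Artifacts: failed replicates (zero reads), outlier replicates (profile
  replaced by another random sample's marker truth — a swapped/failed PCR),
  and tag jumps (each read independently moves to a uniformly chosen other
  replicate of the run with a small probability).
* Per marker, one PCR negative and one PCR positive control replicate are
  appended; the positive control carries marker-specific synthetic control
  sequences, whose leakage into biological replicates tracks the tag-jump
  rate.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import (DIETARY_CATEGORIES, MarkerSpec, MotuRecord,
                        ReplicateTable, default_markers)

DEFAULT_SEED = 20170801  # first trapping season of the emulated study design

_CLADE_OF_CATEGORY = {
    "plant": ("Spermatophyta", "Magnoliopsida"),
    "bryophyte": ("Bryophyta", "Bryopsida"),
    "arthropod": ("Arthropoda", "Insecta"),
    "lichen": ("Lecanoromycetes", "Lecanorales"),
    "mushroom": ("Agaricomycetes", "Agaricales"),
}

# Category-level diet of each species: bank voles are generalist browsers
# (large lichen/fungal component), tundra voles mostly seed plants.
_SPECIES_CATEGORY_WEIGHTS = {
    "bank": {"plant": 0.60, "bryophyte": 0.08, "arthropod": 0.07,
             "lichen": 0.18, "mushroom": 0.07},
    "tundra": {"plant": 0.84, "bryophyte": 0.06, "arthropod": 0.06,
               "lichen": 0.02, "mushroom": 0.02},
}


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults emulate the structure of a two-species, two-season, two-phase
    field study at desk scale: eight samples per design cell, triplicate
    PCRs for the seed-plant and eukaryote markers and duplicates for the
    rest, ~2000 reads per replicate, overdispersed replicates, and low
    rates of failed replicates, outlier replicates and tag jumps.
    """

    n_per_cell: int = 8                      # samples per species x phase x season cell
    species: tuple[str, ...] = ("bank", "tundra")
    taxa_per_category: Mapping[str, int] = field(default_factory=lambda: {
        "plant": 40, "bryophyte": 8, "arthropod": 10, "lichen": 6, "mushroom": 6})
    functional_group_split: tuple[int, int, int] = (12, 16, 12)  # graminoid/forb/shrub of the plant pool
    base_alpha: float = 0.30                 # within-category Dirichlet sparsity of the species base
    diet_concentration: float = 12.0         # Dirichlet concentration of samples around the base
    phase_effect: float = 2.0                # multiplier on affected taxa in the crash_low phase
    season_effect: float = 2.0               # multiplier on affected taxa in winter
    effect_fraction: float = 0.20            # fraction of taxa a phase/season effect touches
    reads_mean: float = 2000.0
    reads_dispersion: float = 0.15           # gamma-Poisson depth CV^2-ish; 0 = Poisson
    replicate_concentration: float = 100.0   # Dirichlet-multinomial phi; larger = less overdispersion
    replicates_per_marker: Mapping[str, int] = field(default_factory=lambda: {
        "Sper01": 3, "Euka02": 3, "Bryo01": 2, "Fung01": 2, "ZBJ": 2})
    tag_jump_rate: float = 0.005
    outlier_replicate_rate: float = 0.02
    replicate_failure_rate: float = 0.02
    marker_bias_sd: float = 0.25             # lognormal sigma of per-taxon detection bias; 0 = unbiased
    junk_motus_per_marker: int = 2           # short/low-read MOTUs exercising the global filter
    markers: Mapping[str, MarkerSpec] = field(default_factory=default_markers)
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        for r in (self.tag_jump_rate, self.outlier_replicate_rate, self.replicate_failure_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.diet_concentration <= 0 or self.base_alpha <= 0 or self.replicate_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.reads_mean < 0:
            raise ValueError("reads_mean must be >= 0")
        needed = {c for m in self.markers.values() for c in m.categories}
        for c in needed:
            if self.taxa_per_category.get(c, 0) <= 0:
                raise ValueError(f"no taxa configured for required category {c!r}")
        if sum(self.functional_group_split) != self.taxa_per_category.get("plant", 0):
            raise ValueError("functional_group_split must sum to the plant pool size")


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    diet: pd.DataFrame                                   # sample x taxon true proportions
    outliers: list[tuple[str, str, str]] = field(default_factory=list)  # (marker, replicate, source_sample)
    failed: list[tuple[str, str]] = field(default_factory=list)         # (marker, replicate)
    tag_jumped_reads: dict[str, int] = field(default_factory=dict)      # marker -> reads moved
    total_reads: dict[str, int] = field(default_factory=dict)           # marker -> reads before jumps
    marker_scopes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    affected_taxa: dict[str, list[str]] = field(default_factory=dict)   # effect -> taxa


@dataclass
class SimStudy:
    tables: dict[str, ReplicateTable]
    metadata: pd.DataFrame
    records: dict[str, dict[str, MotuRecord]]
    truth: SimTruth
    config: SimConfig


def _taxon_pool(config: SimConfig) -> tuple[list[str], dict[str, str], dict[str, str]]:
    """Taxon names, their dietary category, and plant functional groups."""
    taxa, cat_of, fg_of = [], {}, {}
    g, f, s = config.functional_group_split
    fg_seq = ["graminoid"] * g + ["forb"] * f + ["shrub"] * s
    for c in DIETARY_CATEGORIES:
        for i in range(config.taxa_per_category.get(c, 0)):
            name = f"{c}_{i + 1:02d}"
            taxa.append(name)
            cat_of[name] = c
            if c == "plant":
                fg_of[name] = fg_seq[i]
    return taxa, cat_of, fg_of


def _species_base(config: SimConfig, taxa: list[str], cat_of: dict[str, str],
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    base = {}
    for sp in config.species:
        w = _SPECIES_CATEGORY_WEIGHTS.get(sp) or {c: 1.0 for c in DIETARY_CATEGORIES}
        vec = np.zeros(len(taxa))
        for c in DIETARY_CATEGORIES:
            idx = [i for i, t in enumerate(taxa) if cat_of[t] == c]
            if not idx:
                continue
            within = rng.dirichlet(np.full(len(idx), config.base_alpha))
            vec[idx] = w.get(c, 0.0) * within
        base[sp] = vec / vec.sum()
    return base


def _motu_records(config: SimConfig, marker: MarkerSpec, taxa: list[str],
                  cat_of: dict[str, str], fg_of: dict[str, str],
                  rng: np.random.Generator) -> dict[str, MotuRecord]:
    records = {}
    lo, hi = marker.size_range
    for t in taxa:
        c = cat_of[t]
        if c not in marker.categories:
            continue
        phylum, cls = _CLADE_OF_CATEGORY[c]
        lineage = (("superkingdom", "Eukaryota"), ("phylum", phylum), ("class", cls),
                   ("genus", t.capitalize()))
        records[t] = MotuRecord(
            motu_id=t, marker_id=marker.marker_id,
            seq_length=int(rng.integers(max(lo, 10), hi + 1)),
            lineage=lineage, best_rank="genus", dietary_category=c,
            functional_group=fg_of.get(t, "none"),
        )
    return records


def _negbin_depth(mean: float, dispersion: float, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size)
    return rng.poisson(lam)


def _dirichlet_multinomial(p: np.ndarray, depth: int, phi: float,
                           rng: np.random.Generator) -> np.ndarray:
    if depth == 0 or p.sum() == 0:
        return np.zeros(p.size, dtype=np.int64)
    alpha = phi * p / p.sum()
    # Gamma representation tolerates zero-abundance taxa (alpha = 0 -> 0 mass)
    g = np.where(alpha > 0, rng.gamma(np.maximum(alpha, 1e-12)), 0.0)
    if g.sum() == 0:
        return np.zeros(p.size, dtype=np.int64)
    return rng.multinomial(depth, g / g.sum())


def _apply_tag_jumps(counts: np.ndarray, rate: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Move each read to a uniformly chosen *other* replicate with prob rate."""
    if rate <= 0 or counts.sum() == 0 or counts.shape[0] < 2:
        return counts, 0
    R = counts.shape[0]
    jump = rng.binomial(counts, rate)
    out = counts - jump
    moved = int(jump.sum())
    for src in range(R):
        row = jump[src]
        cols = np.flatnonzero(row)
        for j in cols:
            dests = rng.integers(0, R - 1, row[j])
            dests = dests + (dests >= src)       # uniform over the R-1 others
            np.add.at(out[:, j], dests, 1)
    return out, moved


def simulate_study(config: SimConfig | None = None) -> SimStudy:
    """Generate a full multi-marker study; see the module docstring.

    Identical configs (including seed) give identical output.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    taxa, cat_of, fg_of = _taxon_pool(config)
    base = _species_base(config, taxa, cat_of, rng)

    # design cells -> metadata
    rows = []
    k = 0
    for sp in config.species:
        for phase in ("increase_peak", "crash_low"):
            for season in ("summer", "winter"):
                for i in range(config.n_per_cell):
                    k += 1
                    site = (f"F{(i % 6) + 1}" if sp == "bank" else f"T{(i % 2) + 1}")
                    rows.append({"sample_id": f"S{k:03d}", "vole_species": sp,
                                 "season": season, "phase": phase, "site_id": site,
                                 "date": ("2017-08-15" if phase == "increase_peak" else "2018-08-15")})
    metadata = pd.DataFrame(rows).set_index("sample_id")
    samples = list(metadata.index)

    # phase/season effect taxa (chosen once per study)
    n_eff = max(1, int(round(config.effect_fraction * len(taxa))))
    phase_taxa = list(rng.choice(taxa, n_eff, replace=False)) if config.phase_effect != 1 else []
    season_taxa = list(rng.choice(taxa, n_eff, replace=False)) if config.season_effect != 1 else []

    truth_rows = np.empty((len(samples), len(taxa)))
    for i, s in enumerate(samples):
        sp = metadata.at[s, "vole_species"]
        p = rng.dirichlet(np.maximum(base[sp] * config.diet_concentration, 1e-8))
        if phase_taxa and metadata.at[s, "phase"] == "crash_low":
            idx = [taxa.index(t) for t in phase_taxa]
            p[idx] *= config.phase_effect
        if season_taxa and metadata.at[s, "season"] == "winter":
            idx = [taxa.index(t) for t in season_taxa]
            p[idx] *= config.season_effect
        truth_rows[i] = p / p.sum()
    diet = pd.DataFrame(truth_rows, index=samples, columns=taxa)

    truth = SimTruth(diet=diet,
                     marker_scopes={m: spec.categories for m, spec in config.markers.items()},
                     affected_taxa={"phase": phase_taxa, "season": season_taxa})

    tables: dict[str, ReplicateTable] = {}
    records: dict[str, dict[str, MotuRecord]] = {}
    for marker_id, spec in config.markers.items():
        recs = _motu_records(config, spec, taxa, cat_of, fg_of, rng)
        marker_taxa = list(recs)
        idx = [taxa.index(t) for t in marker_taxa]
        bias = (np.exp(rng.normal(0.0, config.marker_bias_sd, len(marker_taxa)))
                if config.marker_bias_sd > 0 else np.ones(len(marker_taxa)))

        def marker_truth(sample: str) -> np.ndarray:
            p = diet.loc[sample].to_numpy()[idx] * bias
            tot = p.sum()
            return p / tot if tot > 0 else p

        n_rep = config.replicates_per_marker.get(marker_id, 2)
        rep_ids, rep_sample, flags = [], {}, {}
        profiles = []
        for s in samples:
            mt = marker_truth(s)
            for r in range(1, n_rep + 1):
                rid = f"{s}_{marker_id}_R{r}"
                rep_ids.append(rid)
                rep_sample[rid] = s
                if rng.random() < config.outlier_replicate_rate:
                    donor = samples[int(rng.integers(len(samples)))]
                    while donor == s and len(samples) > 1:
                        donor = samples[int(rng.integers(len(samples)))]
                    profiles.append(marker_truth(donor))
                    truth.outliers.append((marker_id, rid, donor))
                else:
                    profiles.append(mt)

        depths = _negbin_depth(config.reads_mean, config.reads_dispersion,
                               len(rep_ids), rng)
        for j, rid in enumerate(rep_ids):
            if rng.random() < config.replicate_failure_rate:
                depths[j] = 0
                truth.failed.append((marker_id, rid))

        counts = np.zeros((len(rep_ids), len(marker_taxa)), dtype=np.int64)
        for j in range(len(rep_ids)):
            counts[j] = _dirichlet_multinomial(profiles[j], int(depths[j]),
                                               config.replicate_concentration, rng)

        # junk MOTUs: too short or too rare, removed by the global filter
        junk_names, junk_lens = [], []
        for j in range(config.junk_motus_per_marker):
            junk_names.append(f"JUNK_{marker_id}_{j + 1}")
            junk_lens.append(5 if j % 2 == 0 else max(spec.size_range[0], 10))
        if junk_names:
            junk_counts = np.zeros((len(rep_ids), len(junk_names)), dtype=np.int64)
            for j in range(len(junk_names)):
                hits = rng.choice(len(rep_ids), size=min(3, len(rep_ids)), replace=False)
                junk_counts[hits, j] = rng.integers(1, 4, len(hits))
            counts = np.hstack([counts, junk_counts])
            for name, ln in zip(junk_names, junk_lens):
                phylum, cls = _CLADE_OF_CATEGORY["plant"]
                recs[name] = MotuRecord(motu_id=name, marker_id=marker_id,
                                        seq_length=ln, lineage=(("phylum", phylum),),
                                        best_rank="", dietary_category="other")

        # control replicates: one PCR negative, one PCR positive per marker
        pos_motu = f"POSCTRL_{marker_id}"
        neg_id, pos_id = f"CTRLNEG_{marker_id}_R1", f"CTRLPOS_{marker_id}_R1"
        all_cols = list(recs)  # marker taxa + junk, before control column
        counts = np.vstack([counts,
                            np.zeros((1, counts.shape[1]), dtype=np.int64),  # negative
                            np.zeros((1, counts.shape[1]), dtype=np.int64)])  # positive
        ctrl_col = np.zeros((counts.shape[0], 1), dtype=np.int64)
        ctrl_col[-1, 0] = int(_negbin_depth(config.reads_mean, config.reads_dispersion, 1, rng)[0])
        counts = np.hstack([counts, ctrl_col])
        recs[pos_motu] = MotuRecord(motu_id=pos_motu, marker_id=marker_id,
                                    seq_length=120, lineage=(("synthetic", "control"),),
                                    best_rank="", dietary_category="other")
        rep_ids = rep_ids + [neg_id, pos_id]
        rep_sample[neg_id] = f"CTRL_NEG_{marker_id}"
        rep_sample[pos_id] = f"CTRL_POS_{marker_id}"
        flags[neg_id] = "pcr_negative"
        flags[pos_id] = "pcr_positive"

        truth.total_reads[marker_id] = int(counts.sum())
        counts, moved = _apply_tag_jumps(counts, config.tag_jump_rate, rng)
        truth.tag_jumped_reads[marker_id] = moved

        table = ReplicateTable(
            counts=pd.DataFrame(counts, index=rep_ids, columns=all_cols + [pos_motu]),
            replicate_to_sample=rep_sample, marker_id=marker_id,
            control_flags=flags,
        )
        tables[marker_id] = table
        records[marker_id] = recs

    return SimStudy(tables=tables, metadata=metadata, records=records,
                    truth=truth, config=config)


# ---------------------------------------------------------------------------
# Recovery experiment


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth diagnostics for one simulated study."""

    outlier_sensitivity: float
    outlier_specificity: float
    false_removal_rate: float
    fused_truth_spearman: float
    diversity_bias: float                  # mean fused ^1D minus mean true ^1D
    permanova_p: dict[str, float]
    n_samples: int
    n_outliers_injected: int
    n_removed: int


def run_recovery_experiment(config: SimConfig | None = None,
                            n_perm: int = 999,
                            qc_max_iter: int = 20,
                            stats_seed: int | None = None) -> RecoveryReport:
    """Simulate a study, run the full pipeline, and score it against truth.

    Reports outlier-detection sensitivity/specificity and the false-removal
    rate of the replicate filter, the pooled Spearman correlation between
    fused RRA and the true diet, the bias of fused Shannon-Hill diversity,
    and PERMANOVA p-values for phase and season on the fused profiles.
    """
    from scipy.stats import spearmanr
    from . import pipeline as pl
    from .composition_stats import hellinger, permanova
    from .diet_metrics import hill_diversity

    study = simulate_study(config)
    config = study.config
    out = pl.run_stages(study, qc_max_iter=qc_max_iter)

    injected = {(m, r) for m, r, _ in study.truth.outliers}
    failed = {(m, r) for m, r in study.truth.failed}
    removed = set()
    for m, rep in out.qc_reports.items():
        for _, rid, _ in rep.removed:
            removed.add((m, rid))
    clean = {(m, r) for m, t in study.tables.items()
             for r in t.replicate_ids
             if t.flag(r) == "none" and (m, r) not in injected and (m, r) not in failed}
    detectable = injected - failed
    tp = len(removed & detectable)
    fp = len(removed & clean)
    sens = tp / len(detectable) if detectable else float("nan")
    spec = 1.0 - fp / len(clean) if clean else float("nan")

    fused = out.profile.matrix
    truth = study.truth.diet
    common = [t for t in truth.columns if t in fused.columns]
    rows = [s for s in fused.index if s in truth.index]
    rho = float("nan")
    if common and rows:
        a = fused.loc[rows, common].to_numpy().ravel()
        b = truth.loc[rows, common].to_numpy().ravel()
        rho = float(spearmanr(a, b).statistic)

    d_f = hill_diversity(fused, 1.0)
    d_t = hill_diversity(truth.loc[rows], 1.0)
    bias = float(np.nanmean(d_f) - np.nanmean(d_t))

    design = study.metadata.loc[fused.index, ["phase", "season"]]
    pv = {}
    if fused.shape[0] >= 4:
        res = permanova(hellinger(fused).to_numpy(), design.reset_index(drop=True),
                        terms=["phase", "season"], n_perm=n_perm,
                        seed=stats_seed if stats_seed is not None else config.seed)
        pv = {t: float(res.p_value[t]) for t in res.terms}

    return RecoveryReport(
        outlier_sensitivity=sens, outlier_specificity=spec,
        false_removal_rate=(fp / len(clean) if clean else float("nan")),
        fused_truth_spearman=rho, diversity_bias=bias, permanova_p=pv,
        n_samples=fused.shape[0], n_outliers_injected=len(detectable),
        n_removed=len(removed),
    )
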