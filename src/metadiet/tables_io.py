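"""Reading, validating, writing and merging MOTU count tables.

The raw input of the pipeline is one count table per metabarcoding marker:
rows are MOTUs (molecular operational taxonomic units), columns are PCR
replicates, cells are integer read counts.  A companion map file links each
replicate to the faecal sample it came from.  In memory the table is kept
transposed (replicates x MOTUs) because every downstream operation treats
replicates/samples as observations.

All formats are plain TSV/CSV; nothing here touches FASTQ or aligner output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DIETARY_CATEGORIES = ("plant", "bryophyte", "arthropod", "lichen", "mushroom")
"""The five dietary components resolved by the marker panel."""

FUNCTIONAL_GROUPS = ("graminoid", "forb", "shrub")
"""Coarse plant functional groups; only seed-plant MOTUs carry one."""

CONTROL_FLAGS = ("none", "pcr_negative", "extraction_negative", "pcr_positive")


class ValidationError(ValueError):
    """Raised when an input table or record violates a structural invariant."""


@dataclass(frozen=True)
class MarkerSpec:
    """One metabarcoding primer set and the taxonomic scope it is trusted for.

    Parameters
    ----------
    marker_id :
        Short primer-set name, e.g. ``"Sper01"``.
    target_clades :
        Taxon names; a MOTU is in scope when any of these appears in its
        lineage (e.g. ``("Agaricomycetes", "Lecanoromycetes")`` for a fungal
        ITS marker that covers both mushrooms and lichens).
    categories :
        Dietary categories this marker can report on.
    gene_region :
        Free-text locus description.
    size_range :
        Plausible amplicon length range in bp (used by the simulator).
    """

    marker_id: str
    target_clades: tuple[str, ...]
    categories: tuple[str, ...]
    gene_region: str = ""
    size_range: tuple[int, int] = (10, 300)

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValidationError("marker_id must be non-empty")
        if not self.target_clades or any(not c for c in self.target_clades):
            raise ValidationError(f"marker {self.marker_id}: target clades must be non-empty")
        bad = set(self.categories) - set(DIETARY_CATEGORIES)
        if bad:
            raise ValidationError(f"marker {self.marker_id}: unknown categories {sorted(bad)}")


def default_markers() -> dict[str, MarkerSpec]:
    """The five diet primer sets of the two-vole study design.

    Sper01 (trnL P6 loop) targets seed plants, Bryo01 (trnL) bryophytes,
    Euka02 (18S V7) all eukaryotes and serves as the fusion scaffold,
    Fung01 (ITS1) mushrooms (Agaricomycetes) and lichens (Lecanoromycetes),
    and ZBJ (COI) arthropods.
    """
    return {
        "Sper01": MarkerSpec("Sper01", ("Spermatophyta",), ("plant",),
                             "trnL_P6-loop", (10, 220)),
        "Bryo01": MarkerSpec("Bryo01", ("Bryophyta",), ("bryophyte",),
                             "trnL_P6-loop", (41, 87)),
        "Euka02": MarkerSpec("Euka02", ("Eukaryota",),
                             ("plant", "bryophyte", "arthropod", "lichen", "mushroom"),
                             "18S_V7", (36, 892)),
        "Fung01": MarkerSpec("Fung01", ("Agaricomycetes", "Lecanoromycetes"),
                             ("mushroom", "lichen"), "ITS1", (68, 919)),
        "ZBJ": MarkerSpec("ZBJ", ("Arthropoda",), ("arthropod",),
                          "COI_Folmer", (50, 200)),
    }


@dataclass(frozen=True)
class MotuRecord:
    """Annotation attached to one MOTU of one marker."""

    motu_id: str
    marker_id: str
    seq_length: int
    lineage: tuple[tuple[str, str], ...]  # ordered (rank, name) pairs
    best_rank: str = ""
    dietary_category: str = "other"
    functional_group: str = "none"

    def __post_init__(self) -> None:
        if self.seq_length < 0:
            raise ValidationError(f"MOTU {self.motu_id}: negative seq_length")
        if self.dietary_category not in DIETARY_CATEGORIES + ("other",):
            raise ValidationError(
                f"MOTU {self.motu_id}: unknown dietary_category {self.dietary_category!r}")
        if self.functional_group not in FUNCTIONAL_GROUPS + ("none",):
            raise ValidationError(
                f"MOTU {self.motu_id}: unknown functional_group {self.functional_group!r}")
        if self.functional_group != "none" and self.dietary_category != "plant":
            raise ValidationError(
                f"MOTU {self.motu_id}: functional group only applies to plants")

    @property
    def lineage_names(self) -> frozenset[str]:
        return frozenset(name for _, name in self.lineage)


@dataclass
class ReplicateTable:
    """Integer read counts, PCR replicates x MOTUs, for one marker.

    ``counts`` rows are replicates, columns MOTUs.  ``replicate_to_sample``
    maps every replicate id to its faecal sample; control replicates map to
    pseudo-sample ids and carry a non-``"none"`` control flag.
    """

    counts: pd.DataFrame
    replicate_to_sample: dict[str, str]
    marker_id: str
    run_id: dict[str, str] = field(default_factory=dict)
    control_flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].tolist()
            raise ValidationError(f"duplicate replicate ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate MOTU ids: {dupes}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValidationError("counts must be finite integers")
            self.counts = c.astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValidationError("counts must be non-negative")
        orphans = [r for r in c.index if r not in self.replicate_to_sample]
        if orphans:
            raise ValidationError(f"replicates missing from the sample map: {orphans}")
        for r, flag in self.control_flags.items():
            if flag not in CONTROL_FLAGS:
                raise ValidationError(f"replicate {r}: unknown control flag {flag!r}")

    # -- convenience ----------------------------------------------------

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def motu_ids(self) -> list[str]:
        return list(self.counts.columns)

    def flag(self, replicate_id: str) -> str:
        return self.control_flags.get(replicate_id, "none")

    def sample_of(self, replicate_id: str) -> str:
        return self.replicate_to_sample[replicate_id]

    def noncontrol(self) -> "ReplicateTable":
        """Table restricted to biological (non-control) replicates."""
        keep = [r for r in self.counts.index if self.flag(r) == "none"]
        return self.subset(replicates=keep)

    def subset(self, replicates: Iterable[str] | None = None,
               motus: Iterable[str] | None = None) -> "ReplicateTable":
        c = self.counts
        if replicates is not None:
            c = c.loc[list(replicates)]
        if motus is not None:
            c = c[list(motus)]
        reps = set(c.index)
        return ReplicateTable(
            counts=c.copy(),
            replicate_to_sample={r: s for r, s in self.replicate_to_sample.items() if r in reps},
            marker_id=self.marker_id,
            run_id={r: v for r, v in self.run_id.items() if r in reps},
            control_flags={r: v for r, v in self.control_flags.items() if r in reps},
        )


# ---------------------------------------------------------------------------
# Reading


def _read_delimited(path: Path) -> pd.DataFrame:
    """Read a TSV or CSV with the first column as index; delimiter sniffed."""
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


_REPL_SUFFIX = re.compile(r"_R\d+$")


def read_replicate_map(path: str | Path) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Read a replicate->sample map TSV.

    Columns: ``replicate_id``, ``sample_id``, optional ``control_flag`` and
    ``run_id``.  Returns (replicate_to_sample, control_flags, run_id).
    """
    df = _read_delimited(Path(path)).reset_index()
    need = {"replicate_id", "sample_id"}
    if not need.issubset(df.columns):
        raise ValidationError(f"map file {path} must have columns {sorted(need)}")
    rts = dict(zip(df["replicate_id"], df["sample_id"]))
    flags = dict(zip(df["replicate_id"], df["control_flag"])) if "control_flag" in df else {}
    flags = {r: f for r, f in flags.items() if f and f != "none"}
    runs = dict(zip(df["replicate_id"], df["run_id"])) if "run_id" in df else {}
    return rts, flags, runs


def read_replicate_table(path: str | Path, marker: MarkerSpec | str,
                         map_path: str | Path | None = None) -> ReplicateTable:
    """Read a MOTU x replicate count table (wide, MOTUs as rows) from disk.

    When no map file is given, replicate ids are expected to follow the
    ``<sample>_R<k>`` tag-file convention and the sample id is recovered by
    stripping the ``_R<k>`` suffix.
    """
    marker_id = marker.marker_id if isinstance(marker, MarkerSpec) else marker
    raw = _read_delimited(Path(path))
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate MOTU ids {dupes}")
    try:
        counts = raw.apply(pd.to_numeric).T
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable count cell ({exc})") from exc
    arr = counts.to_numpy()
    if np.any(arr != np.floor(arr)):
        raise ValidationError(f"{path}: non-integer count values")
    if arr.size and arr.min() < 0:
        raise ValidationError(f"{path}: negative count values")
    counts = counts.astype(np.int64)

    if map_path is not None:
        rts, flags, runs = read_replicate_map(map_path)
        missing = [r for r in counts.index if r not in rts]
        if missing:
            raise ValidationError(
                f"{path}: replicates absent from map {map_path}: {missing}")
    else:
        rts = {r: _REPL_SUFFIX.sub("", r) for r in counts.index}
        flags, runs = {}, {}
    return ReplicateTable(counts=counts, replicate_to_sample=rts,
                          marker_id=marker_id, run_id=runs, control_flags=flags)


def read_motu_records(path: str | Path, marker_id: str) -> dict[str, MotuRecord]:
    """Read MOTU annotations from a TSV with one taxonomy rank per column.

    Required columns: ``motu_id``, ``seq_length``; recognised: ``best_rank``,
    ``dietary_category``, ``functional_group``; every other column is treated
    as a taxonomy rank (empty cells are skipped).
    """
    df = _read_delimited(Path(path)).reset_index()
    if "motu_id" not in df.columns or "seq_length" not in df.columns:
        raise ValidationError(f"{path}: need motu_id and seq_length columns")
    special = {"motu_id", "seq_length", "best_rank", "dietary_category", "functional_group"}
    rank_cols = [c for c in df.columns if c not in special]
    records: dict[str, MotuRecord] = {}
    for _, row in df.iterrows():
        lineage = tuple((rk, row[rk]) for rk in rank_cols if row[rk])
        rec = MotuRecord(
            motu_id=row["motu_id"], marker_id=marker_id,
            seq_length=int(row["seq_length"]),
            lineage=lineage,
            best_rank=row.get("best_rank", "") or "",
            dietary_category=row.get("dietary_category", "other") or "other",
            functional_group=row.get("functional_group", "none") or "none",
        )
        if rec.motu_id in records:
            raise ValidationError(f"{path}: duplicate MOTU id {rec.motu_id}")
        records[rec.motu_id] = rec
    return records


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata, validating the categorical levels."""
    df = _read_delimited(Path(path)).reset_index()
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: metadata needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    levels = {"vole_species": {"bank", "tundra"},
              "season": {"summer", "winter"},
              "phase": {"increase_peak", "crash_low"}}
    for col, allowed in levels.items():
        if col in df.columns:
            bad = set(df[col]) - allowed
            if bad:
                raise ValidationError(f"{path}: {col} has unknown levels {sorted(bad)}")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# Merging sequencing runs


def merge_runs(a: ReplicateTable, b: ReplicateTable) -> ReplicateTable:
    """Element-wise sum of two sequencing runs of the same marker.

    Replicate ids identify the same physical PCR in both runs; the union of
    replicates and MOTUs is taken and absent cells contribute zero.  Exact
    integer arithmetic, hence commutative and associative.
    """
    if a.marker_id != b.marker_id:
        raise ValidationError(f"marker mismatch: {a.marker_id} vs {b.marker_id}")
    for r, s in b.replicate_to_sample.items():
        if a.replicate_to_sample.get(r, s) != s:
            raise ValidationError(f"replicate {r} maps to different samples in the two runs")
    counts = a.counts.add(b.counts, fill_value=0).astype(np.int64)
    counts = counts.loc[sorted(counts.index), sorted(counts.columns)]
    return ReplicateTable(
        counts=counts,
        replicate_to_sample={**a.replicate_to_sample, **b.replicate_to_sample},
        marker_id=a.marker_id,
        run_id={**a.run_id, **b.run_id},
        control_flags={**a.control_flags, **b.control_flags},
    )


# ---------------------------------------------------------------------------
# Writing


_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a samples-as-rows table as TSV with full float precision."""
    if table.size and not np.all(np.isfinite(table.to_numpy(dtype=float))):
        raise ValidationError("refusing to write non-finite values")
    table.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="sample_id")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_profile(profile: "DietProfile", path: str | Path) -> None:
    """Write a fused diet profile as wide TSV plus a taxon-annotation sidecar."""
    from .marker_fusion import DietProfile  # local import avoids a cycle
    assert isinstance(profile, DietProfile)
    write_sample_table(profile.matrix, path)
    sidecar = Path(str(path) + ".taxa.tsv")
    profile.annotations.to_csv(sidecar, sep="\t", index_label="taxon")


def read_profile(path: str | Path) -> "DietProfile":
    from .marker_fusion import DietProfile
    matrix = read_sample_table(path)
    sidecar = Path(str(path) + ".taxa.tsv")
    if sidecar.exists():
        annotations = pd.read_csv(sidecar, sep="\t", index_col=0, keep_default_na=False)
    else:
        annotations = pd.DataFrame(index=matrix.columns)
    return DietProfile(matrix=matrix, annotations=annotations)
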