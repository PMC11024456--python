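"""Global and per-sample MOTU filters, taxonomic-scope restriction, controls.

Three filters mirror the post-clustering cleanup of a metabarcoding dataset:

* a global filter dropping very short sequences and MOTUs with negligible
  dataset-wide read support,
* a per-sample relative-abundance filter (the tag-jump filter): entries below
  1% of a sample are zeroed, which removes the low-level cross-talk that
  index switching spreads between samples,
* a taxonomic-scope filter keeping only MOTUs inside the clade each primer
  set is trusted for.

Control screening is advisory: it reports contamination levels in negative
controls and verifies that positive-control sequences were recovered, but
subtracts nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import MarkerSpec, MotuRecord, ReplicateTable


def filter_global(table: ReplicateTable, records: Mapping[str, MotuRecord],
                  min_len: int = 10, min_total_reads: int = 10) -> ReplicateTable:
    """Drop MOTUs shorter than ``min_len`` bp or with dataset-wide total
    reads at or below ``min_total_reads``.

    Boundary semantics: a 10 bp sequence is kept at the default ``min_len``
    (strictly shorter is dropped); a MOTU totalling exactly 10 reads is
    dropped at the default ``min_total_reads`` (<= is dropped).  The two
    criteria are independent, so the filter is order-independent and
    idempotent.
    """
    missing = [m for m in table.motu_ids if m not in records]
    if missing:
        raise KeyError(f"MOTUs without records: {missing}")
    totals = table.counts.sum(axis=0)
    keep = [m for m in table.motu_ids
            if records[m].seq_length >= min_len and totals[m] > min_total_reads]
    return table.subset(motus=keep)


def filter_min_proportion(table: pd.DataFrame, threshold: float = 0.01
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample tag-jump filter on a relative-abundance table.

    Entries below ``threshold`` within a sample are set to zero, columns
    that become all-zero are dropped, and rows are renormalized to sum 1.
    Rows emptied by the filter are kept (as zero rows) and returned as a
    flag list, so sample bookkeeping survives downstream.

    Idempotent: after renormalization every surviving entry is at least
    ``threshold`` (the row sum after zeroing is <= 1), so a second pass
    zeroes nothing new.
    """
    if table.empty:
        return table.copy(), []
    arr = table.to_numpy(dtype=float).copy()
    arr[arr < threshold] = 0.0
    sums = arr.sum(axis=1)
    empty = table.index[sums == 0].tolist()
    nonzero = sums > 0
    arr[nonzero] = arr[nonzero] / sums[nonzero, None]
    out = pd.DataFrame(arr, index=table.index, columns=table.columns)
    out = out.loc[:, (out != 0).any(axis=0)]
    return out, empty


def filter_taxonomic_scope(table, records: Mapping[str, MotuRecord],
                           marker: MarkerSpec):
    """Keep only MOTUs whose lineage contains one of the marker's target clades.

    Works on either a ReplicateTable or a samples x MOTUs DataFrame.  MOTUs
    lacking a lineage are treated as out of scope.
    """
    cols = table.motu_ids if isinstance(table, ReplicateTable) else list(table.columns)
    targets = set(marker.target_clades)
    keep = []
    for m in cols:
        rec = records.get(m)
        if rec is not None and rec.lineage and (rec.lineage_names & targets):
            keep.append(m)
    if isinstance(table, ReplicateTable):
        return table.subset(motus=keep)
    return table[keep].copy()


@dataclass
class ControlReport:
    """Advisory summary of control replicates for one marker table."""

    marker_id: str
    shares: pd.DataFrame = field(default_factory=pd.DataFrame)  # control replicate x MOTU read shares
    negative_flags: list[tuple[str, str, float]] = field(default_factory=list)  # (replicate, motu, share)
    positive_recovered: bool | None = None
    control_failures: list[str] = field(default_factory=list)
    warning: str = ""


def screen_controls(table: ReplicateTable,
                    positive_motus: set[str] | None = None,
                    records: Mapping[str, MotuRecord] | None = None,
                    flag_threshold: float = 0.01) -> ControlReport:
    """Report contamination in negative controls and positive-control recovery.

    Per control replicate, the read share of every MOTU is tabulated.
    Dietary MOTUs exceeding ``flag_threshold`` relative abundance inside a
    negative control are flagged.  Positive-control recovery is confirmed
    when every expected positive-control MOTU has reads in each positive
    control replicate; ``positive_motus`` defaults to MOTU ids starting
    with ``POSCTRL`` (the simulator's convention).
    """
    report = ControlReport(marker_id=table.marker_id)
    ctrl = [r for r in table.replicate_ids if table.flag(r) != "none"]
    if not ctrl:
        report.warning = "no control replicates present"
        return report
    counts = table.counts.loc[ctrl]
    totals = counts.sum(axis=1)
    shares = counts.div(totals.where(totals > 0, 1), axis=0)
    report.shares = shares
    if positive_motus is None:
        positive_motus = {m for m in table.motu_ids if m.startswith("POSCTRL")}

    def is_dietary(m: str) -> bool:
        if m in positive_motus:
            return False
        if records is None:
            return True
        rec = records.get(m)
        return rec is not None and rec.dietary_category != "other"

    for rep in ctrl:
        flag = table.flag(rep)
        if flag in ("pcr_negative", "extraction_negative"):
            for m in table.motu_ids:
                s = float(shares.at[rep, m])
                if s > flag_threshold and is_dietary(m):
                    report.negative_flags.append((rep, m, s))
        elif flag == "pcr_positive":
            missing = [m for m in positive_motus if counts.at[rep, m] == 0] \
                if positive_motus else []
            if missing or not positive_motus:
                report.control_failures.append(rep)
    pos_reps = [r for r in ctrl if table.flag(r) == "pcr_positive"]
    if pos_reps:
        report.positive_recovered = not any(r in report.control_failures for r in pos_reps)
    return report


def positive_control_leakage(table: ReplicateTable,
                             positive_motus: set[str] | None = None) -> float:
    """Mean share of positive-control reads found outside control replicates.

    Tag jumps move reads between replicates of a sequencing run; because the
    positive-control sequences exist nowhere else, any of their reads seen in
    biological replicates measures the cross-contamination rate directly.
    Returns (control-sequence reads in biological replicates) / (all
    control-sequence reads).
    """
    if positive_motus is None:
        positive_motus = {m for m in table.motu_ids if m.startswith("POSCTRL")}
    if not positive_motus:
        return float("nan")
    cols = [m for m in table.motu_ids if m in positive_motus]
    bio = [r for r in table.replicate_ids if table.flag(r) == "none"]
    total = table.counts[cols].to_numpy().sum()
    if total == 0:
        return float("nan")
    stray = table.counts.loc[bio, cols].to_numpy().sum()
    return float(stray) / float(total)
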