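"""Fusing the specialized marker datasets onto the eukaryote scaffold.

The broad-range eukaryote marker sees the whole diet at coarse taxonomic
resolution, while each specialized marker resolves one dietary category
(seed plants, bryophytes, fungi, arthropods) finely but says nothing about
the rest of the diet.  Fusion keeps the eukaryote marker's per-category
proportions as the backbone and re-distributes each category's mass over
the finely resolved taxa of the matching specialized marker, renormalized
within the category.  The result is one relative-read-abundance profile per
sample spanning the full diet.

Categories the eukaryote marker missed entirely get zero fused mass even
when a specialized marker detected them; those detections are preserved in
the occurrence matrix, which unions detections across all markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import DIETARY_CATEGORIES, MotuRecord

PLACEHOLDER_SUFFIX = "_unresolved"


@dataclass
class DietProfile:
    """Per-sample fused relative abundances over diet taxa.

    ``matrix`` rows are samples, columns taxa; each non-empty row sums to 1.
    ``annotations`` is indexed by taxon with columns ``dietary_category``,
    ``functional_group`` and ``source_marker``.
    """

    matrix: pd.DataFrame
    annotations: pd.DataFrame
    unfusable: list[str] = field(default_factory=list)
    scaffold_conflicts: list[tuple[str, str]] = field(default_factory=list)  # (sample, category)

    def __post_init__(self) -> None:
        arr = self.matrix.to_numpy(dtype=float)
        if arr.size:
            if arr.min() < 0:
                raise ValueError("diet profile entries must be non-negative")
            sums = arr.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | (sums == 0))
            if bad.any():
                raise ValueError(
                    f"diet profile rows must sum to 1: {list(self.matrix.index[bad])}")

    def category_sums(self) -> pd.DataFrame:
        """Aggregate the fused matrix back to dietary-category proportions."""
        cats = self.annotations["dietary_category"]
        return self.matrix.T.groupby(cats).sum().T


def category_proportions(euka: pd.DataFrame,
                         records: Mapping[str, MotuRecord]) -> pd.DataFrame:
    """Per-sample proportions of the five dietary categories (plus other).

    ``euka`` is the filtered, replicate-averaged eukaryote sample table.
    Every MOTU is mapped to its dietary category and proportions are summed;
    rows of non-empty samples sum to 1.
    """
    cats = []
    for m in euka.columns:
        rec = records.get(m)
        cats.append(rec.dietary_category if rec is not None else "other")
    order = list(DIETARY_CATEGORIES) + ["other"]
    out = euka.T.groupby(pd.Series(cats, index=euka.columns)).sum().T
    for c in order:
        if c not in out.columns:
            out[c] = 0.0
    return out[order]


def fuse_markers(cat_props: pd.DataFrame,
                 marker_tables: Mapping[str, pd.DataFrame],
                 marker_of_category: Mapping[str, str] | None = None,
                 records: Mapping[str, MotuRecord] | None = None) -> DietProfile:
    """Distribute eukaryote category proportions over specialized-marker taxa.

    Parameters
    ----------
    cat_props :
        Output of :func:`category_proportions`; samples x categories.
    marker_tables :
        Map dietary category -> replicate-averaged, in-scope sample table of
        the specialized marker, already restricted to that category's MOTUs.
    marker_of_category :
        Optional map category -> marker id for provenance annotation.
    records :
        Optional MOTU annotations used to carry functional groups through.

    For each sample and category with scaffold proportion p > 0: if the
    specialized table has data for the sample, its row is renormalized
    within the category and scaled by p; otherwise p is parked on a single
    ``<category>_unresolved`` placeholder taxon.  Mass is conserved per
    category, so fused rows sum to 1.  Samples absent from the scaffold are
    reported as unfusable; specialized detections in categories the scaffold
    scored zero are logged as conflicts (occurrence-only evidence).
    """
    marker_of_category = marker_of_category or {}
    records = records or {}
    categories = [c for c in cat_props.columns]
    taxa: list[str] = []
    ann_rows: list[dict] = []
    for c in categories:
        sub = marker_tables.get(c)
        if sub is not None:
            for t in sub.columns:
                if t not in taxa:
                    rec = records.get(t)
                    taxa.append(t)
                    ann_rows.append({
                        "taxon": t, "dietary_category": c,
                        "functional_group": rec.functional_group if rec else "none",
                        "source_marker": marker_of_category.get(c, ""),
                    })
        ph = c + PLACEHOLDER_SUFFIX
        taxa.append(ph)
        ann_rows.append({"taxon": ph, "dietary_category": c,
                         "functional_group": "none", "source_marker": "scaffold"})

    samples = list(cat_props.index)
    mat = pd.DataFrame(0.0, index=samples, columns=taxa)
    unfusable = []
    conflicts = []
    for s in samples:
        row = cat_props.loc[s]
        if row.sum() == 0:
            unfusable.append(s)
            continue
        for c in categories:
            p = float(row[c])
            sub = marker_tables.get(c)
            has_special = (sub is not None and s in sub.index
                           and float(sub.loc[s].sum()) > 0)
            if p <= 0:
                if has_special:
                    conflicts.append((s, c))
                continue
            if has_special:
                r = sub.loc[s].to_numpy(dtype=float)
                mat.loc[s, list(sub.columns)] += p * r / r.sum()
            else:
                mat.loc[s, c + PLACEHOLDER_SUFFIX] += p
    # drop placeholder columns that never received mass
    used = (mat != 0).any(axis=0)
    for t in list(mat.columns):
        if t.endswith(PLACEHOLDER_SUFFIX) and not used[t]:
            mat = mat.drop(columns=t)
    ann = pd.DataFrame(ann_rows).set_index("taxon").loc[list(mat.columns)]
    profile = DietProfile(matrix=mat, annotations=ann,
                          unfusable=unfusable, scaffold_conflicts=conflicts)
    return profile


def occurrence_union(marker_tables: Mapping[str, pd.DataFrame],
                     threshold: float = 0.01) -> pd.DataFrame:
    """Binary sample x taxon occurrence matrix, unioned over markers.

    A taxon occurs in a sample when its within-marker relative read
    abundance is strictly above ``threshold`` (an RRA of exactly 1% does not
    count as an occurrence).  The union keeps specialized-marker detections
    that lack scaffold support, so occurrence-based metrics (wPOO) see them
    even though fusion assigns them zero abundance.
    """
    samples: list[str] = []
    taxa: list[str] = []
    for t in marker_tables.values():
        samples.extend(s for s in t.index if s not in samples)
        taxa.extend(c for c in t.columns if c not in taxa)
    occ = pd.DataFrame(0, index=samples, columns=taxa, dtype=int)
    for t in marker_tables.values():
        hit = (t > threshold).astype(int)
        block = occ.loc[hit.index, hit.columns].to_numpy()
        occ.loc[hit.index, hit.columns] = np.maximum(block, hit.to_numpy())
    return occ
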