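"""Diet metrics: RRA, weighted percent of occurrence, Hill diversity,
and taxon/functional-group aggregation.

Two complementary summaries of a metabarcoding diet are used throughout:

* RRA (relative read abundance): read counts normalized within each sample;
  semi-quantitative, sensitive to amplification bias.
* wPOO (weighted percent of occurrence): each occurrence of a taxon in a
  sample is weighted by 1/(number of taxa occurring in that sample), then
  averaged across samples.  A sample containing exactly taxa A, B and C
  contributes one third to each, so diverse samples do not dominate.

Diet diversity uses Hill numbers ^qD, the effective number of equally
abundant taxa: ^0D is richness, ^1D = exp(Shannon entropy), and ^qD is
non-increasing in q.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .marker_fusion import DietProfile


def rra(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Row-normalize counts (or abundances) to relative read abundances.

    Rows of zeros stay zero (flagged by callers via ``empty_samples``);
    idempotent on already-normalized rows.
    """
    df = pd.DataFrame(table).astype(float)
    sums = df.sum(axis=1)
    safe = sums.where(sums > 0, 1.0)
    return df.div(safe, axis=0)


def empty_samples(table: pd.DataFrame) -> list:
    """Samples (rows) with no reads / no abundance at all."""
    sums = table.sum(axis=1)
    return table.index[sums == 0].tolist()


def wpoo(occurrences: pd.DataFrame) -> pd.Series:
    """Weighted percent of occurrence per taxon from a binary matrix.

    wPOO(t) = mean over samples of (1/k_s if t occurs in s, else 0) where
    k_s is the number of taxa occurring in sample s.  Samples with zero
    occurrences are excluded from the mean.  Sums to 1 over taxa whenever
    every included sample has at least one occurrence.
    """
    occ = occurrences.astype(float)
    k = occ.sum(axis=1)
    included = occ.loc[k > 0]
    if included.empty:
        return pd.Series(0.0, index=occurrences.columns)
    weights = included.div(k[k > 0], axis=0)
    return weights.mean(axis=0)


def wpoo_per_sample(occurrences: pd.DataFrame) -> pd.DataFrame:
    """Per-sample occurrence weights (each row sums to 1); the across-sample
    mean of these rows is :func:`wpoo`.  Useful for mean +/- SE summaries."""
    occ = occurrences.astype(float)
    k = occ.sum(axis=1)
    out = occ.loc[k > 0].div(k[k > 0], axis=0)
    return out


def hill_diversity(profile, q: float = 1.0):
    """Hill number ^qD of one profile row or of every row of a matrix.

    ^qD = (sum_i p_i^q)^(1/(1-q)) for q != 1, with the analytic q -> 1
    limit ^1D = exp(-sum_i p_i ln p_i); zero entries are ignored.  ^0D is
    taxon richness.  Rows must be relative abundances summing to 1; empty
    rows yield NaN.
    """
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    arr = np.asarray(profile, dtype=float)
    single = arr.ndim == 1
    mat = np.atleast_2d(arr)
    if mat.size and mat.min() < 0:
        raise ValueError("profile entries must be non-negative")
    out = np.full(mat.shape[0], np.nan)
    for i, row in enumerate(mat):
        p = row[row > 0]
        if p.size == 0:
            continue
        if abs(q - 1.0) < 1e-12:
            out[i] = float(np.exp(-np.sum(p * np.log(p))))
        elif q == 0:
            out[i] = float(p.size)
        else:
            out[i] = float(np.sum(p ** q) ** (1.0 / (1.0 - q)))
    if single:
        return float(out[0])
    if isinstance(profile, pd.DataFrame):
        return pd.Series(out, index=profile.index, name=f"hill_q{q:g}")
    return out


def diversity_table(profile: pd.DataFrame, q: float = 1.0,
                    genus_taxa: list | None = None) -> pd.DataFrame:
    """Per-sample ^qD on all taxa and, optionally, on a genus-identified subset.

    Mirrors reporting diversity both for every MOTU and for MOTUs resolved
    to genus; the subset's rows are renormalized before the computation.
    """
    out = pd.DataFrame({"all_motus": hill_diversity(profile, q)})
    if genus_taxa is not None:
        cols = [t for t in genus_taxa if t in profile.columns]
        sub = rra(profile[cols]) if cols else profile.iloc[:, :0]
        out["genus_level"] = hill_diversity(sub, q) if cols else np.nan
    return out


def aggregate(profile, by: str = "dietary_category",
              annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sum member proportions into groups given by an annotation column.

    ``profile`` may be a :class:`DietProfile` (annotations taken from it) or
    a plain sample x taxon DataFrame with ``annotations`` supplied.  Taxa
    without a value under ``by`` fall into ``"other"``.  Row sums are
    preserved, so aggregation commutes with row normalization.
    """
    if isinstance(profile, DietProfile):
        matrix, ann = profile.matrix, profile.annotations
    else:
        if annotations is None:
            raise ValueError("annotations required when profile is a plain table")
        matrix, ann = profile, annotations
    keys = []
    for t in matrix.columns:
        v = ann[by].get(t, None) if by in ann.columns else None
        if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("", "none"):
            v = "other"
        keys.append(v)
    return matrix.T.groupby(pd.Series(keys, index=matrix.columns)).sum().T


def summary_mean_se(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error across samples for each taxon column."""
    n = per_sample.notna().sum(axis=0)
    mean = per_sample.mean(axis=0)
    se = per_sample.std(axis=0, ddof=1) / np.sqrt(n.where(n > 0, 1))
    return pd.DataFrame({"mean": mean, "se": se, "n": n})
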