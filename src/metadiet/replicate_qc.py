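"""PCR-replicate quality control by the iterative dw/db distance procedure.

Non-functional PCR reactions produce replicates whose composition bears
little resemblance to the other replicates of the same faecal sample.  The
filter exploits the expectation that replicates of one sample are more
similar to each other than any two distinct samples are: it compares the
Euclidean distance of each replicate to its sample's mean profile (dw)
against the distribution of pairwise distances between sample mean profiles
(db), and discards replicates beyond the intersection of the two
distributions.  Removal, re-averaging and re-thresholding are repeated until
a fixpoint.

Distances are computed on relative-abundance profiles, never raw counts,
so the procedure is invariant to sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .tables_io import ReplicateTable

_DEGENERATE_TOL = 1e-12


@dataclass
class ReplicateDistances:
    """dw/db distance sets for one marker table at one QC iteration."""

    dw: pd.Series            # per replicate: distance to own sample's mean profile
    db: np.ndarray           # pairwise distances between sample mean profiles
    threshold: float | None = None


@dataclass
class QcReport:
    """What the iterative filter removed and why."""

    removed: list[tuple[int, str, float]] = field(default_factory=list)  # (iteration, replicate, dw)
    thresholds: list[float] = field(default_factory=list)
    n_iterations: int = 0
    samples_dropped: list[str] = field(default_factory=list)
    zero_read_replicates: list[str] = field(default_factory=list)
    converged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["iteration", "replicate_id", "dw"])


def replicate_profiles(table: ReplicateTable) -> tuple[pd.DataFrame, list[str]]:
    """Row-normalize replicate counts to relative abundances.

    Returns (profiles, zero_read_replicates).  Zero-read replicates are
    excluded from the profile matrix rather than divided by zero.
    """
    counts = table.counts
    totals = counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    kept = counts.loc[totals > 0]
    profiles = kept.div(totals[totals > 0], axis=0)
    return profiles, zero


def sample_means(profiles: pd.DataFrame, replicate_to_sample: dict[str, str]) -> pd.DataFrame:
    """Unweighted mean profile per sample (each replicate counts equally)."""
    groups = pd.Series({r: replicate_to_sample[r] for r in profiles.index})
    return profiles.groupby(groups).mean()


def replicate_distances(profiles: pd.DataFrame,
                        replicate_to_sample: dict[str, str]) -> ReplicateDistances:
    """Compute dw (replicate -> own sample mean) and db (sample mean pairs).

    Requires at least two samples; db is undefined otherwise.
    """
    means = sample_means(profiles, replicate_to_sample)
    if len(means) < 2:
        raise ValueError("replicate_distances needs >= 2 samples to form db")
    dw_vals = {}
    for rep in profiles.index:
        mean = means.loc[replicate_to_sample[rep]]
        dw_vals[rep] = float(np.linalg.norm(profiles.loc[rep].to_numpy() - mean.to_numpy()))
    m = means.to_numpy()
    # condensed pairwise Euclidean distances between sample means
    from scipy.spatial.distance import pdist
    db = pdist(m, metric="euclidean")
    return ReplicateDistances(dw=pd.Series(dw_vals), db=db)


def estimate_threshold(d: ReplicateDistances) -> float:
    """Dissimilarity threshold: the intersection of the dw and db densities.

    Gaussian KDEs (Silverman bandwidth) of dw and db are evaluated on a
    512-point grid over [0, max(db)]; the threshold is the smallest grid
    point past the dw mode where the dw density falls below the db density.

    Fallbacks for shapes a KDE cannot resolve:
    - dw degenerate (all values equal): that value plus half the distance to
      min(db);
    - densities that never cross with dw entirely below db: the midpoint of
      max(dw) and min(db).
    """
    dw = np.asarray(d.dw, dtype=float)
    db = np.asarray(d.db, dtype=float)
    if dw.size == 0 or db.size == 0:
        raise ValueError("estimate_threshold needs non-empty dw and db")

    if dw.max() - dw.min() < _DEGENERATE_TOL:  # degenerate dw
        v = float(dw[0])
        gap = float(db.min()) - v
        return v + gap / 2 if gap > 0 else v

    grid = np.linspace(0.0, float(db.max()), 512)
    kde_w = gaussian_kde(dw, bw_method="silverman")
    if db.max() - db.min() < _DEGENERATE_TOL:
        # db degenerate: treat its density as a spike at that value
        fw = kde_w(grid)
        mode = int(np.argmax(fw))
        spike = float(db[0])
        cand = grid[(grid > grid[mode]) & (grid >= spike)]
        return float(cand[0]) if cand.size else float((dw.max() + spike) / 2)
    kde_b = gaussian_kde(db, bw_method="silverman")
    fw = kde_w(grid)
    fb = kde_b(grid)
    mode = int(np.argmax(fw))
    after = np.arange(mode + 1, grid.size)
    below = after[fw[after] < fb[after]]
    if below.size:
        return float(grid[below[0]])
    return float((dw.max() + db.min()) / 2)  # non-crossing fallback


def filter_replicates_iterative(table: ReplicateTable,
                                max_iter: int = 20) -> tuple[ReplicateTable, QcReport]:
    """Iteratively remove outlier replicates with dw above the threshold.

    Each iteration recomputes profiles, sample means, the dw/db sets and the
    threshold from the surviving replicates, then removes every replicate
    with dw strictly above the threshold (batch removal; ties are kept).
    Iteration stops when a pass removes nothing or ``max_iter`` is reached;
    at convergence the result is a fixpoint.

    Control replicates are not subject to the filter (they are not
    biological replicates of any sample) and pass through untouched.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    report = QcReport()
    controls = [r for r in table.replicate_ids if table.flag(r) != "none"]
    work = table.subset(replicates=[r for r in table.replicate_ids
                                    if table.flag(r) == "none"])

    samples_before = set(work.replicate_to_sample[r] for r in work.replicate_ids)
    for it in range(1, max_iter + 1):
        report.n_iterations = it
        profiles, zero = replicate_profiles(work)
        for z in zero:
            if z not in report.zero_read_replicates:
                report.zero_read_replicates.append(z)
        if zero:
            work = work.subset(replicates=[r for r in work.replicate_ids if r not in zero])
        rts = {r: work.replicate_to_sample[r] for r in profiles.index}
        if len(set(rts.values())) < 2:
            report.converged = True  # db undefined; nothing more to test
            break
        d = replicate_distances(profiles, rts)
        thr = estimate_threshold(d)
        report.thresholds.append(thr)
        out = d.dw.index[d.dw > thr].tolist()
        if not out:
            report.converged = True
            break
        for rep in out:
            report.removed.append((it, rep, float(d.dw[rep])))
        work = work.subset(replicates=[r for r in work.replicate_ids if r not in out])

    samples_after = set(work.replicate_to_sample[r] for r in work.replicate_ids)
    report.samples_dropped = sorted(samples_before - samples_after)
    if controls:
        merged = pd.concat([work.counts, table.counts.loc[controls]])
        result = ReplicateTable(
            counts=merged,
            replicate_to_sample={r: table.replicate_to_sample[r] for r in merged.index},
            marker_id=table.marker_id,
            run_id={r: v for r, v in table.run_id.items() if r in merged.index},
            control_flags={r: v for r, v in table.control_flags.items() if r in merged.index},
        )
    else:
        result = work
    return result, report


def average_replicates(table: ReplicateTable) -> pd.DataFrame:
    """Per-sample mean of replicate relative-abundance profiles.

    Equal weight per replicate regardless of its depth.  Control replicates
    are ignored.  Returns a samples x MOTUs DataFrame whose rows sum to 1.
    """
    work = table.noncontrol()
    profiles, zero = replicate_profiles(work)
    if profiles.empty:
        return pd.DataFrame(columns=table.counts.columns)
    rts = {r: work.replicate_to_sample[r] for r in profiles.index}
    return sample_means(profiles, rts)
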