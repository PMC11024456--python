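"""Composition and diversity statistics on Hellinger-transformed profiles.

The compositional analyses follow the standard transformation-based route:
relative read abundances are Hellinger transformed (entry-wise square roots
of row proportions), after which Euclidean geometry on the transformed rows
equals Hellinger distance on the raw compositions.  On that geometry the
module provides

* PERMANOVA with sequential (Type-I) sums of squares over an ordered term
  list, significance by permutation of the response rows (optionally within
  strata), add-one p-value estimator;
* PCA (unconstrained) and RDA (constrained, optionally partial on condition
  factors) with percent explained per axis and adjusted R-squared;
* a univariate permutation ANOVA for diversity ~ phase * season style
  designs, sharing the PERMANOVA machinery.

Factors are dummy-coded with treatment contrasts, alphabetically first
level as reference; interactions are products of main-effect codes.  Rank
deficiencies are detected by SVD and the redundant directions dropped, so
R-squared partitions are invariant to relabelling factor levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_RANK_TOL = 1e-9


def hellinger(profile) -> pd.DataFrame:
    """Hellinger transform: square roots of row-normalized abundances.

    Each non-empty transformed row has Euclidean norm 1, and distances
    between rows lie in [0, sqrt(2)].
    """
    df = pd.DataFrame(profile).astype(float)
    if df.size and df.to_numpy().min() < 0:
        raise ValueError("hellinger requires non-negative entries")
    sums = df.sum(axis=1)
    safe = sums.where(sums > 0, 1.0)
    return np.sqrt(df.div(safe, axis=0))


# ---------------------------------------------------------------------------
# Design-matrix machinery


def _treatment_codes(factor: pd.Series) -> np.ndarray:
    """Treatment-contrast dummy columns, alphabetically first level dropped."""
    levels = sorted(map(str, pd.unique(factor.astype(str))))
    if len(levels) < 2:
        raise ValueError(f"term {factor.name!r} has a single level")
    cols = [(factor.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
    return np.column_stack(cols)


def _term_matrix(design: pd.DataFrame, term: str) -> np.ndarray:
    """Code one term; ``a:b`` is the elementwise product of main codes."""
    parts = term.split(":")
    for p in parts:
        if p not in design.columns:
            raise KeyError(f"term component {p!r} not in design")
    mats = [_treatment_codes(design[p]) for p in parts]
    out = mats[0]
    for m in mats[1:]:
        out = np.einsum("ij,ik->ijk", out, m).reshape(len(design), -1)
    return out


def _orth_basis(M: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, rank-tolerant)."""
    if M.size == 0:
        return np.zeros((M.shape[0], 0))
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    r = int(np.sum(s > _RANK_TOL * max(M.shape) * (s[0] if s.size else 1.0)))
    return U[:, :r]


def _sequential_projections(design: pd.DataFrame, terms: list[str]
                            ) -> tuple[list[np.ndarray], list[int], np.ndarray]:
    """Per-term incremental projection matrices and degrees of freedom.

    Returns (list of n x n matrices P_k projecting onto the part of term k
    orthogonal to everything before it, df per term, residual projector).
    The intercept is always fitted first.
    """
    n = len(design)
    Z = np.ones((n, 1))
    basis = _orth_basis(Z)
    projections, dfs = [], []
    for term in terms:
        Z = np.hstack([Z, _term_matrix(design, term)])
        new_basis = _orth_basis(Z)
        P = new_basis @ new_basis.T - basis @ basis.T
        dfs.append(new_basis.shape[1] - basis.shape[1])
        projections.append(P)
        basis = new_basis
    resid = np.eye(n) - basis @ basis.T
    return projections, dfs, resid


def _permutation_indices(n: int, n_perm: int, rng: np.random.Generator,
                         strata: pd.Series | None) -> np.ndarray:
    """(n_perm, n) permutation index array; within-stratum when given."""
    out = np.empty((n_perm, n), dtype=np.intp)
    if strata is None:
        for b in range(n_perm):
            out[b] = rng.permutation(n)
    else:
        groups = [np.flatnonzero(strata.to_numpy() == g) for g in pd.unique(strata)]
        base = np.arange(n)
        for b in range(n_perm):
            idx = base.copy()
            for g in groups:
                idx[g] = g[rng.permutation(len(g))]
            out[b] = idx
    return out


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    """Sequential-SS permutational MANOVA summary."""

    terms: list[str]
    df: pd.Series
    ss: pd.Series
    pseudo_f: pd.Series
    r2: pd.Series
    p_value: pd.Series
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int | None = None
    degenerate: bool = False

    def summary(self) -> pd.DataFrame:
        rows = pd.DataFrame({"df": self.df, "ss": self.ss, "pseudo_F": self.pseudo_f,
                             "R2": self.r2, "p_value": self.p_value})
        rows.loc["residual"] = [self.residual_df, self.residual_ss, np.nan,
                                self.residual_ss / self.total_ss if self.total_ss else np.nan,
                                np.nan]
        return rows


def permanova(X, design: pd.DataFrame, terms: list[str] | None = None,
              n_perm: int = 999, seed: int | None = None,
              strata: str | pd.Series | None = None) -> PermanovaResult:
    """PERMANOVA on Euclidean geometry with sequential sums of squares.

    ``X`` is the (already transformed) samples x variables matrix aligned
    with ``design`` rows; ``terms`` are fitted in order (Type-I SS), each
    tested with pseudo-F = (SS_term/df_term)/(SS_res/df_res).  The null is
    obtained by permuting the rows of X, within ``strata`` groups when
    given; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    Xa = np.asarray(pd.DataFrame(X), dtype=float)
    n = Xa.shape[0]
    if len(design) != n:
        raise ValueError("design rows must match X rows")
    if terms is None:
        terms = [c for c in design.columns]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(strata, str):
        strata = design[strata]

    Xc = Xa - Xa.mean(axis=0, keepdims=True)
    total_ss = float((Xc ** 2).sum())
    projections, dfs, resid = _sequential_projections(design.reset_index(drop=True), terms)
    res_df = n - 1 - sum(dfs)
    if res_df <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    def stats(Xmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((P @ Xmat).ravel() @ (P @ Xmat).ravel()) for P in projections])
        ssr = float((resid @ Xmat).ravel() @ (resid @ Xmat).ravel())
        return ss, ssr

    ss_obs, ss_res = stats(Xc)
    degenerate = total_ss <= _RANK_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_obs / np.array(dfs)) / (ss_res / res_df)

    rng = np.random.default_rng(seed)
    idx = _permutation_indices(n, n_perm, rng, strata)
    Xp = Xc[idx]                                   # (B, n, p)
    B = n_perm
    f_perm = np.empty((B, len(terms)))
    ssr_perm = np.einsum("ij,bjp->bip", resid, Xp)
    ssr_perm = (ssr_perm ** 2).sum(axis=(1, 2))
    for k, P in enumerate(projections):
        M = np.einsum("ij,bjp->bip", P, Xp)
        ssk = (M ** 2).sum(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm[:, k] = (ssk / dfs[k]) / (ssr_perm / res_df)

    p = np.empty(len(terms))
    for k in range(len(terms)):
        if degenerate or not np.isfinite(f_obs[k]):
            if degenerate:
                p[k] = 1.0
            else:  # infinite observed F: count infinite permuted Fs as ties
                p[k] = (1 + int(np.sum(~np.isfinite(f_perm[:, k])))) / (1 + n_perm)
        else:
            p[k] = (1 + int(np.sum(f_perm[:, k] >= f_obs[k] - 1e-12))) / (1 + n_perm)
    if degenerate:
        p[:] = 1.0

    ti = pd.Index(terms, name="term")
    return PermanovaResult(
        terms=terms,
        df=pd.Series(dfs, index=ti), ss=pd.Series(ss_obs, index=ti),
        pseudo_f=pd.Series(f_obs, index=ti),
        r2=pd.Series(ss_obs / total_ss if total_ss else np.nan, index=ti),
        p_value=pd.Series(p, index=ti),
        residual_df=res_df, residual_ss=ss_res, total_ss=total_ss,
        n_permutations=n_perm, seed=seed, degenerate=degenerate,
    )


def permutation_anova(y, design: pd.DataFrame, terms: list[str] | None = None,
                      n_perm: int = 999, seed: int | None = None,
                      strata: str | pd.Series | None = None) -> PermanovaResult:
    """Univariate permutation ANOVA (e.g. diversity ~ phase * season).

    The scalar response is treated as a one-column matrix; sums of squares,
    sequential F statistics and permutation p-values are identical to the
    classical ANOVA decomposition.  A constant response is degenerate: all
    p-values are 1 and the result is flagged.
    """
    arr = np.asarray(y, dtype=float).reshape(-1, 1)
    return permanova(arr, design, terms=terms, n_perm=n_perm, seed=seed, strata=strata)


# ---------------------------------------------------------------------------
# Ordination


@dataclass
class OrdinationResult:
    """PCA or RDA decomposition of a (transformed) community matrix."""

    eigenvalues: np.ndarray
    percent_explained: np.ndarray      # share of *total* variance, per axis
    site_scores: pd.DataFrame          # samples x axes
    loadings: pd.DataFrame             # variables x axes
    constrained: bool = False
    adjusted_r2: float | None = None
    r2: float | None = None
    degenerate: bool = False
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def axis_labels(self) -> list[str]:
        stem = "RDA" if self.constrained else "PC"
        return [f"{stem}{i + 1} ({p:.1f}%)" for i, p in enumerate(self.percent_explained)]


def _decompose(Xc: np.ndarray, n: int, index, columns, stem: str,
               total_var: float) -> OrdinationResult:
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    keep = eig > _RANK_TOL * max(1.0, eig[0] if eig.size else 1.0)
    eig = eig[keep]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    pct = 100.0 * eig / total_var if total_var > 0 else np.zeros_like(eig)
    axes = [f"{stem}{i + 1}" for i in range(len(eig))]
    return OrdinationResult(
        eigenvalues=eig, percent_explained=pct,
        site_scores=pd.DataFrame(U * s, index=index, columns=axes),
        loadings=pd.DataFrame(Vt.T, index=columns, columns=axes),
        constrained=(stem == "RDA"),
        degenerate=(len(eig) == 0),
    )


def pca(X) -> OrdinationResult:
    """Column-centered PCA by singular value decomposition.

    Eigenvalues are squared singular values / (n - 1); percent explained is
    each axis's share of the total variance.  A constant matrix yields no
    axes and is flagged degenerate.
    """
    df = pd.DataFrame(X).astype(float)
    n = len(df)
    if n < 2:
        raise ValueError("pca needs >= 2 rows")
    Xc = df.to_numpy() - df.to_numpy().mean(axis=0, keepdims=True)
    total_var = float((Xc ** 2).sum()) / (n - 1)
    return _decompose(Xc, n, df.index, df.columns, "PC", total_var)


def rda(X, predictors: pd.DataFrame, terms: list[str] | None = None,
        condition: list[str] | None = None) -> OrdinationResult:
    """Redundancy analysis: PCA of the fitted values of X ~ predictors.

    Factors in ``predictors`` are treatment-coded; ``terms`` selects and
    orders them (default: all columns, additive).  ``condition`` factors are
    partialled out of both X and the predictor codes first (partial RDA).
    Collinear predictor columns are dropped and reported.  With no usable
    predictor columns the result degrades to the PCA of the (conditioned)
    centered matrix.

    adjusted R2 = 1 - (1 - R2) * (n - 1) / (n - m - 1) with m the number of
    independent coded predictor columns.
    """
    df = pd.DataFrame(X).astype(float)
    n = len(df)
    preds = predictors.reset_index(drop=True)
    if terms is None:
        terms = [c for c in preds.columns if condition is None or c not in condition]
    Xc = df.to_numpy() - df.to_numpy().mean(axis=0, keepdims=True)

    if condition:
        Zc = np.hstack([np.ones((n, 1))] + [_term_matrix(preds, t) for t in condition])
        Bc = _orth_basis(Zc)
        Xc = Xc - Bc @ (Bc.T @ Xc)
    total_var = float((Xc ** 2).sum()) / (n - 1)

    blocks, names = [], []
    for t in terms:
        M = _term_matrix(preds, t)
        blocks.append(M)
        names.extend([f"{t}[{j}]" for j in range(M.shape[1])])
    Z = np.hstack(blocks) if blocks else np.zeros((n, 0))
    Zc = Z - Z.mean(axis=0, keepdims=True)
    if condition:
        Zc = Zc - Bc @ (Bc.T @ Zc)

    basis = _orth_basis(Zc)
    m = basis.shape[1]
    dropped = []
    if m < Zc.shape[1]:
        dropped = [f"{Zc.shape[1] - m} collinear predictor column(s) dropped"]
    if m == 0:
        out = _decompose(Xc, n, df.index, df.columns, "PC", total_var)
        out.dropped_columns = dropped
        return out
    if n <= m + 1:
        raise ValueError("rda needs n > number of coded predictor columns + 1")

    fitted = basis @ (basis.T @ Xc)
    out = _decompose(fitted, n, df.index, df.columns, "RDA", total_var)
    ss_fit = float((fitted ** 2).sum())
    ss_tot = float((Xc ** 2).sum())
    scale = float((df.to_numpy() ** 2).sum()) or 1.0
    if ss_tot <= _RANK_TOL * scale:   # no variance left after conditioning
        out.r2 = np.nan
        out.adjusted_r2 = np.nan
        out.degenerate = True
        return out
    r2 = ss_fit / ss_tot
    out.r2 = r2
    out.adjusted_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    out.dropped_columns = dropped
    return out
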