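"""Cross-study starvation axis: harmonize, build PC1, fit trajectory, project.

A reference starvation time-course metabolome defines a principal-component
axis (PC_starvation). Its score follows a saturating trajectory in
starvation time, s(t) = a t/(t + b) - c, fit by non-linear least squares.
Study samples are harmonized to the reference metabolite panel, projected
onto the axis, and displacement is tested with a treatment x phenotype
mixed model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import stage_rng
from .metabolome import MetaboliteMatrix, mixed_model_terms, pca_scores
from .simdata import starvation_score


@dataclass
class StarvationAxis:
    """PC1 of the reference time course plus its fitted time trajectory."""

    metabolites: list[str]
    training_means: np.ndarray
    loadings: np.ndarray  # unit norm
    orientation: float  # +1/-1, chosen so training scores rise with time
    train_scores: np.ndarray
    pc1_varfrac: float
    a: float | None = None
    b: float | None = None
    c: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.loadings)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis loadings must have unit norm")


@dataclass
class HarmonizedPair:
    """Reference and query matrices restricted to the matched metabolite panel."""

    ref: pd.DataFrame  # time-course samples x matched metabolites
    query: pd.DataFrame  # study samples x matched metabolites
    times: np.ndarray
    name_map: pd.DataFrame


def impute_knn(M: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing cells with the mean of the k nearest metabolite neighbours.

    Neighbours are the metabolites with smallest Euclidean distance to the
    target, computed over samples where both are observed; only neighbours
    observed at the missing sample contribute, and if fewer than k exist all
    available ones are used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = M.to_numpy(dtype=float)
    if np.any(np.isnan(X).all(axis=1)):
        bad = M.index[np.isnan(X).all(axis=1)][0]
        raise ValueError(f"sample {bad!r} has no observed metabolites")
    out = X.copy()
    miss_cols = np.flatnonzero(np.isnan(X).any(axis=0))
    for j in miss_cols:
        obs_j = ~np.isnan(X[:, j])
        dists = []
        for l in range(X.shape[1]):
            if l == j:
                continue
            both = obs_j & ~np.isnan(X[:, l])
            if not both.any():
                continue
            dists.append((float(np.sqrt(np.sum((X[both, j] - X[both, l]) ** 2))), l))
        dists.sort()
        for i in np.flatnonzero(~obs_j):
            donors = [l for _, l in dists if not np.isnan(X[i, l])][:k]
            if not donors:
                raise ValueError(f"no complete neighbours for metabolite {M.columns[j]!r}")
            out[i, j] = np.mean([X[i, l] for l in donors])
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def harmonize(
    ref: pd.DataFrame,
    query: MetaboliteMatrix,
    name_map: pd.DataFrame,
    duplicate_ion_pairs: list[tuple[str, str]] | None = None,
    k: int = 10,
) -> HarmonizedPair:
    """Match a reference time course to a query metabolome by name.

    ``ref`` columns: sample, time_h, then metabolites. Steps: drop reference
    metabolites with more than one missing value; impute single-missing ones
    by k-NN mean; per-sample centre/scale the reference; z-score and average
    declared duplicate-ion column pairs into one column; then intersect with
    the query through ``name_map`` (columns ref_name, query_name). Two
    reference columns mapping to one query name outside the declared pairs
    is an error.
    """
    dup_pairs = duplicate_ion_pairs or []
    mets = ref.drop(columns=["sample", "time_h"])
    times = ref["time_h"].to_numpy(dtype=float)

    n_miss = mets.isna().sum(axis=0)
    mets = mets.loc[:, n_miss <= 1]
    if mets.isna().any().any():
        mets = impute_knn(mets, k=k)

    # per-sample normalization of the reference
    vals = mets.to_numpy(dtype=float)
    vals = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    mets = pd.DataFrame(vals, index=mets.index, columns=mets.columns)

    for a_col, b_col in dup_pairs:
        if a_col not in mets.columns or b_col not in mets.columns:
            continue
        za = (mets[a_col] - mets[a_col].mean()) / mets[a_col].std(ddof=1)
        zb = (mets[b_col] - mets[b_col].mean()) / mets[b_col].std(ddof=1)
        merged = a_col.rsplit("_", 1)[0]
        mets = mets.drop(columns=[a_col, b_col])
        mets[merged] = (za + zb) / 2.0

    nm = name_map.copy()
    nm = nm[nm["ref_name"].isin(mets.columns)]
    dup = nm["query_name"].duplicated(keep=False)
    if dup.any():
        bad = nm.loc[dup, "query_name"].unique().tolist()
        raise ValueError(
            f"reference name collision beyond declared duplicate-ion pairs: {bad}"
        )
    nm = nm[nm["query_name"].isin(query.data.columns)]
    ref_cols = nm["ref_name"].tolist()
    qry_cols = nm["query_name"].tolist()
    ref_m = mets[ref_cols].copy()
    ref_m.columns = qry_cols
    return HarmonizedPair(ref=ref_m, query=query.data[qry_cols].copy(), times=times, name_map=nm)


def fit_reference_axis(ref: pd.DataFrame, times: np.ndarray) -> StarvationAxis:
    """PC1 of the reference matrix, oriented to increase with starvation time."""
    times = np.asarray(times, dtype=float)
    if len(ref) < 3 or np.unique(times).size < 2:
        raise ValueError("need >= 3 samples over >= 2 time points")
    means = ref.to_numpy(dtype=float).mean(axis=0)
    scores, loadings, varfrac = pca_scores(ref, center=True, scale=False)
    load = loadings["PC1"].to_numpy()
    sc = scores["PC1"].to_numpy()
    if varfrac[0] < 0.10:
        warnings.warn(f"PC1 explains only {varfrac[0]:.1%} of variance; axis weakly defined")
    rho = stats.spearmanr(sc, times).statistic
    if np.isnan(rho) or abs(rho) < 0.2:
        warnings.warn("score-time correlation is weak; axis orientation poorly defined")
    orient = -1.0 if rho < 0 else 1.0
    return StarvationAxis(
        metabolites=ref.columns.tolist(), training_means=means,
        loadings=load, orientation=orient, train_scores=orient * sc,
        pc1_varfrac=float(varfrac[0]),
    )


def fit_trajectory(scores: np.ndarray, times: np.ndarray, seed: int = 0):
    """Non-linear least squares for score = a t/(t+b) - c.

    Initialized at a0 = range(scores), b0 = median(times), c0 = -min(scores),
    with five jittered restarts; b is bounded positive. Returns (a, b, c, r2).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct times")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    if ss_tot == 0:
        return 0.0, float(np.median(t[t > 0]) if (t > 0).any() else 1.0), float(-s[0]), 0.0

    p0 = np.array([float(np.ptp(s)), float(max(np.median(t), 1e-3)), float(-s.min())])
    rng = stage_rng(seed, "trajectory_fit")
    best = None
    starts = [p0] + [p0 * rng.uniform(0.5, 1.5, size=3) + rng.normal(0, 0.1, 3) for _ in range(5)]
    for start in starts:
        start = np.array([start[0], max(start[1], 1e-6), start[2]])
        try:
            popt, _ = optimize.curve_fit(
                starvation_score, t, s, p0=start,
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((s - starvation_score(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            f"trajectory fit failed to converge from {len(starts)} starts "
            f"(n={s.size}, score range {s.min():.3g}..{s.max():.3g})"
        )
    sse, (a, b, c) = best
    r2 = 1.0 - sse / ss_tot
    return float(a), float(b), float(c), float(r2)


def project(query: pd.DataFrame, axis: StarvationAxis, center: bool = True) -> pd.Series:
    """Project query samples onto the starvation axis.

    score = orientation * sum_i loading_i * (x_i - training_mean_i); with
    ``center=False`` the raw dot product is used instead.
    """
    missing = [m for m in axis.metabolites if m not in query.columns]
    extra = [m for m in query.columns if m not in axis.metabolites]
    if missing or extra:
        raise ValueError(f"query/axis metabolite mismatch (missing={missing}, extra={extra})")
    X = query[axis.metabolites].to_numpy(dtype=float)
    if center:
        X = X - axis.training_means
    return pd.Series(axis.orientation * (X @ axis.loadings), index=query.index, name="pc_starvation")


def displacement_test(scores: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """Treatment x phenotype mixed model on projected starvation scores.

    PC ~ beta_T + beta_P + beta_TxP + (1|line); Type-III F and p per fixed
    term, via the metabolome module's machinery.
    """
    from .metabolome import _design_interaction

    design = design.loc[scores.index]
    if design["treatment"].nunique() < 2 or design["phenotype_class"].nunique() < 2:
        raise ValueError("both treatments and both phenotype classes must be present")
    X, names = _design_interaction(design)
    return mixed_model_terms(scores.to_numpy(dtype=float), X, names, design["line"].to_numpy())
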