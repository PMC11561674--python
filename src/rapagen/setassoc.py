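"""Marker- and set-level genetic association against genomic BLUPs.

The set-level statistic is the covariance association test (CVAT): each
marker's genomic contribution is its scaled dose times its backsolved
effect, and a feature's statistic is the sum over member markers of the
sample covariance between total genomic values and those contributions.
Because the statistic decomposes additively over markers, the permutation
null — sums over random marker subsets of matched size — vectorizes exactly.
Significance is one-sided (large positive covariance = association).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .core import GenotypeMatrix, stage_rng
from . import quantgen
from .quantgen import ld_prune, qc_markers  # noqa: F401  (scan/CVAT entry points)

logger = logging.getLogger(__name__)


@dataclass
class FeatureSet:
    """A named set of marker indices at gene, gene+-window, or pathway level."""

    id: str
    level: str  # gene | gene_1kb | pathway
    marker_idx: np.ndarray
    genes: list[str]

    def __post_init__(self) -> None:
        self.marker_idx = np.unique(np.asarray(self.marker_idx, dtype=int))

    @property
    def n_markers(self) -> int:
        return self.marker_idx.size


def single_marker_scan(W: np.ndarray, ghat: np.ndarray) -> pd.DataFrame:
    """Simple linear regression of line genomic values on each scaled dose.

    One vectorized pass: per marker, the slope t statistic with n-2 df and a
    two-sided p. Constant markers get NaN statistics and are flagged.
    """
    W = np.asarray(W, dtype=float)
    g = np.asarray(ghat, dtype=float).ravel()
    n = g.size
    if W.shape[0] != n:
        raise ValueError("W and ghat have mismatched rows")
    gc = g - g.mean()
    Wc = W - W.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Wc, Wc)
    syy = float(gc @ gc)
    sxy = gc @ Wc
    const = sxx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rss = np.maximum(syy - slope * sxy, 0.0)  # guard tiny negative round-off
        se2 = rss / ((n - 2) * sxx)
        t = slope / np.sqrt(se2)
    t[const] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return pd.DataFrame({
        "marker": np.arange(W.shape[1]), "statistic": t, "p": p,
        "flagged_constant": const,
    })


def storey_pi0(p: np.ndarray) -> float:
    """Null-proportion estimate via the lambda-grid cubic-spline method.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on lambda = 0.05..0.95
    step 0.05; a natural cubic spline in lambda is evaluated at 0.95 and the
    result clipped to (0, 1]. Fewer than 10 p-values returns 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 10:
        return 1.0
    lams = np.arange(0.05, 0.951, 0.05)
    pi0s = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lams])
    spline = CubicSpline(lams, pi0s, bc_type="natural")
    pi0 = float(spline(lams[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = pi0 * min_{p_j >= p_i} (m p_j / rank_j).

    With pi0 forced to 1 this reduces exactly to Benjamini-Hochberg.
    Monotone in p and invariant to input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = storey_pi0(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def build_feature_sets(
    annotations: pd.DataFrame,
    markers: pd.DataFrame,
    window_bp: int = 1000,
    pathways: dict[str, list[str]] | None = None,
    min_pathway_genes: int = 2,
    min_pathway_markers: int = 200,
) -> dict[str, list[FeatureSet]]:
    """Gene, gene+-window and pathway marker sets from transcript intervals.

    ``annotations`` columns: gene, chrom, start, end (1-based closed
    intervals; BED-style input must be converted on read). Gene-level
    features take markers with start <= pos <= end; the gene_1kb level
    widens both ends by ``window_bp``. Pathways union their member genes'
    gene-level marker sets (duplicates collapsed) and are dropped when they
    have fewer than ``min_pathway_genes`` genes with markers or fewer than
    ``min_pathway_markers`` total markers. A marker inside several genes
    contributes to every containing feature.
    """
    pos_by_chrom = {
        chrom: (grp.index.to_numpy(), grp["pos"].to_numpy())
        for chrom, grp in markers.groupby("chrom", sort=False)
    }

    def interval_markers(chrom, lo, hi):
        if chrom not in pos_by_chrom:
            return np.empty(0, dtype=int)
        idx, pos = pos_by_chrom[chrom]
        return idx[(pos >= lo) & (pos <= hi)]

    genes, genes_1kb = [], []
    gene_members: dict[str, np.ndarray] = {}
    for row in annotations.itertuples(index=False):
        mi = interval_markers(row.chrom, row.start, row.end)
        gene_members[row.gene] = mi
        if mi.size:
            genes.append(FeatureSet(row.gene, "gene", mi, [row.gene]))
        wi = interval_markers(row.chrom, row.start - window_bp, row.end + window_bp)
        if wi.size:
            genes_1kb.append(FeatureSet(row.gene, "gene_1kb", wi, [row.gene]))

    pathway_feats = []
    for pid, members in (pathways or {}).items():
        known = []
        for gname in members:
            if gname not in gene_members:
                logger.warning("pathway %s references unknown gene %s; skipped", pid, gname)
                continue
            known.append(gname)
        idx = np.unique(np.concatenate([gene_members[g] for g in known])) if known else np.empty(0, int)
        with_markers = [g for g in known if gene_members[g].size]
        if len(with_markers) < min_pathway_genes or idx.size < min_pathway_markers:
            continue
        pathway_feats.append(FeatureSet(pid, "pathway", idx, with_markers))

    return {"gene": genes, "gene_1kb": genes_1kb, "pathway": pathway_feats}


def cvat_contributions(W: np.ndarray, s_hat: np.ndarray, ghat: np.ndarray) -> np.ndarray:
    """Per-marker covariance contributions cov(ghat, W_i s_i) over lines.

    Sample covariance with the n-1 denominator. The CVAT statistic of any
    feature is the sum of its members' contributions; summed over all
    markers (full-rank K) they reproduce var(ghat).
    """
    W = np.asarray(W, dtype=float)
    g = np.asarray(ghat, dtype=float).ravel()
    n = g.size
    gc = g - g.mean()
    Wc = W - W.mean(axis=0)
    return np.asarray(s_hat, float) * (gc @ Wc) / (n - 1)


def cvat_statistic(
    W: np.ndarray, s_hat: np.ndarray, ghat: np.ndarray, feature: FeatureSet
) -> float:
    """CVAT statistic T = sum over feature markers of cov(ghat, g_i)."""
    if feature.n_markers == 0:
        raise ValueError(f"feature {feature.id!r} is empty")
    return float(cvat_contributions(W, s_hat, ghat)[feature.marker_idx].sum())


def cvat_null(
    contribs: np.ndarray,
    feature_size: int,
    n_perm: int,
    seed: int,
    chunk_cells: int = 20_000_000,
) -> np.ndarray:
    """Null CVAT statistics: contribution sums over random marker subsets.

    Subsets of ``feature_size`` markers are sampled without replacement,
    vectorized via random-key argpartition in memory-bounded chunks.
    """
    contribs = np.asarray(contribs, dtype=float)
    m = contribs.size
    if not 1 <= feature_size <= m:
        raise ValueError("feature_size out of range")
    rng = stage_rng(seed, "cvat_null")
    out = np.empty(n_perm)
    chunk = max(1, chunk_cells // m)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, m))
        idx = np.argpartition(keys, feature_size - 1, axis=1)[:, :feature_size]
        out[done:done + b] = contribs[idx].sum(axis=1)
        done += b
    return out


def cvat_empirical_p(
    T_obs: float,
    feature_size: int,
    all_contribs: np.ndarray,
    n_perm: int,
    seed: int,
    null: np.ndarray | None = None,
) -> tuple[float, bool]:
    """One-sided empirical p = #(null T >= T_obs) / n_perm.

    Returns (p, at_resolution_floor): when no null draw reaches T_obs the
    reported p is 1/n_perm and the flag is set. ``null`` may carry
    precomputed null statistics (shared across same-size features).
    """
    m = np.asarray(all_contribs).size
    if feature_size == m:
        logger.warning("feature spans all markers; empirical p trivially 1")
        return 1.0, False
    if null is None:
        null = cvat_null(all_contribs, feature_size, n_perm, seed)
    count = int(np.sum(null >= T_obs))
    if count == 0:
        return 1.0 / null.size, True
    return count / null.size, False


def run_set_analysis(
    G: GenotypeMatrix,
    y_norm: np.ndarray,
    X: np.ndarray,
    annotations: pd.DataFrame,
    pathways: dict[str, list[str]] | None = None,
    *,
    grm_maf: float = 0.05,
    grm_callrate: float = 0.95,
    scan_maf: float = 0.05,
    scan_callrate: float = 0.80,
    ld_r2: float = 0.8,
    ld_window_bp: int = 200_000,
    ld_step_bp: int = 5_000,
    window_bp: int = 1000,
    min_pathway_markers: int = 200,
    n_perm: int = 100_000,
    seed: int = 0,
    ld_prune_grm: bool = True,
) -> dict:
    """End-to-end set association: QC -> GRM -> gBLUP -> backsolve -> CVAT.

    The GRM uses the inclusive QC profile (MAF >= grm_maf, call rate >=
    grm_callrate) with LD pruning; marker effects are backsolved for the
    larger scan-profile set (strict inequalities) and features are built on
    that set. Per level, CVAT empirical p-values get Storey q-values.
    Returns scan table, per-level association tables, and the gBLUP fit.
    """
    G_grm = qc_markers(G, grm_maf, grm_callrate, strict=False)
    if ld_prune_grm:
        keep_ids = ld_prune(G_grm, ld_r2, ld_window_bp, ld_step_bp)
        G_grm = G_grm.subset_markers(G_grm.markers["id"].isin(keep_ids).to_numpy())
    K = quantgen.compute_grm(G_grm)
    fit = quantgen.fit_gblup(np.asarray(y_norm, float), X, K)

    G_scan = qc_markers(G, scan_maf, scan_callrate, strict=True)
    W_scan = G_scan.scaled_dose()
    s_hat = quantgen.backsolve_marker_effects(W_scan, K, fit.ghat)
    scan = single_marker_scan(W_scan, fit.ghat)
    scan["id"] = G_scan.markers["id"].to_numpy()
    ok = ~scan["flagged_constant"]
    scan.loc[ok, "q"] = storey_qvalues(scan.loc[ok, "p"].to_numpy())

    feats = build_feature_sets(
        annotations, G_scan.markers, window_bp=window_bp, pathways=pathways,
        min_pathway_markers=min_pathway_markers,
    )
    contribs = cvat_contributions(W_scan, s_hat, fit.ghat)
    tables = {}
    for level, features in feats.items():
        rows = []
        null_cache: dict[int, np.ndarray] = {}
        for k, f in enumerate(features):
            if f.n_markers == 0:
                logger.info("skipping empty feature %s", f.id)
                continue
            T = float(contribs[f.marker_idx].sum())
            if f.n_markers not in null_cache:
                null_cache[f.n_markers] = cvat_null(
                    contribs, f.n_markers, n_perm, seed + 1 + len(null_cache))
            p, floor = cvat_empirical_p(
                T, f.n_markers, contribs, n_perm, seed, null=null_cache[f.n_markers])
            rows.append((f.id, level, T, p, floor, f.n_markers))
        tab = pd.DataFrame(rows, columns=["id", "level", "statistic", "p", "p_at_floor", "n_markers"])
        if len(tab):
            tab["q"] = storey_qvalues(tab["p"].to_numpy())
        tables[level] = tab
    return {"scan": scan, "levels": tables, "fit": fit, "grm": K, "n_markers_scan": W_scan.shape[1]}
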