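"""Metabolome normalization, batch correction, PCA and per-metabolite models.

Raw LC-MS peak intensities are natural-log transformed and each sample is
mean-centred and scaled to unit SD; extraction-batch effects are then
removed with a parametric empirical-Bayes location/scale adjustment per
metabolite (ComBat-style, no covariates). Per-metabolite inference uses a
random-intercept-per-line mixed model fit by REML through the same
eigendecomposition machinery as the genomic analyses, with Type-III
(sum-to-zero) F tests for treatment, phenotype class and their interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import Grm
from .quantgen import fit_gblup
from .setassoc import storey_qvalues

COMBAT_TOL = 1e-6
COMBAT_MAX_ITER = 100


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites with line/class/treatment/batch metadata.

    ``data`` is indexed by sample id; ``meta`` carries line,
    phenotype_class, treatment and batch per sample.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            self.meta = self.meta.loc[self.data.index]

    @property
    def samples(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def metabolites(self) -> list[str]:
        return self.data.columns.tolist()


def normalize_metabolome(raw: MetaboliteMatrix) -> MetaboliteMatrix:
    """log_e transform, then centre and scale each sample row to mean 0, SD 1.

    Idempotent on its own output up to the log step (re-normalizing changes
    nothing once rows are standardized). Raises on non-positive intensities
    or a zero within-sample SD.
    """
    X = raw.data.to_numpy(dtype=float)
    if raw.normalized:
        L = X
    else:
        if np.any(X <= 0):
            si, mi = map(int, next(zip(*np.where(X <= 0))))
            raise ValueError(
                f"non-positive intensity at sample {raw.data.index[si]!r}, "
                f"metabolite {raw.data.columns[mi]!r}"
            )
        L = np.log(X)
    mu = L.mean(axis=1, keepdims=True)
    sd = L.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd.ravel() <= 1e-10 * np.maximum(1.0, np.abs(mu.ravel()))
    if degenerate.any():
        bad = raw.data.index[int(np.flatnonzero(degenerate)[0])]
        raise ValueError(f"sample {bad!r} has zero within-sample SD")
    Z = (L - mu) / sd
    return MetaboliteMatrix(
        data=pd.DataFrame(Z, index=raw.data.index, columns=raw.data.columns),
        meta=raw.meta, normalized=True,
    )


def correct_batch(M: MetaboliteMatrix, batches: pd.Series | None = None) -> MetaboliteMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment per metabolite.

    The standard scheme: standardize each metabolite, estimate per-batch
    means and variances, shrink them toward normal / inverse-gamma priors by
    the iterative moment algorithm, then subtract/rescale and restore the
    metabolite scale. No covariates are preserved.
    """
    batches = M.meta["batch"] if batches is None else batches.loc[M.data.index]
    labels, counts = np.unique(batches.to_numpy(), return_counts=True)
    if np.any(counts < 2):
        bad = labels[counts < 2][0]
        raise ValueError(f"batch {bad!r} has fewer than 2 samples")

    Y = M.data.to_numpy(dtype=float).T  # metabolites x samples
    m, n = Y.shape
    design = np.stack([(batches.to_numpy() == b).astype(float) for b in labels], axis=1)
    nb = counts.astype(float)

    # standardization: batch-aware grand mean and pooled variance
    Bhat = np.linalg.solve(design.T @ design, design.T @ Y.T)  # batches x metabolites
    grand = (nb / n) @ Bhat
    resid = Y - (design @ Bhat).T
    var_pooled = (resid**2).mean(axis=1)
    if np.any(var_pooled == 0):
        raise ValueError("zero-variance metabolite cannot be batch-standardized")
    sd_pooled = np.sqrt(var_pooled)
    Z = (Y - grand[:, None]) / sd_pooled[:, None]

    Zadj = Z.copy()
    for bi, b in enumerate(labels):
        cols = batches.to_numpy() == b
        Zb = Z[:, cols]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        gbar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        dbar = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if s2 == 0 or t2 == 0:  # degenerate priors: fall back to raw estimates
            gamma_star, delta_star = gamma_hat, np.maximum(delta_hat, 1e-12)
        else:
            aprior = (2 * s2 + dbar**2) / s2
            bprior = (dbar * s2 + dbar**3) / s2
            nbk = float(cols.sum())
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(COMBAT_MAX_ITER):
                g_new = (t2 * nbk * gamma_hat + delta_star * gbar) / (t2 * nbk + delta_star)
                ss = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (0.5 * ss + bprior) / (nbk / 2.0 + aprior - 1.0)
                change = max(
                    np.max(np.abs(g_new - gamma_star) / np.maximum(np.abs(gamma_star), 1e-12)),
                    np.max(np.abs(d_new - delta_star) / np.maximum(np.abs(delta_star), 1e-12)),
                )
                gamma_star, delta_star = g_new, d_new
                if change < COMBAT_TOL:
                    break
        Zadj[:, cols] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    Yadj = Zadj * sd_pooled[:, None] + grand[:, None]
    return replace(M, data=pd.DataFrame(Yadj.T, index=M.data.index, columns=M.data.columns))


def pca_scores(M, center: bool = True, scale: bool = False):
    """SVD-based PCA over metabolites (columns as variables).

    Returns (scores, loadings, variance_fractions); loadings are orthonormal
    columns and each component is oriented so its largest-magnitude loading
    is positive. Missing values must be imputed first.
    """
    X = (M.data if isinstance(M, MetaboliteMatrix) else M).astype(float)
    cols, idx = X.columns, X.index
    A = X.to_numpy()
    if np.isnan(A).any():
        raise ValueError("missing values present; impute before PCA")
    if A.shape[0] < 2:
        raise ValueError("PCA needs more than one sample")
    if center:
        A = A - A.mean(axis=0)
    if scale:
        sd = A.std(axis=0, ddof=1)
        A = A / np.where(sd == 0, 1.0, sd)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    scores = U * S
    varfrac = S**2 / np.sum(S**2) if np.sum(S**2) > 0 else np.zeros_like(S)
    npc = S.size
    pcs = [f"PC{i + 1}" for i in range(npc)]
    return (
        pd.DataFrame(scores, index=idx, columns=pcs),
        pd.DataFrame(Vt.T, index=cols, columns=pcs),
        varfrac,
    )


def line_kinship(lines: pd.Series | np.ndarray) -> Grm:
    """Block-diagonal relatedness Z Z' for a random intercept per line."""
    lines = np.asarray(lines)
    uniq = pd.unique(lines)
    Z = (lines[:, None] == uniq[None, :]).astype(float)
    return Grm(line_ids=[str(s) for s in range(lines.size)], matrix=Z @ Z.T, m=uniq.size)


def _design_interaction(meta: pd.DataFrame):
    """Sum-to-zero design for ~ T + P + T:P: intercept, T, P, TxP columns."""
    t = np.where(meta["treatment"].to_numpy() == "rapamycin", 0.5, -0.5)
    p = np.where(meta["phenotype_class"].to_numpy() == "sensitive", 0.5, -0.5)
    X = np.column_stack([np.ones(len(meta)), t, p, t * p])
    return X, ["intercept", "treatment", "phenotype", "interaction"]


def mixed_model_terms(
    y: np.ndarray,
    X: np.ndarray,
    term_names: list[str],
    lines: np.ndarray,
    K: Grm | None = None,
) -> pd.DataFrame:
    """Wald Type-III F tests per fixed term in a random-intercept mixed model.

    With sum-to-zero contrasts each 1-df term's marginal (Type-III) test is
    the Wald F on its coefficient, F = beta^2 / Var(beta), against the
    residual denominator df n - rank(X). With a zero line variance this
    reduces exactly to the fixed-effects-only Type-III ANOVA.
    """
    K = line_kinship(lines) if K is None else K
    fit = fit_gblup(np.asarray(y, float), X, K, compute_se=False)
    df_den = max(fit.n - fit.rank_x, 1)
    rows = []
    for j, name in enumerate(term_names):
        if name == "intercept":
            continue
        F = fit.beta[j] ** 2 / fit.beta_cov[j, j]
        p = float(stats.f.sf(F, 1, df_den))
        rows.append((name, float(fit.beta[j]), float(F), 1, df_den, p))
    return pd.DataFrame(rows, columns=["term", "estimate", "F", "df_num", "df_den", "p"])


def interaction_anova(M: MetaboliteMatrix, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-metabolite Type-III tests for Metabolite ~ T + P + TxP + (1|line).

    Returns one row per metabolite x term with F, p and Storey q computed
    across metabolites within each term. Metabolites whose design is
    singular are flagged and excluded from the FDR.
    """
    meta = M.meta if meta is None else meta
    classes = meta.groupby("phenotype_class")["line"].nunique()
    if (classes < 2).any() or classes.size < 2:
        raise ValueError("need >= 2 lines in each phenotype class")
    if meta["treatment"].nunique() < 2:
        raise ValueError("both treatments must be present")
    X, names = _design_interaction(meta)
    lines = meta["line"].to_numpy()
    K = line_kinship(lines)
    out = []
    for met in M.metabolites:
        y = M.data[met].to_numpy(dtype=float)
        try:
            tab = mixed_model_terms(y, X, names, lines, K=K)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"metabolite {met!r} excluded: {exc}")
            continue
        tab.insert(0, "metabolite", met)
        out.append(tab)
    res = pd.concat(out, ignore_index=True)
    res["q"] = np.nan
    for term in res["term"].unique():
        mask = res["term"] == term
        res.loc[mask, "q"] = storey_qvalues(res.loc[mask, "p"].to_numpy())
    return res


def treatment_effects_by_class(M: MetaboliteMatrix, phenotype_class: str) -> pd.DataFrame:
    """Per-metabolite treatment effect within one phenotype class.

    Model: Metabolite ~ beta_T + (1|line) on the class subset, treatment
    coded control=0 / rapamycin=1 so beta_T is the rapamycin shift; Wald
    test on beta_T with Storey q across metabolites.
    """
    mask = M.meta["phenotype_class"] == phenotype_class
    if not mask.any():
        raise ValueError(f"no samples in class {phenotype_class!r}")
    meta = M.meta.loc[mask]
    if meta["line"].nunique() < 2:
        raise ValueError("class subset must contain >= 2 lines")
    t = (meta["treatment"].to_numpy() == "rapamycin").astype(float)
    X = np.column_stack([np.ones(mask.sum()), t])
    lines = meta["line"].to_numpy()
    K = line_kinship(lines)
    rows = []
    for met in M.metabolites:
        y = M.data.loc[mask, met].to_numpy(dtype=float)
        try:
            fit = fit_gblup(y, X, K, compute_se=False)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"metabolite {met!r} excluded: {exc}")
            continue
        df_den = max(fit.n - fit.rank_x, 1)
        F = fit.beta[1] ** 2 / fit.beta_cov[1, 1]
        rows.append((met, float(fit.beta[1]), float(stats.f.sf(F, 1, df_den))))
    res = pd.DataFrame(rows, columns=["metabolite", "beta_T", "p"])
    res["q"] = storey_qvalues(res["p"].to_numpy())
    return res


def effect_sign_concordance(effects_R: np.ndarray, effects_S: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between per-metabolite treatment effects.

    Average ranks for ties; p by the t approximation. Constant input leaves
    the correlation undefined (NaN, with a warning).
    """
    a = np.asarray(effects_R, dtype=float)
    b = np.asarray(effects_S, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("effect vectors must have equal length >= 4")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant effect vector: Spearman correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
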