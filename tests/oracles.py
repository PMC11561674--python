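"""Independent reference implementations used to cross-check the package.

Each oracle is deliberately written along a different code path from the
implementation it validates (brute-force loops, generic optimizers,
textbook formulas, exhaustive enumeration).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats


def pooled_sd_oracle(n_r, n_c, s_r, s_c):
    """Textbook two-sample pooled SD / SE, computed stepwise."""
    var_pooled = ((n_r - 1) * s_r * s_r + (n_c - 1) * s_c * s_c) / (n_r + n_c - 2)
    s = var_pooled**0.5
    return s, s * (1.0 / n_r + 1.0 / n_c) ** 0.5


def ols_scan_oracle(W, ghat):
    """Per-marker two-sided regression p-values via scipy.stats.linregress."""
    out = []
    for j in range(W.shape[1]):
        res = stats.linregress(W[:, j], ghat)
        out.append((res.slope / res.stderr, res.pvalue))
    return np.array(out)


def grm_double_loop_oracle(W):
    """Naive double loop over line pairs: K_ij = sum_k W_ik W_jk / m."""
    n, m = W.shape
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(m):
                acc += W[i, k] * W[j, k]
            K[i, j] = acc / m
    return K


def ld_prune_bruteforce_oracle(dose, pos, r2_max, window_bp, step_bp):
    """Greedy left-to-right pruning, re-deriving window membership per step.

    ``dose`` is mean-imputed lines x markers for one chromosome, ``pos`` the
    sorted positions. Returns indices of retained markers.
    """
    m = dose.shape[1]
    removed = set()
    start = int(pos.min())
    while True:
        win = [j for j in range(m) if start <= pos[j] < start + window_bp and j not in removed]
        for a in range(len(win)):
            i = win[a]
            if i in removed:
                continue
            for b in range(a + 1, len(win)):
                j = win[b]
                if j in removed:
                    continue
                x, y = dose[:, i], dose[:, j]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                if r * r > r2_max:
                    removed.add(j)
        if start + window_bp > pos.max():
            break
        start += step_bp
    return [j for j in range(m) if j not in removed]


def dense_reml_oracle(y, X, K):
    """REML by generic optimization over (log sg2, log se2) with explicit V.

    Restricted log-likelihood computed densely with slogdet; optimized with
    Nelder-Mead from several starts. Returns (sg2, se2, h2).
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    vy = y.var(ddof=1)

    def negll(params):
        sg, se = np.exp(params)
        V = sg * K + se * np.eye(n)
        try:
            Vi = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return 1e12
        s1, ld1 = np.linalg.slogdet(V)
        A = X.T @ Vi @ X
        s2, ld2 = np.linalg.slogdet(A)
        if s1 <= 0 or s2 <= 0:
            return 1e12
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        return 0.5 * (ld1 + ld2 + r @ Vi @ r)

    best = None
    for f in (0.1, 0.5, 0.9):
        x0 = np.log([max(f * vy, 1e-8), max((1 - f) * vy, 1e-8)])
        res = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    sg, se = np.exp(best.x)
    return sg, se, sg / (sg + se)


def bh_oracle(p):
    """Benjamini-Hochberg adjusted p-values via statsmodels."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def cvat_loop_oracle(W, s_hat, ghat, idx):
    """Feature statistic by an explicit per-marker covariance loop."""
    T = 0.0
    for j in idx:
        gi = W[:, j] * s_hat[j]
        T += np.cov(ghat, gi, ddof=1)[0, 1]
    return T


def cvat_exhaustive_null(contribs, k):
    """All subset sums of size k (exact permutation distribution)."""
    return np.array([sum(contribs[list(c)]) for c in itertools.combinations(range(len(contribs)), k)])


def trajectory_grid_oracle(scores, times):
    """Lattice search over (a, b, c) followed by local refinement."""
    s, t = np.asarray(scores, float), np.asarray(times, float)

    def sse(p):
        a, b, c = p
        if b <= 0:
            return 1e12
        return float(np.sum((s - (a * t / (t + b) - c)) ** 2))

    span = max(np.ptp(s), 1.0)
    best = None
    for a in np.linspace(-3 * span, 3 * span, 25):
        for b in np.geomspace(0.1, 50, 25):
            for c in np.linspace(s.min() - span, s.max() + span, 25):
                v = sse((a, b, c))
                if best is None or v < best[0]:
                    best = (v, (a, b, c))
    res = optimize.minimize(sse, best[1], method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000})
    return res.x


def knn_impute_oracle(X, k):
    """Exhaustive distance-sort kNN mean imputation (metabolite neighbours).

    Distances and donor values always come from the original observed data,
    never from freshly imputed cells.
    """
    out = X.copy()
    n, m = X.shape
    for j in range(m):
        miss_rows = np.flatnonzero(np.isnan(X[:, j]))
        if miss_rows.size == 0:
            continue
        cand = []
        for l in range(m):
            if l == j:
                continue
            both = ~np.isnan(X[:, j]) & ~np.isnan(X[:, l])
            if both.any():
                cand.append((np.sqrt(np.sum((X[both, j] - X[both, l]) ** 2)), l))
        cand.sort()
        for i in miss_rows:
            donors = [l for _, l in cand if not np.isnan(X[i, l])][:k]
            out[i, j] = np.mean([X[i, l] for l in donors])
    return out


def pca_eig_oracle(A):
    """PCA via eigendecomposition of the covariance matrix (centred input)."""
    Ac = A - A.mean(axis=0)
    C = np.cov(Ac, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order], Ac @ vecs[:, order]


def spearman_oracle(a, b):
    """Rank (average ties) then Pearson."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return np.corrcoef(ra, rb)[0, 1]
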