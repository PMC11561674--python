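"""Per-line developmental-delay phenotypes from per-vial pupation records.

Delay is the difference in mean egg-to-pupa time between rapamycin and
control conditions; its sampling error is quantified with the two-sample
pooled standard deviation and pooled standard error. Before association
testing, delays are shifted by +1, Box-Cox transformed with a single
maximum-likelihood lambda, then centred on reference lines and scaled
within experimental batch.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


def summarize_pupation(records: pd.DataFrame) -> pd.DataFrame:
    """Pool pupae across vials into per-line, per-condition (mean, SD, n).

    ``records`` columns: vial, line, treatment, batch, day, count. The mean
    is the count-weighted mean observation day over all vials of a line x
    condition; the SD uses the n-1 denominator over pupa-level days. Line x
    condition cells with zero pupae are excluded (logged).
    """
    req = {"vial", "line", "treatment", "batch", "day", "count"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if (records["count"] < 0).any():
        raise ValueError("pupae counts must be non-negative")

    rows = []
    for (line, batch, treatment), grp in records.groupby(["line", "batch", "treatment"], sort=True):
        n = int(grp["count"].sum())
        if n == 0:
            logger.info("excluding %s x %s (batch %s): zero pupae", line, treatment, batch)
            continue
        days = grp["day"].to_numpy(dtype=float)
        cnt = grp["count"].to_numpy(dtype=float)
        mean = float(np.average(days, weights=cnt))
        sd = float(np.sqrt(np.sum(cnt * (days - mean) ** 2) / (n - 1))) if n > 1 else 0.0
        rows.append((line, treatment, batch, mean, sd, n))
    return pd.DataFrame(rows, columns=["line", "treatment", "batch", "mean", "sd", "n"])


def pooled_se(n_r, n_c, s_r, s_c):
    """Pooled SD and SE of a two-sample mean difference.

    pooled s  = sqrt(((n_r-1) s_r^2 + (n_c-1) s_c^2) / (n_r + n_c - 2))
    pooled SE = pooled s * sqrt(1/n_r + 1/n_c)

    Accepts scalars or arrays; requires n_r + n_c >= 3 (else the pooled
    variance is undefined).
    """
    n_r = np.asarray(n_r, dtype=float)
    n_c = np.asarray(n_c, dtype=float)
    s_r = np.asarray(s_r, dtype=float)
    s_c = np.asarray(s_c, dtype=float)
    if np.any(n_r < 1) or np.any(n_c < 1):
        raise ValueError("need at least one pupa per condition")
    if np.any(n_r + n_c <= 2):
        raise ValueError("pooled SD undefined for n_r + n_c <= 2 (degenerate input)")
    if np.any(s_r < 0) or np.any(s_c < 0):
        raise ValueError("SDs must be non-negative")
    s = np.sqrt(((n_r - 1) * s_r**2 + (n_c - 1) * s_c**2) / (n_r + n_c - 2))
    se = s * np.sqrt(1.0 / n_r + 1.0 / n_c)
    if s.ndim == 0:
        return float(s), float(se)
    return s, se


def developmental_delay(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-line delay phenotype: rapamycin mean minus control mean.

    Summaries are per line x batch (reference lines measured in several
    batches yield one row per batch). Lines lacking either condition in a
    batch are flagged and not emitted. Percent delay is 100 * delay /
    control mean. Negative delays (faster development on drug) are allowed.
    """
    wide = summary.pivot(index=["line", "batch"], columns="treatment", values=["mean", "sd", "n"])
    rows = []
    for line, batch in wide.index:
        key = (line, batch)
        mc = wide.loc[key].get(("mean", "control"), np.nan)
        mr = wide.loc[key].get(("mean", "rapamycin"), np.nan)
        if pd.isna(mc) or pd.isna(mr):
            logger.warning("line %s (batch %s) missing a condition; flagged and skipped", line, batch)
            continue
        n_c = int(wide.loc[key, ("n", "control")])
        n_r = int(wide.loc[key, ("n", "rapamycin")])
        s_c = float(wide.loc[key, ("sd", "control")])
        s_r = float(wide.loc[key, ("sd", "rapamycin")])
        delay = mr - mc
        if n_r + n_c > 2:
            s, se = pooled_se(n_r, n_c, s_r, s_c)
        else:
            s, se = np.nan, np.nan
        rows.append({
            "line": line, "batch": batch,
            "mean_control": mc, "mean_rapamycin": mr,
            "n_c": n_c, "n_r": n_r, "s_c": s_c, "s_r": s_r,
            "delay": delay, "pooled_s": s, "pooled_se": se,
            "percent_delay": 100.0 * delay / mc,
        })
    return pd.DataFrame(rows)


def boxcox_lambda(x: np.ndarray, grid=(-2.0, 2.0), step: float = 0.01) -> float:
    """Box-Cox lambda maximizing the profile log-likelihood.

    Coarse grid on [grid[0], grid[1]] with ``step`` spacing, then Brent
    refinement in the best bracket.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    lams = np.arange(grid[0], grid[1] + step / 2, step)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    i = int(np.argmax(llf))
    lo = lams[max(i - 1, 0)]
    hi = lams[min(i + 1, lams.size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def normalize_delay(
    delays: pd.DataFrame,
    reference_lines: list[str],
    lam: float | None = None,
) -> pd.DataFrame:
    """Normalize per-line delays for association testing.

    Steps: (1) shift delays by +1 (must stay positive); (2) Box-Cox with a
    single lambda maximizing the profile likelihood over all lines (or a
    caller-fixed ``lam``); (3) within each batch subtract the mean
    transformed value of the reference lines (every batch must contain all
    of them); (4) within each batch divide by the SD of the centred values
    across all lines in the batch. Reference lines stay in the output with
    ``is_reference`` set, so callers can exclude them downstream.
    """
    df = delays.reset_index(drop=True).copy()
    shifted = df["delay"].to_numpy(dtype=float) + 1.0
    if np.any(shifted <= 0):
        bad = df.loc[shifted <= 0, "line"].tolist()
        raise ValueError(f"delay <= -1 leaves Box-Cox undefined for lines: {bad}")
    if lam is None:
        lam = boxcox_lambda(shifted)
    df["boxcox_lambda"] = lam
    transformed = stats.boxcox(shifted, lmbda=lam)
    df["transformed"] = transformed

    norm = np.full(len(df), np.nan)
    for batch, grp in df.groupby("batch", sort=False):
        present = set(grp["line"])
        missing = [l for l in reference_lines if l not in present]
        if missing:
            raise ValueError(f"batch {batch!r} is missing reference line(s) {missing}")
        ref_mask = grp["line"].isin(reference_lines)
        centred = grp["transformed"].to_numpy() - grp.loc[ref_mask, "transformed"].mean()
        sd = centred.std(ddof=1)
        if sd == 0:
            warnings.warn(f"batch {batch!r}: zero SD after centring; scaling degenerate")
            norm[grp.index] = centred
        else:
            norm[grp.index] = centred / sd
    df["normalized"] = norm
    df["is_reference"] = df["line"].isin(reference_lines)
    return df
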