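"""Synthetic inputs with the statistical structure of an inbred-line panel study.

Every generator takes one integer seed and derives an independent stream per
stage (``core.stage_rng``), so outputs are bit-identical for a fixed seed and
stages are decoupled. Genotypes are generated directly as homozygote doses
{0, 2}: heterozygotes are never simulated, matching fully inbred panels whose
published calls are homozygous. Linkage disequilibrium uses first-order
Markov copying along each chromosome — a simple, controllable adjacent-r2
structure, not a coalescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, stage_rng

CHROMOSOMES = ("X", "2L", "2R", "3L", "3R")


@dataclass
class SimTruth:
    """Ground truth recorded by the generators, for recovery tests."""

    marker_effects: np.ndarray | None = None  # per-marker effects on scaled doses
    h2: float | None = None
    causal_feature_ids: list[str] = field(default_factory=list)
    batch_offsets: dict[str, float] = field(default_factory=dict)
    covariate_effects: np.ndarray | None = None
    genetic_values: np.ndarray | None = None
    environmental_values: np.ndarray | None = None
    line_sd: float | None = None
    metabolite_treatment_effects: np.ndarray | None = None
    metabolite_class_effects: np.ndarray | None = None
    metabolite_interaction_effects: np.ndarray | None = None
    starvation_params: dict | None = None

    def realized_h2(self) -> float:
        """Genetic-variance fraction computed directly from the stored components."""
        g = np.asarray(self.genetic_values)
        e = np.asarray(self.environmental_values)
        vg, ve = g.var(ddof=1), e.var(ddof=1)
        return float(vg / (vg + ve)) if vg + ve > 0 else 0.0


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 0.9,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Homozygous-line genotypes with Markov-copying LD along chromosomes.

    Marker j on a chromosome copies marker j-1's allele (per line) with
    probability ``ld_decay``, else draws fresh from Bernoulli(p_j) with p_j
    uniform on ``maf_range``. Doses are {0, 2}; a fraction ``missing_rate``
    of cells is masked at random. Positions are strictly increasing within
    chromosomes; markers are split evenly across five chromosome arms.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if hi < 0.5 / n_lines:
        raise ValueError(
            f"maf_range {maf_range} infeasible for {n_lines} lines: "
            f"minimum representable nonzero MAF is {1 / n_lines:.4g}"
        )
    if not 0 <= ld_decay <= 1:
        raise ValueError("ld_decay must be a probability")

    rng = stage_rng(seed, "genotypes")
    n_chrom = min(len(CHROMOSOMES), n_markers)
    counts = [n_markers // n_chrom + (1 if i < n_markers % n_chrom else 0) for i in range(n_chrom)]

    dose = np.empty((n_lines, n_markers), dtype=float)
    chroms, positions, ids = [], [], []
    col = 0
    for ci in range(n_chrom):
        k = counts[ci]
        pos = np.cumsum(rng.integers(100, 5001, size=k))
        p = rng.uniform(lo, hi, size=k)
        alleles = np.empty((n_lines, k), dtype=np.int8)
        alleles[:, 0] = rng.random(n_lines) < p[0]
        for j in range(1, k):
            fresh = rng.random(n_lines) < p[j]
            copy = rng.random(n_lines) < ld_decay
            alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
        dose[:, col:col + k] = 2.0 * alleles
        chroms.extend([CHROMOSOMES[ci]] * k)
        positions.extend(pos.tolist())
        ids.extend(f"{CHROMOSOMES[ci]}_{pp}" for pp in pos)
        col += k

    if missing_rate > 0:
        mask = rng.random(dose.shape) < missing_rate
        dose[mask] = np.nan

    markers = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "id": ids,
         "a1": ["A"] * n_markers, "a2": ["T"] * n_markers}
    )
    line_ids = [f"line{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids=line_ids, markers=markers, dose=dose)


def simulate_phenotype(
    G: GenotypeMatrix,
    h2: float,
    causal_features=None,
    batch_design: dict[str, str] | None = None,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    n_causal: int | None = None,
    batch_sd: float = 0.25,
    feature_variance_share: float = 1.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Polygenic phenotype y = X beta + W b + batch + e on the delay scale.

    Causal markers come from ``causal_features`` (a FeatureSet or an iterable
    of them); with none given, effects are spread over ``n_causal`` random
    markers (default: all of them, the fully polygenic architecture the
    gBLUP model assumes).
    The genetic and residual components are rescaled to empirical SDs
    sqrt(h2) and sqrt(1-h2), so the realized genetic-variance fraction equals
    ``h2`` to machine precision; batch offsets and covariate effects sit on
    top and are recorded in ``SimTruth``.
    """
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must be in [0, 1]")
    rng = stage_rng(seed, "phenotype")
    n, m = G.n_lines, G.n_markers
    # scaled doses with zero-variance (chance-monomorphic) markers zeroed out:
    # they can carry no effect
    d = G.imputed_dose()
    sd = d.std(axis=0)
    W = np.where(sd > 0, (d - d.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)

    causal_ids: list[str] = []
    if causal_features:
        feats = causal_features if isinstance(causal_features, (list, tuple)) else [causal_features]
        idx = np.unique(np.concatenate([np.asarray(f.marker_idx) for f in feats]))
        causal_ids = [f.id for f in feats]
    elif n_causal is None:
        idx = np.arange(m)
    else:
        idx = np.sort(rng.choice(m, size=min(n_causal, m), replace=False))

    if not 0 < feature_variance_share <= 1:
        raise ValueError("feature_variance_share must be in (0, 1]")

    def _scaled_effects(sub_idx, target_sd):
        bb = np.zeros(m)
        bb[sub_idx] = rng.normal(size=len(sub_idx))
        gg = W @ bb
        sd = gg.std(ddof=1)
        if sd == 0:
            raise ValueError("causal markers carry no genetic variance")
        bb *= target_sd / sd
        return bb

    b = np.zeros(m)
    g = np.zeros(n)
    if h2 > 0:
        b = _scaled_effects(idx, np.sqrt(h2 * feature_variance_share))
        if feature_variance_share < 1:
            # polygenic background on the remaining markers
            rest = np.setdiff1d(np.arange(m), idx)
            b = b + _scaled_effects(rest, np.sqrt(h2 * (1 - feature_variance_share)))
        g = W @ b
    e = rng.normal(size=n)
    e = e - e.mean()
    if h2 < 1:
        e *= np.sqrt(1 - h2) / e.std(ddof=1)
    else:
        e[:] = 0.0

    batch_design = batch_design or {lid: "B1" for lid in G.line_ids}
    batches = sorted(set(batch_design.values()))
    offsets = {bt: (float(rng.normal(0, batch_sd)) if len(batches) > 1 else 0.0) for bt in batches}
    batch_term = np.array([offsets[batch_design[lid]] for lid in G.line_ids])

    beta = np.zeros(0)
    cov_term = np.zeros(n)
    if covariates is not None:
        Xc = covariates.loc[G.line_ids].to_numpy(dtype=float)
        beta = rng.normal(0, 0.2, size=Xc.shape[1])
        cov_term = Xc @ beta

    y = g + e + batch_term + cov_term
    pheno = pd.DataFrame(
        {"line": G.line_ids,
         "batch": [batch_design[lid] for lid in G.line_ids],
         "delay": y}
    )
    truth = SimTruth(
        marker_effects=b, h2=float(h2), causal_feature_ids=causal_ids,
        batch_offsets=offsets, covariate_effects=beta,
        genetic_values=g, environmental_values=e,
    )
    return pheno, truth


def simulate_pupation_records(
    line_means: dict[str, tuple[float, float]],
    n_vials: int = 4,
    larvae_per_vial: int = 40,
    sd_days: float = 1.0,
    seed: int = 0,
    survival: float = 0.5,
    batches: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-vial daily pupa counts for control and rapamycin conditions.

    Each larva's development time is Gaussian around the requested line x
    condition mean and rounded to the observation day; mortality is binomial
    thinning at rate 1 - ``survival``. The default survival of 0.5 mirrors a
    screen recovering ~77 pupae per condition from 4 vials x 40 embryos.
    """
    if sd_days <= 0:
        raise ValueError("sd_days must be positive")
    if larvae_per_vial < 1:
        raise ValueError("larvae_per_vial must be >= 1")
    if not 0 < survival <= 1:
        raise ValueError("survival must be in (0, 1]")
    rng = stage_rng(seed, "pupation")
    batches = batches or {}
    rows = []
    vial_no = 0
    for line, (mu_c, mu_r) in line_means.items():
        batch = batches.get(line, "B1")
        for treatment, mu in (("control", mu_c), ("rapamycin", mu_r)):
            for _ in range(n_vials):
                vial_no += 1
                n_surv = int(rng.binomial(larvae_per_vial, survival))
                if n_surv == 0:
                    continue
                days = np.maximum(1, np.rint(rng.normal(mu, sd_days, size=n_surv)).astype(int))
                vals, counts = np.unique(days, return_counts=True)
                for day, cnt in zip(vals, counts):
                    rows.append((f"v{vial_no:05d}", line, treatment, batch, int(day), int(cnt)))
    return pd.DataFrame(rows, columns=["vial", "line", "treatment", "batch", "day", "count"])


def simulate_metabolome(
    n_lines_per_class: tuple[int, int] | int = (6, 7),
    metabolites: int = 154,
    effect_spec: SimTruth | None = None,
    batch_shifts: dict[str, tuple[float, float]] | None = None,
    reps: int = 2,
    seed: int = 0,
    noise_sd: float = 0.3,
    line_sd: float = 0.3,
):
    """Raw-scale metabolite intensities with line/class/treatment/batch structure.

    Log-intensities are base abundance + line effect + treatment, class and
    treatment-x-class (sensitive only) effects + batch location/scale
    distortion + noise, then exponentiated to a positive raw scale. The
    default design — six resistant and seven sensitive lines, both
    treatments, two extraction batches — matches a small larval metabolomics
    study (2 x 13 x 2 = 52 samples at reps=2).

    Returns a ``metabolome.MetaboliteMatrix`` (raw scale) and the SimTruth.
    """
    from .metabolome import MetaboliteMatrix

    if isinstance(n_lines_per_class, int):
        n_res = n_sen = n_lines_per_class
    else:
        n_res, n_sen = n_lines_per_class
    rng = stage_rng(seed, "metabolome")
    spec = effect_spec or SimTruth()
    bt = np.zeros(metabolites) if spec.metabolite_treatment_effects is None else np.asarray(spec.metabolite_treatment_effects, float)
    bp = np.zeros(metabolites) if spec.metabolite_class_effects is None else np.asarray(spec.metabolite_class_effects, float)
    btp = np.zeros(metabolites) if spec.metabolite_interaction_effects is None else np.asarray(spec.metabolite_interaction_effects, float)
    lsd = line_sd if spec.line_sd is None else spec.line_sd
    batch_shifts = batch_shifts or {}

    lines = [f"R{i + 1:02d}" for i in range(n_res)] + [f"S{i + 1:02d}" for i in range(n_sen)]
    classes = ["resistant"] * n_res + ["sensitive"] * n_sen
    base = rng.normal(8.0, 1.0, size=metabolites)
    line_eff = rng.normal(0, lsd, size=(len(lines), metabolites))

    rows, meta = [], []
    sn = 0
    for r in range(reps):
        batch = f"E{r + 1}"
        loc, scale = batch_shifts.get(batch, (0.0, 1.0))
        if scale <= 0:
            raise ValueError("batch scale shifts must be positive")
        for li, (line, cls) in enumerate(zip(lines, classes)):
            for treatment in ("control", "rapamycin"):
                t = 1.0 if treatment == "rapamycin" else 0.0
                s = 1.0 if cls == "sensitive" else 0.0
                x = (base + line_eff[li] + t * bt + s * bp + t * s * btp
                     + rng.normal(0, noise_sd, size=metabolites))
                x = loc + scale * x
                sn += 1
                rows.append(np.exp(x))
                meta.append((f"smp{sn:03d}", line, cls, treatment, batch))

    met_ids = [f"met{j + 1:03d}" for j in range(metabolites)]
    data = pd.DataFrame(rows, columns=met_ids, index=[m[0] for m in meta])
    meta_df = pd.DataFrame(meta, columns=["sample", "line", "phenotype_class", "treatment", "batch"]).set_index("sample")
    truth = SimTruth(
        metabolite_treatment_effects=bt, metabolite_class_effects=bp,
        metabolite_interaction_effects=btp, line_sd=lsd,
        batch_offsets={b: v[0] for b, v in batch_shifts.items()},
    )
    return MetaboliteMatrix(data=data, meta=meta_df, normalized=False), truth


def starvation_score(t, a: float, b: float, c: float):
    """Saturating latent trajectory s(t) = a t / (t + b) - c."""
    t = np.asarray(t, dtype=float)
    return a * t / (t + b) - c


def simulate_starvation_timecourse(
    a: float = 20.53,
    b: float = 2.77,
    c: float = 10.01,
    times: list[float] = (0, 2, 4, 6, 8),
    reps: int = 5,
    loadings: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_single_missing: int = 0,
    n_multi_missing: int = 0,
    duplicate_pairs: int = 0,
) -> pd.DataFrame:
    """Reference starvation time-course metabolite table.

    The latent score s(t) = a t/(t+b) - c (defaults are the saturating
    trajectory constants used throughout the tests) drives every metabolite
    through its loading; independent Gaussian noise is added to the latent
    score and to each metabolite. Optional knobs inject metabolites with one
    or several missing values and duplicate-ion column pairs (suffixes
    ``_pos``/``_neg``) to exercise harmonization.

    Returns a frame with columns sample, time_h, then one column per metabolite.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = stage_rng(seed, "starvation")
    loadings = rng.normal(0, 1, size=84) if loadings is None else np.asarray(loadings, float)
    m = loadings.size
    t_grid = np.repeat(np.asarray(times, float), reps)
    s = starvation_score(t_grid, a, b, c) + rng.normal(0, noise_sd, size=t_grid.size)
    X = np.outer(s, loadings) + rng.normal(0, noise_sd, size=(t_grid.size, m))
    names = [f"ref_met{j + 1:03d}" for j in range(m)]
    df = pd.DataFrame(X, columns=names)

    for j in range(duplicate_pairs):
        src = names[j]
        scale = rng.uniform(0.5, 2.0)
        df[src + "_neg"] = df[src] * scale + rng.normal(0, noise_sd, size=len(df))
        df = df.rename(columns={src: src + "_pos"})
    cols = list(df.columns)
    for j in range(n_single_missing):
        col = cols[duplicate_pairs + j]
        df.loc[df.index[rng.integers(len(df))], col] = np.nan
    for j in range(n_multi_missing):
        col = cols[duplicate_pairs + n_single_missing + j]
        ridx = rng.choice(len(df), size=2, replace=False)
        df.loc[df.index[ridx], col] = np.nan

    out = pd.DataFrame({"sample": [f"ref{i + 1:02d}" for i in range(t_grid.size)], "time_h": t_grid})
    return pd.concat([out, df], axis=1)
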