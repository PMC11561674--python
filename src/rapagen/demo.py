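"""Write a complete, self-consistent demo study to disk.

Produces every input the pipeline consumes — genotypes (PLINK + TSV),
per-vial pupation records across two batches with four reference lines run
in both, line covariates, gene annotations and gene sets, a metabolome with
two extraction batches, a starvation reference time course with a name map
— plus the ground-truth JSON and a config.toml wired to the generated
paths. Scaled to run the whole pipeline in minutes on one CPU.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io, simdata
from .config import PipelineConfig, dump_config_toml
from .core import stage_rng
from .setassoc import build_feature_sets

REFERENCE_LINES = ["ref_Ral45", "ref_Ral321", "ref_w1118", "ref_CantonS"]


def _demo_annotations(markers: pd.DataFrame, rng, genes_per_chrom: int = 10) -> pd.DataFrame:
    rows = []
    g = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        lo, hi = int(pos.min()), int(pos.max())
        edges = np.linspace(lo, hi, genes_per_chrom + 1).astype(int)
        for i in range(genes_per_chrom):
            g += 1
            rows.append((f"gene{g:03d}", chrom, int(edges[i]) + 1, int(edges[i + 1])))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def _demo_pathways(genes: list[str], rng, n_pathways: int = 8, size: int = 6) -> dict[str, list[str]]:
    return {
        f"pw{k + 1:02d}": sorted(rng.choice(genes, size=min(size, len(genes)), replace=False).tolist())
        for k in range(n_pathways)
    }


def write_demo_study(
    outdir: str | Path,
    seed: int = 0,
    n_lines: int = 80,
    n_markers: int = 1500,
    h2: float = 0.5,
) -> PipelineConfig:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(seed, "demo")

    G = simdata.simulate_genotypes(
        n_lines, n_markers, maf_range=(0.1, 0.5), ld_decay=0.9,
        missing_rate=0.02, seed=seed,
    )
    io.write_plink(G, outdir / "geno")
    io.write_genotypes_tsv(G, outdir / "genotypes.tsv")

    annotations = _demo_annotations(G.markers, rng)
    io.write_table(annotations, outdir / "annotations.tsv")
    pathways = _demo_pathways(annotations["gene"].tolist(), rng)
    io.write_gmt(pathways, outdir / "genesets.gmt")

    covariates = pd.DataFrame({
        "line": G.line_ids,
        "wolbachia": rng.integers(0, 2, size=n_lines),
        "in_2l_t": rng.integers(0, 2, size=n_lines),
        "in_2r_ns": rng.integers(0, 2, size=n_lines),
    })
    io.write_table(covariates, outdir / "covariates.tsv")

    feats = build_feature_sets(annotations, G.markers, pathways=pathways,
                               min_pathway_markers=20)
    causal = feats["pathway"][:1] if feats["pathway"] else None
    pheno, truth = simdata.simulate_phenotype(
        G, h2=h2, causal_features=causal,
        batch_design={lid: ("B1" if i < n_lines // 2 else "B2") for i, lid in enumerate(G.line_ids)},
        covariates=covariates.set_index("line"), seed=seed,
    )

    # per-vial records: panel lines in their own batch, reference lines in every batch
    base_ctrl = 10.0
    line_delay = dict(zip(pheno["line"], 2.0 + pheno["delay"]))
    records = []
    for bi, batch in enumerate(("B1", "B2")):
        in_batch = pheno.loc[pheno["batch"] == batch, "line"].tolist()
        means = {lid: (base_ctrl, base_ctrl + line_delay[lid]) for lid in in_batch}
        for r, ref in enumerate(REFERENCE_LINES):
            means[ref] = (base_ctrl, base_ctrl + 1.0 + 0.5 * r)
        records.append(simdata.simulate_pupation_records(
            means, n_vials=4, larvae_per_vial=40, sd_days=1.0,
            seed=seed + 1000 * (bi + 1), survival=0.5,
            batches={lid: batch for lid in means},
        ))
    pupation = pd.concat(records, ignore_index=True)
    io.write_table(pupation, outdir / "pupation.tsv")

    interaction = np.zeros(60)
    interaction[:5] = 1.0  # a few metabolites with a class-specific drug response
    spec = simdata.SimTruth(metabolite_interaction_effects=interaction)
    met, met_truth = simdata.simulate_metabolome(
        (6, 7), metabolites=60, effect_spec=spec,
        batch_shifts={"E2": (1.5, 1.1)}, reps=2, seed=seed,
    )
    io.write_table(met.data.reset_index(names="sample"), outdir / "metabolome.tsv")
    io.write_table(met.meta.reset_index(), outdir / "samples.tsv")

    loadings = stage_rng(seed, "demo_loadings").normal(size=40)
    ref = simdata.simulate_starvation_timecourse(
        loadings=loadings, noise_sd=0.1, seed=seed,
        n_single_missing=3, n_multi_missing=2, duplicate_pairs=2,
    )
    io.write_table(ref, outdir / "reference_timecourse.tsv")
    ref_mets = [c for c in ref.columns if c not in ("sample", "time_h")]
    merged = {}
    for name in ref_mets:
        stem = name.rsplit("_", 1)[0] if name.endswith(("_pos", "_neg")) else name
        merged.setdefault(stem, []).append(name)
    rows = []
    qnames = iter(met.data.columns)
    for stem, members in merged.items():
        try:
            q = next(qnames)
        except StopIteration:
            break
        for member in members:
            rows.append((member if len(members) == 1 else stem, q))
    name_map = pd.DataFrame(sorted(set(rows)), columns=["ref_name", "query_name"])
    io.write_table(name_map, outdir / "name_map.tsv")
    dup_rows = [(m[0], m[1]) for m in (sorted(v) for v in merged.values()) if len(m) == 2]
    io.write_table(pd.DataFrame(dup_rows, columns=["ion_a", "ion_b"]), outdir / "duplicate_ions.tsv")

    io.write_json({
        "h2": truth.h2,
        "realized_h2": truth.realized_h2(),
        "causal_feature_ids": truth.causal_feature_ids,
        "batch_offsets": truth.batch_offsets,
        "metabolite_interaction_effects": met_truth.metabolite_interaction_effects,
    }, outdir / "truth.json")

    cfg = PipelineConfig(
        paths={
            "plink_prefix": str(outdir / "geno"),
            "pupation": str(outdir / "pupation.tsv"),
            "covariates": str(outdir / "covariates.tsv"),
            "annotations": str(outdir / "annotations.tsv"),
            "genesets": str(outdir / "genesets.gmt"),
            "metabolome": str(outdir / "metabolome.tsv"),
            "samples": str(outdir / "samples.tsv"),
            "reference_timecourse": str(outdir / "reference_timecourse.tsv"),
            "name_map": str(outdir / "name_map.tsv"),
            "duplicate_ions": str(outdir / "duplicate_ions.tsv"),
        },
        assoc={"n_perm": 2000, "h2_permutations": 200, "bootstrap_reps": 20,
               "min_pathway_markers": 20},
        bootstrap_sizes=[n_lines // 2, (3 * n_lines) // 4],
        reference_lines=REFERENCE_LINES,
        seed=seed,
        outdir=str(outdir / "results"),
    )
    (outdir / "config.toml").write_text(dump_config_toml(cfg))
    return cfg
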