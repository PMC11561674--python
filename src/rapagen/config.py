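"""Pipeline configuration: TOML-backed, with the study's settings as defaults.

The QC defaults encode the two marker profiles used throughout: the GRM
profile (MAF >= 5%, call rate >= 95%, LD-pruned to r2 <= 0.8 in 200 kb
windows sliding 5 kb) and the scan profile (MAF > 5%, call rate > 80%,
strict inequalities, no pruning).
"""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

STUDY_QC = {
    "grm_maf": 0.05,
    "grm_callrate": 0.95,
    "scan_maf": 0.05,
    "scan_callrate": 0.80,
    "ld_r2": 0.8,
    "ld_window_bp": 200_000,
    "ld_step_bp": 5_000,
}

STUDY_ASSOC = {
    "n_perm": 100_000,  # desk-scale default; paper-fidelity mode uses 1e6
    "h2_permutations": 1_000,
    "bootstrap_reps": 200,
    "min_pathway_markers": 200,
    "gene_window_bp": 1_000,
}


@dataclass
class PipelineConfig:
    """Paths, QC thresholds, permutation/bootstrap settings and the seed."""

    paths: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: dict(STUDY_QC))
    assoc: dict = field(default_factory=lambda: dict(STUDY_ASSOC))
    bootstrap_sizes: list[int] = field(default_factory=list)
    reference_lines: list[str] = field(default_factory=list)
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        qc = dict(STUDY_QC); qc.update(self.qc); self.qc = qc
        assoc = dict(STUDY_ASSOC); assoc.update(self.assoc); self.assoc = assoc
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for key in ("grm_maf", "grm_callrate", "scan_maf", "scan_callrate", "ld_r2"):
            v = self.qc[key]
            if not 0 <= v <= 1:
                raise ValueError(f"qc.{key}={v} outside [0, 1]")
        if self.qc["ld_step_bp"] <= 0 or self.qc["ld_window_bp"] <= 0:
            raise ValueError("LD window and step must be positive")

    def path(self, key: str) -> Path:
        if key not in self.paths:
            raise KeyError(f"config has no path for {key!r}")
        return Path(self.paths[key])

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    raw = tomllib.loads(Path(path).read_text())
    return PipelineConfig(
        paths=raw.get("paths", {}),
        qc=raw.get("qc", {}),
        assoc=raw.get("assoc", {}),
        bootstrap_sizes=raw.get("bootstrap_sizes", []),
        reference_lines=raw.get("reference_lines", []),
        seed=raw.get("seed", 0),
        outdir=raw.get("outdir", "results"),
    )


def dump_config_toml(cfg: PipelineConfig) -> str:
    """Serialize a config back to TOML (simple scalar/list/table fields only)."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, list):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(type(v))

    lines = [f"seed = {cfg.seed}", f'outdir = "{cfg.outdir}"']
    if cfg.bootstrap_sizes:
        lines.append(f"bootstrap_sizes = {fmt(cfg.bootstrap_sizes)}")
    if cfg.reference_lines:
        lines.append(f"reference_lines = {fmt(cfg.reference_lines)}")
    for section in ("paths", "qc", "assoc"):
        table = getattr(cfg, section)
        if table:
            lines.append(f"\n[{section}]")
            lines.extend(f"{k} = {fmt(v)}" for k, v in table.items())
    return "\n".join(lines) + "\n"
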