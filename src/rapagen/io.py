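"""Readers and writers for the pipeline's file formats.

Genotypes travel as PLINK 1 .bed/.bim/.fam triplets (SNP-major bit-pairs)
or as a TSV dialect; gene sets as GMT; everything else as TSV with header,
UTF-8, '.' decimal and "NA" as the missing sentinel. Genomic coordinates
are 1-based closed internally; BED-style 0-based half-open input is
converted at the boundary. Heterozygote calls decode to missing, the
convention for fully inbred panels whose usable calls are homozygous.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = bytes([0x01])
NA = "NA"

# PLINK 1 bit-pair -> dose of the A1 allele (het -> missing for inbred lines)
_CODE_TO_DOSE = {0b00: 2.0, 0b01: np.nan, 0b10: np.nan, 0b11: 0.0}
_DOSE_TO_CODE = {2.0: 0b00, 0.0: 0b11}


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam with SNP-major magic bytes 0x6C 0x1B 0x01."""
    prefix = Path(prefix)
    n, m = G.n_lines, G.n_markers
    fam = pd.DataFrame({
        "fid": G.line_ids, "iid": G.line_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": G.markers["chrom"], "id": G.markers["id"], "cm": 0,
        "pos": G.markers["pos"], "a1": G.markers["a1"], "a2": G.markers["a2"],
    })
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)

    n_bytes = (n + 3) // 4
    out = bytearray(PLINK_MAGIC + SNP_MAJOR)
    for j in range(m):
        col = G.dose[:, j]
        buf = bytearray(n_bytes)
        for i in range(n):
            v = col[i]
            code = 0b01 if np.isnan(v) else _DOSE_TO_CODE[float(v)]
            buf[i // 4] |= code << (2 * (i % 4))
        out.extend(buf)
    Path(str(prefix) + ".bed").write_bytes(bytes(out))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 .bed/.bim/.fam triplet into a GenotypeMatrix.

    Requires the SNP-major layout; het calls become missing. Raises on bad
    magic bytes or a .bed length inconsistent with .bim/.fam.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(Path(str(prefix) + ".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    raw = Path(str(prefix) + ".bed").read_bytes()
    if raw[:2] != PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != SNP_MAJOR:
        raise ValueError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#04x})")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    if len(raw) != 3 + n_bytes * m:
        raise ValueError(
            f"{prefix}.bed: {len(raw)} bytes inconsistent with "
            f"{n} samples x {m} markers from .fam/.bim"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    lut = np.array([_CODE_TO_DOSE[c] for c in range(4)])
    dose = lut[codes].T.astype(float)
    markers = bim[["chrom", "pos", "id", "a1", "a2"]].reset_index(drop=True)
    markers["pos"] = markers["pos"].astype(int)
    return GenotypeMatrix(line_ids=fam["iid"].tolist(), markers=markers, dose=dose)


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    """TSV mirror of the genotypes: marker metadata columns then one column per line."""
    df = G.markers[["chrom", "pos", "id", "a1", "a2"]].copy()
    for i, lid in enumerate(G.line_ids):
        df[lid] = G.dose[i, :]
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%g")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[NA], dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "id", "a1", "a2"]
    line_ids = [c for c in df.columns if c not in meta_cols]
    dose = df[line_ids].to_numpy(dtype=float).T
    return GenotypeMatrix(line_ids=line_ids, markers=df[meta_cols].reset_index(drop=True), dose=dose)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: one row per set (id, description, gene ids...)."""
    pathways: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT row needs id, description and >= 1 gene")
        pid = parts[0]
        if pid in pathways:
            raise ValueError(f"{path}:{ln}: duplicate set id {pid!r}")
        pathways[pid] = parts[2:]
    return pathways


def write_gmt(pathways: dict[str, list[str]], path: str | Path, description: str = "-") -> None:
    with open(path, "w") as fh:
        for pid, genes in pathways.items():
            fh.write("\t".join([pid, description, *genes]) + "\n")


def read_annotations(path: str | Path, bed_style: bool = False) -> pd.DataFrame:
    """Gene intervals TSV (gene, chrom, start, end[, strand]).

    With ``bed_style=True`` the input is 0-based half-open and is converted
    to the internal 1-based closed convention (start+1, end unchanged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = {"gene", "chrom", "start", "end"}
    if not req.issubset(df.columns):
        raise ValueError(f"annotations need columns {sorted(req)}")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids in annotations: {dups[:5]}")
    if bed_style:
        df = df.copy()
        df["start"] = df["start"] + 1
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV with header; 'NA' decodes to missing."""
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Deterministic TSV writer: fixed float format, 'NA' sentinel, no index."""
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format=float_format)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
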