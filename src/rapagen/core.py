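"""Shared containers and utilities for genotype-based analyses.

Allele doses follow the inbred-line convention: each line is fully
homozygous, so the dose of the counted allele at a marker is 0 or 2;
missing calls are ``NaN``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Derive an independent random stream from a global seed and a stage name.

    Each pipeline stage gets its own stream so that changing e.g. the number
    of markers simulated does not perturb phenotype noise downstream.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass
class GenotypeMatrix:
    """Lines x biallelic markers with allele-dose codes in {0, 2, NaN}.

    ``markers`` holds one row per marker: chrom, pos (1-based bp), id, a1, a2.
    Positions are non-decreasing within each chromosome.
    """

    line_ids: list[str]
    markers: pd.DataFrame
    dose: np.ndarray  # float (n_lines, n_markers); NaN = missing

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError("dose shape does not match line/marker metadata")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (a1) allele per marker, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dose, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dose), axis=0)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            dose=self.dose[:, keep],
        )

    def subset_lines(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in keep],
            markers=self.markers,
            dose=self.dose[keep, :],
        )

    def imputed_dose(self) -> np.ndarray:
        """Doses with missing cells filled by the per-marker mean."""
        d = self.dose.copy()
        mu = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = mu[idx[1]]
        return d

    def scaled_dose(self) -> np.ndarray:
        """Mean-centred, unit-SD doses (missing imputed to the marker mean).

        SD uses the population denominator (ddof=0). Raises on a marker with
        zero variance, which cannot be scaled.
        """
        d = self.imputed_dose()
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            ids = self.markers["id"].iloc[bad[:5]].tolist()
            raise ValueError(f"zero-variance marker(s) cannot be scaled: {ids}")
        return (d - mu) / sd


@dataclass
class Grm:
    """Genomic relationship matrix K = W W' / m over centred, scaled doses."""

    line_ids: list[str]
    matrix: np.ndarray
    m: int
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square over the line ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return len(self.line_ids)

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (values ascending, column eigenvectors)."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.matrix)
            if vals[0] < -1e-8 * max(1.0, vals[-1]):
                raise ValueError(f"GRM is not PSD (min eigenvalue {vals[0]:.3g})")
            self._eig = (np.maximum(vals, 0.0), vecs)
        return self._eig

    def subset(self, keep: np.ndarray) -> "Grm":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Grm(
            line_ids=[self.line_ids[i] for i in keep],
            matrix=self.matrix[np.ix_(keep, keep)],
            m=self.m,
        )
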