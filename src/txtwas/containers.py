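"""Shared in-memory containers for genotype, LD, and GWAS summary data.

Matrix orientation is samples x features everywhere. Genotype dosages are
column-standardized (mean 0, variance 1) unless stated otherwise; SNP
metadata travels alongside the matrix as a pandas DataFrame with 1-based
positions, following PLINK/GWAS convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GwasSummary",
    "LDMatrix",
    "DegenerateGenotypeError",
    "InconsistentConfigError",
]

SNP_COLUMNS = ["snp", "chr", "pos", "a1", "a2"]


class DegenerateGenotypeError(RuntimeError):
    """A genotype column stayed monomorphic after bounded resampling."""


class InconsistentConfigError(ValueError):
    """Simulation parameters contradict each other (e.g. h_g2>0 with no effects)."""


@dataclass
class GenotypeMatrix:
    """Standardized dosage matrix plus SNP metadata.

    Parameters
    ----------
    X : (N, P) ndarray
        Column-standardized dosages.
    snps : DataFrame
        One row per SNP with at least columns ``snp, chr, pos, a1, a2``;
        simulated panels also carry ``maf``.
    counts : optional (N, P) int8 ndarray of raw 0/1/2 allele counts.
    """

    X: np.ndarray
    snps: pd.DataFrame
    counts: np.ndarray | None = None
    # latent-model state needed to draw matched panels (simulated loci only)
    maf: np.ndarray | None = None
    ld_chol: np.ndarray | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x SNPs)")
        if len(self.snps) != self.X.shape[1]:
            raise ValueError("snps metadata does not match X columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp"].tolist()

    def ld(self, ridge: float = 0.0) -> "LDMatrix":
        """In-sample LD correlation matrix V = X'X / N (optionally ridged)."""
        V = self.X.T @ self.X / self.n_samples
        if ridge > 0:
            V = (1 - ridge) * V + ridge * np.eye(self.n_snps)
        np.fill_diagonal(V, 1.0)
        return LDMatrix(snp_ids=self.snp_ids, V=V)


@dataclass
class LDMatrix:
    """SNP-SNP correlation matrix with identifiers."""

    snp_ids: list[str]
    V: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        P = len(self.snp_ids)
        if self.V.shape != (P, P):
            raise ValueError("V shape does not match snp_ids")
        if not np.allclose(self.V, self.V.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.V), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        w = np.linalg.eigvalsh(self.V)
        if w.min() < -1e-6:
            raise ValueError(f"LD matrix is not PSD (min eigenvalue {w.min():.3g})")

    def subset(self, ids: list[str]) -> "LDMatrix":
        idx = pd.Index(self.snp_ids).get_indexer(ids)
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise KeyError(f"SNPs absent from LD matrix: {missing[:5]}")
        return LDMatrix(snp_ids=list(ids), V=self.V[np.ix_(idx, idx)])


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics (id, alleles, z-score, sample size)."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ["snp", "a1", "a2", "z", "n"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"GWAS summary table missing columns: {missing}")
        if self.table["snp"].duplicated().any():
            dup = self.table.loc[self.table["snp"].duplicated(), "snp"].iloc[0]
            raise ValueError(f"duplicated SNP id in GWAS summary: {dup!r}")
        z = self.table["z"].to_numpy(dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite z-score in GWAS summary")
        same = self.table["a1"].astype(str) == self.table["a2"].astype(str)
        if same.any():
            bad = self.table.loc[same, "snp"].iloc[0]
            raise ValueError(f"identical alleles for SNP {bad!r}")

    @property
    def z(self) -> np.ndarray:
        return self.table["z"].to_numpy(dtype=float)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp"].tolist()

    def __len__(self) -> int:
        return len(self.table)
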