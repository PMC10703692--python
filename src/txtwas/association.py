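"""Trait association from GWAS summary statistics (or individual data).

The summary-level engine is the weighted burden test,

    Z = w'z / sqrt(w' V w),

where w are the trained SNP weights for one isoform, z the GWAS z-scores and
V the LD correlation matrix from a reference panel. Isoform p-values are
aggregated per gene with the Cauchy combination test (ACAT), screened across
genes by Benjamini-Hochberg FDR, and isoforms of screened genes are
confirmed with Shaffer's modified sequentially rejective Bonferroni
procedure. A permutation test (shuffling the SNP weights) controls for LD
architecture at GWAS loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GwasSummary, LDMatrix
from .model import WeightModel

logger = logging.getLogger(__name__)

__all__ = [
    "align_alleles",
    "impute_and_test_individual",
    "burden_test",
    "acat",
    "stepwise_test",
    "shaffer_confirm",
    "permutation_test",
    "ld_clump",
    "effective_n_heuristic",
    "TraitAssociationScan",
    "AssociationResults",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_P_FLOOR = 1e-300
_DENOM_FLOOR = 1e-12


def zscore_to_p(z) -> np.ndarray:
    """Two-sided normal p-value from |Z|, floored away from exact zero."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, _P_FLOOR)


def align_alleles(
    model_snps: pd.DataFrame,
    gwas: GwasSummary,
    keep_ambiguous: bool = False,
):
    """Harmonize GWAS z-scores to the weight model's allele coding.

    Returns (z harmonized to model a1 dosage, boolean mask over model SNPs).
    Swapped A1/A2 flips the z sign; strand-ambiguous pairs (A/T, C/G) are
    dropped unless keep_ambiguous; SNPs absent from the GWAS are masked out.
    """
    g = gwas.table.set_index("snp")
    mask = np.zeros(len(model_snps), dtype=bool)
    z_out = np.zeros(len(model_snps))
    for i, row in enumerate(model_snps.itertuples(index=False)):
        if row.snp not in g.index:
            continue
        rec = g.loc[row.snp]
        a1, a2 = str(rec["a1"]).upper(), str(rec["a2"]).upper()
        m1, m2 = str(row.a1).upper(), str(row.a2).upper()
        if not keep_ambiguous and (m1, m2) in _AMBIGUOUS:
            continue
        if (a1, a2) == (m1, m2):
            z_out[i], mask[i] = rec["z"], True
        elif (a1, a2) == (m2, m1):
            z_out[i], mask[i] = -rec["z"], True
        # other allele codings (tri-allelic / strand mismatch) are dropped
    if not mask.any():
        raise ValueError("no overlapping SNPs between weights and GWAS summary")
    return z_out[mask], mask


def impute_and_test_individual(X_gwas: np.ndarray, weights: np.ndarray, phenotype: np.ndarray):
    """Individual-level test: regress the phenotype on imputed expression.

    Imputed expression is X_gwas @ w; returns (z, p) from the OLS slope
    t-statistic, or (nan, nan) when the imputed expression is constant.
    """
    g = np.asarray(X_gwas, dtype=float) @ np.asarray(weights, dtype=float)
    if g.std() == 0:
        logger.warning("zero-variance imputed expression; association not testable")
        return np.nan, np.nan
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    r = np.corrcoef(g, y)[0, 1]
    r = np.clip(r, -0.999999999, 0.999999999)
    z = r * np.sqrt((n - 2) / (1.0 - r**2))
    return float(z), float(zscore_to_p(z))


def burden_test(w: np.ndarray, z: np.ndarray, V: LDMatrix | np.ndarray):
    """Weighted burden test Z = w'z / sqrt(w'Vw) with two-sided normal p.

    Returns (nan, nan) for a degenerate model (w'Vw at the numerical floor).
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    Vm = V.V if isinstance(V, LDMatrix) else np.asarray(V, dtype=float)
    denom2 = float(w @ Vm @ w)
    if denom2 <= _DENOM_FLOOR:
        logger.warning("burden test: w'Vw <= floor; degenerate model")
        return np.nan, np.nan
    Z = float(w @ z) / np.sqrt(denom2)
    return Z, float(zscore_to_p(Z))


def acat(p_values, weights=None) -> float:
    """Cauchy combination of (possibly dependent) p-values.

    T = sum_i w_i tan((0.5 - p_i) * pi) / sum_i w_i; combined
    p = 0.5 - arctan(T)/pi, with tail-safe evaluation for extreme inputs:
    p below ~1e-16 contributes 1/(p*pi) (the tangent's leading term) and a
    very large T returns 1/(T*pi).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("acat requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in (0, 1]")
    p = np.clip(p, _P_FLOOR, 1.0 - 1e-16)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, matching p, not all zero")
        w = w / w.sum()
    small = p < 1e-16
    terms = np.empty_like(p)
    terms[small] = 1.0 / (p[small] * np.pi)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    T = float(w @ terms)
    if T > 1e15:
        return max(1.0 / (T * np.pi), _P_FLOOR)
    return float(min(max(0.5 - np.arctan(T) / np.pi, _P_FLOOR), 1.0))


def shaffer_confirm(p_values, alpha: float = 0.05) -> np.ndarray:
    """Shaffer's modified sequentially rejective Bonferroni procedure.

    Assumes the gene passed gene-level screening, which guarantees at least
    one false null among the t isoforms: the ordered p-values are compared
    to alpha divided by (t-1, t-1, t-2, ..., 1) and rejection stops at the
    first failure. Returns rejection booleans in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    t = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(t, dtype=bool)
    for rank, idx in enumerate(order):  # rank is 0-based
        divisor = max(t - max(rank, 1), 1)
        if p[idx] <= alpha / divisor:
            reject[idx] = True
        else:
            break
    return reject


def stepwise_test(
    assoc: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str = "bh",
    stage2_level: str = "adjusted",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step testing ladder: gene-level ACAT screening, isoform
    confirmation within screened genes.

    `assoc` needs columns gene, isoform, p. Gene ACAT p-values are adjusted
    across genes (Benjamini-Hochberg by default, Bonferroni optional);
    genes with adjusted p < alpha are screened in, and their isoforms go
    through Shaffer confirmation at the screening level (stage2_level
    "adjusted", the stage-wise convention) or at raw alpha ("raw").

    Returns (gene table, isoform table).
    """
    if assoc.empty:
        raise ValueError("no associations to test")
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[adjust]
    genes = []
    for gene, grp in assoc.groupby("gene", sort=True):
        genes.append(
            {
                "gene": gene,
                "acat_p": acat(grp["p"].to_numpy()),
                "n_isoforms_tested": len(grp),
            }
        )
    gene_df = pd.DataFrame(genes)
    _, adj, _, _ = multipletests(gene_df["acat_p"], alpha=alpha, method=method)
    gene_df["fdr_adjusted_p"] = adj
    gene_df["screened"] = gene_df["fdr_adjusted_p"] < alpha

    iso_df = assoc.copy()
    iso_df["stage2_reject"] = False
    screened = set(gene_df.loc[gene_df["screened"], "gene"])
    level = alpha  # the stage-wise convention reuses the overall alpha
    for gene in screened:
        sel = iso_df["gene"] == gene
        p = iso_df.loc[sel, "p"].to_numpy()
        if stage2_level == "raw":
            iso_df.loc[sel, "stage2_reject"] = p < alpha
        else:
            iso_df.loc[sel, "stage2_reject"] = shaffer_confirm(p, level)
    return gene_df, iso_df


def permutation_test(
    w: np.ndarray,
    z: np.ndarray,
    V: LDMatrix | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Empirical p-value of the burden statistic under shuffled SNP weights.

    p = (1 + #{|Z_perm| >= |Z_obs|}) / (1 + n_perm); P=1 has no permutation
    space and returns 1 with a warning.
    """
    w = np.asarray(w, dtype=float)
    if w.size < 2:
        logger.warning("permutation test undefined for a single SNP; p = 1")
        return 1.0
    Vm = V.V if isinstance(V, LDMatrix) else np.asarray(V, dtype=float)
    z = np.asarray(z, dtype=float)
    Z_obs, _ = burden_test(w, z, Vm)
    if not np.isfinite(Z_obs):
        return np.nan
    rng = np.random.default_rng(seed)
    W = rng.permuted(np.tile(w, (n_perm, 1)), axis=1)
    num = W @ z
    denom2 = np.einsum("ij,jk,ik->i", W, Vm, W)
    ok = denom2 > _DENOM_FLOOR
    Zp = num[ok] / np.sqrt(denom2[ok])
    n_eff = int(ok.sum())
    exceed = int(np.sum(np.abs(Zp) >= abs(Z_obs)))
    return (1 + exceed) / (1 + n_eff)


def ld_clump(
    gwas: GwasSummary,
    V: LDMatrix,
    p_threshold: float = 5e-8,
    r2: float = 0.2,
) -> list[str]:
    """Greedy LD clumping: repeatedly take the most significant remaining
    SNP below the threshold and remove everything with r^2 >= `r2` to it."""
    sub = V.subset(gwas.snp_ids)
    p = zscore_to_p(gwas.z)
    order = np.argsort(p, kind="stable")
    available = p < p_threshold
    leads: list[str] = []
    R2 = sub.V**2
    for idx in order:
        if not available[idx]:
            continue
        leads.append(gwas.snp_ids[idx])
        available &= R2[idx] < r2
        available[idx] = False
    return leads


def effective_n_heuristic(p_method_a, p_method_b) -> float:
    """Mean percent increase in 1-df chi-square statistics of method A over
    method B, restricted to pairs where the comparator's chi-square exceeds
    1; proportional to the gain in effective GWAS sample size."""
    pa = np.asarray(p_method_a, dtype=float)
    pb = np.asarray(p_method_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("paired p-value vectors must have equal length")
    chi_a = stats.chi2.isf(np.clip(pa, _P_FLOOR, 1.0), df=1)
    chi_b = stats.chi2.isf(np.clip(pb, _P_FLOOR, 1.0), df=1)
    mask = chi_b > 1
    if not mask.any():
        return np.nan
    return float(np.mean(100.0 * (chi_a[mask] - chi_b[mask]) / chi_b[mask]))


# ---------------------------------------------------------------------------
# high-level scan
# ---------------------------------------------------------------------------


class TraitAssociationScan:
    """Summary-statistic association scan over a set of trained weight models.

    Parameters
    ----------
    weights : list of WeightModel
    gwas : GwasSummary
    ld : LDMatrix (reference panel correlation)
    """

    def __init__(self, weights: list[WeightModel], gwas: GwasSummary, ld: LDMatrix):
        self.weights = list(weights)
        self.gwas = gwas
        self.ld = ld

    def fit(
        self,
        alpha: float = 0.05,
        adjust: str = "bh",
        n_perm: int = 0,
        keep_ambiguous: bool = True,
        seed: int = 0,
    ) -> "AssociationResults":
        rows = []
        for wm in self.weights:
            try:
                z_g, mask = align_alleles(wm.snps, self.gwas, keep_ambiguous=keep_ambiguous)
            except ValueError:
                logger.warning("gene %s: no SNP overlap with GWAS; skipped", wm.gene)
                continue
            kept_ids = wm.snps.loc[mask, "snp"].tolist()
            V = self.ld.subset(kept_ids)
            for m, iso in enumerate(wm.isoform_ids):
                w = wm.b_hat[mask, m]
                Z, p = burden_test(w, z_g, V)
                if not np.isfinite(Z):
                    logger.warning("isoform %s: degenerate burden test; skipped", iso)
                    continue
                row = {"gene": wm.gene, "isoform": iso, "z": Z, "p": p}
                if n_perm > 0:
                    row["permutation_p"] = permutation_test(
                        w, z_g, V, n_perm=n_perm, seed=seed
                    )
                rows.append(row)
        iso_df = pd.DataFrame(rows)
        if iso_df.empty:
            raise ValueError("no testable isoform associations")
        gene_df, iso_df = stepwise_test(iso_df, alpha=alpha, adjust=adjust)
        return AssociationResults(genes=gene_df, isoforms=iso_df, alpha=alpha)


@dataclass
class AssociationResults:
    """Gene- and isoform-level association tables from one scan."""

    genes: pd.DataFrame
    isoforms: pd.DataFrame
    alpha: float = 0.05

    def summary(self) -> str:
        n_sig = int(self.genes["screened"].sum())
        n_iso = int(self.isoforms["stage2_reject"].sum())
        lines = [
            f"Trait association scan: {len(self.genes)} genes, "
            f"{len(self.isoforms)} isoforms",
            f"  screened genes (adjusted ACAT p < {self.alpha}): {n_sig}",
            f"  confirmed isoforms (within-gene FWER): {n_iso}",
        ]
        return "\n".join(lines)
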