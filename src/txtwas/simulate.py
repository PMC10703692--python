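"""Synthetic cis-locus generator: genotypes, isoform expression, GWAS traits.

The generative model mirrors the standard eQTL/TWAS simulation protocol.
A locus carries P cis-SNPs with AR(1)-decaying LD and M transcript isoforms
of one gene. Isoform expression is

    Y[:, m] = scale(X b_m, h_g2) + scale(u * gamma_m, sigma_h) + scale(eps_m, sigma_e2)

with sigma_e2 = 1 - sigma_h - h_g2, i.e. per-isoform cis-heritability h_g2,
a shared non-cis latent factor u (an N-vector) explaining sigma_h of the
variance in every isoform, and independent noise for the rest. Each genetic
column is rescaled empirically so the realized in-sample variance share hits
its target exactly. Gene-level expression is a usage-weighted sum of the
(standardized) isoforms, standardized again; usage weights default to equal
and encode the "effect isoform makes up fraction p_g of the gene" scenarios.

GWAS phenotypes are built on an independently drawn genotype panel with the
same allele frequencies and LD, under four causal scenarios (gene-only
effect, one effect isoform, two effect isoforms with effect ratio p_e, and a
pure null), and summary statistics are per-SNP OLS z-scores on standardized
dosages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    DegenerateGenotypeError,
    GenotypeMatrix,
    GwasSummary,
    InconsistentConfigError,
)

__all__ = [
    "SimConfig",
    "TraitConfig",
    "SimulatedLocus",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_isoform_expression",
    "simulate_locus",
    "simulate_trait",
    "marginal_z_scores",
]

_MAX_RESAMPLE = 20


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def standardize(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Column-standardize to mean 0, variance 1 (population variance)."""
    a = np.asarray(a, dtype=float)
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant column")
    return (a - mu) / sd


def _scale_to_variance(v: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale a vector so its sample variance equals target_var."""
    if target_var == 0:
        return np.zeros_like(v)
    v = v - v.mean()
    sd = v.std()
    if sd == 0:
        raise InconsistentConfigError(
            "component has zero variance but a positive variance target"
        )
    return v * (math.sqrt(target_var) / sd)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cis-locus.

    h_g2 is the per-isoform cis-heritability, sigma_h the variance share of
    the shared non-cis factor, p_causal the fraction of the P SNPs that are
    causal per isoform and p_shared the fraction of each isoform's causal set
    drawn from a common shared set.
    """

    n_train: int = 500
    n_gwas: int = 50_000
    p_snps: int = 100
    m_isoforms: int = 5
    p_causal: float = 0.01
    p_shared: float = 1.0
    h_g2: float = 0.05
    sigma_h: float = 0.1
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    haplotype_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_isoforms < 1:
            raise ValueError("m_isoforms must be >= 1")
        if not (0 < self.p_causal <= 1):
            raise ValueError("p_causal must be in (0, 1]")
        if not (0 <= self.p_shared <= 1):
            raise ValueError("p_shared must be in [0, 1]")
        if self.sigma_h + self.h_g2 > 1:
            raise ValueError("sigma_h + h_g2 must be <= 1")
        if math.ceil(self.p_causal * self.p_snps) < 1:
            raise ValueError("p_causal * p_snps must round up to >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def sigma_e2(self) -> float:
        return 1.0 - self.sigma_h - self.h_g2

    @property
    def n_causal(self) -> int:
        return math.ceil(self.p_causal * self.p_snps)


@dataclass(frozen=True)
class TraitConfig:
    """Causal scenario linking the locus to a simulated complex trait."""

    scenario: str = "null"  # gene_only | one_isoform | two_isoforms | null
    h_t2: float = 0.05
    p_g: float = 0.5
    p_e: float = 1.0
    seed: int = 0

    SCENARIOS = ("gene_only", "one_isoform", "two_isoforms", "null")

    def __post_init__(self) -> None:
        if self.scenario not in self.SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 <= self.h_t2 < 1):
            raise ValueError("h_t2 must be in [0, 1)")
        if not (0 < self.p_g < 1):
            raise ValueError("p_g must be in (0, 1)")


@dataclass
class SimulatedLocus:
    """One simulated locus: genotypes, true effects, expression components."""

    genotypes: GenotypeMatrix
    b_true: np.ndarray  # (P, M) raw draws on causal entries
    b_scaled: np.ndarray  # (P, M) effects on the standardized-expression scale
    expression: np.ndarray  # (N, M), columns standardized
    gene_expression: np.ndarray  # (N,), standardized usage-weighted sum
    genetic: np.ndarray  # (N, M) genetic component (pre-standardization scale)
    shared: np.ndarray  # (N, M) shared non-cis component
    noise: np.ndarray  # (N, M) independent noise component
    usage: np.ndarray  # (M,) usage weights, sum to 1
    config: SimConfig = field(repr=False, default=None)

    @property
    def isoform_ids(self) -> list[str]:
        return [f"iso{m + 1}" for m in range(self.expression.shape[1])]

    def realized_variance_shares(self) -> pd.DataFrame:
        """Per-isoform realized variance of each component over the total."""
        total = self.expression_raw_var()
        return pd.DataFrame(
            {
                "h_g2": self.genetic.var(axis=0) / total,
                "sigma_h": self.shared.var(axis=0) / total,
                "sigma_e2": self.noise.var(axis=0) / total,
            },
            index=self.isoform_ids,
        )

    def expression_raw_var(self) -> np.ndarray:
        return (self.genetic + self.shared + self.noise).var(axis=0)


def _threshold_counts(latent_a: np.ndarray, latent_b: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Two latent haplotypes -> additive 0/1/2 counts via MAF quantile cut."""
    return (latent_a < q).astype(np.int8) + (latent_b < q).astype(np.int8)


def _ar1_chol(p: int, rho: float) -> np.ndarray:
    if rho == 0:
        return np.eye(p)
    idx = np.arange(p)
    C = rho ** np.abs(np.subtract.outer(idx, idx))
    return np.linalg.cholesky(C + 1e-10 * np.eye(p))


def _draw_counts(n: int, L: np.ndarray, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = len(q)
    Za = rng.standard_normal((n, p)) @ L.T
    Zb = rng.standard_normal((n, p)) @ L.T
    G = _threshold_counts(Za, Zb, q)
    # resample monomorphic columns with independent redraws (LD to that
    # column is sacrificed; essentially unreachable for maf >= 0.05, n >= 100)
    for _ in range(_MAX_RESAMPLE):
        mono = np.flatnonzero(G.std(axis=0) == 0)
        if mono.size == 0:
            return G
        za = rng.standard_normal((n, mono.size))
        zb = rng.standard_normal((n, mono.size))
        G[:, mono] = (za < q[mono]).astype(np.int8) + (zb < q[mono]).astype(np.int8)
    raise DegenerateGenotypeError(
        f"columns {mono.tolist()} monomorphic after {_MAX_RESAMPLE} resamples"
    )


def _load_haplotypes(path: str) -> np.ndarray:
    H = pd.read_csv(path, sep="\t", comment="#").to_numpy()
    if H.ndim != 2 or H.shape[0] % 2:
        raise ValueError("haplotype panel must have an even number of rows (2 per sample)")
    if not np.isin(H, [0, 1]).all():
        raise ValueError("haplotype panel must be 0/1 coded")
    return H.astype(np.int8)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an N x P standardized dosage panel.

    Synthetic mode thresholds AR(1) latent-Gaussian haplotypes at the MAF
    quantile, so the latent correlation between SNPs j and k is
    ld_rho**|j-k|. Haplotype mode resamples pairs of rows (with replacement)
    from a 0/1 reference haplotype TSV instead.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    P = config.p_snps
    if config.haplotype_path is not None:
        H = _load_haplotypes(config.haplotype_path)
        if H.shape[1] != P:
            raise ValueError("haplotype panel width does not match p_snps")
        pick_a = rng.integers(0, H.shape[0], size=config.n_train)
        pick_b = rng.integers(0, H.shape[0], size=config.n_train)
        G = (H[pick_a] + H[pick_b]).astype(np.int8)
        if (G.std(axis=0) == 0).any():
            raise DegenerateGenotypeError("monomorphic column in resampled haplotypes")
        maf = H.mean(axis=0)
        L = None
        haps = H
    else:
        lo, hi = config.maf_range
        maf = rng.uniform(lo, hi, size=P)
        q = stats.norm.ppf(maf)
        L = _ar1_chol(P, config.ld_rho)
        G = _draw_counts(config.n_train, L, q, rng)
        haps = None
    snps = pd.DataFrame(
        {
            "snp": [f"snp{j + 1:04d}" for j in range(P)],
            "chr": 1,
            "pos": 1_000_000 + 1_000 * np.arange(P),  # 1-based, 1 kb spacing
            "a1": "A",
            "a2": "G",
            "maf": maf,
        }
    )
    X = standardize(G)
    return GenotypeMatrix(X=X, snps=snps, counts=G, maf=maf, ld_chol=L, haplotypes=haps)


def sample_matched_panel(
    genotypes: GenotypeMatrix, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Standardized dosages for a fresh panel with the same MAF/LD as `genotypes`."""
    if genotypes.haplotypes is not None:
        H = genotypes.haplotypes
        G = (H[rng.integers(0, H.shape[0], n)] + H[rng.integers(0, H.shape[0], n)])
    else:
        if genotypes.ld_chol is None or genotypes.maf is None:
            raise ValueError("genotype panel lacks the latent model needed for resampling")
        q = stats.norm.ppf(genotypes.maf)
        G = _draw_counts(n, genotypes.ld_chol, q, rng)
    return standardize(G)


def simulate_effects(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the P x M matrix of true SNP-isoform effects.

    Each isoform receives c = ceil(p_causal * P) causal SNPs; round-half-up
    p_shared * c of them come from one common shared set of causal SNPs, the
    remainder are isoform-private draws from the leftover SNPs. Nonzero
    effect values are i.i.d. standard normal per isoform (so isoforms share
    causal variants, not effect sizes, and the usage-weighted gene keeps the
    per-isoform heritability in expectation); column scaling to the
    heritability target happens in simulate_isoform_expression.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    P, M, c = config.p_snps, config.m_isoforms, config.n_causal
    n_shared = min(_round_half_up(config.p_shared * c), c)
    shared = rng.choice(P, size=n_shared, replace=False)
    B = np.zeros((P, M))
    rest = np.setdiff1d(np.arange(P), shared)
    for m in range(M):
        own = rng.choice(rest, size=c - n_shared, replace=False)
        support = np.concatenate([shared, own]).astype(int)
        B[support, m] = rng.standard_normal(support.size)
    return B


def simulate_isoform_expression(
    genotypes: GenotypeMatrix,
    b_true: np.ndarray,
    config: SimConfig,
    usage: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedLocus:
    """Compose expression from genetic, shared non-cis, and noise components.

    Components are each rescaled to hit their variance targets (h_g2,
    sigma_h, sigma_e2) exactly in-sample; isoform columns are standardized
    on output. `usage` sets the weight of each isoform in the gene-level sum
    (defaults to equal usage).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    X = genotypes.X
    N, P = X.shape
    M = config.m_isoforms
    b_true = np.asarray(b_true, dtype=float)
    if b_true.shape != (P, M):
        raise ValueError(f"b_true must be {(P, M)}, got {b_true.shape}")
    if usage is None:
        usage = np.full(M, 1.0 / M)
    usage = np.asarray(usage, dtype=float)
    if usage.shape != (M,) or (usage < 0).any() or usage.sum() == 0:
        raise ValueError("usage must be M non-negative weights")
    usage = usage / usage.sum()

    u = rng.standard_normal(N)  # one shared latent sample factor
    gamma = rng.standard_normal(M)  # per-isoform loadings (sign/shape only)
    genetic = np.zeros((N, M))
    shared = np.zeros((N, M))
    noise = np.zeros((N, M))
    b_scaled = np.zeros((P, M))
    for m in range(M):
        raw = X @ b_true[:, m]
        if config.h_g2 > 0:
            if not np.any(b_true[:, m]):
                raise InconsistentConfigError(
                    f"isoform {m}: h_g2 > 0 but its effect column is all zero"
                )
            g = _scale_to_variance(raw, config.h_g2)
            with np.errstate(invalid="ignore"):
                b_scaled[:, m] = b_true[:, m] * math.sqrt(config.h_g2) / raw.std()
        else:
            g = np.zeros(N)
        genetic[:, m] = g
        shared[:, m] = _scale_to_variance(u * gamma[m], config.sigma_h)
        noise[:, m] = _scale_to_variance(rng.standard_normal(N), config.sigma_e2)

    raw_expr = genetic + shared + noise
    sd = raw_expr.std(axis=0)
    expression = (raw_expr - raw_expr.mean(axis=0)) / sd
    b_scaled = b_scaled / sd  # effects on the standardized-expression scale
    gene_raw = expression @ usage
    gene_expression = (gene_raw - gene_raw.mean()) / gene_raw.std()
    return SimulatedLocus(
        genotypes=genotypes,
        b_true=b_true,
        b_scaled=b_scaled,
        expression=expression,
        gene_expression=gene_expression,
        genetic=genetic,
        shared=shared,
        noise=noise,
        usage=usage,
        config=config,
    )


def simulate_locus(config: SimConfig, usage: np.ndarray | None = None) -> SimulatedLocus:
    """Genotypes + effects + expression in one deterministic call."""
    genotypes = simulate_genotypes(config)
    b = simulate_effects(config)
    return simulate_isoform_expression(genotypes, b, config, usage=usage)


def usage_for_scenario(tconfig: TraitConfig, m_isoforms: int) -> np.ndarray:
    """Usage weights implied by a trait scenario (effect isoform is iso1)."""
    if tconfig.scenario == "one_isoform":
        if m_isoforms < 2:
            raise ValueError("one_isoform scenario needs >= 2 isoforms")
        w = np.full(m_isoforms, (1.0 - tconfig.p_g) / (m_isoforms - 1))
        w[0] = tconfig.p_g
        return w
    return np.full(m_isoforms, 1.0 / m_isoforms)


def marginal_z_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-SNP marginal OLS z-scores (no covariates), vectorized.

    With standardized columns this is the t-statistic of the slope,
    z_j = r_j * sqrt((n-2) / (1 - r_j^2)).
    """
    n = len(y)
    yc = (y - y.mean()) / y.std()
    xs = (X - X.mean(axis=0)) / X.std(axis=0)
    r = xs.T @ yc / n
    r = np.clip(r, -0.999999, 0.999999)
    return r * np.sqrt((n - 2) / (1.0 - r**2))


def simulate_trait(
    locus: SimulatedLocus,
    tconfig: TraitConfig,
    n_gwas: int | None = None,
    return_panel: bool = False,
):
    """Simulate a GWAS panel and trait under one causal scenario.

    A fresh genotype panel (independent of the training panel, same MAF/LD)
    is drawn; the trait's genetic score is built from the true standardized-
    scale effects, scaled so the genetic variance share equals h_t2, and
    per-SNP marginal z-scores are returned as a GwasSummary.
    """
    config = locus.config
    if n_gwas is None:
        n_gwas = config.n_gwas
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, tconfig.seed, 53]))
    Xg = sample_matched_panel(locus.genotypes, n_gwas, rng)
    M = locus.expression.shape[1]

    if tconfig.scenario == "null":
        y = rng.standard_normal(n_gwas)
    else:
        iso_scores = Xg @ locus.b_scaled  # genetic component per isoform
        if tconfig.scenario == "gene_only":
            score = iso_scores @ locus.usage
        elif tconfig.scenario == "one_isoform":
            score = iso_scores[:, 0]
        elif tconfig.scenario == "two_isoforms":
            if M < 2:
                raise ValueError("two_isoforms scenario needs >= 2 isoforms")
            score = iso_scores[:, 0] + tconfig.p_e * iso_scores[:, 1]
        if score.std() == 0:
            if tconfig.h_t2 > 0:
                raise InconsistentConfigError("zero-variance genetic score with h_t2 > 0")
            score = np.zeros(n_gwas)
            y = rng.standard_normal(n_gwas)
        else:
            score = _scale_to_variance(score, tconfig.h_t2)
            y = score + math.sqrt(1.0 - tconfig.h_t2) * rng.standard_normal(n_gwas)

    z = marginal_z_scores(Xg, y)
    table = locus.genotypes.snps[["snp", "chr", "pos", "a1", "a2"]].copy()
    table["z"] = z
    table["n"] = n_gwas
    gwas = GwasSummary(table=table)
    if return_panel:
        return y, gwas, Xg
    return y, gwas
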