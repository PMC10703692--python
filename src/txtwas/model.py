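"""Model selection layer: cross-validated fitting of isoform weight models.

`IsoformImputationModel` holds one gene's standardized expression matrix and
cis-genotypes; `.fit()` runs the requested fitters under one shared fold
assignment, selects the method with the largest mean 5-fold CV adjusted R2,
refits it on the full panel, trains the gene-level stacking model (elastic
net of total gene expression on out-of-fold predicted isoforms, same folds)
and the univariate gene-level TWAS baseline, and returns an
`IsoformImputationResults` carrying weights, scores and diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .fitters import (
    FITTERS,
    METHOD_PRECEDENCE,
    FitterConfig,
    adjusted_r2,
    fit_univariate_best,
    make_fold_ids,
)
from .simulate import SimulatedLocus, standardize

logger = logging.getLogger(__name__)

__all__ = [
    "IsoformImputationModel",
    "IsoformImputationResults",
    "WeightModel",
    "cv_adjusted_r2",
    "filter_models",
    "stack_gene_model",
    "train_gene_twas",
    "UntrainableGeneError",
]

CV_R2_THRESHOLD = 0.01


class UntrainableGeneError(RuntimeError):
    """Every requested fitter failed for this gene."""


def cv_adjusted_r2(
    fitter,
    X: np.ndarray,
    Y: np.ndarray,
    fold_ids: np.ndarray,
    cfg: FitterConfig | None = None,
):
    """Out-of-fold predictions and per-isoform CV adjusted R2 for one fitter.

    R2 is the squared Pearson correlation between observed and out-of-fold
    predicted expression, adjusted as 1 - (1-R2)(N-1)/(N-2); a constant
    prediction scores 0.
    """
    if isinstance(fitter, str):
        fitter = FITTERS[fitter]
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n, M = Y.shape
    counts = np.bincount(fold_ids)
    if counts.min() < 2:
        raise ValueError("every CV fold needs at least 2 samples")
    oof = np.zeros((n, M))
    for k in np.unique(fold_ids):
        tr, te = fold_ids != k, fold_ids == k
        res = fitter(X[tr], Y[tr], cfg)
        oof[te] = res.predict(X[te])
    scores = np.array([adjusted_r2(Y[:, m], oof[:, m]) for m in range(M)])
    return scores, oof


def stack_gene_model(
    predicted_iso: np.ndarray,
    gene_expr: np.ndarray,
    fold_ids: np.ndarray,
    cfg: FitterConfig | None = None,
):
    """Gene-level stacking: elastic net of gene expression on the
    out-of-fold genetic predictions of its isoforms, trained and scored on
    the same fold partition (no leakage into the gene CV R2).

    Returns (coefficients, intercept, gene CV adjusted R2).
    """
    cfg = cfg or FitterConfig()
    predicted_iso = np.atleast_2d(np.asarray(predicted_iso, dtype=float))
    if predicted_iso.shape[0] == 1:
        predicted_iso = predicted_iso.T
    if predicted_iso.shape[1] == 0:
        raise ValueError("stacking requires at least one isoform")
    gene_expr = np.asarray(gene_expr, dtype=float).ravel()
    n = len(gene_expr)
    grid = [max(r, 0.01) for r in cfg.mixing_grid]

    def _cv_est(A, y):
        cv = KFold(cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
        return ElasticNetCV(
            l1_ratio=grid, alphas=cfg.n_lambda, cv=cv, fit_intercept=True, max_iter=2000
        ).fit(A, y)

    oof = np.zeros(n)
    for k in np.unique(fold_ids):
        tr, te = fold_ids != k, fold_ids == k
        if predicted_iso[tr].std(axis=0).max() == 0:
            oof[te] = gene_expr[tr].mean()
            continue
        est_k = _cv_est(predicted_iso[tr], gene_expr[tr])
        oof[te] = est_k.predict(predicted_iso[te])
    gene_cv_r2 = adjusted_r2(gene_expr, oof)
    if predicted_iso.std(axis=0).max() == 0:
        return np.zeros(predicted_iso.shape[1]), float(gene_expr.mean()), 0.0
    est = _cv_est(predicted_iso, gene_expr)
    return est.coef_, float(est.intercept_), float(gene_cv_r2)


def train_gene_twas(
    X: np.ndarray,
    gene_expr: np.ndarray,
    cfg: FitterConfig | None = None,
    fold_ids: np.ndarray | None = None,
):
    """Univariate gene-level TWAS comparator: best of elastic net,
    ridge-BLUP and SuSiE on total gene expression (delegates to
    fit_univariate_best with the shared folds)."""
    cfg = cfg or FitterConfig()
    if cfg.univariate_candidates != cfg.gene_univariate_candidates:
        from dataclasses import replace as _replace

        cfg = _replace(cfg, univariate_candidates=cfg.gene_univariate_candidates)
    return fit_univariate_best(X, gene_expr, cfg, fold_ids=fold_ids)


# ---------------------------------------------------------------------------


@dataclass
class WeightModel:
    """Lightweight trained-weight record for one gene (the on-disk unit)."""

    gene: str
    isoform_ids: list[str]
    b_hat: np.ndarray  # (P, M)
    snps: pd.DataFrame  # snp, a1, a2 (+ chr/pos when known)
    cv_r2: np.ndarray  # (M,)
    method: str
    gene_stack_coefs: np.ndarray | None = None
    gene_stack_intercept: float = 0.0
    gene_cv_r2: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, iso in enumerate(self.isoform_ids):
            df = self.snps[["snp", "a1", "a2"]].copy()
            df.insert(0, "gene", self.gene)
            df.insert(1, "isoform", iso)
            df["weight"] = self.b_hat[:, m]
            df["cv_r2"] = self.cv_r2[m]
            df["method"] = self.method
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


class IsoformImputationModel:
    """Multivariate SNP model of one gene's isoform expression.

    Parameters
    ----------
    expression : (N, M) array or DataFrame (columns = isoform ids)
    genotypes : (N, P) array or GenotypeMatrix
    gene_expression : optional N-vector of total gene expression; defaults
        to the standardized row-sum of the (standardized) isoforms.
    """

    def __init__(
        self,
        expression,
        genotypes,
        gene_expression=None,
        isoform_ids=None,
        snps: pd.DataFrame | None = None,
        gene: str = "gene1",
    ):
        if isinstance(expression, pd.DataFrame):
            isoform_ids = isoform_ids or list(expression.columns)
            expression = expression.to_numpy(dtype=float)
        if hasattr(genotypes, "X"):  # GenotypeMatrix
            snps = genotypes.snps if snps is None else snps
            genotypes = genotypes.X
        self.Y = standardize(np.atleast_2d(np.asarray(expression, dtype=float)))
        if self.Y.shape[0] == 1:
            self.Y = self.Y.T
        self.X = standardize(np.asarray(genotypes, dtype=float))
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("expression and genotypes must be row-aligned")
        n, M = self.Y.shape
        self.isoform_ids = list(isoform_ids) if isoform_ids else [f"iso{m+1}" for m in range(M)]
        self.gene = gene
        if snps is None:
            snps = pd.DataFrame(
                {"snp": [f"snp{j+1:04d}" for j in range(self.X.shape[1])], "a1": "A", "a2": "G"}
            )
        self.snps = snps.reset_index(drop=True)
        if gene_expression is None:
            gene_expression = self.Y.sum(axis=1)
        self.gene_expression = standardize(
            np.asarray(gene_expression, dtype=float).reshape(-1, 1)
        ).ravel()

    @classmethod
    def from_locus(cls, locus: SimulatedLocus, gene: str = "gene1") -> "IsoformImputationModel":
        return cls(
            expression=locus.expression,
            genotypes=locus.genotypes,
            gene_expression=locus.gene_expression,
            isoform_ids=locus.isoform_ids,
            gene=gene,
        )

    def fit(
        self,
        methods: list[str] | None = None,
        cfg: FitterConfig | None = None,
        folds: int = 5,
        granularity: str = "gene",
        stack: bool = True,
        twas_baseline: bool = True,
    ) -> "IsoformImputationResults":
        """Run the fitters under shared folds and select the best model.

        granularity="gene" keeps the single method with the largest mean
        per-isoform CV adjusted R2 (ties broken by fixed method precedence);
        granularity="isoform" picks the best method per isoform instead.
        """
        cfg = cfg or FitterConfig()
        methods = list(methods) if methods else list(METHOD_PRECEDENCE)
        unknown = set(methods) - set(FITTERS)
        if unknown:
            raise KeyError(f"unknown fitters: {sorted(unknown)}")
        fold_ids = make_fold_ids(self.X.shape[0], folds, cfg.seed)

        scores: dict[str, np.ndarray] = {}
        oofs: dict[str, np.ndarray] = {}
        for name in methods:
            try:
                scores[name], oofs[name] = cv_adjusted_r2(
                    name, self.X, self.Y, fold_ids, cfg
                )
            except Exception as exc:  # noqa: BLE001 - fitter failure is data-dependent
                logger.warning("fitter %s failed on gene %s: %s", name, self.gene, exc)
        if not scores:
            raise UntrainableGeneError(f"all fitters failed for gene {self.gene}")

        order = {m: i for i, m in enumerate(METHOD_PRECEDENCE)}
        if granularity == "gene":
            best = max(
                scores, key=lambda m: (np.nanmean(scores[m]), -order.get(m, 99))
            )
            b_hat = FITTERS[best](self.X, self.Y, cfg).b_hat
            cv_r2 = scores[best]
            oof = oofs[best]
            method_label = best
        elif granularity == "isoform":
            M = self.Y.shape[1]
            b_hat = np.zeros((self.X.shape[1], M))
            cv_r2 = np.zeros(M)
            oof = np.zeros_like(self.Y)
            picks = []
            full = {m: FITTERS[m](self.X, self.Y, cfg).b_hat for m in scores}
            for j in range(M):
                bm = max(scores, key=lambda m: (scores[m][j], -order.get(m, 99)))
                b_hat[:, j] = full[bm][:, j]
                cv_r2[j] = scores[bm][j]
                oof[:, j] = oofs[bm][:, j]
                picks.append(bm)
            method_label = "per-isoform:" + ",".join(picks)
        else:
            raise ValueError("granularity must be 'gene' or 'isoform'")

        stack_coefs = stack_intercept = None
        gene_stack_cv_r2 = np.nan
        if stack:
            stack_coefs, stack_intercept, gene_stack_cv_r2 = stack_gene_model(
                oof, self.gene_expression, fold_ids, cfg
            )
        twas_w = None
        twas_method = None
        twas_cv_r2 = np.nan
        if twas_baseline:
            twas_w, twas_method, twas_cv_r2, twas_flag = train_gene_twas(
                self.X, self.gene_expression, cfg, fold_ids
            )
            if twas_flag:
                logger.warning("gene %s: TWAS baseline untrainable", self.gene)

        return IsoformImputationResults(
            model=self,
            b_hat=b_hat,
            method=method_label,
            cv_r2=np.asarray(cv_r2, dtype=float),
            method_scores={m: s.copy() for m, s in scores.items()},
            fold_ids=fold_ids,
            oof_predictions=oof,
            gene_stack_coefs=stack_coefs,
            gene_stack_intercept=stack_intercept if stack_intercept is not None else 0.0,
            gene_stack_cv_r2=float(gene_stack_cv_r2),
            twas_weights=twas_w,
            twas_method=twas_method,
            twas_cv_r2=float(twas_cv_r2) if twas_cv_r2 is not None else np.nan,
        )


@dataclass
class IsoformImputationResults:
    """Fitted weights, CV scores and gene-level companions for one gene."""

    model: IsoformImputationModel = field(repr=False)
    b_hat: np.ndarray
    method: str
    cv_r2: np.ndarray
    method_scores: dict = field(default_factory=dict, repr=False)
    fold_ids: np.ndarray | None = field(default=None, repr=False)
    oof_predictions: np.ndarray | None = field(default=None, repr=False)
    gene_stack_coefs: np.ndarray | None = None
    gene_stack_intercept: float = 0.0
    gene_stack_cv_r2: float = np.nan
    twas_weights: np.ndarray | None = field(default=None, repr=False)
    twas_method: str | None = None
    twas_cv_r2: float = np.nan

    _kept_isoforms: list[str] | None = field(default=None, repr=False, compare=False)

    @property
    def isoform_ids(self) -> list[str]:
        if self._kept_isoforms is not None:
            return self._kept_isoforms
        return self.model.isoform_ids

    @property
    def gene(self) -> str:
        return self.model.gene

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.b_hat

    def predict_gene(self, X: np.ndarray) -> np.ndarray:
        """Stacked gene-level prediction from imputed isoform expression."""
        if self.gene_stack_coefs is None:
            raise ValueError("model was fitted without the gene-level stacker")
        return self.predict(X) @ self.gene_stack_coefs + self.gene_stack_intercept

    def filter(self, threshold: float = CV_R2_THRESHOLD) -> "IsoformImputationResults":
        """Drop isoforms with CV R2 <= threshold (strict survival rule).

        Returns a results object restricted to the surviving isoforms; the
        gene is considered testable iff at least one isoform survives.
        Idempotent.
        """
        keep = np.flatnonzero(self.cv_r2 > threshold)
        if keep.size == len(self.cv_r2):
            return self
        out = replace(
            self,
            b_hat=self.b_hat[:, keep],
            cv_r2=self.cv_r2[keep],
            oof_predictions=self.oof_predictions[:, keep]
            if self.oof_predictions is not None
            else None,
            gene_stack_coefs=self.gene_stack_coefs[keep]
            if self.gene_stack_coefs is not None
            else None,
        )
        out._kept_isoforms = [self.isoform_ids[i] for i in keep]
        return out

    @property
    def is_testable(self) -> bool:
        return self.b_hat.shape[1] > 0

    def to_weight_model(self) -> WeightModel:
        return WeightModel(
            gene=self.gene,
            isoform_ids=[self.isoform_ids[i] for i in range(self.b_hat.shape[1])],
            b_hat=self.b_hat,
            snps=self.model.snps,
            cv_r2=self.cv_r2,
            method=self.method,
            gene_stack_coefs=self.gene_stack_coefs,
            gene_stack_intercept=self.gene_stack_intercept,
            gene_cv_r2=self.gene_stack_cv_r2,
        )

    def summary(self) -> str:
        lines = [
            f"Isoform imputation results -- gene {self.gene}",
            f"  samples: {self.model.Y.shape[0]}  SNPs: {self.model.X.shape[1]}"
            f"  isoforms: {len(self.isoform_ids)}",
            f"  selected method: {self.method}",
            "",
            f"  {'isoform':<12}{'cv_adj_r2':>10}",
        ]
        for iso, r2 in zip(self.isoform_ids, self.cv_r2):
            lines.append(f"  {iso:<12}{r2:>10.4f}")
        lines.append("")
        if self.gene_stack_coefs is not None:
            lines.append(f"  stacked gene CV adj R2: {self.gene_stack_cv_r2:.4f}")
        if self.twas_weights is not None:
            lines.append(
                f"  TWAS baseline ({self.twas_method}) gene CV adj R2: {self.twas_cv_r2:.4f}"
            )
        return "\n".join(lines)


def filter_models(
    results: IsoformImputationResults, threshold: float = CV_R2_THRESHOLD
) -> IsoformImputationResults:
    """Functional alias for IsoformImputationResults.filter."""
    return results.filter(threshold)
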