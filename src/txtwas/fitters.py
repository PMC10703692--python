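"""SNP-effect estimators for multivariate isoform expression.

Five families estimate B_hat, the P x M matrix of SNP effects on the M
isoforms of one gene, from standardized genotypes X (N x P) and standardized
expression Y (N x M):

* ``mvenet``   -- multi-response elastic net whose L1 part is a group-lasso
                  penalty on the rows of B, so a SNP is either active for all
                  isoforms or for none (sklearn MultiTaskElasticNet).
* ``mrce``     -- multivariate lasso with covariance estimation: alternates an
                  L1-penalized weighted regression for B given the error
                  precision Omega with a graphical-lasso update of Omega on
                  the residuals.
* ``joinet``   -- stacked generalization: per-isoform elastic nets produce
                  out-of-fold predicted isoforms, a second elastic net layer
                  predicts each isoform from the predicted matrix; the two
                  linear maps collapse into one P x M coefficient matrix.
* ``spls``     -- sparse partial least squares: soft-thresholded dominant
                  singular directions of X'Y with deflation, regression of Y
                  on the latent scores.
* ``univariate`` -- per-isoform baseline: elastic net, ridge (the BLUP
                  family), and a sum-of-single-effects Bayesian regression
                  (SuSiE-style IBSS); the CV-best of the three is kept.

All fitters assume column-standardized inputs and fit without intercepts;
returned weights are on the standardized scale.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import (
    ElasticNet,
    ElasticNetCV,
    MultiTaskElasticNet,
    MultiTaskElasticNetCV,
    RidgeCV,
)
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "FitterConfig",
    "FitResult",
    "fit_mvenet",
    "fit_mrce",
    "fit_joinet",
    "fit_spls",
    "fit_univariate_best",
    "susie_ibss",
    "adjusted_r2",
    "FITTERS",
]


@dataclass(frozen=True)
class FitterConfig:
    """Hyperparameter grids and numerical knobs shared by all fitters."""

    n_lambda: int = 100
    mixing_grid: tuple[float, ...] = (0.01, 0.25, 0.5, 0.75, 1.0)
    mrce_lambda_b_fracs: tuple[float, ...] = (0.5, 0.2, 0.1, 0.05)
    mrce_lambda_omega_grid: tuple[float, ...] = (0.01, 0.1)
    mrce_tol: float = 1e-4
    mrce_max_iter: int = 100
    spls_k_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    spls_eta_grid: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    susie_l: int = 10
    ridge_grid: tuple[float, ...] = tuple(np.logspace(-2, 5, 30))
    # candidate set for the per-isoform univariate fitter; the gene-level
    # comparator always uses gene_univariate_candidates
    univariate_candidates: tuple[str, ...] = ("enet", "blup", "susie")
    gene_univariate_candidates: tuple[str, ...] = ("enet", "blup", "susie")
    inner_cv_folds: int = 5
    tol: float = 1e-4
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0) -> "FitterConfig":
        """Reduced grids for large simulation sweeps."""
        return cls(
            n_lambda=10,
            mixing_grid=(0.5,),
            mrce_lambda_b_fracs=(0.2, 0.05),
            mrce_lambda_omega_grid=(0.1,),
            spls_k_grid=(1, 2, 3),
            spls_eta_grid=(0.3, 0.7),
            susie_l=5,
            inner_cv_folds=3,
            tol=1e-3,
            seed=seed,
        )


@dataclass
class FitResult:
    """Estimated SNP-effect matrix with fitting metadata."""

    b_hat: np.ndarray  # (P, M)
    method: str
    hyperparameters: dict = field(default_factory=dict)
    precision_hat: np.ndarray | None = None  # (M, M), MRCE only
    converged: bool = True

    def __post_init__(self) -> None:
        self.b_hat = np.atleast_2d(np.asarray(self.b_hat, dtype=float))
        if not np.all(np.isfinite(self.b_hat)):
            raise ValueError("non-finite entries in fitted coefficients")
        if self.precision_hat is not None:
            O = self.precision_hat
            if not np.allclose(O, O.T, atol=1e-8):
                raise ValueError("precision matrix must be symmetric")
            if np.linalg.eigvalsh(O).min() <= 0:
                raise ValueError("precision matrix must be positive definite")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.b_hat


def adjusted_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation, adjusted as 1 - (1-R2)(N-1)/(N-2).

    Constant predictions score 0 (no predictive information).
    """
    n = len(observed)
    if np.std(predicted) == 0 or np.std(observed) == 0:
        return 0.0
    r2 = np.corrcoef(observed, predicted)[0, 1] ** 2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def _check_xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be row-aligned")
    return X, Y


# ---------------------------------------------------------------------------
# multivariate elastic net (group penalty on rows of B)
# ---------------------------------------------------------------------------

def fit_mvenet(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: FitterConfig | None = None,
    alpha: float | None = None,
    l1_ratio: float | None = None,
) -> FitResult:
    """Multi-response elastic net with an L2,1 row penalty.

    The mixed penalty keeps whole rows of B jointly zero or jointly active,
    i.e. a SNP has either a (generically) nonzero effect on every isoform or
    on none. Passing ``alpha``/``l1_ratio`` fixes the hyperparameters;
    ``alpha=0`` returns the ordinary least-squares solution.
    """
    cfg = cfg or FitterConfig()
    X, Y = _check_xy(X, Y)
    if alpha is not None and alpha == 0:
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("lambda=0 requires full-column-rank X (penalty required)")
        B = np.linalg.lstsq(X, Y, rcond=None)[0]
        return FitResult(b_hat=B, method="mvenet", hyperparameters={"alpha": 0.0})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if alpha is not None:
            est = MultiTaskElasticNet(
                alpha=alpha, l1_ratio=l1_ratio if l1_ratio is not None else 0.5,
                fit_intercept=False, max_iter=10000, tol=1e-10,
            ).fit(X, Y)
            hp = {"alpha": alpha, "l1_ratio": est.l1_ratio}
        else:
            grid = [max(r, 0.01) for r in cfg.mixing_grid]
            cv = KFold(cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
            est = MultiTaskElasticNetCV(
                l1_ratio=grid, alphas=cfg.n_lambda, cv=cv,
                fit_intercept=False, max_iter=2000, tol=cfg.tol,
            ).fit(X, Y)
            hp = {"alpha": float(est.alpha_), "l1_ratio": float(est.l1_ratio_)}
    return FitResult(b_hat=est.coef_.T, method="mvenet", hyperparameters=hp)


# ---------------------------------------------------------------------------
# MRCE: multivariate lasso with covariance estimation
# ---------------------------------------------------------------------------

def _soft(B: np.ndarray, t) -> np.ndarray:
    return np.sign(B) * np.maximum(np.abs(B) - t, 0.0)


def _mrce_b_step(
    S: np.ndarray,
    H: np.ndarray,
    Omega: np.ndarray,
    lam: float,
    n: int,
    B0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 3000,
) -> np.ndarray:
    """FISTA for (1/n) tr((Y-XB) Omega (Y-XB)') + lam * ||B||_1.

    S = X'X, H = X'Y. The smooth gradient is (2/n)(S B - H) Omega and the
    Lipschitz constant (2/n) ||S||_2 ||Omega||_2; with Omega = I the optimum
    coincides column-wise with a lasso at penalty lam.
    """
    Ls = np.linalg.eigvalsh(S)[-1] * np.linalg.eigvalsh(Omega)[-1] * 2.0 / n
    step = 1.0 / Ls
    B = B0.copy()
    Z = B.copy()
    t_k = 1.0
    for _ in range(max_iter):
        grad = (2.0 / n) * (S @ Z - H) @ Omega
        B_new = _soft(Z - step * grad, step * lam)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_k**2))
        Z = B_new + ((t_k - 1.0) / t_new) * (B_new - B)
        delta = np.max(np.abs(B_new - B))
        B, t_k = B_new, t_new
        if delta < tol:
            break
    return B


def fit_mrce(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: FitterConfig | None = None,
    lambda_b: float | None = None,
    lambda_omega: float | None = None,
    max_outer: int | None = None,
) -> FitResult:
    """Joint estimation of SNP effects and the error precision matrix.

    Alternates (i) an L1-penalized regression for B under the working
    precision Omega and (ii) graphical-lasso estimation of Omega on the
    residual covariance, until the max-abs change in B drops below
    ``cfg.mrce_tol``. Non-convergence is flagged, not raised. Hyperparameters
    are chosen by inner CV on prediction R2 unless given explicitly.
    """
    cfg = cfg or FitterConfig()
    X, Y = _check_xy(X, Y)
    n, P = X.shape
    M = Y.shape[1]
    S = X.T @ X
    H = X.T @ Y
    lam_max = 2.0 * np.abs(H).max() / n

    def _run(lb: float, lo: float, Xf, Yf) -> tuple[np.ndarray, np.ndarray, bool]:
        Sf, Hf = Xf.T @ Xf, Xf.T @ Yf
        Omega = np.eye(M)
        B = np.zeros((P, M))
        converged = False
        n_outer = max_outer if max_outer is not None else cfg.mrce_max_iter
        for _ in range(n_outer):
            B_new = _mrce_b_step(Sf, Hf, Omega, lb, Xf.shape[0], B)
            if M > 1:
                R = Yf - Xf @ B_new
                Sr = R.T @ R / Xf.shape[0]
                Sr = Sr + 1e-6 * np.eye(M)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        _, Omega = graphical_lasso(Sr, alpha=lo, max_iter=200)
                except FloatingPointError:  # pragma: no cover - rare numerical failure
                    Omega = np.linalg.inv(Sr)
            delta = np.max(np.abs(B_new - B))
            B = B_new
            if delta < cfg.mrce_tol:
                converged = True
                break
        return B, Omega, converged

    if lambda_b is None and (
        len(cfg.mrce_lambda_b_fracs) * len(cfg.mrce_lambda_omega_grid) == 1
    ):
        lambda_b = cfg.mrce_lambda_b_fracs[0] * lam_max
        lambda_omega = cfg.mrce_lambda_omega_grid[0]
    if lambda_b is None:
        # inner CV over the small (lambda_b, lambda_omega) grid
        cv = KFold(cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
        best, best_score = None, -np.inf
        for fb in cfg.mrce_lambda_b_fracs:
            for lo in cfg.mrce_lambda_omega_grid:
                lb = fb * lam_max
                score = 0.0
                for tr, te in cv.split(X):
                    Bf, _, _ = _run(lb, lo, X[tr], Y[tr])
                    pred = X[te] @ Bf
                    resid = Y[te] - pred
                    score -= float(np.sum(resid**2))
                if score > best_score:
                    best, best_score = (lb, lo), score
        lambda_b, lambda_omega = best
    if lambda_omega is None:
        lambda_omega = cfg.mrce_lambda_omega_grid[0]

    B, Omega, converged = _run(lambda_b, lambda_omega, X, Y)
    if not converged:
        logger.warning("MRCE did not converge (lambda_b=%.4g)", lambda_b)
    Omega = 0.5 * (Omega + Omega.T)
    return FitResult(
        b_hat=B,
        method="mrce",
        hyperparameters={"lambda_b": float(lambda_b), "lambda_omega": float(lambda_omega)},
        precision_hat=Omega if M > 1 else None,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# joinet: stacked elastic nets
# ---------------------------------------------------------------------------

def _enet_cv(X, y, cfg: FitterConfig) -> ElasticNetCV:
    grid = [max(r, 0.01) for r in cfg.mixing_grid]
    cv = KFold(cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return ElasticNetCV(
            l1_ratio=grid, alphas=cfg.n_lambda, cv=cv, fit_intercept=False,
            max_iter=2000, tol=cfg.tol,
        ).fit(X, y)


def fit_joinet(X: np.ndarray, Y: np.ndarray, cfg: FitterConfig | None = None) -> FitResult:
    """Two-stage stacked prediction.

    Stage 1 fits a per-isoform elastic net and assembles out-of-fold
    predictions Y_hat; stage 2 regresses each isoform on Y_hat with another
    elastic net, borrowing strength across correlated isoforms. The composite
    map is returned as a single coefficient matrix B1 @ C2.
    """
    cfg = cfg or FitterConfig()
    if cfg.inner_cv_folds < 2:
        raise ValueError("joinet requires inner_cv_folds >= 2")
    X, Y = _check_xy(X, Y)
    n, P = X.shape
    M = Y.shape[1]
    folds = KFold(cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
    B1 = np.zeros((P, M))
    Yhat = np.zeros((n, M))
    hp: dict = {"stage1": [], "stage2": []}
    split = list(folds.split(X))
    for m in range(M):
        est = _enet_cv(X, Y[:, m], cfg)
        B1[:, m] = est.coef_
        hp["stage1"].append({"alpha": float(est.alpha_), "l1_ratio": float(est.l1_ratio_)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for tr, te in split:
                fold_est = ElasticNet(
                    alpha=est.alpha_, l1_ratio=est.l1_ratio_,
                    fit_intercept=False, max_iter=2000,
                ).fit(X[tr], Y[tr, m])
                Yhat[te, m] = fold_est.predict(X[te])
    usable = Yhat.std(axis=0) > 0
    if not usable.any():
        logger.warning("joinet: no stage-1 column has out-of-fold variance; returning stage 1")
        return FitResult(b_hat=B1, method="joinet", hyperparameters=hp)
    if not usable.all():
        logger.warning(
            "joinet: %d stage-1 column(s) had zero out-of-fold variance; excluded",
            int((~usable).sum()),
        )
    C2 = np.zeros((M, M))
    for m in range(M):
        est2 = _enet_cv(Yhat[:, usable], Y[:, m], cfg)
        C2[usable, m] = est2.coef_
        hp["stage2"].append({"alpha": float(est2.alpha_), "l1_ratio": float(est2.l1_ratio_)})
    return FitResult(b_hat=B1 @ C2, method="joinet", hyperparameters=hp)


# ---------------------------------------------------------------------------
# sparse partial least squares
# ---------------------------------------------------------------------------

def _spls_direction(X: np.ndarray, R: np.ndarray, eta: float) -> np.ndarray:
    """Soft-thresholded dominant left singular direction of X'R."""
    u = np.linalg.svd(X.T @ R, full_matrices=False)[0][:, 0]
    if eta > 0:
        u = _soft(u, eta * np.abs(u).max())
    norm = np.linalg.norm(u)
    return u / norm if norm > 0 else u


def _pls_coef(X: np.ndarray, Y: np.ndarray, K: int) -> np.ndarray:
    """Dense PLS2 regression coefficients (NIPALS with X deflation)."""
    n, P = X.shape
    Xd = X.copy()
    W = np.zeros((P, K))
    T = np.zeros((n, K))
    k_eff = 0
    for k in range(K):
        Z = Xd.T @ Y
        u = np.linalg.svd(Z, full_matrices=False)[0][:, 0]
        t = Xd @ u
        tt = t @ t
        if tt <= 1e-12:
            break
        W[:, k], T[:, k] = u, t
        Xd = Xd - np.outer(t, t @ Xd) / tt
        k_eff += 1
    if k_eff == 0:
        return np.zeros((P, Y.shape[1]))
    # regress on scores from the original X so the coefficient map is linear in X
    C, *_ = np.linalg.lstsq(X @ W[:, :k_eff], Y, rcond=None)
    return W[:, :k_eff] @ C


def _spls_coef(X: np.ndarray, Y: np.ndarray, K: int, eta: float) -> np.ndarray:
    """Sparse PLS coefficients: grow an active predictor set from
    soft-thresholded directions of the residual cross-covariance, then fit
    dense PLS with k components restricted to the active set."""
    P, M = X.shape[1], Y.shape[1]
    active: np.ndarray = np.zeros(P, dtype=bool)
    B = np.zeros((P, M))
    R = Y
    for k in range(1, K + 1):
        w = _spls_direction(X, R, eta)
        if not np.any(w):
            logger.warning("spls: all-zero direction at component %d; truncating K", k)
            break
        active |= w != 0
        idx = np.flatnonzero(active)
        B = np.zeros((P, M))
        B[idx] = _pls_coef(X[:, idx], Y, min(k, idx.size))
        R = Y - X @ B
    return B


def fit_spls(X: np.ndarray, Y: np.ndarray, cfg: FitterConfig | None = None) -> FitResult:
    """Sparse PLS: latent directions maximizing covariance with Y under an
    eta-controlled soft-threshold, then regression of Y on the scores.
    (K, eta) are chosen by inner CV on prediction error."""
    cfg = cfg or FitterConfig()
    X, Y = _check_xy(X, Y)
    n, P = X.shape
    k_grid = [k for k in cfg.spls_k_grid if 1 <= k <= min(P, n - 1)]
    if not k_grid:
        raise ValueError("spls_k_grid has no feasible component count")
    cv = KFold(cfg.inner_cv_folds, shuffle=True, random_state=cfg.seed)
    split = list(cv.split(X))
    best, best_err = None, np.inf
    for K in k_grid:
        for eta in cfg.spls_eta_grid:
            err = 0.0
            for tr, te in split:
                B = _spls_coef(X[tr], Y[tr], K, eta)
                err += float(np.sum((Y[te] - X[te] @ B) ** 2))
            if err < best_err:
                best, best_err = (K, eta), err
    K, eta = best
    B = _spls_coef(X, Y, K, eta)
    return FitResult(b_hat=B, method="spls", hyperparameters={"K": K, "eta": eta})


# ---------------------------------------------------------------------------
# SuSiE-style sum of single effects (individual-level IBSS)
# ---------------------------------------------------------------------------

def susie_ibss(
    X: np.ndarray,
    y: np.ndarray,
    L: int = 10,
    prior_variance: float = 0.2,
    tol: float = 1e-4,
    max_iter: int = 200,
):
    """Iterative Bayesian sum-of-single-effects regression.

    Fits y = X (sum_l b_l) + e where each b_l has exactly one nonzero entry
    a priori. Returns (posterior-mean weight vector, L x P inclusion-
    probability matrix alpha, info dict with the ELBO trace). The scaled
    prior variance (prior_variance * var(y)) is held fixed; the residual
    variance is re-estimated each sweep. Stops when the ELBO improves by
    less than ``tol``; a decreasing ELBO stops early and is flagged.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, P = X.shape
    d = np.einsum("ij,ij->j", X, X)  # x_j'x_j
    var_y = y.var()
    sigma0_2 = prior_variance * var_y if var_y > 0 else prior_variance
    sigma2 = var_y if var_y > 0 else 1.0
    log_prior = -math.log(P)

    alpha = np.full((L, P), 1.0 / P)
    mu = np.zeros((L, P))
    mu2 = np.zeros((L, P))
    Xb_l = np.zeros((L, n))  # fitted values per effect
    elbo_trace: list[float] = []
    flagged = False

    for _ in range(max_iter):
        kl_sum = 0.0
        for l in range(L):
            r_l = y - (Xb_l.sum(axis=0) - Xb_l[l])
            bhat = (X.T @ r_l) / d
            s2 = sigma2 / d
            post_var = 1.0 / (1.0 / sigma0_2 + 1.0 / s2)
            logbf = 0.5 * np.log(s2 / (s2 + sigma0_2)) + 0.5 * bhat**2 / s2 * (
                sigma0_2 / (s2 + sigma0_2)
            )
            logw = log_prior + logbf
            logbf_model = logsumexp(logw)
            a = np.exp(logw - logbf_model)
            m = (sigma0_2 / (sigma0_2 + s2)) * bhat  # = post_var * bhat / s2
            alpha[l], mu[l] = a, m
            mu2[l] = post_var + m**2
            Xb_l[l] = X @ (a * m)
            # KL via the single-effect-regression likelihood identity
            loglik_null = -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * (
                r_l @ r_l
            ) / sigma2
            loglik_ser = logbf_model + loglik_null
            e_ss = r_l @ r_l - 2 * r_l @ Xb_l[l] + float(d @ (a * mu2[l]))
            e_neg_loglik = 0.5 * n * math.log(2 * math.pi * sigma2) + 0.5 * e_ss / sigma2
            kl_sum += -loglik_ser - e_neg_loglik

        fitted = Xb_l.sum(axis=0)
        resid = y - fitted
        erss = float(resid @ resid)
        for l in range(L):
            erss += float(d @ (alpha[l] * mu2[l])) - float(Xb_l[l] @ Xb_l[l])
        elbo = (
            -0.5 * n * math.log(2 * math.pi * sigma2) - 0.5 * erss / sigma2 - kl_sum
        )
        if elbo_trace:
            change = elbo - elbo_trace[-1]
            if change < -tol:
                logger.warning("susie: ELBO decreased by %.3g; stopping", -change)
                flagged = True
                elbo_trace.append(elbo)
                break
            if abs(change) < tol:
                elbo_trace.append(elbo)
                break
        elbo_trace.append(elbo)
        sigma2 = max(erss / n, 1e-10)

    weights = (alpha * mu).sum(axis=0)
    info = {"elbo": elbo_trace, "sigma2": sigma2, "flagged": flagged}
    return weights, alpha, info


# ---------------------------------------------------------------------------
# univariate baseline: best of elastic net / ridge-BLUP / SuSiE
# ---------------------------------------------------------------------------

def _univariate_candidates(cfg: FitterConfig):
    """(name, fit(X, y) -> weight vector) for the three univariate fitters."""

    def enet(X, y):
        return _enet_cv(X, y, cfg).coef_

    def blup(X, y):
        # BLUP in a linear mixed model is ridge with penalty sigma_e2/sigma_g2;
        # the penalty is chosen by efficient leave-one-out CV over a log grid.
        est = RidgeCV(alphas=cfg.ridge_grid, fit_intercept=False).fit(X, y)
        return est.coef_

    def susie(X, y):
        w, _, _ = susie_ibss(X, y, L=cfg.susie_l)
        return w

    table = {"enet": enet, "blup": blup, "susie": susie}
    return [(name, table[name]) for name in cfg.univariate_candidates]


def fit_univariate_best(
    X: np.ndarray,
    y: np.ndarray,
    cfg: FitterConfig | None = None,
    fold_ids: np.ndarray | None = None,
):
    """Fit elastic net, ridge-BLUP and SuSiE; keep the CV-best.

    Each candidate is refit within every fold (its internal hyperparameter
    search included) so the CV adjusted R2 is leakage-free. Returns
    (weights, method label, cv adjusted R2, flag). A model whose CV R2 is
    non-finite for all candidates yields a zero vector flagged untrainable.
    """
    cfg = cfg or FitterConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    candidates = _univariate_candidates(cfg)
    if len(candidates) == 1:
        # nothing to select between; skip the scoring pass
        name, fit = candidates[0]
        try:
            w = fit(X, y)
        except Exception:  # noqa: BLE001
            return np.zeros(X.shape[1]), "untrainable", np.nan, True
        return w, name, np.nan, False
    if fold_ids is None:
        fold_ids = make_fold_ids(n, cfg.inner_cv_folds, cfg.seed)
    scores: dict[str, float] = {}
    for name, fit in _univariate_candidates(cfg):
        pred = np.zeros(n)
        ok = True
        for k in np.unique(fold_ids):
            tr, te = fold_ids != k, fold_ids == k
            try:
                w = fit(X[tr], y[tr])
            except Exception:  # noqa: BLE001 - candidate failure is data-dependent
                ok = False
                break
            pred[te] = X[te] @ w
        scores[name] = adjusted_r2(y, pred) if ok and np.isfinite(pred).all() else np.nan
    finite = {k: v for k, v in scores.items() if np.isfinite(v)}
    if not finite:
        return np.zeros(X.shape[1]), "untrainable", np.nan, True
    best = max(finite, key=finite.get)
    fit = dict(_univariate_candidates(cfg))[best]
    return fit(X, y), best, float(finite[best]), False


def make_fold_ids(n: int, k: int, seed: int) -> np.ndarray:
    """Deterministic shuffled fold assignment shared across fitters."""
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    ids = np.zeros(n, dtype=int)
    for fold, (_, te) in enumerate(
        KFold(k, shuffle=True, random_state=seed).split(np.arange(n))
    ):
        ids[te] = fold
    return ids


def _fit_univariate_matrix(X, Y, cfg: FitterConfig) -> FitResult:
    """Per-isoform best-univariate fits assembled into a P x M matrix."""
    X, Y = _check_xy(X, Y)
    B = np.zeros((X.shape[1], Y.shape[1]))
    labels = []
    for m in range(Y.shape[1]):
        w, label, _, _ = fit_univariate_best(X, Y[:, m], cfg)
        B[:, m] = w
        labels.append(label)
    return FitResult(b_hat=B, method="univariate", hyperparameters={"per_isoform": labels})


FITTERS = {
    "mvenet": fit_mvenet,
    "mrce": fit_mrce,
    "joinet": fit_joinet,
    "spls": fit_spls,
    "univariate": _fit_univariate_matrix,
}

#: fixed precedence for breaking CV ties reproducibly
METHOD_PRECEDENCE = ["mvenet", "mrce", "joinet", "spls", "univariate"]
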