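"""Bayesian fine-mapping of correlated isoform-trait associations.

Within a risk region, the burden z-scores of the significant isoforms are
correlated because their predicted expressions share SNPs and LD. Following
the probabilistic TWAS fine-mapping model, each causal configuration c (a
subset of isoforms, |c| <= max_causal, the empty/null set included) gets a
Bayes factor from the multivariate-normal marginal likelihood

    z | c ~ N(0, S + prior_var * S[:, c] S[c, :]),   S = predicted-expression
                                                          correlation matrix,

with an independent prior inclusion probability per isoform. Posterior
inclusion probabilities (PIPs) are the posterior mass of configurations
containing each isoform; the rho-credible set is the smallest PIP-descending
prefix reaching rho of the normalized mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "predicted_expression_correlation",
    "focus_finemap",
    "credible_set",
    "build_risk_regions",
    "FocusFineMapper",
    "FineMapResults",
    "CredibleSet",
]

_EIG_FLOOR = 1e-8
_RIDGE = 1e-4


def predicted_expression_correlation(
    weight_vectors: np.ndarray, V: LDMatrix | np.ndarray
) -> np.ndarray:
    """LD-induced correlation of imputed expression across t features.

    corr(i, j) = w_i' V w_j / sqrt(w_i' V w_i * w_j' V w_j). Raises on a
    degenerate (zero-variance) weight vector; callers should exclude those
    features first.
    """
    W = np.atleast_2d(np.asarray(weight_vectors, dtype=float))  # (t, P)
    Vm = V.V if isinstance(V, LDMatrix) else np.asarray(V, dtype=float)
    G = W @ Vm @ W.T
    d = np.sqrt(np.diag(G))
    if np.any(d <= 0):
        raise ValueError("degenerate weight vector (zero predicted-expression variance)")
    C = G / np.outer(d, d)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def _logpdf_mvn_zero_mean(z: np.ndarray, cov: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite")
    t = len(z)
    sol = np.linalg.solve(cov, z)
    return -0.5 * (t * np.log(2 * np.pi) + logdet + float(z @ sol))


def focus_finemap(
    z_iso: np.ndarray,
    corr: np.ndarray,
    prior_prob: float = 1e-3,
    prior_var: float = 40.0,
    max_causal: int = 3,
    rho: float = 0.9,
    ids: list[str] | None = None,
):
    """Enumerate causal configurations and return PIPs plus a credible set.

    prior_var is the prior variance of a causal feature's non-centrality on
    the z-score scale (the n * sigma^2 term of the underlying model);
    prior_prob the independent prior inclusion probability per feature. The
    null configuration competes in the posterior. Exhaustive over all
    subsets of size <= max_causal.
    """
    z = np.asarray(z_iso, dtype=float).ravel()
    S = np.asarray(corr, dtype=float)
    t = z.size
    if t < 1:
        raise ValueError("need at least one feature")
    if ids is None:
        ids = [f"feature{i + 1}" for i in range(t)]
    w_eig = np.linalg.eigvalsh(S)
    if w_eig.min() < _EIG_FLOOR:
        S = S + _RIDGE * np.eye(t)
        if np.linalg.eigvalsh(S).min() < _EIG_FLOOR:
            raise np.linalg.LinAlgError(
                f"correlation matrix not PSD after ridge (min eig {w_eig.min():.3g})"
            )
    max_causal = min(max_causal, t)
    log_null = _logpdf_mvn_zero_mean(z, S)
    lp, lq = np.log(prior_prob), np.log1p(-prior_prob)

    configs: list[tuple[tuple[int, ...], float]] = [((), t * lq)]  # (members, log prior + logBF)
    for k in range(1, max_causal + 1):
        for c in combinations(range(t), k):
            cov = S + prior_var * S[:, c] @ S[c, :]
            logbf = _logpdf_mvn_zero_mean(z, cov) - log_null
            logprior = k * lp + (t - k) * lq
            configs.append((c, logprior + logbf))
    logw = np.array([w for _, w in configs])
    post = np.exp(logw - logw.max())
    post /= post.sum()
    pips = np.zeros(t)
    for (c, _), pr in zip(configs, post):
        for i in c:
            pips[i] += pr
    cs = credible_set(pips, rho=rho, ids=ids)
    return pips, cs, {"posterior": post, "configs": [c for c, _ in configs]}


@dataclass
class CredibleSet:
    """Minimal feature set capturing >= rho of the normalized PIP mass."""

    members: list[str]
    pips: np.ndarray
    rho: float = 0.9
    region: str = ""

    def __len__(self) -> int:
        return len(self.members)


def credible_set(pips, rho: float = 0.9, ids: list[str] | None = None) -> CredibleSet:
    """Smallest PIP-descending prefix with normalized cumulative mass >= rho.

    Ties are broken by feature id for determinism; an all-zero PIP vector
    returns the full set with a warning.
    """
    p = np.asarray(pips, dtype=float)
    if np.any(p < 0):
        raise ValueError("PIPs must be non-negative")
    t = p.size
    if ids is None:
        ids = [f"feature{i + 1}" for i in range(t)]
    if p.sum() == 0:
        logger.warning("all-zero PIPs: credible set defaults to the full feature set")
        return CredibleSet(members=list(ids), pips=p, rho=rho)
    order = sorted(range(t), key=lambda i: (-p[i], ids[i]))
    norm = p / p.sum()
    members, acc = [], 0.0
    for i in order:
        members.append(i)
        acc += norm[i]
        if acc >= rho - 1e-12:
            break
    return CredibleSet(
        members=[ids[i] for i in members], pips=p[members], rho=rho
    )


def build_risk_regions(positions: dict[str, float], window: float = 1e6) -> list[set[str]]:
    """Merge significant features within `window` of one another into risk
    regions (transitive single-linkage on genomic position)."""
    items = sorted(positions.items(), key=lambda kv: kv[1])
    regions: list[set[str]] = []
    last_pos = None
    for name, pos in items:
        if last_pos is not None and pos - last_pos <= window:
            regions[-1].add(name)
        else:
            regions.append({name})
        last_pos = pos
    return regions


class FocusFineMapper:
    """Model-style wrapper: fine-map one region's isoform z-scores.

    Parameters
    ----------
    z : t-vector of burden z-scores for the significant isoforms
    corr : t x t predicted-expression correlation (from
        `predicted_expression_correlation`), or weight vectors + LD.
    """

    def __init__(self, z, corr=None, weights=None, ld: LDMatrix | None = None, ids=None):
        self.z = np.asarray(z, dtype=float).ravel()
        if corr is None:
            if weights is None or ld is None:
                raise ValueError("provide either corr or (weights, ld)")
            corr = predicted_expression_correlation(weights, ld)
        self.corr = np.asarray(corr, dtype=float)
        self.ids = list(ids) if ids is not None else [f"iso{i+1}" for i in range(self.z.size)]

    def fit(
        self,
        prior_prob: float = 1e-3,
        prior_var: float = 40.0,
        max_causal: int = 3,
        rho: float = 0.9,
    ) -> "FineMapResults":
        pips, cs, extra = focus_finemap(
            self.z, self.corr, prior_prob=prior_prob, prior_var=prior_var,
            max_causal=max_causal, rho=rho, ids=self.ids,
        )
        return FineMapResults(
            ids=self.ids, pips=pips, credible=cs,
            posterior=extra["posterior"], configs=extra["configs"],
        )


@dataclass
class FineMapResults:
    ids: list[str]
    pips: np.ndarray
    credible: CredibleSet
    posterior: np.ndarray = field(repr=False, default=None)
    configs: list = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.ids, "pip": self.pips,
             "in_credible_set": [i in set(self.credible.members) for i in self.ids]}
        )

    def summary(self) -> str:
        lines = [f"Fine-mapping over {len(self.ids)} features (rho={self.credible.rho})"]
        for fid, pip in sorted(zip(self.ids, self.pips), key=lambda kv: -kv[1]):
            star = "*" if fid in set(self.credible.members) else " "
            lines.append(f"  {star} {fid:<12} PIP={pip:.4f}")
        return "\n".join(lines)
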