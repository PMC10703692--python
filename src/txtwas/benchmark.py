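"""Simulation benchmarks: prediction, null calibration, power, fine-mapping.

Each driver runs the full pipeline end to end on simulated loci -- simulate
genotypes/expression, train weight models, build GWAS summary statistics,
test -- and returns tidy DataFrames. Replication counts are arguments so the
same code serves quick smoke runs and full studies.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .association import acat, burden_test
from .fitters import FitterConfig, adjusted_r2
from .finemap import focus_finemap, predicted_expression_correlation
from .model import CV_R2_THRESHOLD, IsoformImputationModel
from .simulate import SimConfig, TraitConfig, simulate_locus, simulate_trait, usage_for_scenario

logger = logging.getLogger(__name__)

__all__ = [
    "benchmark_prediction",
    "benchmark_null_fpr",
    "benchmark_power",
    "benchmark_finemap",
    "run_benchmark",
]

GWS_THRESHOLD = 2.5e-6  # transcriptome-wide significance used in power curves


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible child seeds below 2**31."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _locus_config(base: SimConfig, seed: int, rng: np.random.Generator) -> SimConfig:
    """Per-replicate locus config: fresh seed and isoform count in 2-10."""
    m = int(rng.integers(2, 11))
    return replace(base, seed=int(seed), m_isoforms=m)


def benchmark_prediction(
    base: SimConfig,
    n_loci: int = 50,
    seed: int = 0,
    methods: tuple[str, ...] = ("mvenet",),
    fitter_cfg: FitterConfig | None = None,
    vary_isoforms: bool = True,
) -> pd.DataFrame:
    """Gene-level prediction gain of stacked isoform models over the TWAS
    baseline, one row per simulated locus.

    Columns include the per-isoform mean CV adjusted R2 of the selected
    multivariate model, the stacked gene CV adjusted R2, the TWAS gene CV
    adjusted R2, and their difference in percentage points.
    """
    seeds = _spawn_seeds(seed, n_loci)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, s in enumerate(seeds):
        cfg_i = _locus_config(base, s, rng) if vary_isoforms else replace(base, seed=int(s))
        fc = fitter_cfg or FitterConfig.fast(seed=int(s) % (2**31 - 1))
        locus = simulate_locus(cfg_i)
        res = IsoformImputationModel.from_locus(locus, gene=f"gene{i+1}").fit(
            methods=list(methods), cfg=fc
        )
        # gene-level prediction by aggregation: usage-weighted sum of the
        # out-of-fold predicted isoforms (the gene is the sum of its
        # isoforms, so this is the model-free aggregate)
        summed = res.oof_predictions @ locus.usage
        sum_r2 = adjusted_r2(locus.gene_expression, summed)
        rows.append(
            {
                "locus": i,
                "seed": int(s),
                "m_isoforms": cfg_i.m_isoforms,
                "p_causal": cfg_i.p_causal,
                "p_shared": cfg_i.p_shared,
                "sigma_h": cfg_i.sigma_h,
                "method": res.method,
                "mean_iso_cv_r2": float(np.mean(res.cv_r2)),
                "sum_gene_cv_r2": float(sum_r2),
                "stacked_gene_cv_r2": res.gene_stack_cv_r2,
                "twas_gene_cv_r2": res.twas_cv_r2,
                "gain_sum_pp": 100.0 * (sum_r2 - res.twas_cv_r2),
                "gain_pp": 100.0 * (res.gene_stack_cv_r2 - res.twas_cv_r2),
            }
        )
    return pd.DataFrame(rows)


def benchmark_null_fpr(
    base: SimConfig,
    n_loci: int = 20,
    panels_per_locus: int = 250,
    n_gwas: int = 5_000,
    seed: int = 0,
    fitter_cfg: FitterConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-level ACAT false positive rate under a null GWAS.

    Trains weight models on `n_loci` simulated eQTL panels (isoforms passing
    the CV R2 > 0.01 filter), then tests each trained gene against
    `panels_per_locus` independent GWAS panels whose trait has no genetic
    effect. Returns one row per (locus, panel) with the gene ACAT p-value.
    """
    seeds = _spawn_seeds(seed, n_loci)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for i, s in enumerate(seeds):
        cfg_i = _locus_config(base, s, rng)
        fc = fitter_cfg or FitterConfig.fast(seed=int(s) % (2**31 - 1))
        locus = simulate_locus(cfg_i)
        res = IsoformImputationModel.from_locus(locus, gene=f"gene{i+1}").fit(
            methods=["mvenet"], cfg=fc, stack=False, twas_baseline=False
        ).filter(CV_R2_THRESHOLD)
        if not res.is_testable:
            logger.info("locus %d: no isoform passes the CV filter; skipped", i)
            continue
        V = locus.genotypes.ld()
        panel_seeds = _spawn_seeds(int(s) + 7, panels_per_locus)
        for j, ps in enumerate(panel_seeds):
            tcfg = TraitConfig(scenario="null", seed=int(ps))
            _, gwas = simulate_trait(locus, tcfg, n_gwas=n_gwas)
            pvals = []
            for m in range(res.b_hat.shape[1]):
                _, p = burden_test(res.b_hat[:, m], gwas.z, V)
                if np.isfinite(p):
                    pvals.append(p)
            if pvals:
                rows.append({"locus": i, "panel": j, "acat_p": acat(pvals)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df.attrs["fpr"] = float((df["acat_p"] < alpha).mean())
    return df


def _train_pair(locus, seed: int, fitter_cfg: FitterConfig | None):
    """Multivariate isoform weights + univariate TWAS gene weights."""
    fc = fitter_cfg or FitterConfig.fast(seed=seed)
    res = IsoformImputationModel.from_locus(locus).fit(
        methods=["mvenet"], cfg=fc, stack=False, twas_baseline=True
    )
    return res.filter(CV_R2_THRESHOLD), res.twas_weights


def benchmark_power(
    base: SimConfig,
    tconfig: TraitConfig,
    reps: int = 50,
    seed: int = 0,
    n_gwas: int | None = None,
    fitter_cfg: FitterConfig | None = None,
    threshold: float = GWS_THRESHOLD,
) -> pd.DataFrame:
    """Power of the gene-level ACAT test vs the gene-level TWAS burden test
    under one causal scenario, at the transcriptome-wide threshold.

    One row per replicate with the two gene-level p-values; the empirical
    powers are stored in DataFrame.attrs.
    """
    seeds = _spawn_seeds(seed, reps)
    rows = []
    for i, s in enumerate(seeds):
        cfg_i = replace(base, seed=int(s))
        usage = usage_for_scenario(tconfig, cfg_i.m_isoforms)
        locus = simulate_locus(cfg_i, usage=usage)
        iso_res, twas_w = _train_pair(locus, int(s) % (2**31 - 1), fitter_cfg)
        tcfg_i = replace(tconfig, seed=int(s))
        _, gwas = simulate_trait(locus, tcfg_i, n_gwas=n_gwas)
        V = locus.genotypes.ld()
        iso_p = np.nan
        if iso_res.is_testable:
            pvals = []
            for m in range(iso_res.b_hat.shape[1]):
                _, p = burden_test(iso_res.b_hat[:, m], gwas.z, V)
                if np.isfinite(p):
                    pvals.append(p)
            if pvals:
                iso_p = acat(pvals)
        twas_p = np.nan
        if twas_w is not None and np.any(twas_w):
            _, twas_p = burden_test(twas_w, gwas.z, V)
        rows.append({"rep": i, "iso_acat_p": iso_p, "twas_p": twas_p})
    df = pd.DataFrame(rows)
    iso = df["iso_acat_p"].to_numpy()
    twa = df["twas_p"].to_numpy()
    df.attrs["iso_power"] = float(np.mean(np.where(np.isfinite(iso), iso < threshold, False)))
    df.attrs["twas_power"] = float(np.mean(np.where(np.isfinite(twa), twa < threshold, False)))
    return df


def benchmark_finemap(
    base: SimConfig,
    reps: int = 25,
    seed: int = 0,
    h_t2: float = 0.05,
    n_gwas: int | None = None,
    prior_var: float = 40.0,
    rho: float = 0.9,
    fitter_cfg: FitterConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity and size of rho-credible sets under one effect isoform.

    End-to-end per replicate: simulate, train, associate, fine-map all
    trained isoforms of the gene; report whether the credible set contains
    the true effect isoform (iso1) and its size. Untrainable replicates are
    excluded but counted in DataFrame.attrs["n_untrainable"].
    """
    if base.m_isoforms < 2:
        raise ValueError("fine-mapping benchmark needs >= 2 isoforms")
    tconfig = TraitConfig(scenario="one_isoform", h_t2=h_t2, p_g=0.5)
    seeds = _spawn_seeds(seed, reps)
    rows, n_untrainable = [], 0
    for i, s in enumerate(seeds):
        cfg_i = replace(base, seed=int(s))
        usage = usage_for_scenario(tconfig, cfg_i.m_isoforms)
        locus = simulate_locus(cfg_i, usage=usage)
        iso_res, _ = _train_pair(locus, int(s) % (2**31 - 1), fitter_cfg)
        if not iso_res.is_testable or "iso1" not in iso_res.isoform_ids:
            n_untrainable += 1
            continue
        tcfg_i = replace(tconfig, seed=int(s))
        _, gwas = simulate_trait(locus, tcfg_i, n_gwas=n_gwas)
        V = locus.genotypes.ld()
        z_iso, keep = [], []
        for m in range(iso_res.b_hat.shape[1]):
            Z, _ = burden_test(iso_res.b_hat[:, m], gwas.z, V)
            if np.isfinite(Z):
                z_iso.append(Z)
                keep.append(m)
        if not keep or iso_res.isoform_ids.index("iso1") not in keep:
            n_untrainable += 1
            continue
        W = iso_res.b_hat[:, keep].T
        corr = predicted_expression_correlation(W, V)
        ids = [iso_res.isoform_ids[m] for m in keep]
        _, cs, _ = focus_finemap(
            np.array(z_iso), corr, prior_var=prior_var, rho=rho, ids=ids,
            max_causal=min(3, len(ids)),
        )
        rows.append(
            {
                "rep": i,
                "n_isoforms_mapped": len(ids),
                "set_size": len(cs),
                "contains_effect": "iso1" in set(cs.members),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_untrainable"] = n_untrainable
    if not df.empty:
        df.attrs["sensitivity"] = float(df["contains_effect"].mean())
        df.attrs["mean_set_size"] = float(df["set_size"].mean())
    return df


def run_benchmark(config: dict, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Dispatch a benchmark suite from a config mapping.

    Recognized sections: prediction, null_fpr, power, finemap; each maps to
    keyword arguments of the corresponding driver, with a nested `sim`
    mapping for SimConfig fields and `trait` for TraitConfig fields.
    """
    out: dict[str, pd.DataFrame] = {}
    for section, fn in [
        ("prediction", benchmark_prediction),
        ("null_fpr", benchmark_null_fpr),
        ("power", benchmark_power),
        ("finemap", benchmark_finemap),
    ]:
        if section not in config:
            continue
        kw = dict(config[section])
        sim = SimConfig(**kw.pop("sim", {}))
        args = [sim]
        if section == "power":
            args.append(TraitConfig(**kw.pop("trait", {})))
        kw.setdefault("seed", seed)
        out[section] = fn(*args, **kw)
    return out
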