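"""Ecoregion-stratified selection mapping and its meta-analysis.

The generation-proxy scan is run independently within every ecoregion with
enough samples (its own GRM per region), then per-SNP effects are combined by
inverse-variance fixed-effects meta-analysis.  Region-specific selection shows
up as effect-size heterogeneity: Cochran's Q (chi-square, k-1 df) flags it,
and a binary-effects posterior (the m-value) says in which regions the SNP
actually has an effect.  Loci passing the conjunction filter -- significant
heterogeneity AND a significant within-region scan -- are finally classified
as converging to or diverging from the pooled allele-frequency trajectory.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .gpsm import allele_frequency_trajectory, clump_loci, run_gpsm
from .io_formats import GenotypeMatrix
from .lmm_core import ScanConfig

logger = logging.getLogger(__name__)

__all__ = [
    "within_region_scans",
    "meta_fixed_effects",
    "compute_mvalues",
    "region_specific_loci",
    "classify_region_trajectory",
    "write_metasoft_input",
]


def within_region_scans(geno: GenotypeMatrix, samples: pd.DataFrame,
                        min_n: int = 600, config: ScanConfig | None = None,
                        region_column: str = "ecoregion",
                        y_column: str = "birthdate_age") -> dict:
    """Independent generation-proxy scans per region.

    Each region with at least ``min_n`` samples gets its own panel subset,
    its own (re-standardized) GRM and its own scan; smaller regions are
    excluded and logged.  Returns region -> GpsmResult.
    """
    if region_column not in samples.columns:
        raise ValueError(f"sample table lacks {region_column!r}")
    lookup = samples.set_index("id")
    regions = lookup.loc[geno.samples, region_column].to_numpy()
    out = {}
    for region in pd.unique(regions):
        if pd.isna(region):
            continue
        idx = np.where(regions == region)[0]
        if len(idx) < min_n:
            logger.info("region %s has %d < %d samples; excluded",
                        region, len(idx), min_n)
            continue
        sub = geno.subset(sample_idx=idx)
        out[region] = run_gpsm(sub, samples, config=config, y_column=y_column)
    return out


def meta_fixed_effects(betas: np.ndarray, ses: np.ndarray) -> pd.DataFrame:
    """Inverse-variance fixed-effects summary with Cochran's Q.

    ``betas``/``ses`` are (m SNPs x k regions).  Per SNP:
    w_i = 1/se_i^2, beta_FE = sum(w b)/sum(w), Q = sum w (b - beta_FE)^2,
    p_Q from chi-square with (k_obs - 1) df where k_obs counts regions with
    finite estimates.  Q is NA when only one region is observed.
    """
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    if betas.shape != ses.shape:
        raise ValueError("betas and ses differ in shape")
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / ses ** 2
    ok = np.isfinite(betas) & np.isfinite(w) & (w > 0)
    w = np.where(ok, w, 0.0)
    b = np.where(ok, betas, 0.0)
    k_obs = ok.sum(axis=1)
    sw = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_fe = (w * b).sum(axis=1) / sw
        se_fe = 1.0 / np.sqrt(sw)
    Q = (w * (b - beta_fe[:, None]) ** 2).sum(axis=1)
    df = k_obs - 1
    p_q = np.full(Q.shape, np.nan)
    has = df >= 1
    p_q[has] = stats.chi2.sf(Q[has], df[has])
    Q = np.where(k_obs >= 2, Q, np.nan)
    beta_fe = np.where(k_obs >= 1, beta_fe, np.nan)
    se_fe = np.where(k_obs >= 1, se_fe, np.nan)
    return pd.DataFrame({
        "beta_fe": beta_fe, "se_fe": se_fe, "Q": Q, "df": df, "p_Q": p_q,
        "k_obs": k_obs,
    })


def compute_mvalues(betas: np.ndarray, ses: np.ndarray,
                    prior_var: float = 0.04,
                    prior_p: float = 0.5) -> np.ndarray:
    """Binary-effects posterior probability of an effect per region.

    All 2^k effect/no-effect configurations are enumerated.  Regions with an
    effect share one true effect mu ~ N(0, prior_var), so their estimates are
    jointly normal with covariance diag(se^2) + prior_var * J; no-effect
    regions contribute N(beta; 0, se^2).  Configurations get an independent
    Bernoulli(prior_p) prior; m_i is the posterior mass of configurations in
    which region i has an effect.
    """
    betas = np.asarray(betas, dtype=float).ravel()
    ses = np.asarray(ses, dtype=float).ravel()
    k = len(betas)
    if k > 12:
        raise ValueError("m-value enumeration limited to 12 regions; subset")
    if np.any(ses <= 0) or not np.all(np.isfinite(betas)):
        raise ValueError("betas must be finite and ses positive")

    log_null = stats.norm.logpdf(betas, loc=0.0, scale=ses)
    log_weights = np.empty(2 ** k)
    members = np.zeros((2 ** k, k), dtype=bool)
    for idx, cfg in enumerate(itertools.product([0, 1], repeat=k)):
        cfg = np.array(cfg, dtype=bool)
        members[idx] = cfg
        ll = float(log_null[~cfg].sum())
        if cfg.any():
            s2 = ses[cfg] ** 2
            cov = np.diag(s2) + prior_var
            ll += stats.multivariate_normal.logpdf(betas[cfg], mean=None,
                                                   cov=cov)
        n_eff = int(cfg.sum())
        ll += n_eff * np.log(prior_p) + (k - n_eff) * np.log(1.0 - prior_p)
        log_weights[idx] = ll
    log_total = logsumexp(log_weights)
    m = np.empty(k)
    for i in range(k):
        m[i] = np.exp(logsumexp(log_weights[members[:, i]]) - log_total)
    return m


def combine_region_results(region_results: dict) -> pd.DataFrame:
    """Stack per-region scan tables into one meta table (aligned on SNP id)."""
    regions = list(region_results)
    if not regions:
        raise ValueError("no region results to combine")
    first = region_results[regions[0]].assoc
    out = first[["chrom", "pos_bp", "id"]].copy()
    for r in regions:
        tab = region_results[r].assoc
        if not np.array_equal(tab["id"].to_numpy(), out["id"].to_numpy()):
            tab = tab.set_index("id").reindex(out["id"]).reset_index()
        out[f"beta_{r}"] = tab["beta"].to_numpy()
        out[f"se_{r}"] = tab["se"].to_numpy()
        out[f"p_{r}"] = tab["p_wald"].to_numpy()
    betas = out[[f"beta_{r}" for r in regions]].to_numpy()
    ses = out[[f"se_{r}" for r in regions]].to_numpy()
    meta = meta_fixed_effects(betas, ses)
    out = pd.concat([out.reset_index(drop=True), meta], axis=1)
    out.attrs["regions"] = regions
    return out


def region_specific_loci(meta: pd.DataFrame, p_q_threshold: float = 1e-5,
                         p_region_threshold: float = 1e-5,
                         merge_bp: int = 1_000_000,
                         mvalue_kwargs: dict | None = None) -> pd.DataFrame:
    """Loci with significant heterogeneity AND a significant within-region scan.

    SNPs must pass both filters (conjunction); survivors are clumped at 1 Mb
    and each locus's lead SNP gets an m-value profile across regions.
    """
    regions = meta.attrs.get("regions")
    if regions is None:
        raise ValueError("meta table must come from combine_region_results")
    pcols = [f"p_{r}" for r in regions]
    min_region_p = meta[pcols].min(axis=1).to_numpy()
    sig = (meta["p_Q"].to_numpy() < p_q_threshold) & \
          (min_region_p < p_region_threshold)
    tab = meta.copy()
    tab["p_wald"] = tab["p_Q"]  # clump ranks leads by heterogeneity p
    loci = clump_loci(tab, significant=sig, merge_bp=merge_bp)
    if loci.empty:
        loci["m_values"] = pd.Series(dtype=object)
        return loci
    mk = mvalue_kwargs or {}
    profiles = []
    lead = tab.set_index("id")
    for snp in loci["lead_id"]:
        betas = lead.loc[snp, [f"beta_{r}" for r in regions]].to_numpy(float)
        ses = lead.loc[snp, [f"se_{r}" for r in regions]].to_numpy(float)
        profiles.append(dict(zip(regions, compute_mvalues(betas, ses, **mk))))
    loci = loci.copy()
    loci["m_values"] = profiles
    return loci


def classify_region_trajectory(dosages: np.ndarray, times: np.ndarray,
                               region_mask: np.ndarray, span: float = 0.75,
                               window_fraction: float = 1.0 / 3.0) -> str:
    """Is a region's allele-frequency path converging to the pooled one?

    Both the region and the pooled trajectory are smoothed on the region's
    observed time range; the mean |region - pooled| gap over the last tercile
    is compared with the first tercile.  Shrinking gap -> "convergent",
    growing -> "divergent"; an exact tie (including a region identical to the
    pool) counts as convergent and is logged.  Regions spanning under 3 years
    are "unclassified".
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    t_region = np.asarray(times, dtype=float)[region_mask]
    if t_region.size == 0 or np.ptp(t_region) < 3.0:
        return "unclassified"
    grid_lo, grid_hi = t_region.min(), t_region.max()

    pooled = allele_frequency_trajectory(dosages, times, span=span)
    region = allele_frequency_trajectory(np.asarray(dosages)[region_mask],
                                         t_region, span=span)
    grid = np.linspace(grid_lo, grid_hi, 50)
    f_pool = np.interp(grid, pooled.curve["time"], pooled.curve["freq"])
    f_reg = np.interp(grid, region.curve["time"], region.curve["freq"])
    gap = np.abs(f_reg - f_pool)
    w = max(int(np.floor(window_fraction * len(grid))), 1)
    first, last = gap[:w].mean(), gap[-w:].mean()
    if last < first:
        return "convergent"
    if last > first:
        return "divergent"
    logger.info("trajectory gap tie (%.3g); resolved as convergent", first)
    return "convergent"


def write_metasoft_input(meta: pd.DataFrame, path) -> None:
    """Write rsid + per-region beta/se pairs, the layout METASOFT consumes."""
    regions = meta.attrs.get("regions")
    if regions is None:
        raise ValueError("meta table must come from combine_region_results")
    cols = []
    for r in regions:
        cols += [f"beta_{r}", f"se_{r}"]
    with open(path, "w") as fh:
        for rec in meta[["id"] + cols].itertuples(index=False):
            vals = " ".join("NA" if pd.isna(v) else f"{v:.12g}"
                            for v in rec[1:])
            fh.write(f"{rec[0]} {vals}\n")
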