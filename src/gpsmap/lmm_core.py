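"""Linear mixed model numerics shared by the selection-mapping scans.

The model is the standard single-random-effect GWAS LMM

    y = X b + Z u + e,   u ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

with G a standardized genomic relationship matrix.  REML estimation is
profiled over the variance ratio lambda = sigma_a^2 / sigma_e^2 on the
eigen-rotated model, and per-SNP tests are generalized least squares under the
null-fitted lambda (the EMMAX/GEMMA-Wald compromise: lambda is not
re-optimized per SNP).  Multi-GRM variance partitioning uses average
information (AI) REML with EM fallback steps, and the multivariate scan uses
EM estimation of the genetic / residual trait covariance matrices at the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Grm",
    "VarianceComponents",
    "ScanConfig",
    "MvNullFit",
    "ScanEngine",
    "compute_grm",
    "reml_single",
    "assoc_scan",
    "multi_component_reml",
    "mv_scan",
]


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

@dataclass
class Grm:
    """Genomic relationship matrix with cached eigendecomposition.

    ``matrix = eigenvectors @ diag(eigenvalues) @ eigenvectors.T`` to machine
    precision; eigenvalues are stored in descending order.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    m_used: int

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, m_used: int = 0) -> "Grm":
        matrix = np.asarray(matrix, dtype=np.float64)
        if not np.allclose(matrix, matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        vals, vecs = np.linalg.eigh(matrix)
        order = np.argsort(vals)[::-1]
        return cls(matrix=matrix, eigenvalues=vals[order],
                   eigenvectors=vecs[:, order], m_used=m_used)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def impute_dosage_means(dosage: np.ndarray) -> np.ndarray:
    """Return a copy with missing dosages replaced by the per-SNP mean."""
    out = dosage.copy()
    nan_mask = np.isnan(out)
    if nan_mask.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(out, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        out[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    return out


def grm_snp_filter(geno: GenotypeMatrix, maf_min: float = 0.01,
                   max_missing: float = 0.1) -> np.ndarray:
    """Boolean mask of SNPs usable for GRM construction and scanning."""
    maf = geno.maf()
    miss = np.mean(np.isnan(geno.dosage), axis=0)
    with np.errstate(invalid="ignore"):
        return (~np.isnan(maf)) & (maf > maf_min) & (miss <= max_missing)


def compute_grm(geno: GenotypeMatrix, maf_min: float = 0.01,
                max_missing: float = 0.1, standardize: bool = True,
                max_n: int = 30_000) -> Grm:
    """Build the (default standardized) GRM, G = W W^T / m.

    Each retained SNP column is centered at 2p and, when ``standardize`` is
    true, scaled by sqrt(2 p (1-p)) so every SNP contributes equal variance
    (trace(G) ~ n).  Missing dosages are mean-imputed here only.
    """
    n = geno.n_samples
    if n > max_n:
        raise MemoryError(
            f"n={n} exceeds the dense-GRM cap ({max_n}); compute G in blocks "
            "and pass it via Grm.from_matrix"
        )
    keep = grm_snp_filter(geno, maf_min, max_missing)
    m_used = int(keep.sum())
    if m_used < 2:
        raise ValueError("fewer than 2 polymorphic SNPs above the MAF threshold")
    X = impute_dosage_means(geno.dosage[:, keep])
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    if standardize:
        W /= np.sqrt(2.0 * p * (1.0 - p))
    G = (W @ W.T) / m_used
    G = (G + G.T) / 2.0
    return Grm.from_matrix(G, m_used=m_used)


# ---------------------------------------------------------------------------
# Single-component REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance component estimates for one or several GRMs."""

    sigma_a2: float
    sigma_e2: float
    pve: float
    pve_se: float
    loglik: float
    lam: float = np.nan                      # sigma_a2 / sigma_e2
    components: np.ndarray | None = None     # per-GRM variances (multi-GRM fits)
    component_se: np.ndarray | None = None
    component_pve: np.ndarray | None = None
    component_pve_se: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    n_iter: int = 0

    def summary_table(self) -> pd.DataFrame:
        """One PVE +/- SE row per GRM plus the total (multi-GRM layout)."""
        if self.components is None:
            rows = [("G1", self.pve, self.pve_se)]
        else:
            rows = [(f"G{i + 1}", pve, se)
                    for i, (pve, se) in enumerate(
                        zip(self.component_pve, self.component_pve_se))]
        rows.append(("total", self.pve, self.pve_se))
        return pd.DataFrame(rows, columns=["component", "pve", "se"])


@dataclass
class ScanConfig:
    """Options shared by all per-SNP scans."""

    maf_min: float = 0.01
    max_missing: float = 0.1
    covariates: np.ndarray | None = None  # extra columns beyond the intercept

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")

    def design(self, n: int) -> np.ndarray:
        X = np.ones((n, 1))
        if self.covariates is not None:
            C = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            X = np.hstack([X, C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        return X


def _rotated_reml_parts(lam: float, d: np.ndarray, ystar: np.ndarray,
                        Xstar: np.ndarray):
    """Weighted-regression pieces for the profiled criterion at one lambda."""
    w = lam * d + 1.0
    winv = 1.0 / w
    XtW = Xstar * winv[:, None]
    XtWX = XtW.T @ Xstar
    beta = np.linalg.solve(XtWX, XtW.T @ ystar)
    r = ystar - Xstar @ beta
    rss = float(np.sum(r * r * winv))
    return w, winv, XtWX, beta, rss


def _profiled_reml_loglik(lam: float, d: np.ndarray, ystar: np.ndarray,
                          Xstar: np.ndarray, logdet_xtx: float) -> float:
    n, c = Xstar.shape
    w, _, XtWX, _, rss = _rotated_reml_parts(lam, d, ystar, Xstar)
    if rss <= 0 or not np.isfinite(rss):
        return -np.inf
    nc = n - c
    sigma_e2 = rss / nc
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        nc * np.log(2.0 * np.pi * sigma_e2) + nc
        + np.sum(np.log(w)) + logdet_xwx - logdet_xtx
    )


def _reml_loglik_components(sa2: float, se2: float, d: np.ndarray,
                            ystar: np.ndarray, Xstar: np.ndarray,
                            logdet_xtx: float) -> float:
    """Unprofiled restricted log-likelihood in (sigma_a2, sigma_e2)."""
    n, c = Xstar.shape
    w = sa2 * d + se2
    if np.any(w <= 0):
        return -np.inf
    winv = 1.0 / w
    XtW = Xstar * winv[:, None]
    XtWX = XtW.T @ Xstar
    beta = np.linalg.solve(XtWX, XtW.T @ ystar)
    r = ystar - Xstar @ beta
    quad = float(np.sum(r * r * winv))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - c) * np.log(2.0 * np.pi) + np.sum(np.log(w))
        + logdet_xwx - logdet_xtx + quad
    )


LOG_LAMBDA_RANGE = (-10.0, 10.0)
N_GRID = 101


def reml_single(y: np.ndarray, grm: Grm, covariates: np.ndarray | None = None,
                config: ScanConfig | None = None) -> VarianceComponents:
    """Single-GRM REML by 1-D profiling over log(lambda).

    A 101-point grid on log lambda in [-10, 10] locates the basin; Brent
    refinement polishes the optimum.  PVE = sigma_a2 / (sigma_a2 + sigma_e2)
    with a delta-method standard error from the observed information.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = grm.n
    if len(y) != n:
        raise ValueError("y length does not match GRM dimension")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if np.var(y) == 0:
        raise ValueError("y is constant; variance components are undefined")

    cfg = config or ScanConfig(covariates=covariates)
    if config is None and covariates is not None:
        cfg = ScanConfig(covariates=covariates)
    X = cfg.design(n)
    c = X.shape[1]

    d = np.maximum(grm.eigenvalues, 0.0)
    warns: list[str] = []
    if np.ptp(d) < 1e-8:
        warns.append("GRM is (numerically) a multiple of the identity; "
                     "lambda is unidentifiable")

    U = grm.eigenvectors
    ystar = U.T @ y
    Xstar = U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    grid = np.linspace(*LOG_LAMBDA_RANGE, N_GRID)
    lls = np.array([
        _profiled_reml_loglik(np.exp(g), d, ystar, Xstar, logdet_xtx)
        for g in grid
    ])
    if not np.any(np.isfinite(lls)):
        raise FloatingPointError("REML likelihood non-finite on the whole grid")
    k = int(np.nanargmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, N_GRID - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profiled_reml_loglik(np.exp(g), d, ystar, Xstar, logdet_xtx),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    best = res.x if -res.fun >= lls[k] else grid[k]
    lam = float(np.exp(best))
    ll = _profiled_reml_loglik(lam, d, ystar, Xstar, logdet_xtx)

    _, _, _, _, rss = _rotated_reml_parts(lam, d, ystar, Xstar)
    sigma_e2 = rss / (n - c)
    sigma_a2 = lam * sigma_e2
    pve = sigma_a2 / (sigma_a2 + sigma_e2)

    pve_se = _delta_pve_se(sigma_a2, sigma_e2, d, ystar, Xstar, logdet_xtx)
    if np.isclose(best, LOG_LAMBDA_RANGE[0], atol=1e-6):
        warns.append("lambda at lower bound; sigma_a2 is effectively zero")
    if np.isclose(best, LOG_LAMBDA_RANGE[1], atol=1e-6):
        warns.append("lambda at upper bound; sigma_e2 is effectively zero")

    return VarianceComponents(
        sigma_a2=float(sigma_a2), sigma_e2=float(sigma_e2), pve=float(pve),
        pve_se=float(pve_se), loglik=float(ll), lam=lam, warnings=warns,
    )


def _delta_pve_se(sa2, se2, d, ystar, Xstar, logdet_xtx) -> float:
    """Delta-method SE of PVE from a finite-difference observed information."""
    theta = np.array([sa2, se2])
    h = np.maximum(1e-5 * np.abs(theta), 1e-8)

    def f(t):
        return _reml_loglik_components(t[0], t[1], d, ystar, Xstar, logdet_xtx)

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        tot = sa2 + se2
        g = np.array([se2, -sa2]) / tot ** 2
        var = float(g @ cov @ g)
        return float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan


# ---------------------------------------------------------------------------
# Per-SNP Wald scan (univariate)
# ---------------------------------------------------------------------------

class ScanEngine:
    """Precomputed eigen-rotated genotypes for repeated scans of one panel.

    The expensive piece of a scan is rotating the dosage matrix by the GRM's
    eigenvectors; permutation analyses rescan the same panel many times with
    different phenotypes, so the rotation is cached here.
    """

    def __init__(self, geno: GenotypeMatrix, grm: Grm,
                 config: ScanConfig | None = None):
        self.cfg = config or ScanConfig()
        n = geno.n_samples
        if grm.n != n:
            raise ValueError("GRM dimension does not match genotype panel")
        self.geno = geno
        self.grm = grm
        self.U = grm.eigenvectors
        self.d = np.maximum(grm.eigenvalues, 0.0)
        self.X = self.cfg.design(n)
        self.keep = grm_snp_filter(geno, self.cfg.maf_min, self.cfg.max_missing)
        W = impute_dosage_means(geno.dosage[:, self.keep])
        self.Gstar = self.U.T @ W          # rotated dosages (cached)
        self.Xstar = self.U.T @ self.X

    def fit_null(self, y: np.ndarray) -> VarianceComponents:
        return reml_single(np.asarray(y, float).ravel(), self.grm, config=self.cfg)

    def scan(self, y: np.ndarray,
             vc: VarianceComponents | None = None) -> pd.DataFrame:
        """Wald scan of every SNP at the null-fitted variance ratio."""
        y = np.asarray(y, dtype=float).ravel()
        n, c = self.X.shape
        if len(y) != n:
            raise ValueError("y length does not match panel")
        if vc is None:
            vc = self.fit_null(y)
        sw = 1.0 / np.sqrt(vc.lam * self.d + 1.0)

        ys = (self.U.T @ y) * sw
        Xs = self.Xstar * sw[:, None]
        Gs = self.Gstar * sw[:, None]

        Q, _ = np.linalg.qr(Xs)
        ry = ys - Q @ (Q.T @ ys)
        rG = Gs - Q @ (Q.T @ Gs)

        xtx = np.einsum("ij,ij->j", rG, rG)
        xty = rG.T @ ry
        yty = float(ry @ ry)

        ok = xtx > 1e-12 * n
        beta = np.full(xtx.shape, np.nan)
        se = np.full(xtx.shape, np.nan)
        pvals = np.full(xtx.shape, np.nan)
        dof = n - c - 1
        beta[ok] = xty[ok] / xtx[ok]
        rss = np.maximum(yty - beta[ok] ** 2 * xtx[ok], 0.0)
        sigma2 = rss / dof
        se[ok] = np.sqrt(sigma2 / xtx[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[ok] / se[ok]
        pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), dof)

        out = self.geno.snps[["chrom", "pos_bp", "id"]].copy()
        out["af"] = self.geno.maf()
        out["beta"] = np.nan
        out["se"] = np.nan
        out["p_wald"] = np.nan
        out.loc[self.keep, "beta"] = beta
        out.loc[self.keep, "se"] = se
        out.loc[self.keep, "p_wald"] = pvals
        tested = self.keep.copy()
        tested[np.where(self.keep)[0][~ok]] = False  # collinear SNPs flagged
        out["tested"] = tested
        return out


def assoc_scan(geno: GenotypeMatrix, y: np.ndarray, grm: Grm,
               config: ScanConfig | None = None,
               vc: VarianceComponents | None = None) -> pd.DataFrame:
    """GLS Wald scan of every SNP under the null-fitted variance ratio.

    Effects and SEs come from the eigen-rotated, weighted regression
    y* = X* b + x* g + eps with weights (lambda d_i + 1); the residual variance
    is re-estimated per SNP and the Wald p comes from a Student-t with
    n - c - 1 degrees of freedom.  SNPs failing the MAF/missingness filter get
    NA statistics; SNPs collinear with the covariates are flagged the same way.
    """
    return ScanEngine(geno, grm, config).scan(y, vc=vc)


# ---------------------------------------------------------------------------
# Multi-GRM AI-REML
# ---------------------------------------------------------------------------

def multi_component_reml(y: np.ndarray, grms: list[Grm],
                         covariates: np.ndarray | None = None,
                         max_iter: int = 100, rtol: float = 1e-8,
                         ) -> VarianceComponents:
    """Partition variance across 2-4 GRMs by AI-REML.

    Average-information updates with EM fallback when an AI step would leave
    the parameter space; variances are kept non-negative by projection onto a
    small floor.  Standard errors come from the inverse AI matrix; per-GRM PVE
    SEs by the delta method.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not 2 <= len(grms) <= 4:
        raise ValueError("multi_component_reml expects 2-4 GRMs")
    n = len(y)
    for g in grms:
        if g.n != n:
            raise ValueError("GRM dimension does not match y")
    cfg = ScanConfig(covariates=covariates)
    X = cfg.design(n)
    c = X.shape[1]

    for a in range(len(grms)):
        for b in range(a + 1, len(grms)):
            diff = np.max(np.abs(grms[a].matrix - grms[b].matrix))
            if diff < 1e-10 * max(np.max(np.abs(grms[a].matrix)), 1.0):
                raise ValueError(
                    f"GRMs {a} and {b} are numerically identical; the "
                    "variance split is non-identifiable (singular AI matrix)")

    Ks = [g.matrix for g in grms] + [np.eye(n)]
    K = len(Ks)
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("y is constant")
    floor = 1e-8 * vary
    sigma = np.full(K, vary / K)

    def reml_ll(sig):
        V = sum(s * Kk for s, Kk in zip(sig, Ks))
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf, None, None
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        XtVinvX = XtVinv @ X
        B = np.linalg.solve(XtVinvX, XtVinv @ y)
        P = Vinv - XtVinv.T @ np.linalg.solve(XtVinvX, XtVinv)
        Py = P @ y
        logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
        _, logdet_xvx = np.linalg.slogdet(XtVinvX)
        ll = -0.5 * ((n - c) * np.log(2 * np.pi) + logdet_v + logdet_xvx
                     + float(y @ Py))
        return ll, P, Py

    ll, P, Py = reml_ll(sigma)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite REML likelihood at initial values")

    AI = np.eye(K)
    grad = np.zeros(K)
    warns: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        KPy = [Kk @ Py for Kk in Ks]
        trPK = [float(np.sum(P * Kk)) for Kk in Ks]  # tr(P K), K symmetric
        quad = [float(Py @ KPy_k) for KPy_k in KPy]
        grad = -0.5 * (np.array(trPK) - np.array(quad))

        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array([[float(KPy[a] @ PKPy[b]) for b in range(K)]
                             for a in range(K)])
        if np.linalg.cond(AI) > 1e12:
            warns.append("AI matrix near-singular (weakly identified split)")

        # damped Fisher scoring: inflate the AI diagonal until the step stays
        # in the parameter space and improves the restricted likelihood
        new_sigma = None
        diag = np.diag(np.maximum(np.diag(AI), 1e-12))
        for damp in (0.0, 1e-6, 1e-4, 1e-2, 1.0, 1e2, 1e4):
            try:
                step = np.linalg.solve(AI + damp * diag, grad)
            except np.linalg.LinAlgError:
                continue
            for _ in range(8):
                cand = sigma + step
                if np.all(cand >= 0):
                    ll_new, P_new, Py_new = reml_ll(cand)
                    if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                        new_sigma = cand
                        break
                step = step / 2.0
            if new_sigma is not None:
                break
        if new_sigma is None:
            # EM update: sigma_k' = sigma_k + sigma_k^2 (y'PKPy - tr(PK)) / n
            new_sigma = sigma + sigma ** 2 * (np.array(quad) - np.array(trPK)) / n
            new_sigma = np.maximum(new_sigma, floor)
            ll_new, P_new, Py_new = reml_ll(new_sigma)

        delta = np.max(np.abs(new_sigma - sigma)) / max(np.max(np.abs(new_sigma)), floor)
        sigma, P, Py = new_sigma, P_new, Py_new
        conv = delta < rtol or (np.isfinite(ll_new) and abs(ll_new - ll) < rtol * (1 + abs(ll)))
        ll = ll_new
        if conv:
            break
    else:
        raise FloatingPointError(
            f"AI-REML did not converge in {max_iter} iterations "
            f"(last gradient norm {np.linalg.norm(grad):.3e})"
        )

    try:
        cov = np.linalg.inv(AI)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((K, K), np.nan)
        ses = np.full(K, np.nan)
        warns.append("AI matrix singular at convergence; SEs unavailable")

    tot = float(np.sum(sigma))
    comp_pve = sigma[:-1] / tot
    comp_pve_se = np.empty(K - 1)
    for k in range(K - 1):
        g = np.full(K, -sigma[k] / tot ** 2)
        g[k] += 1.0 / tot
        v = float(g @ cov @ g)
        comp_pve_se[k] = np.sqrt(v) if v > 0 else np.nan
    # total genetic PVE and its SE
    g = np.full(K, -float(np.sum(sigma[:-1])) / tot ** 2)
    g[:-1] += 1.0 / tot
    v = float(g @ cov @ g)
    tot_pve = float(np.sum(sigma[:-1]) / tot)
    tot_pve_se = np.sqrt(v) if v > 0 else np.nan

    return VarianceComponents(
        sigma_a2=float(np.sum(sigma[:-1])), sigma_e2=float(sigma[-1]),
        pve=tot_pve, pve_se=float(tot_pve_se), loglik=float(ll),
        components=sigma[:-1].copy(), component_se=ses[:-1].copy(),
        component_pve=comp_pve, component_pve_se=comp_pve_se,
        warnings=warns, n_iter=it,
    )


# ---------------------------------------------------------------------------
# Multivariate scan
# ---------------------------------------------------------------------------

@dataclass
class MvNullFit:
    """Null-model trait covariance estimates for the multivariate LMM."""

    v_genetic: np.ndarray
    v_residual: np.ndarray
    n_iter: int
    loglik: float

    @property
    def genetic_correlation(self) -> np.ndarray:
        s = np.sqrt(np.diag(self.v_genetic))
        return self.v_genetic / np.outer(s, s)

    @property
    def residual_correlation(self) -> np.ndarray:
        s = np.sqrt(np.diag(self.v_residual))
        return self.v_residual / np.outer(s, s)


def _mv_em_null(Ystar: np.ndarray, Xstar: np.ndarray, d: np.ndarray,
                max_iter: int = 5000, rtol: float = 1e-8) -> MvNullFit:
    """EM fit of per-trait genetic/residual covariances on rotated data."""
    n, t = Ystar.shape
    Vg = np.cov(Ystar.T) * 0.5 + np.eye(t) * 1e-6
    Ve = Vg.copy()

    def gls_residuals(Siginv):
        # B solves sum_i x_i (y_i - B'x_i)' Siginv_i = 0 ; B is c x t
        c = Xstar.shape[1]
        Sy = np.einsum("ijk,ik->ij", Siginv, Ystar)
        XX = np.einsum("ia,ib,ijk->abjk", Xstar, Xstar, Siginv)
        info = XX.transpose(0, 2, 1, 3).reshape(c * t, c * t)
        rhs = np.einsum("ia,ij->aj", Xstar, Sy).reshape(c * t)
        B = np.linalg.solve(info, rhs).reshape(c, t)
        return Ystar - Xstar @ B

    ll_old = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        Sig = d[:, None, None] * Vg[None] + Ve[None]
        Siginv = np.linalg.inv(Sig)
        R = gls_residuals(Siginv)
        SR = np.einsum("ijk,ik->ij", Siginv, R)

        # EM sandwich updates
        outer = np.einsum("ij,ik->ijk", SR, SR)
        A_g = (d[:, None, None] * (outer - Siginv)).sum(axis=0)
        A_e = (outer - Siginv).sum(axis=0)
        Vg_new = Vg + Vg @ A_g @ Vg / n
        Ve_new = Ve + Ve @ A_e @ Ve / n
        # keep symmetric positive semidefinite
        Vg_new = _nearest_psd((Vg_new + Vg_new.T) / 2)
        Ve_new = _nearest_psd((Ve_new + Ve_new.T) / 2, floor=1e-8)

        change = max(np.max(np.abs(Vg_new - Vg)), np.max(np.abs(Ve_new - Ve)))
        scale = max(np.max(np.abs(Vg_new)), np.max(np.abs(Ve_new)), 1e-12)
        Vg, Ve = Vg_new, Ve_new
        if change / scale < rtol:
            break

    Sig = d[:, None, None] * Vg[None] + Ve[None]
    sign, logdets = np.linalg.slogdet(Sig)
    Siginv = np.linalg.inv(Sig)
    R = gls_residuals(Siginv)
    quad = float(np.einsum("ij,ijk,ik->", R, Siginv, R))
    ll = -0.5 * (n * t * np.log(2 * np.pi) + float(np.sum(logdets)) + quad)
    return MvNullFit(v_genetic=Vg, v_residual=Ve, n_iter=it, loglik=ll)


def _nearest_psd(A: np.ndarray, floor: float = 0.0) -> np.ndarray:
    vals, vecs = np.linalg.eigh(A)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def mv_scan(geno: GenotypeMatrix, Y: np.ndarray, grm: Grm,
            config: ScanConfig | None = None) -> pd.DataFrame:
    """Multivariate LMM scan: a d-vector of SNP effects tested jointly.

    Trait covariances are estimated once at the null by EM on the
    eigen-rotated data, then each SNP's effect vector is solved by GLS and
    tested with a Wald chi-square on d degrees of freedom.  With a single
    trait this reduces to (and delegates to) the univariate scan.
    """
    cfg = config or ScanConfig()
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != geno.n_samples:
        Y = Y.T
    n, t = Y.shape
    if t > 5:
        raise ValueError("multivariate scan supports at most 5 traits")
    if t == 1:
        out = assoc_scan(geno, Y[:, 0], grm, cfg)
        out["p_mv"] = out["p_wald"]
        return out
    if np.linalg.matrix_rank(np.corrcoef(Y.T)) < t or \
            np.any(np.triu(np.abs(np.corrcoef(Y.T)), 1) > 1 - 1e-12):
        raise ValueError("Y has duplicated or collinear trait columns")

    X = cfg.design(n)
    c = X.shape[1]
    U = grm.eigenvectors
    d = np.maximum(grm.eigenvalues, 0.0)
    Ystar = U.T @ Y
    Xstar = U.T @ X
    null = _mv_em_null(Ystar, Xstar, d)

    Sig = d[:, None, None] * null.v_genetic[None] + null.v_residual[None]
    A = np.linalg.inv(Sig)                       # n x t x t

    keep = grm_snp_filter(geno, cfg.maf_min, cfg.max_missing)
    W = impute_dosage_means(geno.dosage[:, keep])
    Gs = U.T @ W                                 # n x m rotated dosages

    AY = np.einsum("ijk,ik->ij", A, Ystar)       # n x t
    A_flat = A.reshape(n, t * t)

    # accumulated GLS blocks for (covariates, snp) joint solve, per SNP
    XX = np.einsum("ia,ib,ijk->abjk", Xstar, Xstar, A)   # c x c x t x t
    XA_y = np.einsum("ia,ij->aj", Xstar, AY)             # c x t
    Sx = (Gs.T @ (Xstar[:, :, None] * A_flat[:, None, :]).reshape(n, -1))
    Sx = Sx.reshape(-1, c, t, t)                          # m x c x t x t
    Sxx = (Gs ** 2).T @ A_flat                            # m x (t*t)
    Sxx = Sxx.reshape(-1, t, t)
    Sxy = Gs.T @ AY                                       # m x t

    m_kept = Gs.shape[1]
    p_mv = np.full(m_kept, np.nan)
    betas = np.full((m_kept, t), np.nan)
    top = XX.transpose(0, 2, 1, 3).reshape(c * t, c * t)
    for j in range(m_kept):
        off = Sx[j].reshape(c * t, t)                     # cov-x cross block
        info = np.empty((c * t + t, c * t + t))
        info[: c * t, : c * t] = top
        info[: c * t, c * t:] = off
        info[c * t:, : c * t] = off.T
        info[c * t:, c * t:] = Sxx[j]
        rhs = np.concatenate([XA_y.reshape(-1), Sxy[j]])
        try:
            theta = np.linalg.solve(info, rhs)
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            continue
        b = theta[c * t:]
        vb = cov[c * t:, c * t:]
        try:
            stat = float(b @ np.linalg.solve(vb, b))
        except np.linalg.LinAlgError:
            continue
        betas[j] = b
        p_mv[j] = stats.chi2.sf(stat, t)

    out = geno.snps[["chrom", "pos_bp", "id"]].copy()
    out["af"] = geno.maf()
    out["p_mv"] = np.nan
    out.loc[keep, "p_mv"] = p_mv
    for k in range(t):
        col = np.full(len(out), np.nan)
        col[np.where(keep)[0]] = betas[:, k]
        out[f"beta_{k + 1}"] = col
    out["p_wald"] = out["p_mv"]
    out["tested"] = keep
    out.attrs["null_fit"] = null
    return out
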