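"""Generation-proxy selection mapping (GPSM).

A SNP whose allele frequency is changing over time beyond what drift and
pedigree structure allow becomes statistically associated with an individual's
birth date (or generation number).  GPSM scans every SNP for such an
association with a linear mixed model whose random effect, structured by the
genomic relationship matrix, absorbs relatedness, population structure and
inbreeding.  Multiple testing is handled with Storey q-values (threshold
q < 0.1 by default); significant SNPs are grouped into loci by single-linkage
clumping at 1 Mb, and allele-frequency trajectories of lead SNPs are
summarized by linear slopes and a local-linear (tricube-weighted) smoother.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate

from .io_formats import GenotypeMatrix
from .lmm_core import (Grm, ScanConfig, ScanEngine, VarianceComponents,
                       compute_grm)

logger = logging.getLogger(__name__)

__all__ = [
    "GpsmResult",
    "Trajectory",
    "run_gpsm",
    "storey_qvalues",
    "permutation_null",
    "clump_loci",
    "allele_frequency_trajectory",
    "delta_af_per_generation",
    "annotate_candidates",
]


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values.

    pi0 is estimated from the tail counts #{p > lambda} / (m (1 - lambda))
    over lambda = 0.05, 0.10, ..., 0.95 and smoothed with a natural cubic
    smoothing spline evaluated at the largest lambda.  With fewer than 100
    p-values pi0 falls back to 1 (plain Benjamini-Hochberg) with a warning.
    NaN entries pass through as NaN.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size == 0:
        return out
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values outside [0, 1]")

    m = pv.size
    if m < 100:
        warnings.warn("fewer than 100 p-values; using pi0 = 1 (BH)", stacklevel=2)
        pi0 = 1.0
    else:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([np.mean(pv > lam) / (1.0 - lam) for lam in lambdas])
        try:
            spl = interpolate.make_smoothing_spline(lambdas, pi0_lam)
            pi0 = float(spl(lambdas[-1]))
        except Exception:  # degenerate tail counts
            pi0 = float(pi0_lam[-1])
        pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qs = np.empty(m)
    qs[order] = q
    out[valid] = qs
    return out


# ---------------------------------------------------------------------------
# Locus clumping
# ---------------------------------------------------------------------------

def clump_loci(assoc: pd.DataFrame, q_threshold: float = 0.1,
               merge_bp: int = 1_000_000,
               significant: np.ndarray | None = None) -> pd.DataFrame:
    """Group significant SNPs into loci by single linkage at ``merge_bp``.

    Consecutive significant SNPs on the same chromosome join one locus when
    their gap is at most ``merge_bp``; the lead SNP is the smallest p (ties
    broken by smallest position).  ``significant`` overrides the default
    q < q_threshold mask.
    """
    if significant is None:
        if "q" not in assoc.columns:
            raise ValueError("association table lacks a q column")
        significant = assoc["q"].to_numpy() < q_threshold
    sig = assoc.loc[np.asarray(significant, dtype=bool)].copy()
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp")
        pos = grp["pos_bp"].to_numpy()
        breaks = np.where(np.diff(pos) > merge_bp)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            block = grp.iloc[a:b]
            lead = block.sort_values(["p_wald", "pos_bp"]).iloc[0]
            rows.append({
                "chrom": chrom,
                "start_bp": int(block["pos_bp"].min()),
                "end_bp": int(block["pos_bp"].max()),
                "span_bp": int(block["pos_bp"].max() - block["pos_bp"].min()),
                "n_snps": len(block),
                "lead_id": lead["id"],
                "lead_pos_bp": int(lead["pos_bp"]),
                "lead_p": float(lead["p_wald"]),
            })
    return pd.DataFrame(rows, columns=[
        "chrom", "start_bp", "end_bp", "span_bp", "n_snps",
        "lead_id", "lead_pos_bp", "lead_p",
    ])


# ---------------------------------------------------------------------------
# Allele-frequency trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-SNP allele-frequency history against a continuous time axis."""

    snp_id: str
    slope_per_year: float
    slope_se: float
    curve: pd.DataFrame  # columns: time, freq (smoothed, clipped to [0, 1])


def allele_frequency_trajectory(dosages: np.ndarray, times: np.ndarray,
                                snp_id: str = "", span: float = 0.75,
                                n_grid: int = 50) -> Trajectory:
    """Regress frequency-coded genotypes (dosage / 2) on time.

    The linear slope estimates the frequency change per year; a
    tricube-weighted local linear smoother with the given span provides the
    curve (evaluated on the observed time range only, clipped to [0, 1]).
    """
    dosages = np.asarray(dosages, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = ~(np.isnan(dosages) | np.isnan(times))
    dosages, times = dosages[mask], times[mask]
    if dosages.size < 30:
        raise ValueError("need at least 30 genotyped samples for a trajectory")
    if np.ptp(times) < 2.0:
        raise ValueError("samples must span at least 2 years")

    freq = dosages / 2.0
    X = np.column_stack([np.ones_like(times), times])
    coef, res, *_ = np.linalg.lstsq(X, freq, rcond=None)
    slope = float(coef[1])
    n = len(freq)
    resid = freq - X @ coef
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(np.sum((times - times.mean()) ** 2))
    slope_se = float(np.sqrt(s2 / sxx))

    grid = np.linspace(times.min(), times.max(), n_grid)
    fitted = _tricube_local_linear(times, freq, grid, span)
    curve = pd.DataFrame({"time": grid, "freq": np.clip(fitted, 0.0, 1.0)})
    return Trajectory(snp_id=snp_id, slope_per_year=slope,
                      slope_se=slope_se, curve=curve)


def _tricube_local_linear(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                          span: float) -> np.ndarray:
    """Loess-style local linear fit with tricube weights on the span-nearest points."""
    n = len(x)
    k = max(int(np.ceil(span * n)), 3)
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        dist = np.abs(x - g)
        idx = np.argpartition(dist, k - 1)[:k]
        h = dist[idx].max()
        if h == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (dist[idx] / h) ** 3) ** 3
        xw, yw = x[idx], y[idx]
        W = np.diag(w)
        Xl = np.column_stack([np.ones(k), xw - g])
        A = Xl.T @ W @ Xl
        b = Xl.T @ (w * yw)
        try:
            coef = np.linalg.solve(A, b)
            out[i] = coef[0]
        except np.linalg.LinAlgError:
            out[i] = np.average(yw, weights=w)
    return out


def delta_af_per_generation(traj: Trajectory,
                            generation_interval_years: float = 5.0) -> float:
    """Per-generation allele frequency change: slope/year x generation interval."""
    return traj.slope_per_year * generation_interval_years


# ---------------------------------------------------------------------------
# Candidate-gene annotation
# ---------------------------------------------------------------------------

def annotate_candidates(snps: pd.DataFrame, genes: pd.DataFrame,
                        window: int = 10_000) -> pd.DataFrame:
    """All genes within ``window`` bp of each SNP, with the bp distance.

    Distance is 0 when the SNP lies inside the gene; otherwise the gap to the
    nearest interval edge.  Gene intervals are 0-based half-open; SNP positions
    1-based.
    """
    rows = []
    for snp in snps.itertuples(index=False):
        pos0 = snp.pos_bp - 1
        sub = genes[genes["chrom"].astype(str) == str(snp.chrom)]
        for gene in sub.itertuples(index=False):
            if gene.start <= pos0 < gene.end:
                dist = 0
            elif pos0 < gene.start:
                dist = gene.start - pos0
            else:
                dist = pos0 - (gene.end - 1)
            if dist <= window:
                rows.append({"snp": snp.id, "chrom": snp.chrom,
                             "pos_bp": snp.pos_bp, "gene": gene.name,
                             "distance_bp": int(dist)})
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos_bp", "gene",
                                       "distance_bp"])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class GpsmResult:
    """Everything a GPSM run produces."""

    assoc: pd.DataFrame
    pve: VarianceComponents
    loci: pd.DataFrame
    permutation_summaries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["perm", "seed", "pve", "min_p"]))
    q_threshold: float = 0.1

    @property
    def n_significant(self) -> int:
        return int((self.assoc["q"] < self.q_threshold).sum())


def run_gpsm(geno: GenotypeMatrix, samples: pd.DataFrame,
             config: ScanConfig | None = None, q_threshold: float = 0.1,
             merge_bp: int = 1_000_000, n_perm: int = 0,
             seed: int | None = None, grm: Grm | None = None,
             y_column: str = "birthdate_age") -> GpsmResult:
    """The full GPSM pipeline on one panel.

    GRM -> single-component REML -> per-SNP Wald scan with birth date (or any
    generation proxy in ``y_column``) as the dependent variable -> Storey
    q-values -> 1-Mb locus clumping, plus optional birth-date permutations as
    a negative control.
    """
    cfg = config or ScanConfig()
    if geno.n_samples < 10:
        raise ValueError("GPSM needs at least 10 samples (GRM underdetermined)")
    y = _aligned_phenotype(geno, samples, y_column)
    if grm is None:
        grm = compute_grm(geno, maf_min=cfg.maf_min, max_missing=cfg.max_missing)

    engine = ScanEngine(geno, grm, cfg)
    vc = engine.fit_null(y)
    assoc = engine.scan(y, vc=vc)
    assoc["q"] = storey_qvalues(assoc["p_wald"].to_numpy())
    loci = clump_loci(assoc, q_threshold=q_threshold, merge_bp=merge_bp)

    perms = permutation_null(geno, samples, n_perm=n_perm, seed=seed,
                             config=cfg, grm=grm, engine=engine,
                             y_column=y_column) if n_perm else None
    result = GpsmResult(assoc=assoc, pve=vc, loci=loci, q_threshold=q_threshold)
    if perms is not None:
        result.permutation_summaries = perms
    return result


def permutation_null(geno: GenotypeMatrix, samples: pd.DataFrame,
                     n_perm: int = 10, seed: int | None = None,
                     config: ScanConfig | None = None, grm: Grm | None = None,
                     engine: ScanEngine | None = None,
                     y_column: str = "birthdate_age") -> pd.DataFrame:
    """Scan permuted birth dates: the negative control for GPSM.

    Each permutation detaches genotypes from the generation proxy, so the PVE
    should collapse to ~0 and no SNP should stay significant.  Returns one row
    per permutation with the PVE, the minimum scan p and the count of q < 0.1
    SNPs; seeds are recorded for reproducibility.
    """
    cfg = config or ScanConfig()
    y = _aligned_phenotype(geno, samples, y_column)
    if engine is None:
        if grm is None:
            grm = compute_grm(geno, maf_min=cfg.maf_min, max_missing=cfg.max_missing)
        engine = ScanEngine(geno, grm, cfg)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_perm):
        perm_seed = int(rng.integers(0, 2**31 - 1))
        yperm = np.random.default_rng(perm_seed).permutation(y)
        vc = engine.fit_null(yperm)
        assoc = engine.scan(yperm, vc=vc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = storey_qvalues(assoc["p_wald"].to_numpy())
        rows.append({
            "perm": i, "seed": perm_seed, "pve": vc.pve,
            "min_p": float(np.nanmin(assoc["p_wald"].to_numpy())),
            "n_q_below_0.1": int(np.nansum(q < 0.1)),
        })
    return pd.DataFrame(rows, columns=["perm", "seed", "pve", "min_p",
                                       "n_q_below_0.1"])


def _aligned_phenotype(geno: GenotypeMatrix, samples: pd.DataFrame,
                       column: str) -> np.ndarray:
    """Phenotype vector in panel sample order, validated complete."""
    if column not in samples.columns:
        raise ValueError(f"sample table lacks column {column!r}")
    lookup = samples.set_index("id")[column]
    missing = [s for s in geno.samples if s not in lookup.index]
    if missing:
        raise ValueError(f"{len(missing)} panel samples absent from the sample "
                         f"table (first: {missing[0]!r})")
    y = lookup.loc[geno.samples].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError(f"missing {column} for some panel samples")
    return y
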