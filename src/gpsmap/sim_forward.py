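"""Forward-in-time breeding simulation with known selection truth.

The simulator validates that the generation-proxy scan separates selection
from drift.  Founders carry standing variation drawn from a neutral-shaped
site frequency spectrum (density proportional to 1/x on (0.01, 0.99)) and go
through 50 generations of random-mating burn-in at the target effective size
to build linkage disequilibrium.  A quantitative trait is controlled by
purely additive QTL with normal or gamma(shape 0.42, random sign) effects.
After a truncation-selection burn-in, breeding proceeds for a configurable
number of generations, either with truncation selection on true breeding
value or at random (drift only), crossing a fixed number of selected sires
and dams.  Per-generation QTL frequencies, breeding values and genotypes are
recorded so that the scan's true/false positives can be counted exactly.

Meiosis draws crossover counts from a Poisson with mean one per 100 Mb of
chromosome (times a configurable factor) with uniform crossover positions
and a random start phase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix
from .lmm_core import ScanConfig
from .gpsm import GpsmResult, run_gpsm

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "SimTruth",
    "HaplotypePool",
    "generate_founders",
    "assign_qtl_architecture",
    "simulate_scenario",
    "sample_individuals",
    "evaluate_gpsm_performance",
    "pve_metaregression",
]


@dataclass
class Scenario:
    """One cell of the simulation grid."""

    n_chrom: int = 10
    sites_per_chrom: int = 20_000
    n_founders: int = 2_000          # half male, half female
    ne_target: int = 100             # {50, 100, 250} in the study grid
    n_qtl: int = 500                 # {200, 500, 1000}
    qtl_dist: str = "normal"         # "normal" (0,1) or "gamma" (shape 0.42)
    n_crosses: int = 2_000           # {1000, 2000, 4000, 8000}
    n_generations: int = 10          # {5, 10, 20}
    burn_in: int = 5
    selection: str = "tbv_truncation"  # or "random"
    sampling: str = "even"           # or "uneven"
    n_sampled: int = 10_000
    n_males_selected: int = 50
    n_females_selected: int = 500
    chrom_length_mb: float = 100.0
    recomb_factor: float = 1.0
    founder_burnin_generations: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_chrom", "sites_per_chrom", "n_founders", "ne_target",
                     "n_crosses", "n_generations", "n_sampled",
                     "n_males_selected", "n_females_selected"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_qtl < 0:
            raise ValueError("n_qtl must be non-negative")
        if self.selection not in {"tbv_truncation", "random"}:
            raise ValueError("selection must be 'tbv_truncation' or 'random'")
        if self.sampling not in {"even", "uneven"}:
            raise ValueError("sampling must be 'even' or 'uneven'")
        if self.qtl_dist not in {"normal", "gamma"}:
            raise ValueError("qtl_dist must be 'normal' or 'gamma'")


@dataclass
class HaplotypePool:
    """Phased haplotypes (2N x m, 0/1) with a physical map."""

    haps: np.ndarray
    chrom: np.ndarray      # site -> chromosome index (0-based)
    pos_bp: np.ndarray     # 1-based, strictly increasing within chromosome
    chrom_length_mb: float

    @property
    def n_individuals(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def frequencies(self) -> np.ndarray:
        return self.haps.mean(axis=0)

    def chromosome_slices(self) -> list[tuple[int, int]]:
        bounds = np.flatnonzero(np.diff(self.chrom)) + 1
        edges = np.concatenate([[0], bounds, [len(self.chrom)]])
        return list(zip(edges[:-1], edges[1:]))


@dataclass
class SimTruth:
    """Truth record of one simulated scenario."""

    scenario: Scenario
    chrom: np.ndarray
    pos_bp: np.ndarray
    qtl_idx: np.ndarray
    qtl_effects: np.ndarray
    qtl_freq: np.ndarray                # (n_generations + 1) x n_qtl, gen 0 first
    generation_dosage: list = field(default_factory=list)  # int8 (n, m) per gen
    generation_tbv: list = field(default_factory=list)
    generation_numbers: list = field(default_factory=list)

    def mean_tbv_by_generation(self) -> np.ndarray:
        return np.array([t.mean() for t in self.generation_tbv])


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def _batch_gametes(haps: np.ndarray, parents: np.ndarray,
                   slices: list[tuple[int, int]], pos_mb: list[np.ndarray],
                   chrom_length_mb: float, recomb_factor: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent (vectorized across parents).

    Crossover counts are Poisson(length_mb / 100 * recomb_factor) per
    chromosome, positions uniform, start phase random.  With recomb_factor 0
    every gamete is an unmodified parental haplotype.
    """
    n_gam = len(parents)
    m = haps.shape[1]
    out = np.empty((n_gam, m), dtype=np.uint8)
    hap_a = haps[2 * parents]
    hap_b = haps[2 * parents + 1]
    lam = chrom_length_mb / 100.0 * recomb_factor
    for (s, e), pmb in zip(slices, pos_mb):
        start = rng.integers(0, 2, size=n_gam)
        counts = rng.poisson(lam, size=n_gam) if lam > 0 else np.zeros(n_gam, int)
        kmax = int(counts.max())
        if kmax == 0:
            phase = np.broadcast_to(start[:, None], (n_gam, e - s))
        else:
            breaks = rng.uniform(0.0, chrom_length_mb, size=(n_gam, kmax))
            breaks[np.arange(kmax)[None, :] >= counts[:, None]] = np.inf
            breaks.sort(axis=1)
            n_before = (breaks[:, None, :] <= pmb[None, :, None]).sum(axis=2)
            phase = (start[:, None] + n_before) % 2
        out[:, s:e] = np.where(phase == 0, hap_a[:, s:e], hap_b[:, s:e])
    return out


def _mate(pool_haps: np.ndarray, sires: np.ndarray, dams: np.ndarray,
          slices, pos_mb, chrom_length_mb, recomb_factor,
          rng: np.random.Generator) -> np.ndarray:
    """Return offspring haplotypes (2 * n_off, m): paternal then maternal."""
    gam_s = _batch_gametes(pool_haps, sires, slices, pos_mb,
                           chrom_length_mb, recomb_factor, rng)
    gam_d = _batch_gametes(pool_haps, dams, slices, pos_mb,
                           chrom_length_mb, recomb_factor, rng)
    n_off, m = gam_s.shape
    out = np.empty((2 * n_off, m), dtype=np.uint8)
    out[0::2] = gam_s
    out[1::2] = gam_d
    return out


# ---------------------------------------------------------------------------
# Founders and architecture
# ---------------------------------------------------------------------------

def generate_founders(scenario: Scenario,
                      rng: np.random.Generator | None = None) -> HaplotypePool:
    """Standing-variation founders with drift-generated LD.

    Site frequencies are drawn with density proportional to 1/x on
    (0.01, 0.99) -- the neutral SFS shape -- with haplotypes initially in
    linkage equilibrium; 50 generations of random mating at ``ne_target``
    then impose drift and LD before a final expansion to ``n_founders``.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    m_c = scenario.sites_per_chrom
    m = scenario.n_chrom * m_c
    L_bp = int(scenario.chrom_length_mb * 1e6)

    chrom = np.repeat(np.arange(scenario.n_chrom), m_c)
    pos_bp = np.concatenate([
        np.sort(rng.integers(1, L_bp - m_c, size=m_c)) + np.arange(m_c)
        for _ in range(scenario.n_chrom)
    ])

    # 1/x density on (a, b) inverts to a * (b/a)**u
    a, b = 0.01, 0.99
    p = a * (b / a) ** rng.uniform(size=m)
    ne = scenario.ne_target
    haps = (rng.uniform(size=(2 * ne, m)) < p).astype(np.uint8)

    pool = HaplotypePool(haps=haps, chrom=chrom, pos_bp=pos_bp,
                         chrom_length_mb=scenario.chrom_length_mb)
    slices = pool.chromosome_slices()
    pos_mb = [pos_bp[s:e] / 1e6 for s, e in slices]

    sex = np.arange(ne) % 2  # 0 male, 1 female, alternating
    for _ in range(scenario.founder_burnin_generations):
        males = np.flatnonzero(sex == 0)
        females = np.flatnonzero(sex == 1)
        sires = rng.choice(males, size=ne)
        dams = rng.choice(females, size=ne)
        pool.haps = _mate(pool.haps, sires, dams, slices, pos_mb,
                          scenario.chrom_length_mb, scenario.recomb_factor, rng)
        sex = _balanced_sex(ne, rng)

    # expand to the founder census
    males = np.flatnonzero(sex == 0)
    females = np.flatnonzero(sex == 1)
    if len(males) == 0 or len(females) == 0:
        raise RuntimeError("burn-in population lost one sex entirely")
    nf = scenario.n_founders
    sires = rng.choice(males, size=nf)
    dams = rng.choice(females, size=nf)
    pool.haps = _mate(pool.haps, sires, dams, slices, pos_mb,
                      scenario.chrom_length_mb, scenario.recomb_factor, rng)

    frac_mono = float(np.mean((pool.frequencies() == 0) |
                              (pool.frequencies() == 1)))
    if frac_mono > 0.5:
        warnings.warn(f"{frac_mono:.0%} of sites monomorphic after burn-in",
                      stacklevel=2)
    return pool


def assign_qtl_architecture(pool: HaplotypePool, scenario: Scenario,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Pick QTL sites and draw their additive effects.

    QTL are sampled uniformly from segregating sites; effects come from
    N(0, 1) or gamma(shape 0.42) with a random sign.  All other sites are
    neutral.  Returns (qtl_idx, qtl_effects).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    freq = pool.frequencies()
    seg = np.flatnonzero((freq > 0) & (freq < 1))
    if scenario.n_qtl > len(seg):
        raise ValueError(f"n_qtl={scenario.n_qtl} exceeds {len(seg)} "
                         "segregating sites")
    qtl_idx = np.sort(rng.choice(seg, size=scenario.n_qtl, replace=False))
    if scenario.qtl_dist == "normal":
        effects = rng.normal(0.0, 1.0, size=scenario.n_qtl)
    else:
        effects = rng.gamma(shape=0.42, scale=1.0, size=scenario.n_qtl)
        effects *= rng.choice([-1.0, 1.0], size=scenario.n_qtl)
    return qtl_idx, effects


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------

def _balanced_sex(n: int, rng: np.random.Generator) -> np.ndarray:
    """Half male (0) / half female (1), randomly ordered."""
    sex = np.zeros(n, dtype=int)
    sex[n // 2:] = 1
    return rng.permutation(sex)


def _tbv(haps: np.ndarray, qtl_idx: np.ndarray,
         effects: np.ndarray) -> np.ndarray:
    dos = haps[0::2][:, qtl_idx].astype(np.float64) + \
        haps[1::2][:, qtl_idx].astype(np.float64)
    return dos @ effects


def _select_parents(tbv: np.ndarray, sex: np.ndarray, n_males: int,
                    n_females: int, random_selection: bool,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    males = np.flatnonzero(sex == 0)
    females = np.flatnonzero(sex == 1)
    if len(males) < n_males or len(females) < n_females:
        raise ValueError(
            f"candidate pool ({len(males)} M / {len(females)} F) smaller than "
            f"the selection quota ({n_males} M / {n_females} F)")
    if random_selection:
        keep_m = rng.choice(males, size=n_males, replace=False)
        keep_f = rng.choice(females, size=n_females, replace=False)
    else:
        keep_m = males[np.argsort(tbv[males])[::-1][:n_males]]
        keep_f = females[np.argsort(tbv[females])[::-1][:n_females]]
    return keep_m, keep_f


def simulate_scenario(scenario: Scenario,
                      pool: HaplotypePool | None = None,
                      qtl: tuple[np.ndarray, np.ndarray] | None = None,
                      rng: np.random.Generator | None = None) -> SimTruth:
    """Run burn-in plus the selection (or drift) phase, recording truth.

    Burn-in applies truncation selection on true breeding value (this is what
    fixes the largest-effect QTL before sampling starts); the post-burn-in
    phase selects parents either by TBV truncation or at random.  Every
    post-burn-in generation's QTL frequencies, breeding values and genotype
    dosages are stored.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    if pool is None:
        pool = generate_founders(scenario, rng)
    if qtl is None:
        qtl_idx, effects = assign_qtl_architecture(pool, scenario, rng)
    else:
        qtl_idx, effects = qtl

    slices = pool.chromosome_slices()
    pos_mb = [pool.pos_bp[s:e] / 1e6 for s, e in slices]
    haps = pool.haps
    sex = _balanced_sex(haps.shape[0] // 2, rng)

    def advance(haps, sex, random_selection):
        tbv = _tbv(haps, qtl_idx, effects)
        keep_m, keep_f = _select_parents(
            tbv, sex, scenario.n_males_selected, scenario.n_females_selected,
            random_selection, rng)
        sires = rng.choice(keep_m, size=scenario.n_crosses)
        dams = rng.choice(keep_f, size=scenario.n_crosses)
        new = _mate(haps, sires, dams, slices, pos_mb,
                    scenario.chrom_length_mb, scenario.recomb_factor, rng)
        new_sex = _balanced_sex(scenario.n_crosses, rng)
        return new, new_sex

    for _ in range(scenario.burn_in):
        haps, sex = advance(haps, sex, random_selection=False)

    truth = SimTruth(
        scenario=scenario, chrom=pool.chrom, pos_bp=pool.pos_bp,
        qtl_idx=qtl_idx, qtl_effects=effects,
        qtl_freq=np.empty((scenario.n_generations + 1, scenario.n_qtl)),
    )
    truth.qtl_freq[0] = haps[:, qtl_idx].mean(axis=0)

    random_sel = scenario.selection == "random"
    for g in range(1, scenario.n_generations + 1):
        haps, sex = advance(haps, sex, random_selection=random_sel)
        truth.qtl_freq[g] = haps[:, qtl_idx].mean(axis=0)
        dosage = (haps[0::2] + haps[1::2]).astype(np.int8)
        truth.generation_dosage.append(dosage)
        truth.generation_tbv.append(_tbv(haps, qtl_idx, effects))
        truth.generation_numbers.append(g)
    return truth


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def uneven_sampling_rate(n_generations: int, recent_mass: float = 0.6,
                         recent_window: int = 3) -> float:
    """Decay rate r with counts ~ exp(-r (G - g)) putting ``recent_mass``
    of the samples in the last ``recent_window`` generations."""
    if n_generations <= recent_window:
        return 0.0
    from scipy.optimize import brentq

    gens = np.arange(1, n_generations + 1)

    def mass(r):
        w = np.exp(-r * (n_generations - gens))
        return w[-recent_window:].sum() / w.sum() - recent_mass

    if mass(1e-12) >= 0:  # even sampling already concentrates enough
        return 0.0
    return brentq(mass, 1e-12, 20.0)


def sample_individuals(truth: SimTruth, sampling: str | None = None,
                       n_sampled: int | None = None, rate: float | None = None,
                       seed: int | None = None
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw the genotyped panel across generations.

    ``even`` takes n/G per generation; ``uneven`` weights generations by a
    negative-exponential in age so the most recent three generations hold
    about 60% of the panel (mimicking how commercial genotyping concentrates
    on young animals).  Individuals are drawn uniformly within a generation
    and sampling has no effect on who becomes a parent.
    """
    scenario = truth.scenario
    sampling = sampling or scenario.sampling
    n_sampled = n_sampled or scenario.n_sampled
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    G = len(truth.generation_numbers)

    if sampling == "even":
        base = n_sampled // G
        counts = np.full(G, base)
        rem = n_sampled - base * G
        if rem:
            counts[-rem:] += 1
    else:
        r = uneven_sampling_rate(G) if rate is None else rate
        gens = np.arange(1, G + 1)
        w = np.exp(-r * (G - gens))
        counts = np.floor(w / w.sum() * n_sampled).astype(int)
        counts[-1] += n_sampled - counts.sum()

    rows, ids, gens_out = [], [], []
    for gi, (gen, dosage) in enumerate(zip(truth.generation_numbers,
                                           truth.generation_dosage)):
        want = int(counts[gi])
        avail = dosage.shape[0]
        if want > avail:
            warnings.warn(f"generation {gen} exhausted ({avail} < {want}); "
                          "sampling all", stacklevel=2)
            want = avail
        idx = rng.choice(avail, size=want, replace=False)
        rows.append(dosage[idx].astype(np.float64))
        ids.extend(f"g{gen}_i{j}" for j in idx)
        gens_out.extend([gen] * want)

    dosage = np.vstack(rows)
    snps = pd.DataFrame({
        "chrom": (truth.chrom + 1).astype(str),
        "pos_bp": truth.pos_bp,
        "id": [f"snp_{c + 1}_{p}" for c, p in zip(truth.chrom, truth.pos_bp)],
        "allele1": "A", "allele0": "B",
    })
    geno = GenotypeMatrix(samples=ids, snps=snps, dosage=dosage)
    samples = pd.DataFrame({
        "id": ids, "generation": gens_out,
        "birthdate_age": np.asarray(gens_out, dtype=float),
    })
    return geno, samples


# ---------------------------------------------------------------------------
# Performance evaluation
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    """True/false positive accounting for one scanned panel."""

    n_tests: int
    n_significant: int
    true_positives: int
    false_positives: int
    n_detectable_qtl: int
    prop_detected: float          # QTL themselves reaching significance
    qtl_loci_recovered: int       # QTL with a significant SNP within the window
    prop_loci_detected: float
    fp_per_200k: float
    pve: float
    gpsm: GpsmResult


def evaluate_gpsm_performance(geno: GenotypeMatrix, samples: pd.DataFrame,
                              truth: SimTruth, q_threshold: float = 0.1,
                              fp_window_bp: int = 1_000_000,
                              config: ScanConfig | None = None
                              ) -> PerformanceReport:
    """Scan the panel with generation number as the phenotype and score it.

    True positives are simulated QTL reaching q < threshold.  The detectable
    denominator excludes QTL fixed before or during sampling (and QTL below
    the scan's MAF filter in the panel) -- the scan cannot see a site that no
    longer segregates.  Under random mating every significant site is a false
    positive; under selection, significant non-QTL sites within
    ``fp_window_bp`` of a QTL are attributed to linkage and not counted.
    """
    cfg = config or ScanConfig()
    result = run_gpsm(geno, samples, config=cfg, q_threshold=max(q_threshold, 0.0))
    q = result.assoc["q"].to_numpy()
    sig = np.flatnonzero(q < q_threshold)
    qtl_set = set(truth.qtl_idx.tolist())

    final_freq = truth.qtl_freq[-1]
    panel_maf = geno.maf()[truth.qtl_idx]
    detectable = (final_freq > 0) & (final_freq < 1) & \
        (np.nan_to_num(panel_maf) > cfg.maf_min)
    detectable_idx = set(truth.qtl_idx[detectable].tolist())

    tp = sum(1 for s in sig if s in qtl_set)
    tp_detectable = sum(1 for s in sig if s in detectable_idx)

    # locus-level recovery: a QTL counts as found when any significant SNP
    # sits within the linkage window around it
    sig_pos_by_chrom: dict = {}
    for s in sig:
        sig_pos_by_chrom.setdefault(truth.chrom[s], []).append(truth.pos_bp[s])
    sig_pos_by_chrom = {c: np.array(sorted(p))
                        for c, p in sig_pos_by_chrom.items()}
    loci_recovered = 0
    for i in truth.qtl_idx[detectable]:
        near = sig_pos_by_chrom.get(truth.chrom[i])
        if near is not None and \
                np.min(np.abs(near - truth.pos_bp[i])) <= fp_window_bp:
            loci_recovered += 1

    if truth.scenario.selection == "random":
        fp = len(sig)
    else:
        fp = 0
        qtl_pos = {}
        for i in truth.qtl_idx:
            qtl_pos.setdefault(truth.chrom[i], []).append(truth.pos_bp[i])
        qtl_pos = {c: np.array(sorted(p)) for c, p in qtl_pos.items()}
        for s in sig:
            if s in qtl_set:
                continue
            pos = truth.pos_bp[s]
            near = qtl_pos.get(truth.chrom[s])
            if near is not None and np.min(np.abs(near - pos)) <= fp_window_bp:
                continue  # linkage shadow of a real QTL
            fp += 1

    n_tests = int(result.assoc["tested"].sum())
    n_det = int(detectable.sum())
    return PerformanceReport(
        n_tests=n_tests, n_significant=len(sig), true_positives=tp,
        false_positives=fp, n_detectable_qtl=n_det,
        prop_detected=tp_detectable / n_det if n_det else np.nan,
        qtl_loci_recovered=loci_recovered,
        prop_loci_detected=loci_recovered / n_det if n_det else np.nan,
        fp_per_200k=fp / n_tests * 200_000 if n_tests else np.nan,
        pve=result.pve.pve, gpsm=result,
    )


def pve_metaregression(table: pd.DataFrame, response: str = "pve",
                       predictors: list[str] | None = None):
    """OLS of per-replicate PVE on scenario covariates.

    Categorical predictors (e.g. the QTL effect distribution) are handled by
    patsy ``C()``; single-level predictors are aliased and reported rather
    than silently dropped.
    """
    import statsmodels.formula.api as smf

    predictors = predictors or [c for c in table.columns if c != response]
    aliased = [p for p in predictors if table[p].nunique() <= 1]
    used = [p for p in predictors if p not in aliased]
    if not used:
        raise ValueError(f"all predictors aliased: {aliased}")
    terms = []
    for p in used:
        terms.append(f"C({p})" if table[p].dtype == object else p)
    if table[response].nunique() <= 1:
        params = pd.DataFrame({
            "coef": np.zeros(len(used)), "p": np.ones(len(used))}, index=used)
        return {"params": params, "fvalue": np.nan, "aliased": aliased,
                "model": None}
    model = smf.ols(f"{response} ~ {' + '.join(terms)}", data=table).fit()
    params = pd.DataFrame({"coef": model.params, "p": model.pvalues})
    return {"params": params, "fvalue": float(model.fvalue),
            "aliased": aliased, "model": model}
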