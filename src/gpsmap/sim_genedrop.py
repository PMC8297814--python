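"""Pedigree gene-drop null for the generation-proxy scan.

Founder haplotypes are dropped through a fixed pedigree in Mendelian fashion
with recombination, so the only association between generation number and
genotype is the one pedigree structure itself creates.  Scanning the
resulting panels measures how many "significant" loci family structure alone
produces -- the null against which real selection signal is judged.

Crossovers occur at a configurable rate per Mb.  The default of one per Mb
reproduces the published null design as printed; a biological map
(~1 cM/Mb, i.e. 0.01 crossovers per Mb) is a flag away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gpsm import clump_loci, run_gpsm
from .io_formats import GenotypeMatrix
from .lmm_core import ScanConfig
from .sim_forward import _batch_gametes

logger = logging.getLogger(__name__)

__all__ = [
    "synthetic_pedigree",
    "pedigree_generations",
    "gene_drop",
    "genedrop_null_rate",
]

BIOLOGICAL_CROSSOVER_RATE_PER_MB = 0.01  # ~1 cM/Mb


def synthetic_pedigree(n_founders: int = 200, n_generations: int = 5,
                       offspring_rate: float = 1.0, overlap: float = 0.0,
                       sire_reuse: float = 0.0,
                       seed: int | None = None) -> pd.DataFrame:
    """Random-mating pedigree with configurable sire reuse and overlap.

    ``offspring_rate`` scales each generation's size relative to the founder
    census.  ``overlap`` is the probability a parent is drawn from any earlier
    generation instead of the immediately previous one.  ``sire_reuse`` in
    [0, 1) concentrates paternity geometrically on a few sires, mimicking
    heavily used artificial-insemination bulls.  Rows are topologically
    sorted; founders have sire = dam = 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    next_id = 1
    generations: list[dict] = []

    founders = {"male": [], "female": []}
    for _ in range(n_founders):
        sex = "male" if rng.random() < 0.5 else "female"
        founders[sex].append(next_id)
        rows.append((next_id, 0, 0, 0))
        next_id += 1
    if not founders["male"] or not founders["female"]:
        raise ValueError("founder cohort must contain both sexes")
    generations.append(founders)

    n_off = max(int(round(offspring_rate * n_founders)), 2)
    for g in range(1, n_generations + 1):
        cohort = {"male": [], "female": []}
        for _ in range(n_off):
            gen_s = _pick_generation(generations, overlap, rng)
            gen_d = _pick_generation(generations, overlap, rng)
            sire = _pick_parent(gen_s["male"], sire_reuse, rng)
            dam = _pick_parent(gen_d["female"], 0.0, rng)
            sex = "male" if rng.random() < 0.5 else "female"
            cohort[sex].append(next_id)
            rows.append((next_id, sire, dam, g))
            next_id += 1
        if not cohort["male"]:
            cohort["male"].append(cohort["female"].pop())
        if not cohort["female"]:
            cohort["female"].append(cohort["male"].pop())
        generations.append(cohort)

    ped = pd.DataFrame(rows, columns=["id", "sire", "dam", "cohort"])
    return ped.drop(columns="cohort")


def _pick_generation(generations, overlap, rng):
    usable = [g for g in generations if g["male"] and g["female"]]
    if len(usable) > 1 and rng.random() < overlap:
        return usable[int(rng.integers(0, len(usable) - 1))]
    return usable[-1]


def _pick_parent(candidates: list[int], reuse: float,
                 rng: np.random.Generator) -> int:
    if not 0.0 <= reuse < 1.0:
        raise ValueError("sire_reuse must be in [0, 1)")
    if reuse == 0.0 or len(candidates) == 1:
        return int(rng.choice(candidates))
    ranks = np.arange(len(candidates))
    w = (1.0 - reuse) ** ranks
    return int(rng.choice(candidates, p=w / w.sum()))


def pedigree_generations(ped: pd.DataFrame) -> pd.Series:
    """Generation number per individual: longest path from a founder.

    Also validates the pedigree: parents must precede offspring (acyclic,
    topologically sorted) and nobody is their own ancestor in a single step.
    """
    gen: dict[int, int] = {}
    for rec in ped.itertuples(index=False):
        ind, sire, dam = int(rec.id), int(rec.sire), int(rec.dam)
        if ind in (sire, dam):
            raise ValueError(f"individual {ind} is its own parent")
        g = 0
        for par in (sire, dam):
            if par == 0:
                continue
            if par not in gen:
                raise ValueError(
                    f"parent {par} of {ind} appears later in the pedigree or "
                    "is missing (need topological order; 0 = unknown)")
            g = max(g, gen[par] + 1)
        gen[ind] = g
    return pd.Series(gen, name="generation")


def gene_drop(ped: pd.DataFrame, founder_haps: np.ndarray,
              chrom: np.ndarray, pos_bp: np.ndarray,
              crossover_rate_per_mb: float = 1.0,
              seed: int | None = None,
              emit: str | list = "all") -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop phased founder haplotypes through the pedigree.

    Each transmission is a recombinant gamete: crossover count
    Poisson(rate x chromosome Mb), uniform positions, random start phase.
    ``emit`` selects whose genotypes to output: "all", "last" (the deepest
    generation) or an explicit list of ids.  Returns the genotype panel plus
    a sample table with generation numbers (the scan's dependent variable).
    """
    gens = pedigree_generations(ped)
    founder_ids = ped.loc[(ped["sire"] == 0) & (ped["dam"] == 0), "id"].tolist()
    n_f = len(founder_ids)
    founder_haps = np.asarray(founder_haps, dtype=np.uint8)
    if founder_haps.shape[0] != 2 * n_f:
        raise ValueError(f"{founder_haps.shape[0]} founder haplotypes for "
                         f"{n_f} pedigree founders (need 2 per founder)")
    m = founder_haps.shape[1]
    chrom = np.asarray(chrom)
    pos_bp = np.asarray(pos_bp)

    bounds = np.flatnonzero(np.diff(chrom)) + 1
    edges = np.concatenate([[0], bounds, [m]])
    slices = list(zip(edges[:-1], edges[1:]))
    length_mb = float(pos_bp.max()) / 1e6
    pos_mb = [pos_bp[s:e] / 1e6 for s, e in slices]

    rng = np.random.default_rng(seed)
    haps: dict[int, np.ndarray] = {}
    for i, fid in enumerate(founder_ids):
        haps[fid] = founder_haps[2 * i:2 * i + 2]

    # _batch_gametes draws Poisson(length_mb / 100 * factor) crossovers, so a
    # per-Mb rate maps to factor = rate * 100
    recomb_factor = crossover_rate_per_mb * 100.0

    def gamete_from(parent_id: int) -> np.ndarray:
        pair = haps[parent_id]
        return _batch_gametes(pair.reshape(2, m), np.array([0]), slices,
                              pos_mb, length_mb, recomb_factor, rng)[0]

    for rec in ped.itertuples(index=False):
        ind, sire, dam = int(rec.id), int(rec.sire), int(rec.dam)
        if sire == 0 and dam == 0:
            continue
        if sire == 0 or dam == 0:
            raise ValueError(f"individual {ind} has exactly one known parent; "
                             "gene drop needs both or neither")
        haps[ind] = np.stack([gamete_from(sire), gamete_from(dam)])

    if emit == "all":
        emit_ids = ped["id"].tolist()
    elif emit == "last":
        deepest = int(gens.max())
        emit_ids = [i for i in ped["id"] if gens[i] == deepest]
    else:
        emit_ids = list(emit)

    dosage = np.array([haps[i][0] + haps[i][1] for i in emit_ids],
                      dtype=np.float64)
    snps = pd.DataFrame({
        "chrom": (chrom + 1).astype(str), "pos_bp": pos_bp,
        "id": [f"snp_{c + 1}_{p}" for c, p in zip(chrom, pos_bp)],
        "allele1": "A", "allele0": "B",
    })
    geno = GenotypeMatrix(samples=[str(i) for i in emit_ids], snps=snps,
                          dosage=dosage)
    samples = pd.DataFrame({
        "id": [str(i) for i in emit_ids],
        "generation": [int(gens[i]) for i in emit_ids],
        "birthdate_age": [float(gens[i]) for i in emit_ids],
    })
    return geno, samples


def sfs_founder_haplotypes(n_founders: int, n_sites: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Founder haplotypes with 1/x-density site frequencies (no LD)."""
    a, b = 0.01, 0.99
    p = a * (b / a) ** rng.uniform(size=n_sites)
    return (rng.uniform(size=(2 * n_founders, n_sites)) < p).astype(np.uint8)


def genedrop_null_rate(ped: pd.DataFrame, n_sites: int = 2_000,
                       n_chrom: int = 2, n_replicates: int = 10,
                       crossover_rate_per_mb: float = 1.0,
                       chrom_length_mb: float = 100.0,
                       q_threshold: float = 0.1,
                       seed: int | None = None,
                       config: ScanConfig | None = None) -> pd.DataFrame:
    """Significant-locus counts per gene-drop replicate, per 200K markers.

    Each replicate draws fresh founder haplotypes, drops them through the
    pedigree, scans with generation number as the phenotype, clumps q <
    threshold SNPs at 1 Mb and normalizes the locus count to 200,000 tests.
    """
    if n_replicates == 0:
        return pd.DataFrame(columns=["replicate", "n_loci", "n_tests",
                                     "loci_per_200k", "pve"])
    rng = np.random.default_rng(seed)
    n_f = int(((ped["sire"] == 0) & (ped["dam"] == 0)).sum())
    sites_per_chrom = n_sites // n_chrom
    chrom = np.repeat(np.arange(n_chrom), sites_per_chrom)
    L_bp = int(chrom_length_mb * 1e6)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        pos_bp = np.concatenate([
            np.sort(rep_rng.integers(1, L_bp - sites_per_chrom,
                                     size=sites_per_chrom))
            + np.arange(sites_per_chrom)
            for _ in range(n_chrom)
        ])
        founder_haps = sfs_founder_haplotypes(n_f, len(chrom), rep_rng)
        geno, samples = gene_drop(ped, founder_haps, chrom, pos_bp,
                                  crossover_rate_per_mb=crossover_rate_per_mb,
                                  seed=rep_seed)
        result = run_gpsm(geno, samples, config=config,
                          q_threshold=q_threshold)
        n_tests = int(result.assoc["tested"].sum())
        n_loci = len(result.loci)
        rows.append({
            "replicate": rep, "seed": rep_seed, "n_loci": n_loci,
            "n_tests": n_tests,
            "loci_per_200k": n_loci / n_tests * 200_000 if n_tests else np.nan,
            "pve": result.pve.pve,
        })
    return pd.DataFrame(rows)
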