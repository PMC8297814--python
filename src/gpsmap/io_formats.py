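"""Readers and writers for the file formats the toolkit touches.

Supported formats: PLINK 1.9 binary genotypes (bed/bim/fam, SNP-major),
tab-delimited sample tables with birth dates, GFF3/BED gene annotation and the
canonical columnar association-results table.

Conventions
-----------
* Dosage counts copies of allele1 (BIM column 5), matching PLINK: code ``00``
  decodes to dosage 2, ``10`` to 1, ``11`` to 0 and ``01`` to missing.
* Internal interval coordinates are 0-based half-open; everything user-facing
  is 1-based bp as in BIM/GFF3.
* Missing genotypes are kept missing (NaN) at read time; mean imputation only
  happens inside GRM construction and scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "FormatError",
    "read_plink",
    "write_plink",
    "read_sample_table",
    "write_assoc_table",
    "read_assoc_table",
    "read_gene_annotation",
]

ASSOC_COLUMNS = ["chr", "rs", "ps", "af", "beta", "se", "p_wald", "q"]

#: chromosome labels never treated as autosomes
_NON_AUTOSOMAL = {"X", "Y", "MT", "M", "XY", "0"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """An n-samples x m-SNPs dosage matrix with per-SNP metadata.

    Attributes
    ----------
    samples : list of str
        Sample identifiers in row order.
    snps : pandas.DataFrame
        One row per SNP with columns ``chrom``, ``pos_bp`` (1-based), ``id``,
        ``allele1`` (counted allele), ``allele0``.
    dosage : numpy.ndarray
        Float array of shape (n, m) with values in [0, 2]; missing is NaN.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample IDs for {n} dosage rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNP records for {m} dosage columns")
        if len(set(self.samples)) != n:
            raise FormatError("duplicate sample IDs")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError("dosage values outside [0, 2]")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Frequency of allele1 per SNP, ignoring missing; NaN if all missing."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP (NaN where undefined)."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/SNP indices."""
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in sample_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            dosage=self.dosage[np.ix_(sample_idx, snp_idx)],
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> dosage of allele1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _decode_bed_bytes(raw: np.ndarray, n_samples: int) -> np.ndarray:
    """Decode one SNP's packed bytes into an n-vector of dosages."""
    codes = np.empty(len(raw) * 4, dtype=np.uint8)
    for shift in range(4):
        codes[shift::4] = (raw >> (2 * shift)) & 0b11
    return _CODE_TO_DOSAGE[codes[:n_samples]]


def read_plink(prefix: str | Path, autosomes_only: bool = True) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    prefix : str or Path
        Path without extension; ``prefix.bed``, ``.bim`` and ``.fam`` must exist.
    autosomes_only : bool
        Drop records on X/Y/MT/unplaced chromosomes (logged).
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FormatError(f"missing file: {prefix.with_suffix(ext)}")

    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    samples = fam["iid"].tolist()
    if len(set(samples)) != len(samples):
        raise FormatError(f"duplicate sample IDs in {prefix.with_suffix('.fam')}")

    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos_bp", "allele1", "allele0"],
        dtype={"chrom": str, "id": str, "allele1": str, "allele0": str},
    )

    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise FormatError(f"bad magic bytes in {prefix.with_suffix('.bed')} (need SNP-major v1.9 bed)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"truncated or oversized bed {prefix.with_suffix('.bed')}: "
            f"{len(raw)} bytes, expected {expected}"
        )
    body = raw[3:].reshape(m, bytes_per_snp)
    dosage = np.empty((n, m), dtype=np.float64)
    for j in range(m):
        dosage[:, j] = _decode_bed_bytes(body[j], n)

    if autosomes_only:
        keep = ~bim["chrom"].str.upper().isin(_NON_AUTOSOMAL)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d non-autosomal records from %s", n_drop, prefix)
            bim = bim[keep].reset_index(drop=True)
            dosage = dosage[:, keep.to_numpy()]

    all_missing = np.all(np.isnan(dosage), axis=0)
    if all_missing.any():
        logger.warning("%d SNPs have no called genotypes", int(all_missing.sum()))

    snps = bim[["chrom", "pos_bp", "id", "allele1", "allele0"]].copy()
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.dosage.shape

    fam = pd.DataFrame({
        "fid": geno.samples, "iid": geno.samples,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame({
        "chrom": geno.snps["chrom"], "id": geno.snps["id"], "cm": 0,
        "pos_bp": geno.snps["pos_bp"],
        "allele1": geno.snps["allele1"], "allele0": geno.snps["allele0"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    # dosage -> 2-bit codes (hard calls only; fractional dosages are rounded)
    d = geno.dosage
    codes = np.full((n, m), 1, dtype=np.uint8)  # 01 = missing
    with np.errstate(invalid="ignore"):
        rounded = np.round(d)
    codes[rounded == 2] = 0b00
    codes[rounded == 1] = 0b10
    codes[rounded == 0] = 0b11

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------

def read_sample_table(
    path: str | Path,
    reference_date: str | date = "2017-04-05",
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited sample table and derive continuous age.

    The table must have an ``id`` column and a ``birth_date`` column
    (ISO dates); ``zip``, ``lat``, ``lon`` and ``ecoregion`` columns are kept
    when present.  ``birthdate_age`` is the age in fractional years at
    ``reference_date`` and serves as the generation proxy.
    """
    if isinstance(reference_date, str):
        reference_date = datetime.strptime(reference_date, "%Y-%m-%d").date()
    tab = pd.read_csv(path, sep=sep, dtype={"id": str, "zip": str})
    if "id" not in tab.columns:
        raise FormatError(f"{path}: no 'id' column")
    if tab["id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs")

    if "birth_date" in tab.columns:
        ages = np.full(len(tab), np.nan)
        for i, raw in enumerate(tab["birth_date"]):
            if pd.isna(raw):
                continue
            try:
                bd = datetime.strptime(str(raw), "%Y-%m-%d").date()
            except ValueError as exc:
                raise FormatError(f"{path} line {i + 2}: unparseable birth date {raw!r}") from exc
            ages[i] = (reference_date - bd).days / 365.25
        if np.any(ages < 0):
            warnings.warn("birth dates after the reference date give negative ages", stacklevel=2)
        tab["birthdate_age"] = ages
    elif "birthdate_age" not in tab.columns:
        raise FormatError(f"{path}: need a 'birth_date' or 'birthdate_age' column")
    return tab


def write_sample_table(tab: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

def write_assoc_table(assoc: pd.DataFrame, path: str | Path) -> None:
    """Write an association table with fixed column order.

    Columns are ``chr rs ps af beta se p_wald q`` (GEMMA-style); a missing
    ``q`` column is written as NA.  Floats round-trip at 12 significant digits.
    """
    out = pd.DataFrame()
    rename = {"chrom": "chr", "id": "rs", "pos_bp": "ps"}
    src = assoc.rename(columns=rename)
    for col in ASSOC_COLUMNS:
        out[col] = src[col] if col in src.columns else np.nan
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_assoc_table(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chr": str, "rs": str})
    missing = [c for c in ASSOC_COLUMNS if c not in tab.columns]
    if missing:
        raise FormatError(f"{path}: missing association columns {missing}")
    return tab


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene intervals from GFF3 or BED.

    Returns a frame with ``chrom``, ``start``, ``end`` (0-based half-open) and
    ``name``.  GFF3 coordinates (1-based inclusive) are converted; BED is taken
    as-is.  Malformed lines are skipped and counted in the log.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    is_gff = path.suffix.lower() in {".gff", ".gff3"} or (first.count("\t") >= 8)

    records, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("browser") or line.startswith("track"):
                continue
            parts = line.split("\t")
            try:
                if is_gff:
                    if len(parts) < 9:
                        raise ValueError
                    if parts[2] != feature:
                        continue
                    start, end = int(parts[3]) - 1, int(parts[4])
                    name = _gff_attr(parts[8])
                    records.append((parts[0], start, end, name))
                else:
                    if len(parts) < 3:
                        raise ValueError
                    start, end = int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
                    records.append((parts[0], start, end, name))
            except ValueError:
                skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed lines", path, skipped)
    genes = pd.DataFrame(records, columns=["chrom", "start", "end", "name"])
    if (genes["end"] <= genes["start"]).any():
        raise FormatError(f"{path}: empty or inverted intervals")
    return genes


def _gff_attr(attrs: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
    )
    return fields.get("Name", fields.get("ID", attrs))


def write_gene_annotation_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene intervals back to GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in genes.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t.\tgene\t{rec.start + 1}\t{rec.end}\t.\t+\t.\t"
                f"ID={rec.name};Name={rec.name}\n"
            )
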