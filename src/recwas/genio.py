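"""Plain-text genotype, peak, phenotype, weight and result I/O.

Genotypes travel as PLINK transposed text (``.tped``/``.tfam``), peaks as
BED (0-based, half-open), everything tabular as TSV.  Genotypes are recoded
to counts of the minor allele, with the minor allele determined per variant
from the observed allele frequency; ``0 0`` calls (and half-missing calls)
become missing values (NaN in the matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ParseError
from ._utils import impute_column_mean, standardize_columns

__all__ = [
    "VariantRecord", "PeakRegion", "GenotypeDataset", "WeightVector",
    "read_tped_tfam", "write_tped_tfam", "compute_maf", "extract_cis_window",
    "read_bed", "write_bed", "read_weights", "write_weights",
    "read_phenotype", "write_phenotype", "read_results", "write_results",
]

MISSING = np.nan


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP.  ``allele_a`` is the counted (minor) allele."""
    chrom: str
    pos: int
    id: str
    allele_a: str = "A"
    allele_b: str = "B"
    maf: float = np.nan

    def __post_init__(self):
        if self.pos < 1:
            raise ParseError(f"variant {self.id}: position {self.pos} < 1")
        if self.allele_a == self.allele_b:
            raise ParseError(f"variant {self.id}: identical alleles")


@dataclass(frozen=True)
class PeakRegion:
    """A ChIP-seq peak interval in BED convention (0-based, half-open)."""
    chrom: str
    start: int
    end: int
    peak_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ParseError(
                f"peak {self.peak_id}: start {self.start} >= end {self.end}")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class WeightVector:
    """Per-SNP effect sizes linking cis-genotypes to peak activity.

    Weights live on the standardized-genotype scale (the same scale the
    kernel and prediction code use).
    """
    variant_ids: list
    weights: np.ndarray
    method: str = "lasso"
    cv_p: float | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variant_ids) != self.weights.size:
            raise ValueError("ids and weights length mismatch")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")

    @property
    def is_null(self) -> bool:
        """True when every weight is zero (the 'null model' outcome)."""
        return not np.any(self.weights != 0.0)


class GenotypeDataset:
    """n samples x p SNPs of minor-allele counts {0, 1, 2} (NaN = missing)."""

    def __init__(self, samples: Sequence[str],
                 variants: Sequence[VariantRecord], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(samples), len(variants)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants")
        ok = np.isnan(matrix) | np.isin(matrix, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        self.samples = list(samples)
        self.variants = list(variants)
        self.matrix = matrix

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list:
        return [v.id for v in self.variants]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=int)

    def maf(self) -> np.ndarray:
        return np.array([compute_maf(self.matrix[:, j])
                         for j in range(self.n_variants)])

    def subset_variants(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(self.samples,
                               [self.variants[i] for i in index],
                               self.matrix[:, index])

    def imputed(self) -> np.ndarray:
        return impute_column_mean(self.matrix)

    def standardized(self) -> np.ndarray:
        return standardize_columns(self.matrix)


# ---------------------------------------------------------------------------
# PLINK transposed text
# ---------------------------------------------------------------------------

def read_tped_tfam(tped_path, tfam_path) -> GenotypeDataset:
    """Read PLINK transposed text genotypes.

    Alleles are recoded to minor-allele counts per variant; a frequency tie
    at 0.5 is broken toward the lexicographically smaller allele.  ``0`` in
    either slot of a call marks the call missing.
    """
    samples = []
    with open(tfam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 2:
                raise ParseError(f"{tfam_path}:{lineno}: expected >=2 fields")
            samples.append(tok[1])
    n = len(samples)
    if n == 0:
        raise ParseError(f"{tfam_path}: no samples")

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    with open(tped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4 + 2 * n:
                raise ParseError(
                    f"{tped_path}:{lineno}: expected {4 + 2 * n} tokens "
                    f"for {n} samples, got {len(tok)}")
            chrom, vid, _cm, pos = tok[:4]
            calls = tok[4:]
            a1 = calls[0::2]
            a2 = calls[1::2]
            counts: dict[str, int] = {}
            for a, b in zip(a1, a2):
                if a == "0" or b == "0":
                    continue
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            alleles = sorted(counts)
            if len(alleles) > 2:
                raise ParseError(
                    f"{tped_path}:{lineno}: variant {vid} has "
                    f"{len(alleles)} alleles: {alleles}")
            if len(alleles) == 0:
                minor, major = "A", "B"  # fully missing variant
            elif len(alleles) == 1:
                minor, major = alleles[0], "?"
            else:
                f0 = counts[alleles[0]]
                f1 = counts[alleles[1]]
                if f0 < f1:
                    minor, major = alleles[0], alleles[1]
                elif f1 < f0:
                    minor, major = alleles[1], alleles[0]
                else:  # tie at MAF 0.5: lexicographically smaller is minor
                    minor, major = alleles[0], alleles[1]
            col = np.full(n, MISSING)
            for i, (a, b) in enumerate(zip(a1, a2)):
                if a == "0" or b == "0":
                    continue
                col[i] = (a == minor) + (b == minor)
            nonmiss = ~np.isnan(col)
            maf = (col[nonmiss].sum() / (2.0 * nonmiss.sum())
                   if nonmiss.any() else np.nan)
            variants.append(VariantRecord(chrom=chrom, pos=int(pos), id=vid,
                                          allele_a=minor, allele_b=major,
                                          maf=min(maf, 1 - maf)
                                          if np.isfinite(maf) else np.nan))
            columns.append(col)
    matrix = (np.column_stack(columns) if columns
              else np.empty((n, 0)))
    return GenotypeDataset(samples, variants, matrix)


def write_tped_tfam(dataset: GenotypeDataset, tped_path, tfam_path) -> None:
    with open(tfam_path, "w") as fh:
        for s in dataset.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    code = {2.0: None, 1.0: None, 0.0: None}  # filled per variant
    with open(tped_path, "w") as fh:
        for j, v in enumerate(dataset.variants):
            code[2.0] = f"{v.allele_a} {v.allele_a}"
            code[1.0] = f"{v.allele_a} {v.allele_b}"
            code[0.0] = f"{v.allele_b} {v.allele_b}"
            calls = ["0 0" if np.isnan(g) else code[g]
                     for g in dataset.matrix[:, j]]
            fh.write(f"{v.chrom} {v.id} 0 {v.pos} " + " ".join(calls) + "\n")


# ---------------------------------------------------------------------------
# Frequencies and windows
# ---------------------------------------------------------------------------

def compute_maf(column: np.ndarray) -> float:
    """Minor-allele frequency of one genotype column, missing excluded."""
    col = np.asarray(column, dtype=float)
    nonmiss = ~np.isnan(col)
    m = int(nonmiss.sum())
    if m == 0:
        raise DegenerateDataError("all genotypes missing in column")
    f = float(col[nonmiss].sum()) / (2.0 * m)
    return min(f, 1.0 - f)


def extract_cis_window(dataset: GenotypeDataset, peak: PeakRegion,
                       half_width_bp: int) -> GenotypeDataset:
    """Variants on the peak's chromosome within +-half_width of its center
    (both boundaries inclusive).  An empty selection is a valid result."""
    if half_width_bp <= 0:
        raise ValueError("half_width_bp must be positive")
    center = peak.center
    keep = [(v.chrom == peak.chrom
             and center - half_width_bp <= v.pos <= center + half_width_bp)
            for v in dataset.variants]
    return dataset.subset_variants(np.array(keep, dtype=bool))


# ---------------------------------------------------------------------------
# BED / TSV plumbing
# ---------------------------------------------------------------------------

def read_bed(path) -> list[PeakRegion]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok or tok[0].startswith(("#", "track", "browser")):
                continue
            if len(tok) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(tok[1]), int(tok[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates") from exc
            name = tok[3] if len(tok) > 3 else f"peak{lineno}"
            peaks.append(PeakRegion(tok[0], start, end, name))
    return peaks


def write_bed(peaks: Iterable[PeakRegion], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


def read_weights(path) -> WeightVector:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "weight", "method"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: weight table needs columns {required}")
    method = str(df["method"].iloc[0]) if len(df) else "lasso"
    cv_p = float(df["cv_p"].iloc[0]) if "cv_p" in df.columns and len(df) \
        else None
    return WeightVector(list(df["variant_id"].astype(str)),
                        df["weight"].to_numpy(float), method, cv_p)


def write_weights(wv: WeightVector, path) -> None:
    df = pd.DataFrame({"variant_id": wv.variant_ids, "weight": wv.weights,
                       "method": wv.method})
    if wv.cv_p is not None:
        df["cv_p"] = wv.cv_p
    df.to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "value"}.issubset(df.columns):
        raise ParseError(f"{path}: phenotype table needs sample_id, value")
    return pd.Series(df["value"].to_numpy(float),
                     index=df["sample_id"].astype(str), name="value")


def write_phenotype(values, sample_ids, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "value": values}).to_csv(
        path, sep="\t", index=False)


RESULT_COLUMNS = ["peak_id", "method", "kernel", "statistic", "p_value",
                  "n_snps", "pvalue_method"]


def write_results(results, path) -> None:
    """Write association results (iterable of AssociationResult) as TSV."""
    rows = [{"peak_id": r.peak_id, "method": r.method, "kernel": r.kernel,
             "statistic": r.statistic, "p_value": r.p_value,
             "n_snps": r.n_snps_used, "pvalue_method": r.pvalue_method}
            for r in results]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
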