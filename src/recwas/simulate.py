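"""Synthetic genotypes, cistrome activity and phenotypes.

The generator emulates the study design used to benchmark peak-level
association tests: biallelic common SNPs (MAF above 5%) in cis-windows
around ChIP-seq peak centers, peak activity built from a small causal set
under one of five genetic architectures, and phenotypes produced either
downstream of the cistrome (causality) or directly from the same causal
genotypes (pleiotropy).  Heritability is controlled exactly in expectation:
the environmental component is drawn with variance
``Var(C_G) * (1 - h2) / h2`` so that ``Var(genetic) / Var(total)``
converges to the target ``h2``.

Architectures
-------------
additive        C_G = sum_j beta_j G_j over ``n_causal`` SNPs, beta ~ N(0,1)
single          C_G = beta * G_k for one SNP
epistatic       C_G = beta * 1[G_1 >= 1 and G_2 >= 1]
heterogeneous   C_G = beta * 1[G_1 >= 1 or G_2 >= 1]
compensatory    C_G = beta * 1[exactly one of G_1, G_2 >= 1]

"Mutated allele" is carrier status (dosage >= 1), not a dosage weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, ParameterError
from .genio import GenotypeDataset, VariantRecord

__all__ = [
    "ArchitectureSpec", "CistromeSim", "PhenotypeSim",
    "simulate_genotypes", "simulate_cistrome_genetic", "apply_heritability",
    "simulate_cistrome", "simulate_phenotype", "genetic_component",
    "ARCHITECTURES", "CAUSALITY_H2_GRID", "PLEIOTROPY_H2_GRID",
    "N_CAUSAL_GRID",
]

ARCHITECTURES = ("additive", "single", "epistatic", "heterogeneous",
                 "compensatory")
#: heritability grids used in the benchmark experiments
CAUSALITY_H2_GRID = (0.05, 0.10, 0.15, 0.20, 0.25)
PLEIOTROPY_H2_GRID = (0.01, 0.02, 0.04, 0.06, 0.08)
N_CAUSAL_GRID = (2, 3, 5, 10)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of simulated peak activity."""
    kind: str
    n_causal: int = 0

    def __post_init__(self):
        if self.kind not in ARCHITECTURES:
            raise ParameterError(f"unknown architecture {self.kind!r}")
        n = self.n_causal
        if n == 0:  # per-kind defaults
            n = {"additive": 5, "single": 1}.get(self.kind, 2)
            object.__setattr__(self, "n_causal", n)
        if self.kind == "single" and self.n_causal != 1:
            raise ParameterError("single architecture uses exactly 1 SNP")
        if self.kind in ("epistatic", "heterogeneous", "compensatory") \
                and self.n_causal != 2:
            raise ParameterError(
                f"{self.kind} architecture interacts exactly 2 SNPs")
        if self.n_causal < 1:
            raise ParameterError("n_causal must be >= 1")


@dataclass
class CistromeSim:
    """Simulated peak activity C = C_G + C_E with its generating truth."""
    C: np.ndarray
    C_G: np.ndarray
    C_E: np.ndarray
    h2: float
    causal_ids: list
    beta: np.ndarray
    architecture: str = "additive"


@dataclass
class PhenotypeSim:
    """Simulated trait with its generating mode and heritability."""
    Y: np.ndarray
    mode: str
    h2_pheno: float
    genetic: np.ndarray = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(n_samples: int, n_snps: int, maf_low: float = 0.05,
                       maf_high: float = 0.5, ld_rho: float = 0.0,
                       seed=0, chrom: str = "1", start_pos: int = 1,
                       spacing_bp: int = 1000, freqs=None,
                       sample_prefix: str = "S") -> GenotypeDataset:
    """Biallelic genotypes as two Bernoulli haplotypes per sample.

    Allele frequencies are uniform on ``[maf_low, maf_high]`` (or supplied
    through ``freqs``, e.g. to reuse one population for a reference and a
    test cohort).  Linkage between adjacent SNPs comes from a first-order
    copying process on the latent haplotype uniforms, which preserves each
    SNP's marginal frequency while inducing correlation ~ ``ld_rho``.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ParameterError(
            f"need 0 < maf_low <= maf_high <= 0.5, got "
            f"[{maf_low}, {maf_high}]")
    if not (0.0 <= ld_rho < 1.0):
        raise ParameterError("ld_rho must be in [0, 1)")
    rng = _rng(seed)
    if freqs is None:
        freqs = rng.uniform(maf_low, maf_high, size=n_snps)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (n_snps,):
            raise ParameterError("freqs length must equal n_snps")
    u = rng.uniform(size=(n_samples, 2, n_snps))
    if ld_rho > 0.0 and n_snps > 1:
        copy = rng.uniform(size=(n_samples, 2, n_snps - 1)) < ld_rho
        for k in range(1, n_snps):
            u[:, :, k] = np.where(copy[:, :, k - 1], u[:, :, k - 1],
                                  u[:, :, k])
    haplos = (u < freqs).astype(float)
    matrix = haplos.sum(axis=1)
    variants = [VariantRecord(chrom=chrom, pos=start_pos + k * spacing_bp,
                              id=f"snp{k + 1}", allele_a="A", allele_b="G",
                              maf=min(float(m), 1.0 - float(m)))
                for k, m in enumerate(matrix.mean(axis=0) / 2.0)]
    samples = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
    return GenotypeDataset(samples, variants, matrix)


# ---------------------------------------------------------------------------
# Cistrome activity
# ---------------------------------------------------------------------------

def genetic_component(genotypes: np.ndarray, kind: str,
                      beta: np.ndarray) -> np.ndarray:
    """Genetic contribution of the causal genotype columns under ``kind``.

    ``genotypes`` is the (n x n_causal) causal sub-matrix in the order the
    causal set was drawn; ``beta`` is the stored effect vector (length
    n_causal for additive, length 1 otherwise).
    """
    g = np.asarray(genotypes, dtype=float)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if kind == "additive":
        return g @ beta
    if kind == "single":
        return beta[0] * g[:, 0]
    carrier = g >= 1.0
    if kind == "epistatic":
        ind = carrier[:, 0] & carrier[:, 1]
    elif kind == "heterogeneous":
        ind = carrier[:, 0] | carrier[:, 1]
    elif kind == "compensatory":
        ind = carrier[:, 0] ^ carrier[:, 1]
    else:
        raise ParameterError(f"unknown architecture {kind!r}")
    return beta[0] * ind.astype(float)


def simulate_cistrome_genetic(dataset: GenotypeDataset,
                              spec: ArchitectureSpec,
                              seed=0) -> tuple[np.ndarray, list, np.ndarray]:
    """Draw a causal set and effects, return (C_G, causal_ids, beta)."""
    if spec.n_causal > dataset.n_variants:
        raise ParameterError(
            f"n_causal={spec.n_causal} exceeds {dataset.n_variants} SNPs")
    rng = _rng(seed)
    idx = rng.choice(dataset.n_variants, size=spec.n_causal, replace=False)
    n_beta = spec.n_causal if spec.kind == "additive" else 1
    beta = rng.standard_normal(n_beta)
    g = dataset.imputed()[:, idx]
    c_g = genetic_component(g, spec.kind, beta)
    causal_ids = [dataset.variants[i].id for i in idx]
    return c_g, causal_ids, beta


def apply_heritability(c_g: np.ndarray, h2: float, seed=0,
                       minmax_rescale: bool = False) -> CistromeSim:
    """Add i.i.d. Gaussian environment so Var(C_G)/Var(C) targets ``h2``.

    ``minmax_rescale`` first maps the genetic component onto [0, 1]; the
    subsequent variance-ratio noise makes this immaterial for any test that
    is location/scale invariant, so it is off by default.
    """
    if not (0.0 < h2 <= 1.0):
        raise ParameterError(f"h2 must be in (0, 1], got {h2}")
    c_g = np.asarray(c_g, dtype=float)
    if minmax_rescale:
        span = c_g.max() - c_g.min()
        if span <= 0:
            raise DegenerateDataError("constant genetic component")
        c_g = (c_g - c_g.min()) / span
    var_g = float(np.var(c_g))
    if var_g <= 0.0:
        raise DegenerateDataError("constant genetic component")
    rng = _rng(seed)
    if h2 == 1.0:
        c_e = np.zeros_like(c_g)
    else:
        c_e = rng.normal(0.0, np.sqrt(var_g * (1.0 - h2) / h2),
                         size=c_g.shape)
    return CistromeSim(C=c_g + c_e, C_G=c_g, C_E=c_e, h2=h2,
                       causal_ids=[], beta=np.array([]))


def simulate_cistrome(dataset: GenotypeDataset, spec: ArchitectureSpec,
                      h2: float, seed=0,
                      minmax_rescale: bool = False) -> CistromeSim:
    """Full cistrome simulation: causal draw, genetic component, noise."""
    rng = _rng(seed)
    c_g, causal_ids, beta = simulate_cistrome_genetic(dataset, spec, rng)
    sim = apply_heritability(c_g, h2, rng, minmax_rescale=minmax_rescale)
    sim.causal_ids = causal_ids
    sim.beta = beta
    sim.architecture = spec.kind
    return sim


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotype(mode: str, cistrome_sim: CistromeSim, h2_pheno: float,
                       seed=0, minmax_rescale: bool = False) -> PhenotypeSim:
    """Trait simulation under the causality or pleiotropy model.

    causality   the trait's genetic component is the *noisy* cistrome C
                (genotype -> cistrome -> trait), re-noised to ``h2_pheno``.
    pleiotropy  the trait's genetic component is recomputed from the same
                causal SNPs and effects (C_G); its noise is drawn
                independently of the cistrome's environmental term.
    """
    if mode not in ("causality", "pleiotropy"):
        raise ParameterError(f"unknown phenotype mode {mode!r}")
    if cistrome_sim is None:
        raise ParameterError(f"{mode} mode requires a cistrome simulation")
    g = cistrome_sim.C if mode == "causality" else cistrome_sim.C_G
    sim = apply_heritability(g, h2_pheno, seed, minmax_rescale=minmax_rescale)
    return PhenotypeSim(Y=sim.C, mode=mode, h2_pheno=h2_pheno, genetic=g)
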