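"""Power and type-I-error experiments comparing the fixed-effect and
random-effect peak association tests.

Design of one simulated peak (the unit of replication):

1. draw per-SNP allele frequencies for the peak's cis-window, then draw an
   independent reference cohort (weight training) and test cohort
   (association testing) from that population;
2. simulate reference peak activity under the configured architecture and
   cistrome heritability, and train per-SNP weights on it (LASSO, falling
   back to the TOP1 marginal model when the LASSO solution is all-zero);
3. simulate the test-cohort trait — N(0,1) independent of genotype for the
   null experiments, or causality/pleiotropy with the *same* causal SNPs
   and effects for power — and run both tests with the trained weights.

The two-cohort split is essential: weights are never trained on the cohort
that is tested.  Per-peak randomness is spawned from one master seed, so
every cell of a grid is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cwas import cwas_individual_test, predict_cistrome
from .exceptions import DegenerateDataError, ParameterError, RecwasError
from .score_test import recwas_test
from .simulate import (ArchitectureSpec, apply_heritability,
                       genetic_component, simulate_genotypes,
                       simulate_phenotype)
from .weights import marginal_effects, top1, train_lasso

__all__ = ["ExperimentConfig", "Type1Estimate", "bonferroni_threshold",
           "run_type1_experiment", "run_power_experiment", "power_cell"]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Study-wide per-test threshold alpha / n_tests."""
    if not (0.0 < alpha < 1.0):
        raise ParameterError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ExperimentConfig:
    """One simulation experiment (a single cell unless grids are swept)."""
    architecture: str = "additive"
    disease_model: str = "causality"      # or "pleiotropy"
    n_causal: int = 5
    h2_cistrome: float = 0.25
    h2_pheno: float = 0.25
    n_ref: int = 400                      # reference (training) cohort
    n_test: int = 1200                    # test cohort
    n_peaks: int = 1000                   # replicates per cell
    n_snps_per_peak: int = 30             # common SNPs in the cis-window
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.0
    kernel_name: str = "weighted_linear"
    threshold: float = 0.05
    lasso_n_alphas: int = 100
    cv_folds: int = 5
    # per-method weight sources: the fixed-effect test imputes activity
    # from the sparse cross-validated LASSO fit (TOP1 fallback), while the
    # random-effect kernel aggregates per-SNP marginal effects
    cwas_weights: str = "lasso"           # "lasso" or "marginal"
    recwas_weights: str = "marginal"      # "marginal" or "lasso"
    # inversion accuracy for the per-peak p-value; 1e-7 keeps the numeric
    # error orders of magnitude below Monte Carlo noise at harness scale
    davies_acc: float = 1e-7

    def __post_init__(self):
        if self.n_peaks < 1:
            raise ParameterError("n_peaks must be positive")
        if self.disease_model not in ("causality", "pleiotropy"):
            raise ParameterError("disease_model must be causality/pleiotropy")


@dataclass
class Type1Estimate:
    """Empirical rejection rates under a genotype-independent trait."""
    rate_recwas: float
    rate_cwas: float
    n_peaks: int
    mc_se_recwas: float
    mc_se_cwas: float
    alpha: float
    mode: str = "nominal"
    n_untestable: int = 0
    pvalues: pd.DataFrame | None = field(default=None, repr=False)


def _train_weights(G_ref, C_ref, cfg: ExperimentConfig, seed: int):
    """Weights for both methods from one reference panel.

    LASSO falls back to the TOP1 marginal model when the cross-validated
    solution is all-zero, mirroring best-of-candidates model selection.
    Returns ``(w_cwas, w_recwas)`` on the standardized-genotype scale.
    """
    table = marginal_effects(G_ref, C_ref)
    w_marginal = np.where(table.flagged, 0.0, table.beta_hat)

    def lasso_w():
        wv = train_lasso(G_ref, C_ref, cv_folds=cfg.cv_folds, seed=seed,
                         n_alphas=cfg.lasso_n_alphas)
        return top1(table).weights if wv.is_null else wv.weights

    lasso_cache = None
    out = []
    for policy in (cfg.cwas_weights, cfg.recwas_weights):
        if policy == "marginal":
            out.append(w_marginal)
        else:
            if lasso_cache is None:
                lasso_cache = lasso_w()
            out.append(lasso_cache)
    return out[0], out[1]


def _one_peak(cfg: ExperimentConfig, n_causal: int, n_snps: int,
              seed_seq: np.random.SeedSequence, null_trait: bool):
    """Simulate, train and test one peak; returns (p_cwas, p_recwas)."""
    s_freq, s_ref, s_test, s_sim, s_w = seed_seq.spawn(5)
    rng_f = np.random.default_rng(s_freq)
    freqs = rng_f.uniform(cfg.maf_low, cfg.maf_high, size=n_snps)
    ref = simulate_genotypes(cfg.n_ref, n_snps, cfg.maf_low, cfg.maf_high,
                             ld_rho=cfg.ld_rho, seed=np.random.default_rng(
                                 s_ref), freqs=freqs)
    test = simulate_genotypes(cfg.n_test, n_snps, cfg.maf_low, cfg.maf_high,
                              ld_rho=cfg.ld_rho, seed=np.random.default_rng(
                                  s_test), freqs=freqs)
    rng_sim = np.random.default_rng(s_sim)
    spec = ArchitectureSpec(cfg.architecture, n_causal)
    idx = rng_sim.choice(n_snps, size=n_causal, replace=False)
    n_beta = n_causal if cfg.architecture == "additive" else 1
    beta = rng_sim.standard_normal(n_beta)
    c_g_ref = genetic_component(ref.matrix[:, idx], spec.kind, beta)
    try:
        ref_sim = apply_heritability(c_g_ref, cfg.h2_cistrome, rng_sim)
        w_cwas, w_recwas = _train_weights(
            ref.matrix, ref_sim.C, cfg,
            seed=int(s_w.generate_state(1)[0] % 2**31))
    except DegenerateDataError:
        return np.nan, np.nan

    if null_trait or cfg.h2_pheno == 0.0:
        # no genetic effect on the trait
        Y = rng_sim.standard_normal(cfg.n_test)
    else:
        c_g_test = genetic_component(test.matrix[:, idx], spec.kind, beta)
        try:
            test_sim = apply_heritability(c_g_test, cfg.h2_cistrome, rng_sim)
            Y = simulate_phenotype(cfg.disease_model, test_sim,
                                   cfg.h2_pheno, rng_sim).Y
        except DegenerateDataError:
            return np.nan, np.nan

    try:
        c_hat = predict_cistrome(test.matrix, w_cwas)
        p_cwas = cwas_individual_test(c_hat, Y).p_value
    except RecwasError:
        p_cwas = np.nan
    try:
        res = recwas_test(test.matrix, w_recwas, Y,
                          kernel_name=cfg.kernel_name,
                          maf_min=cfg.maf_low,
                          davies_acc=cfg.davies_acc)
        p_recwas = res.p_value if res.testable else np.nan
    except RecwasError:
        p_recwas = np.nan
    return p_cwas, p_recwas


def _run_cell(cfg: ExperimentConfig, master_seed: int, null_trait: bool,
              n_causal_cycle=None) -> pd.DataFrame:
    """P-values for every peak of one experiment cell."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(cfg.n_peaks)
    rows = []
    for i, child in enumerate(children):
        if n_causal_cycle is not None:
            n_causal = int(n_causal_cycle[i % len(n_causal_cycle)])
            n_snps = n_causal
        else:
            n_causal = cfg.n_causal
            n_snps = max(cfg.n_snps_per_peak, cfg.n_causal)
        p_c, p_r = _one_peak(cfg, n_causal, n_snps, child, null_trait)
        rows.append((p_c, p_r))
    return pd.DataFrame(rows, columns=["p_cwas", "p_recwas"])


def _rejection(pvals: pd.Series, threshold: float, mode: str):
    """Rejection fraction; untestable peaks (NaN) count as non-rejections."""
    n = len(pvals)
    if mode == "empirical":
        finite = pvals.dropna().to_numpy()
        cut = np.quantile(finite, threshold)
        rate = float((pvals <= cut).sum()) / n
    else:
        rate = float((pvals < threshold).sum()) / n
    se = float(np.sqrt(rate * (1.0 - rate) / n))
    return rate, se


def run_type1_experiment(cfg: ExperimentConfig, master_seed: int = 0,
                         alpha: float = 0.05, mode: str = "nominal",
                         n_causal_cycle=(2, 3, 5, 10),
                         return_pvalues: bool = False) -> Type1Estimate:
    """Null experiment: traits N(0,1), independent of every genotype.

    ``mode='nominal'`` rejects at p < alpha; ``mode='empirical'`` rejects at
    the top-``alpha`` quantile of the realized null statistics (which is
    alpha by construction — a protocol sanity check, not an error estimate).
    Cis-window sizes cycle over ``n_causal_cycle`` with every window SNP
    causal for the reference cistrome.
    """
    if mode not in ("nominal", "empirical"):
        raise ParameterError("mode must be 'nominal' or 'empirical'")
    df = _run_cell(cfg, master_seed, null_trait=True,
                   n_causal_cycle=n_causal_cycle)
    rate_r, se_r = _rejection(df["p_recwas"], alpha, mode)
    rate_c, se_c = _rejection(df["p_cwas"], alpha, mode)
    return Type1Estimate(rate_recwas=rate_r, rate_cwas=rate_c,
                         n_peaks=cfg.n_peaks, mc_se_recwas=se_r,
                         mc_se_cwas=se_c, alpha=alpha, mode=mode,
                         n_untestable=int(df.isna().any(axis=1).sum()),
                         pvalues=df if return_pvalues else None)


def power_cell(cfg: ExperimentConfig, master_seed: int = 0):
    """Power of both methods in one cell, with per-method MC standard error.

    Returns a dict with powers, standard errors and the raw p-values (for
    paired comparisons between methods on identical peaks).
    """
    df = _run_cell(cfg, master_seed, null_trait=False)
    out = {"pvalues": df, "n_peaks": cfg.n_peaks}
    for m in ("cwas", "recwas"):
        rate, se = _rejection(df[f"p_{m}"], cfg.threshold, "nominal")
        out[f"power_{m}"] = rate
        out[f"mc_se_{m}"] = se
    return out


def run_power_experiment(cfg: ExperimentConfig, h2_cistrome_grid=None,
                         h2_pheno_grid=None,
                         master_seed: int = 0) -> pd.DataFrame:
    """Sweep heritability grids; one row per (method, cell) with power and
    MC standard error.  Cell seeds derive from the master seed by counter."""
    h2c = h2_cistrome_grid if h2_cistrome_grid is not None \
        else [cfg.h2_cistrome]
    h2p = h2_pheno_grid if h2_pheno_grid is not None else [cfg.h2_pheno]
    rows = []
    counter = 0
    for hc in h2c:
        for hp in h2p:
            cell_cfg = replace(cfg, h2_cistrome=hc, h2_pheno=hp)
            cell_seed = (master_seed * 100003 + counter) % (2 ** 31)
            counter += 1
            res = power_cell(cell_cfg, cell_seed)
            for m in ("cwas", "recwas"):
                rows.append({
                    "method": m, "kernel": cfg.kernel_name if m == "recwas"
                    else "linear-fixed",
                    "architecture": cfg.architecture,
                    "disease_model": cfg.disease_model,
                    "n_causal": cfg.n_causal,
                    "h2_cistrome": hc, "h2_pheno": hp,
                    "power": res[f"power_{m}"],
                    "n_peaks": cfg.n_peaks,
                    "mc_se": res[f"mc_se_{m}"]})
    return pd.DataFrame(rows)
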