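"""Generator correctness: frequencies, architectures, heritability."""

import numpy as np
import pytest

from recwas.exceptions import DegenerateDataError, ParameterError
from recwas.simulate import (ArchitectureSpec, apply_heritability,
                             genetic_component, simulate_cistrome,
                             simulate_cistrome_genetic, simulate_genotypes,
                             simulate_phenotype)


class TestGenotypes:
    def test_deterministic_under_seed(self):
        a = simulate_genotypes(50, 8, seed=11)
        b = simulate_genotypes(50, 8, seed=11)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert [v.pos for v in a.variants] == [v.pos for v in b.variants]

    def test_invalid_maf_bounds(self):
        with pytest.raises(ParameterError):
            simulate_genotypes(10, 2, maf_low=0.0)
        with pytest.raises(ParameterError):
            simulate_genotypes(10, 2, maf_low=0.3, maf_high=0.2)

    def test_empirical_maf_respects_lower_bound(self):
        ds = simulate_genotypes(10_000, 40, maf_low=0.05, seed=3)
        assert (ds.maf() >= 0.03).all()  # binomial tolerance band

    def test_no_ld_by_default(self):
        ds = simulate_genotypes(20_000, 12, seed=5)
        corr = np.corrcoef(ds.matrix.T)
        off = np.abs(corr[np.triu_indices(12, k=1)])
        assert off.mean() < 0.02

    def test_ld_induces_adjacent_correlation(self):
        ds = simulate_genotypes(20_000, 12, ld_rho=0.8, seed=5)
        corr = np.corrcoef(ds.matrix.T)
        adjacent = np.diag(corr, k=1)
        assert adjacent.mean() > 0.3


CARRIER_TABLES = {
    # contribution indicator for each (g1, g2) dosage pair
    "epistatic": lambda g1, g2: float(g1 >= 1 and g2 >= 1),
    "heterogeneous": lambda g1, g2: float(g1 >= 1 or g2 >= 1),
    "compensatory": lambda g1, g2: float((g1 >= 1) != (g2 >= 1)),
}


class TestArchitectures:
    @pytest.mark.parametrize("kind", list(CARRIER_TABLES))
    def test_interaction_truth_tables(self, kind):
        beta = np.array([1.7])
        pairs = [(a, b) for a in (0, 1, 2) for b in (0, 1, 2)]
        g = np.array(pairs, dtype=float)
        got = genetic_component(g, kind, beta)
        want = np.array([1.7 * CARRIER_TABLES[kind](a, b) for a, b in pairs])
        np.testing.assert_array_equal(got, want)

    def test_additive_direct(self):
        g = np.array([[2.0, 0.0], [1.0, 1.0]])
        np.testing.assert_array_equal(
            genetic_component(g, "additive", np.array([1.0, -1.0])),
            [2.0, 0.0])

    def test_single_uses_one_snp(self):
        g = np.array([[2.0], [0.0], [1.0]])
        np.testing.assert_array_equal(
            genetic_component(g, "single", np.array([0.5])), [1.0, 0.0, 0.5])

    def test_spec_validation(self):
        with pytest.raises(ParameterError):
            ArchitectureSpec("single", 3)
        with pytest.raises(ParameterError):
            ArchitectureSpec("epistatic", 5)
        with pytest.raises(ParameterError):
            ArchitectureSpec("sigmoid")

    def test_depends_only_on_causal_columns(self, rng):
        ds = simulate_genotypes(200, 20, seed=7)
        c_g, causal_ids, beta = simulate_cistrome_genetic(
            ds, ArchitectureSpec("additive", 3), seed=9)
        noncausal = [j for j, v in enumerate(ds.variants)
                     if v.id not in causal_ids]
        perm = ds.matrix.copy()
        perm[:, noncausal] = perm[:, rng.permutation(noncausal)]
        idx = [ds.variant_ids.index(i) for i in causal_ids]
        np.testing.assert_array_equal(
            genetic_component(perm[:, idx], "additive", beta), c_g)

    def test_too_many_causal(self):
        ds = simulate_genotypes(20, 2, seed=1)
        with pytest.raises(ParameterError):
            simulate_cistrome_genetic(ds, ArchitectureSpec("additive", 5))


class TestHeritability:
    def test_h2_one_is_noiseless(self, rng):
        c_g = rng.standard_normal(100)
        sim = apply_heritability(c_g, 1.0, seed=0)
        np.testing.assert_array_equal(sim.C, c_g)
        assert not sim.C_E.any()

    @pytest.mark.parametrize("h2", [0.05, 0.25])
    def test_variance_ratio_converges(self, h2, rng):
        c_g = rng.standard_normal(100_000) * 2.3
        sim = apply_heritability(c_g, h2, seed=1)
        ratio = np.var(sim.C_G) / np.var(sim.C)
        assert ratio == pytest.approx(h2, abs=0.01)

    def test_constant_component_rejected(self):
        with pytest.raises(DegenerateDataError):
            apply_heritability(np.ones(50), 0.5)

    def test_invalid_h2(self, rng):
        with pytest.raises(ParameterError):
            apply_heritability(rng.standard_normal(50), 0.0)

    def test_decomposition_identity(self, rng):
        c_g = rng.standard_normal(500)
        sim = apply_heritability(c_g, 0.4, seed=2)
        np.testing.assert_allclose(sim.C, sim.C_G + sim.C_E)


class TestPhenotype:
    def _cistrome(self, n=10_000, h2=0.5, seed=0):
        ds = simulate_genotypes(n, 10, seed=seed)
        return simulate_cistrome(ds, ArchitectureSpec("additive", 5), h2,
                                 seed=seed + 1)

    def test_causality_noiseless_limit(self):
        cis = self._cistrome()
        phe = simulate_phenotype("causality", cis, 1.0, seed=3)
        assert abs(np.corrcoef(phe.Y, cis.C)[0, 1]) == pytest.approx(1.0)

    def test_pleiotropy_noise_independent_of_cistrome_noise(self):
        cis = self._cistrome()
        phe = simulate_phenotype("pleiotropy", cis, 0.3, seed=4)
        noise = phe.Y - cis.C_G
        r = np.corrcoef(noise, cis.C_E)[0, 1]
        assert abs(r) < 0.03  # ~3 sigma at n = 10000

    def test_phenotype_heritability_recovered(self):
        ds = simulate_genotypes(100_000, 10, seed=8)
        cis = simulate_cistrome(ds, ArchitectureSpec("additive", 5), 1.0,
                                seed=9)
        phe = simulate_phenotype("pleiotropy", cis, 0.15, seed=10)
        # R^2 of Y on the genetic component equals h2 in the large-n limit
        r2 = np.corrcoef(phe.Y, cis.C_G)[0, 1] ** 2
        assert r2 == pytest.approx(0.15, abs=0.01)

    def test_requires_cistrome(self):
        with pytest.raises(ParameterError):
            simulate_phenotype("causality", None, 0.5)

    def test_unknown_mode(self):
        with pytest.raises(ParameterError):
            simulate_phenotype("mediation", self._cistrome(n=100), 0.5)
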