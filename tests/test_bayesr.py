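"""BayesR marker effects, GEBV prediction and the GBLUP h2 utility."""

import numpy as np
import pandas as pd
import pytest

import safbreed as sb

SHORT = dict(n_iter=400, burn_in=100, thin=2)


def _sim_trait(rng, n, m, n_qtl, h2):
    X = rng.binomial(2, rng.uniform(0.1, 0.9, m), (n, m)).astype(float)
    beta = np.zeros(m)
    q = rng.choice(m, n_qtl, replace=False)
    beta[q] = rng.normal(0, 1, n_qtl)
    g = X @ beta
    ve = g.var() * (1 - h2) / h2
    y = g + rng.normal(0, np.sqrt(ve), n)
    return X, y, beta, g


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            sb.BayesRConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            sb.BayesRConfig(mixture_variance_fractions=(0.1, 1e-4, 1e-3, 1e-2))
        with pytest.raises(ValueError):
            sb.BayesRConfig(dirichlet_prior=(0, 1, 1, 1))


class TestFitBayesR:
    def test_seeded_fits_are_reproducible(self, rng):
        X, y, _, _ = _sim_trait(rng, 80, 60, 5, 0.5)
        cfg = sb.BayesRConfig(seed=3, **SHORT)
        b1, *_ = sb.fit_bayesr(X, y, cfg)
        b2, *_ = sb.fit_bayesr(X, y, cfg)
        assert np.array_equal(b1, b2)

    def test_pure_noise_markers_land_in_null_class(self):
        """With no QTL, at least 80% of markers have the zero component as
        their modal class (checked over 20 seeds)."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.binomial(2, rng.uniform(0.1, 0.9, 500), (300, 500)).astype(float)
            y = rng.normal(0, 1, 300)
            _, probs, _, _ = sb.fit_bayesr(
                X, y, sb.BayesRConfig(seed=seed, **SHORT)
            )
            frac_null = np.mean(probs.argmax(axis=1) == 0)
            ok += frac_null >= 0.8
        assert ok >= 18

    def test_single_qtl_effect_recovered(self):
        """One QTL explaining 50% of phenotypic variance: posterior-mean
        effect within +-25% of truth on average, corr(beta_hat, beta) > 0.5."""
        errs, cors = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, m = 500, 200
            X = rng.binomial(2, rng.uniform(0.2, 0.8, m), (n, m)).astype(float)
            beta = np.zeros(m)
            j = int(rng.integers(m))
            beta[j] = 1.0
            g = X @ beta
            y = g + rng.normal(0, g.std(), n)  # QTL explains half the variance
            bhat, _, _, _ = sb.fit_bayesr(X, y, sb.BayesRConfig(seed=seed, **SHORT))
            errs.append(bhat[j] - 1.0)
            cors.append(np.corrcoef(bhat, beta)[0, 1])
        assert abs(np.mean(errs)) < 0.25
        assert np.mean(cors) > 0.5

    def test_noise_free_marker_leaves_null_class(self, rng):
        """Phenotype an exact linear function of one marker: that marker is
        assigned to a non-zero class with probability near 1."""
        n, m = 200, 50
        X = rng.binomial(2, rng.uniform(0.3, 0.7, m), (n, m)).astype(float)
        y = 2.5 * X[:, 7] + rng.normal(0, 1e-3, n)
        _, probs, _, _ = sb.fit_bayesr(X, y, sb.BayesRConfig(seed=1, **SHORT))
        assert probs[7, 1:].sum() > 0.95

    def test_class_probs_are_a_simplex(self, rng):
        X, y, _, _ = _sim_trait(rng, 100, 80, 8, 0.5)
        _, probs, _, _ = sb.fit_bayesr(X, y, sb.BayesRConfig(seed=2, **SHORT))
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_variance_components_sum_to_phenotypic_variance(self, rng):
        """Posterior sigma_g2 + sigma_e2 tracks var(y) within 15% on a
        polygenic trait (standardized internally, back-transformed)."""
        X, y, _, _ = _sim_trait(rng, 300, 400, 40, 0.5)
        _, _, sg, se = sb.fit_bayesr(X, y, sb.BayesRConfig(seed=4, **SHORT))
        assert (sg + se) == pytest.approx(y.var(), rel=0.15)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.integers(0, 3, (10, 5)).astype(float)
        with pytest.raises(ValueError):
            sb.fit_bayesr(X, np.full(10, np.nan), sb.BayesRConfig(**SHORT))
        with pytest.raises(ValueError):
            sb.fit_bayesr(X, np.zeros(7), sb.BayesRConfig(**SHORT))

    def test_prediction_accuracy_increases_with_h2(self):
        """Held-out accuracy corr(GEBV, TBV) is positive at h2 = 0.5 and
        monotone over h2 in {0.2, 0.5, 0.8} (20-seed averages)."""
        accs = {}
        for h2 in (0.2, 0.5, 0.8):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(1000 * seed + int(h2 * 10))
                X, y, beta, g = _sim_trait(rng, 350, 300, 30, h2)
                tr, te = slice(0, 300), slice(300, 350)
                bhat, _, _, _ = sb.fit_bayesr(
                    X[tr], y[tr], sb.BayesRConfig(seed=seed, n_iter=300, burn_in=100, thin=2)
                )
                vals.append(np.corrcoef(X[te] @ bhat, g[te])[0, 1])
            accs[h2] = np.mean(vals)
        assert accs[0.2] < accs[0.5] < accs[0.8]
        assert accs[0.5] > 0.3


class TestPredictGEBV:
    def test_zero_effects_zero_gebv(self, small_pop):
        m = small_pop.n_markers
        eff = sb.MarkerEffects(
            pd.DataFrame({"GY": np.zeros(m), "OL": np.zeros(m)}),
            {}, pd.DataFrame(),
        )
        assert (sb.predict_gebv(small_pop.dosages(), eff, "GY") == 0).all()

    def test_single_marker_identity(self):
        eff = sb.MarkerEffects(pd.DataFrame({"GY": [1.0]}), {}, pd.DataFrame())
        X = np.array([[0], [1], [2]])
        assert np.allclose(sb.predict_gebv(X, eff, "GY"), [0, 1, 2])

    def test_matches_double_loop_oracle(self, rng):
        X = rng.integers(0, 3, (10, 50)).astype(float)
        beta = rng.normal(0, 1, 50)
        eff = sb.MarkerEffects(pd.DataFrame({"GY": beta}), {}, pd.DataFrame())
        oracle = np.array([sum(X[i, j] * beta[j] for j in range(50)) for i in range(10)])
        assert np.allclose(sb.predict_gebv(X, eff, "GY"), oracle)

    def test_dimension_mismatch_rejected(self, rng):
        eff = sb.MarkerEffects(pd.DataFrame({"GY": np.zeros(5)}), {}, pd.DataFrame())
        with pytest.raises(ValueError):
            sb.predict_gebv(np.zeros((3, 7)), eff, "GY")


class TestEstimateH2GBLUP:
    def test_noise_free_limit(self):
        """With phenotype = TBV and a panel-sized sample the REML h2 estimate
        approaches 1 (at small n a single genetic realization can masquerade
        as partly environmental, so this limit needs n in the hundreds)."""
        pop = sb.simulate_founders(
            sb.FounderConfig(n_individuals=349, n_markers=600, seed=3)
        )
        arch = sb.simulate_trait_architecture(pop, 120, seed=3)
        tbv = sb.true_breeding_values(pop.dosages(), arch)
        grm = sb.compute_grm(pop.dosages(), "from-data")
        assert sb.estimate_h2_gblup(tbv[:, 0], grm) > 0.95

    def test_permuted_phenotypes_near_zero(self, small_pop, small_arch, rng):
        phen = sb.simulate_phenotypes(small_pop, small_arch, seed=3)
        y = phen["GY"].to_numpy().copy()
        rng.shuffle(y)
        grm = sb.compute_grm(small_pop.dosages(), "from-data")
        assert sb.estimate_h2_gblup(y, grm) <= 0.15

    def test_recovers_generating_h2(self):
        """REML h2 averages the generating 0.54 within +-0.15 over 20 seeds
        on a 349-individual panel."""
        pop = sb.simulate_founders(
            sb.FounderConfig(n_individuals=349, n_markers=600, seed=20)
        )
        arch = sb.simulate_trait_architecture(pop, 120, h2=(0.54, 0.80), seed=20)
        grm = sb.compute_grm(pop.dosages(), "from-data")
        ests = [
            sb.estimate_h2_gblup(
                sb.simulate_phenotypes(pop, arch, seed=s)["GY"].to_numpy(), grm
            )
            for s in range(20)
        ]
        assert abs(np.mean(ests) - 0.54) < 0.15
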