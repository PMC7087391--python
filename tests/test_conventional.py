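import numpy as np
import pytest

import bayesxii as bx
from bayesxii import _kernels
from bayesxii.conventional import (
    _prepare_cache,
    draw_initial_state,
    sample_marker_effect,
    sample_mu,
    sample_variances_and_pi,
)


def _toy_genotypes(n=50, p=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, p)).astype(float)
    X -= X.mean(axis=0)
    freq = rng.uniform(0.1, 0.9, p)
    return bx.GenotypeData(ids=np.arange(n).astype(str), X=X,
                           allele_freq=freq, centered=True)


class TestStartingValues:
    def test_variance_formula(self):
        # sigma2_g=1, pi=0.95, sum 2 p q = 250 -> 1/(0.05 * 250) = 0.08
        freq = np.full(500, 0.5)  # 2*0.5*0.5 = 0.5 each -> sum 250
        assert bx.starting_effect_variance(1.0, 0.95, freq) == pytest.approx(0.08)
        assert bx.starting_effect_variance(1.0, 0.0, freq) == pytest.approx(1 / 250)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            bx.starting_effect_variance(1.0, 0.5, np.zeros(10))

    def test_initial_state_deterministic_and_consistent(self):
        G = _toy_genotypes()
        y = np.arange(G.n, dtype=float)
        hyper = bx.Hyperparameters(genetic_variance=1.0, pi_init=0.9)
        s1 = draw_initial_state(G, y, hyper, np.random.default_rng(5))
        s2 = draw_initial_state(G, y, hyper, np.random.default_rng(5))
        assert np.array_equal(s1.a, s2.a)
        assert s1.mu == pytest.approx(y.mean())
        assert np.all(s1.delta == 1)
        assert np.allclose(s1.residual, y - s1.mu - G.X @ s1.a)


class TestSampleMu:
    def test_moments(self):
        n, reps = 25, 20_000
        rng = np.random.default_rng(8)
        y = np.zeros(n)
        draws = np.empty(reps)
        for r in range(reps):
            state = bx.ModelState(mu=0.0, a=np.zeros(1),
                                  delta=np.ones(1, np.int8), pi=0.5,
                                  sigma2_a=1.0, sigma2_e=2.0,
                                  residual=y.copy())
            draws[r] = sample_mu(state, y, rng)
        se_mean = np.sqrt(2.0 / n / reps)
        assert abs(draws.mean()) < 4 * se_mean
        assert draws.var() == pytest.approx(2.0 / n, rel=0.05)


class TestMarkerEffect:
    def test_conditional_moments(self):
        # cj=10, s2e=2, s2a=1, rhs=5: mean 5/12, var 2/12 when included
        rng = np.random.default_rng(9)
        draws = [sample_marker_effect(5.0, 10.0, 0.0, 1.0, 2.0, rng)[0]
                 for _ in range(20_000)]
        draws = np.asarray(draws)
        assert draws.mean() == pytest.approx(5 / 12, abs=4 * np.sqrt(2 / 12 / 2e4))
        assert draws.var() == pytest.approx(2 / 12, rel=0.05)

    def test_prior_mass_edges(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            a, d = sample_marker_effect(3.0, 5.0, 1.0, 1.0, 1.0, rng)
            assert (a, d) == (0.0, 0)
            a, d = sample_marker_effect(3.0, 5.0, 0.0, 1.0, 1.0, rng)
            assert d == 1 and a != 0.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            sample_marker_effect(1.0, 0.0, 0.5, 1.0, 1.0,
                                 np.random.default_rng(0))

    @pytest.mark.parametrize("rhs,cj,s2a,s2e,pi", [
        (5.0, 10.0, 1.0, 2.0, 0.5),
        (-2.0, 3.0, 0.25, 1.0, 0.9),
        (0.1, 50.0, 2.0, 0.5, 0.99),
    ])
    def test_inclusion_probability_matches_quadrature(self, rhs, cj, s2a, s2e, pi):
        # P(delta=1) from the closed-form likelihood ratio vs numerical
        # integration of the marginal likelihood of rhs over the effect
        t1 = cj * s2a + s2e
        ell = -0.5 * np.log(t1 / s2e) + rhs ** 2 * s2a / (2 * s2e * t1)
        p1 = _kernels._incl_prob(ell, pi)

        grid = np.linspace(-30 * np.sqrt(s2a), 30 * np.sqrt(s2a), 200_001)
        # rhs | a ~ N(cj a, cj s2e); a ~ N(0, s2a)
        lik = np.exp(-(rhs - cj * grid) ** 2 / (2 * cj * s2e)) / np.sqrt(
            2 * np.pi * cj * s2e)
        prior = np.exp(-grid ** 2 / (2 * s2a)) / np.sqrt(2 * np.pi * s2a)
        L1 = np.trapezoid(lik * prior, grid)
        L0 = np.exp(-rhs ** 2 / (2 * cj * s2e)) / np.sqrt(2 * np.pi * cj * s2e)
        oracle = (1 - pi) * L1 / ((1 - pi) * L1 + pi * L0)
        assert p1 == pytest.approx(oracle, abs=1e-6)


class TestSweepAndChain:
    def test_variant_equivalence(self):
        G = _toy_genotypes(50, 20, seed=3)
        rng = np.random.default_rng(4)
        y = G.X @ rng.normal(size=20) * 0.3 + rng.normal(size=50)
        hyper = bx.Hyperparameters.from_data(y, G.allele_freq)
        tr1 = bx.run_chain(G, y, hyper, 200, thin=1, seed=6, variant="I")
        tr2 = bx.run_chain(G, y, hyper, 200, thin=1, seed=6, variant="II")
        assert np.array_equal(tr1.n_included, tr2.n_included)
        assert np.max(np.abs(tr1.a_samples - tr2.a_samples)) < 1e-8
        assert np.max(np.abs(tr1.sigma2_e - tr2.sigma2_e)) < 1e-8

    def test_single_marker_sweep_reduces_to_single_site_draw(self):
        G = _toy_genotypes(30, 1, seed=5)
        y = np.random.default_rng(1).normal(size=30)
        state = bx.ModelState(mu=0.0, a=np.zeros(1), delta=np.zeros(1, np.int8),
                              pi=0.5, sigma2_a=1.0, sigma2_e=1.0,
                              residual=y.copy())
        rng = np.random.default_rng(77)
        u, z = rng.random(1), rng.standard_normal(1)
        from bayesxii.conventional import marker_sweep
        marker_sweep(state, G, y, "I", np.random.default_rng(77))
        # replay the same draw through the scalar operation
        cj = float(G.X[:, 0] @ G.X[:, 0])
        rhs = float(G.X[:, 0] @ y)
        t1 = cj * 1.0 + 1.0
        ell = -0.5 * np.log(t1) + rhs ** 2 / (2 * t1)
        p1 = _kernels._incl_prob(ell, 0.5)
        if u[0] < p1:
            v = cj + 1.0
            expected = rhs / v + z[0] * np.sqrt(1.0 / v)
        else:
            expected = 0.0
        assert state.a[0] == pytest.approx(expected, rel=1e-12)

    def test_conjugate_oracle(self, ridge_problem):
        # pi = 0, fixed variances: stationary distribution is the
        # closed-form normal posterior of the ridge/GLS model
        rp = ridge_problem
        tr = bx.run_chain(rp["G"], rp["y"], rp["hyper"], 30_000, thin=10,
                          seed=11, variant="II")
        emp = np.concatenate([[tr.mu[3000:].mean()],
                              tr.a_samples[300:].mean(axis=0)])
        z = np.abs(emp - rp["post_mean"]) / rp["post_sd"]
        assert np.max(z) < 0.1
        var_ratio = tr.a_samples[300:].var(axis=0) / rp["post_sd"][1:] ** 2
        assert np.all(np.abs(var_ratio - 1) < 0.1)

    def test_indicator_coherence(self, small_dataset):
        (G, T), _ = small_dataset.train, small_dataset.test
        hyper = bx.Hyperparameters.from_data(T.y, G.allele_freq)
        tr = bx.run_chain(G, T.y, hyper, 300, thin=1, seed=2, variant="I")
        # a_j = 0 exactly wherever excluded; nonzero count matches delta
        nonzero = (tr.a_samples != 0).sum(axis=1)
        assert np.array_equal(nonzero, tr.n_included)

    def test_stale_residual_detected(self):
        G = _toy_genotypes(20, 5, seed=8)
        y = np.random.default_rng(2).normal(size=20)
        hyper = bx.Hyperparameters.from_data(y, G.allele_freq)
        state = draw_initial_state(G, y, hyper, np.random.default_rng(3))
        state.residual = state.residual + 1e-3  # corrupt
        with pytest.raises(RuntimeError, match="residual"):
            bx.run_chain(G, y, hyper, 60, seed=3, variant="I",
                         initial_state=state, audit_every=50)

    def test_zero_length_chain_keeps_initial_state(self):
        G = _toy_genotypes(20, 5, seed=9)
        y = np.random.default_rng(3).normal(size=20)
        hyper = bx.Hyperparameters.from_data(y, G.allele_freq)
        tr = bx.run_chain(G, y, hyper, 0, seed=1)
        assert tr.mu.size == 0 and "a" in tr.initial
        assert np.array_equal(tr.a_mean, tr.initial["a"])

    def test_monomorphic_column_rejected(self):
        G = _toy_genotypes(20, 5, seed=10)
        G.X[:, 2] = 0.0
        y = np.random.default_rng(4).normal(size=20)
        hyper = bx.Hyperparameters.from_data(y, G.allele_freq)
        with pytest.raises(ValueError, match="monomorphic"):
            bx.run_chain(G, y, hyper, 10, seed=1)

    def test_same_seed_same_trace(self, small_dataset):
        (G, T), _ = small_dataset.train, small_dataset.test
        hyper = bx.Hyperparameters.from_data(T.y, G.allele_freq)
        tr1 = bx.run_chain(G, T.y, hyper, 100, seed=13)
        tr2 = bx.run_chain(G, T.y, hyper, 100, seed=13)
        assert np.array_equal(tr1.sigma2_a, tr2.sigma2_a)
        assert np.array_equal(tr1.a_samples, tr2.a_samples)


class TestVariancesAndPi:
    class _StubRng:
        """Records conjugate-update parameters instead of sampling."""

        def __init__(self):
            self.calls = []

        def chisquare(self, df):
            self.calls.append(("chisquare", df))
            return df  # deterministic placeholder

        def beta(self, a, b):
            self.calls.append(("beta", a, b))
            return a / (a + b)

    def test_beta_counts(self):
        # p=10, m=4 -> pi ~ Beta(7, 5)
        state = bx.ModelState(mu=0.0, a=np.zeros(10),
                              delta=np.zeros(10, np.int8), pi=0.5,
                              sigma2_a=1.0, sigma2_e=1.0)
        state.delta[:4] = 1
        hyper = bx.Hyperparameters()
        stub = self._StubRng()
        sample_variances_and_pi(state, hyper, stub, ete=1.0, n=20)
        assert ("beta", 7, 5) == stub.calls[-1]
        assert stub.calls[0] == ("chisquare", hyper.nu_a + 4)
        assert stub.calls[1] == ("chisquare", hyper.nu_e + 20)

    def test_prior_reproduction_when_no_marker_included(self):
        # m=0: sigma2_a ~ nu_a S2_a inv-chi2_{nu_a}; with nu_a=4, S2_a=1
        # the prior mean is nu S2/(nu-2) = 2
        state = bx.ModelState(mu=0.0, a=np.zeros(5),
                              delta=np.zeros(5, np.int8), pi=0.5,
                              sigma2_a=1.0, sigma2_e=1.0)
        hyper = bx.Hyperparameters(nu_a=4.0, S2_a=1.0, estimate_pi=False)
        rng = np.random.default_rng(21)
        draws = np.empty(20_000)
        for i in range(draws.size):
            sample_variances_and_pi(state, hyper, rng, ete=0.0, n=0)
            draws[i] = state.sigma2_a
        assert draws.mean() == pytest.approx(2.0, rel=0.05)


class TestComplexityCounters:
    def _count_dot_ops(self, fn, *args):
        ops = {"n": 0}
        real_dot = np.dot

        def counting_dot(a, b):
            ops["n"] += np.size(a)
            return real_dot(a, b)

        _kernels.np.dot = counting_dot
        try:
            getattr(fn, "py_func", fn)(*args)
        finally:
            _kernels.np.dot = real_dot
        return ops["n"]

    @pytest.mark.parametrize("n1,n2", [(20, 40)])
    def test_variant1_cost_linear_in_n(self, n1, n2):
        p = 6
        counts = []
        for n in (n1, n2):
            G = _toy_genotypes(n, p, seed=n)
            cache = _prepare_cache(G, np.zeros(n), "I")
            a = np.zeros(p)
            delta = np.zeros(p, np.int8)
            e = np.random.default_rng(0).normal(size=n)
            counts.append(self._count_dot_ops(
                _kernels.sweep_variant1, cache["Xf"], cache["colsq"], e, a,
                delta, np.full(p, 0.99), np.zeros(p), 0.5, 1.0, 1.0))
        assert counts[1] == counts[0] * n2 // n1

    @pytest.mark.parametrize("p1,p2", [(5, 10)])
    def test_variant2_cost_linear_in_p_per_marker(self, p1, p2):
        n = 30
        counts = []
        for p in (p1, p2):
            G = _toy_genotypes(n, p, seed=p)
            cache = _prepare_cache(G, np.zeros(n), "II")
            a = np.zeros(p)
            delta = np.zeros(p, np.int8)
            counts.append(self._count_dot_ops(
                _kernels.sweep_variant2, cache["XtX"], cache["Xty"],
                cache["Xt1"], 0.0, a, delta, np.full(p, 0.99), np.zeros(p),
                0.5, 1.0, 1.0))
        # total sweep cost is p * p => quadratic in p
        assert counts[1] == counts[0] * (p2 * p2) // (p1 * p1)
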