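import numpy as np
import pytest

import bayesxii as bx


@pytest.fixture(scope="session")
def small_dataset():
    """A quick drift cohort: 200 train / 100 test individuals, ~120 markers."""
    cfg = bx.SimConfig(n_founders=50, n_generations=10, n_final=300,
                       p_loci=120, n_train=200, n_test=100,
                       heritability=0.3, seed=1)
    return bx.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def ridge_problem():
    """Centered 100 x 10 design with known conjugate-normal posterior.

    With pi = 0 and both variances fixed, the joint posterior of (mu, a) is
    N(solve(W'W + Lambda, W'y), sigma2_e (W'W + Lambda)^-1) with
    Lambda = diag(0, sigma2_e/sigma2_a I); any correct sampler must
    reproduce its mean and marginal variances.
    """
    rng = np.random.default_rng(7)
    n, p = 100, 10
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(size=n) + 2.0
    G = bx.GenotypeData(ids=np.char.add("i", np.arange(n).astype(str)),
                        X=X, allele_freq=np.full(p, 0.5), centered=True)
    s2a, s2e = 0.5, 1.0
    hyper = bx.Hyperparameters(pi_init=0.0, estimate_pi=False,
                               fix_sigma2_a=s2a, fix_sigma2_e=s2e)
    W = np.hstack([np.ones((n, 1)), X])
    A = W.T @ W + np.diag([0.0] + [s2e / s2a] * p)
    post_mean = np.linalg.solve(A, W.T @ y)
    post_cov = s2e * np.linalg.inv(A)
    return dict(G=G, y=y, hyper=hyper, post_mean=post_mean,
                post_sd=np.sqrt(np.diag(post_cov)))
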