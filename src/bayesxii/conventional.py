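"""Conventional single-site Gibbs sampler for BayesCpi.

Model: y = 1*mu + X a + e with a flat prior on mu, e ~ N(0, I sigma2_e),
and a spike-and-slab prior on each marker effect: a_j = 0 with probability
pi, else a_j ~ N(0, sigma2_a).  Both variances carry scaled-inverse-chi2
priors (nu S^2 chi^-2) and pi, the null-effect probability, carries a
uniform prior, giving a Beta posterior on the inclusion counts.

Two computational variants of the marker sweep are provided:

* variant "I" keeps the n-residual up to date (O(n p) per iteration,
  O(n p) memory);
* variant "II" works from the precomputed crossproducts X'X and X'y
  (O(p^2) per iteration, O(p^2) memory).

Both consume the random stream identically, so chains from the two
variants agree draw by draw up to floating-point roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .sim_data import GenotypeData

__all__ = [
    "Hyperparameters",
    "ModelState",
    "ChainTrace",
    "draw_initial_state",
    "sample_mu",
    "sample_marker_effect",
    "marker_sweep",
    "sample_variances_and_pi",
    "run_chain",
    "starting_effect_variance",
]


@dataclass
class Hyperparameters:
    """Prior settings shared by both samplers.

    ``fix_sigma2_a`` / ``fix_sigma2_e`` pin a variance at a constant instead
    of sampling it (used for validation against conjugate closed forms);
    ``estimate_pi=False`` keeps pi at ``pi_init``.
    """

    nu_e: float = 4.0
    S2_e: float = 1.0
    nu_a: float = 4.0
    S2_a: float = 1.0
    pi_init: float = 0.5
    estimate_pi: bool = True
    genetic_variance: float = 1.0
    h2_guess: float = 0.5
    fix_sigma2_a: float | None = None
    fix_sigma2_e: float | None = None

    def __post_init__(self) -> None:
        if self.nu_e <= 0 or self.nu_a <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if self.S2_e <= 0 or self.S2_a <= 0:
            raise ValueError("prior scales must be positive")
        if not 0.0 <= self.pi_init <= 1.0:
            raise ValueError("pi_init must lie in [0, 1]")

    @classmethod
    def from_data(
        cls,
        y: np.ndarray,
        allele_freq: np.ndarray,
        pi_init: float = 0.5,
        h2_guess: float = 0.5,
        genetic_variance: float | None = None,
        **kwargs,
    ) -> "Hyperparameters":
        """Data-driven defaults: S2_e = var(y)(1 - h2_guess); S2_a from the
        starting-value variance sigma2_g / ((1-pi) * sum 2 p_i (1-p_i))."""
        vy = float(np.var(y))
        sg = vy * h2_guess if genetic_variance is None else genetic_variance
        s2a0 = starting_effect_variance(sg, pi_init, allele_freq)
        return cls(S2_e=vy * (1.0 - h2_guess), S2_a=s2a0, pi_init=pi_init,
                   genetic_variance=sg, h2_guess=h2_guess, **kwargs)


def starting_effect_variance(sigma2_g: float, pi: float, allele_freq: np.ndarray) -> float:
    """sigma2_a = sigma2_g / ((1 - pi) * sum_i 2 p_i (1 - p_i))."""
    het = float(np.sum(2.0 * allele_freq * (1.0 - allele_freq)))
    if het <= 0.0:
        raise ValueError("sum 2 p_i (1 - p_i) is zero; all loci monomorphic")
    if pi >= 1.0:
        raise ValueError("pi = 1 leaves no marker to carry variance")
    return sigma2_g / ((1.0 - pi) * het)


@dataclass
class ModelState:
    """Current values of all sampled quantities."""

    mu: float
    a: np.ndarray
    delta: np.ndarray
    pi: float
    sigma2_a: float
    sigma2_e: float
    residual: np.ndarray | None = None

    def copy(self) -> "ModelState":
        return ModelState(
            mu=self.mu,
            a=self.a.copy(),
            delta=self.delta.copy(),
            pi=self.pi,
            sigma2_a=self.sigma2_a,
            sigma2_e=self.sigma2_e,
            residual=None if self.residual is None else self.residual.copy(),
        )


@dataclass
class ChainTrace:
    """Per-iteration scalar samples plus thinned marker-effect samples.

    ``a_samples`` holds rows recorded at iterations thin, 2*thin, ...;
    ``a_mean`` is the running mean of a over all post-initial iterations.
    """

    length: int
    thin: int
    seed: int
    chain_index: int
    variant: str
    mu: np.ndarray
    pi: np.ndarray
    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    n_included: np.ndarray
    a_samples: np.ndarray
    a_mean: np.ndarray
    initial: dict = field(default_factory=dict)

    def posterior_mean_a(self, burn_in_frac: float = 0.2) -> np.ndarray:
        """Posterior-mean marker effects from the thinned samples after burn-in."""
        if self.a_samples.shape[0] == 0:
            return self.a_mean
        start = int(np.floor(burn_in_frac * self.a_samples.shape[0]))
        return self.a_samples[start:].mean(axis=0)

    def posterior_mean_mu(self, burn_in_frac: float = 0.2) -> float:
        if self.mu.size == 0:
            return float(self.initial.get("mu", 0.0))
        start = int(np.floor(burn_in_frac * self.mu.size))
        return float(self.mu[start:].mean())


def chain_rng(seed: int, chain_index: int = 0) -> np.random.Generator:
    """One generator per chain, derived from (master seed, chain index)."""
    return np.random.default_rng(np.random.SeedSequence((seed, chain_index)))


def draw_initial_state(
    G: GenotypeData,
    y: np.ndarray,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> ModelState:
    """Dispersed starting state.

    Marker effects start at N(0, sigma2_a) with
    sigma2_a = sigma2_g / ((1-pi) sum 2 p_i (1-p_i)); all indicators start
    included, mu at mean(y), sigma2_e at var(y) (1 - h2_guess).
    """
    s2a0 = starting_effect_variance(hyper.genetic_variance, hyper.pi_init,
                                    G.allele_freq)
    p = G.p
    a = rng.normal(0.0, np.sqrt(s2a0), size=p)
    mu = float(np.mean(y))
    sigma2_e = float(np.var(y) * (1.0 - hyper.h2_guess))
    state = ModelState(
        mu=mu,
        a=a,
        delta=np.ones(p, dtype=np.int8),
        pi=hyper.pi_init,
        sigma2_a=s2a0 if hyper.fix_sigma2_a is None else hyper.fix_sigma2_a,
        sigma2_e=sigma2_e if hyper.fix_sigma2_e is None else hyper.fix_sigma2_e,
    )
    state.residual = y - state.mu - G.X @ state.a
    return state


def sample_mu(state: ModelState, y: np.ndarray, rng: np.random.Generator) -> float:
    """Draw mu ~ N(1'(y - X a)/n, sigma2_e/n) and update the residual."""
    n = y.shape[0]
    mean = float(np.mean(state.residual)) + state.mu
    mu_new = mean + rng.standard_normal() * np.sqrt(state.sigma2_e / n)
    state.residual += state.mu - mu_new
    state.mu = mu_new
    return mu_new


def sample_marker_effect(
    rhs_j: float,
    cj: float,
    pi: float,
    sigma2_a: float,
    sigma2_e: float,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Single-marker spike-and-slab draw.

    ``rhs_j`` is X_j'(y - 1 mu - sum_{j' != j} X_j' a_j') and cj = X_j'X_j.
    The indicator is Bernoulli with odds (1-pi) exp(ell) : pi, where ell is
    the log marginal-likelihood ratio of inclusion over exclusion; the
    included effect is N(rhs/(cj + sigma2_e/sigma2_a), sigma2_e/(cj +
    sigma2_e/sigma2_a)).
    """
    if cj <= 0.0:
        raise ValueError("X_j'X_j <= 0: monomorphic marker reached the sampler")
    t1 = cj * sigma2_a + sigma2_e
    ell = -0.5 * np.log(t1 / sigma2_e) + rhs_j * rhs_j * sigma2_a / (2.0 * sigma2_e * t1)
    p1 = _kernels._incl_prob(ell, pi)
    if rng.random() < p1:
        v = cj + sigma2_e / sigma2_a
        a_j = rhs_j / v + rng.standard_normal() * np.sqrt(sigma2_e / v)
        return float(a_j), 1
    return 0.0, 0


def marker_sweep(
    state: ModelState,
    G: GenotypeData,
    y: np.ndarray,
    variant: str,
    rng: np.random.Generator,
    *,
    _cache: dict | None = None,
) -> int:
    """One full pass over markers in ascending index order; returns the
    inclusion count.  Both variants consume 2p pre-drawn random numbers."""
    cache = _prepare_cache(G, y) if _cache is None else _cache
    p = G.p
    u = rng.random(p)
    z = rng.standard_normal(p)
    if variant == "I":
        m = _kernels.sweep_variant1(
            cache["Xf"], cache["colsq"], state.residual, state.a, state.delta,
            u, z, state.pi, state.sigma2_a, state.sigma2_e,
        )
    elif variant == "II":
        m = _kernels.sweep_variant2(
            cache["XtX"], cache["Xty"], cache["Xt1"], state.mu, state.a,
            state.delta, u, z, state.pi, state.sigma2_a, state.sigma2_e,
        )
    else:
        raise ValueError(f"unknown sweep variant {variant!r}")
    return int(m)


def sample_variances_and_pi(
    state: ModelState,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    ete: float,
    n: int,
) -> None:
    """Conjugate updates given the current effects and residual sum of squares.

    sigma2_a ~ (nu_a S2_a + sum_{delta=1} a_j^2) / chi2_{nu_a + m};
    sigma2_e ~ (nu_e S2_e + e'e) / chi2_{nu_e + n};
    pi ~ Beta(p - m + 1, m + 1) under a uniform prior (pi = null-effect
    probability).
    """
    p = state.a.shape[0]
    m = int(state.delta.sum())
    if hyper.fix_sigma2_a is None:
        ss = float(state.a @ state.a)
        state.sigma2_a = (hyper.nu_a * hyper.S2_a + ss) / rng.chisquare(hyper.nu_a + m)
    if hyper.fix_sigma2_e is None:
        state.sigma2_e = (hyper.nu_e * hyper.S2_e + ete) / rng.chisquare(hyper.nu_e + n)
    if hyper.estimate_pi:
        state.pi = float(rng.beta(p - m + 1, m + 1))


def _prepare_cache(G: GenotypeData, y: np.ndarray, variant: str = "both") -> dict:
    X = np.asarray(G.X, np.float64)
    cache: dict = {"colsq": np.einsum("ij,ij->j", X, X)}
    if np.any(cache["colsq"] <= 0.0):
        bad = int(np.argmin(cache["colsq"]))
        raise ValueError(f"marker column {bad} has zero sum of squares "
                         "(monomorphic); filter it before sampling")
    if variant in ("I", "both"):
        cache["Xf"] = np.asfortranarray(X)
    if variant in ("II", "both"):
        cache["XtX"] = X.T @ X
        cache["Xty"] = X.T @ y
        cache["Xt1"] = X.sum(axis=0)
        cache["yty"] = float(y @ y)
        cache["sum_y"] = float(y.sum())
    return cache


def run_chain(
    G: GenotypeData,
    y: np.ndarray,
    hyper: Hyperparameters,
    length: int,
    thin: int = 10,
    seed: int = 0,
    variant: str = "I",
    chain_index: int = 0,
    initial_state: ModelState | None = None,
    audit_every: int = 1000,
) -> ChainTrace:
    """Run one conventional BayesCpi chain.

    Each iteration is the full Gibbs cycle mu -> marker sweep ->
    (sigma2_a, sigma2_e, pi).  For variant I the maintained residual is
    audited against y - 1 mu - X a every ``audit_every`` iterations.
    Deterministic given (seed, chain_index).
    """
    if variant not in ("I", "II"):
        raise ValueError("variant must be 'I' or 'II'")
    y = np.asarray(y, np.float64)
    n, p = G.X.shape
    cache = _prepare_cache(G, y, variant)
    rng = chain_rng(seed, chain_index)
    state = draw_initial_state(G, y, hyper, rng) if initial_state is None \
        else initial_state.copy()
    if state.residual is None:
        state.residual = y - state.mu - G.X @ state.a

    trace = ChainTrace(
        length=length, thin=thin, seed=seed, chain_index=chain_index,
        variant=f"conventional-{variant}",
        mu=np.empty(length), pi=np.empty(length), sigma2_a=np.empty(length),
        sigma2_e=np.empty(length), n_included=np.empty(length, dtype=np.int64),
        a_samples=np.empty((length // thin if thin else 0, p)),
        a_mean=np.zeros(p),
        initial={"mu": state.mu, "pi": state.pi, "sigma2_a": state.sigma2_a,
                 "sigma2_e": state.sigma2_e, "a": state.a.copy()},
    )

    a_sum = np.zeros(p)
    for t in range(1, length + 1):
        # general mean
        if variant == "I":
            sample_mu(state, y, rng)
        else:
            mean = (cache["sum_y"] - cache["Xt1"] @ state.a) / n
            state.mu = float(
                mean + rng.standard_normal() * np.sqrt(state.sigma2_e / n)
            )
        # marker effects
        marker_sweep(state, G, y, variant, rng, _cache=cache)
        # variance components and pi
        if variant == "I":
            ete = float(state.residual @ state.residual)
        else:
            a, mu = state.a, state.mu
            XtXa = cache["XtX"] @ a
            ete = (cache["yty"] + n * mu * mu + float(a @ XtXa)
                   - 2.0 * mu * cache["sum_y"] - 2.0 * float(a @ cache["Xty"])
                   + 2.0 * mu * float(cache["Xt1"] @ a))
        sample_variances_and_pi(state, hyper, rng, ete, n)

        if not (np.isfinite(state.sigma2_a) and np.isfinite(state.sigma2_e)
                and np.isfinite(state.mu)):
            raise RuntimeError(f"non-finite state at iteration {t}")

        i = t - 1
        trace.mu[i] = state.mu
        trace.pi[i] = state.pi
        trace.sigma2_a[i] = state.sigma2_a
        trace.sigma2_e[i] = state.sigma2_e
        trace.n_included[i] = int(state.delta.sum())
        a_sum += state.a
        if thin and t % thin == 0:
            trace.a_samples[t // thin - 1] = state.a

        if variant == "I" and audit_every and t % audit_every == 0:
            e_check = y - state.mu - G.X @ state.a
            if np.max(np.abs(e_check - state.residual)) > 1e-6:
                raise RuntimeError(
                    f"stale residual detected at iteration {t}: maintained "
                    "residual drifted from y - 1 mu - X a by more than 1e-6"
                )
            state.residual = e_check

    if length:
        trace.a_mean = a_sum / length
    else:
        trace.a_mean = trace.initial["a"].copy()
    return trace
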