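"""BayesXII: the orthogonally augmented, parallelizable BayesCpi sampler.

After orthogonal data augmentation the stacked design [W_o; W_a] has
orthogonal columns, so given the latent phenotypes y_tilde attached to the
augmented rows, the full conditionals of mu and of every marker effect are
mutually independent univariate normals:

    mu  | ELSE ~ N((1'y + J_tilde' y_tilde)/d, sigma2_e/d)
    a_j | ELSE ~ N(r_j/(d + sigma2_e/sigma2_a), sigma2_e/(d + sigma2_e/sigma2_a)),
    r_j = X_j'y + X_tilde_j' y_tilde,

with the same spike-and-slab indicator rule as the conventional sampler,
cj replaced by d.  Each iteration then refreshes the latent phenotypes,

    y_tilde | ELSE ~ N(J_tilde mu + X_tilde a, I sigma2_e),

and updates the variance components; the residual sum of squares for
sigma2_e includes both the observed and the augmented residual block, with
nu_e + n + p + 1 degrees of freedom.

Parallelism is a contract, not a wall-clock claim: every random number of
iteration t comes from a substream keyed by (seed, chain, t) and the
matrix-vector products are evaluated in fixed-size tiles, so any number of
workers (threads over tiles) produces bit-identical chains.
"""

from __future__ import annotations

import hashlib
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from .conventional import (
    ChainTrace,
    Hyperparameters,
    ModelState,
    draw_initial_state,
)
from .oda import Augmentation, GroupedAugmentation
from .sim_data import GenotypeData

__all__ = [
    "XiiState",
    "sample_effects_xii",
    "sample_missing_phenotypes",
    "sample_variances_and_pi_xii",
    "run_chain_xii",
    "run_chain_xii_grouped",
    "genotype_hash",
    "iteration_rng",
]

_TILE = 512  # fixed row-tile for matvecs => schedule-independent results

# multiply-add counter for the dominant per-iteration operation; used by the
# complexity tests to verify the O(p^2)-per-iteration contract
_op_counter = {"madds": 0, "enabled": False}


def reset_op_counter(enabled: bool = True) -> None:
    _op_counter["madds"] = 0
    _op_counter["enabled"] = enabled


def op_count() -> int:
    return _op_counter["madds"]


@dataclass
class XiiState(ModelState):
    """ModelState plus the latent phenotypes of the augmented rows."""

    y_tilde: np.ndarray | None = None

    def copy(self) -> "XiiState":
        base = super().copy()
        return XiiState(
            mu=base.mu, a=base.a, delta=base.delta, pi=base.pi,
            sigma2_a=base.sigma2_a, sigma2_e=base.sigma2_e,
            residual=base.residual,
            y_tilde=None if self.y_tilde is None else self.y_tilde.copy(),
        )


def genotype_hash(X: np.ndarray) -> str:
    """Provenance hash of a genotype matrix (shape + contents)."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X, dtype=np.float64).tobytes())
    h.update(str(X.shape).encode())
    return h.hexdigest()


def iteration_rng(seed: int, chain_index: int, t: int) -> np.random.Generator:
    """Dedicated substream for iteration t of one chain.

    Keying streams by (seed, chain, iteration) is what makes the sampler's
    output independent of how markers are scheduled across workers.
    """
    return np.random.default_rng(np.random.SeedSequence((seed, chain_index, t)))


def _tiled_matvec(A: np.ndarray, v: np.ndarray, workers: int) -> np.ndarray:
    """A @ v computed in fixed row tiles, optionally on a thread pool.

    The tiling (not the worker count) defines the arithmetic, so results
    are bit-identical for any ``workers``.
    """
    m = A.shape[0]
    if _op_counter["enabled"]:
        _op_counter["madds"] += A.shape[0] * A.shape[1]
    tiles = [(lo, min(lo + _TILE, m)) for lo in range(0, m, _TILE)]
    out = np.empty(m)
    if workers > 1 and len(tiles) > 1:
        def work(bounds):
            lo, hi = bounds
            out[lo:hi] = A[lo:hi] @ v
        with ThreadPoolExecutor(max_workers=workers) as ex:
            list(ex.map(work, tiles))
    else:
        for lo, hi in tiles:
            out[lo:hi] = A[lo:hi] @ v
    return out


def sample_effects_xii(
    state: XiiState,
    aug: Augmentation,
    y: np.ndarray,
    rng_or_draws,
    workers: int = 1,
    *,
    _WaT: np.ndarray | None = None,
) -> np.ndarray:
    """Draw (mu, a, delta) from their mutually independent conditionals.

    ``rng_or_draws`` is either a Generator or a pre-drawn (u, z, z_mu)
    tuple; the latter is what the chain driver passes so draws are keyed to
    the iteration.  Returns the r vector (for diagnostics/tests).
    """
    p = aug.p
    if aug.xty is None:
        raise ValueError("augmentation has no cached X'y; call attach_phenotype")
    if isinstance(rng_or_draws, tuple):
        u, z, z_mu = rng_or_draws
    else:
        u = rng_or_draws.random(p)
        z = rng_or_draws.standard_normal(p)
        z_mu = rng_or_draws.standard_normal()

    WaT = np.ascontiguousarray(aug.W_a.T) if _WaT is None else _WaT
    wty = _tiled_matvec(WaT, state.y_tilde, workers)
    d, s2a, s2e, pi = aug.d, state.sigma2_a, state.sigma2_e, state.pi

    state.mu = float((aug.one_ty + wty[0]) / d
                     + z_mu * np.sqrt(s2e / d))

    r = aug.xty + wty[1:]
    t1 = d * s2a + s2e
    ell = -0.5 * np.log(t1 / s2e) + r * r * s2a / (2.0 * s2e * t1)
    if pi <= 0.0:
        p1 = np.ones(p)
    elif pi >= 1.0:
        p1 = np.zeros(p)
    else:
        q = np.clip(np.log(pi / (1.0 - pi)) - ell, -700.0, 700.0)
        p1 = 1.0 / (1.0 + np.exp(q))
    incl = u < p1
    v = d + s2e / s2a
    state.a = np.where(incl, r / v + z * np.sqrt(s2e / v), 0.0)
    state.delta = incl.astype(np.int8)
    return r


def sample_missing_phenotypes(
    state: XiiState,
    aug: Augmentation,
    rng_or_draws,
    workers: int = 1,
    *,
    _Wa: np.ndarray | None = None,
) -> np.ndarray:
    """Refresh y_tilde ~ N(J_tilde mu + X_tilde a, I sigma2_e).

    Returns the mean vector (needed by the variance update)."""
    Wa = aug.W_a if _Wa is None else _Wa
    coef = np.concatenate(([state.mu], state.a))
    mean = _tiled_matvec(Wa, coef, workers)
    if isinstance(rng_or_draws, np.ndarray):
        z = rng_or_draws
    else:
        z = rng_or_draws.standard_normal(aug.p + 1)
    state.y_tilde = mean + z * np.sqrt(state.sigma2_e)
    return mean


def sample_variances_and_pi_xii(
    state: XiiState,
    y: np.ndarray,
    X: np.ndarray,
    aug: Augmentation,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> None:
    """Variance/pi updates under the augmented joint model.

    sigma2_e ~ (nu_e S2_e + e'e + e_tilde'e_tilde) / chi2_{nu_e + n + p + 1}
    with e = y - 1 mu - X a and e_tilde = y_tilde - J_tilde mu - X_tilde a;
    sigma2_a and pi are updated exactly as in the conventional sampler.
    """
    n, p = X.shape
    m = int(state.delta.sum())
    if hyper.fix_sigma2_a is None:
        ss = float(state.a @ state.a)
        state.sigma2_a = (hyper.nu_a * hyper.S2_a + ss) / rng.chisquare(hyper.nu_a + m)
    if hyper.fix_sigma2_e is None:
        e = y - state.mu - X @ state.a
        e_t = state.y_tilde - aug.J_tilde * state.mu - aug.X_tilde @ state.a
        sse = float(e @ e) + float(e_t @ e_t)
        state.sigma2_e = (hyper.nu_e * hyper.S2_e + sse) / rng.chisquare(
            hyper.nu_e + n + p + 1
        )
    if hyper.estimate_pi:
        state.pi = float(rng.beta(p - m + 1, m + 1))


def run_chain_xii(
    G: GenotypeData,
    y: np.ndarray,
    aug: Augmentation,
    hyper: Hyperparameters,
    length: int,
    thin: int = 10,
    seed: int = 0,
    chain_index: int = 0,
    workers: int = 1,
    initial_state: ModelState | None = None,
    callback=None,
    callback_every: int = 0,
) -> ChainTrace:
    """Run one BayesXII chain.

    Per iteration: independent effect draws -> latent-phenotype refresh ->
    variance/pi updates.  The latent phenotypes start at their conditional
    mean J_tilde mu0 + X_tilde a0.  The observed-data residual sum of
    squares is obtained from crossproducts via the orthogonality identity
    X'X = I d - X_tilde'X_tilde, keeping every iteration O(p^2) regardless
    of n.  Output is identical for any ``workers``.
    """
    y = np.asarray(y, np.float64)
    X = np.asarray(G.X, np.float64)
    n, p = X.shape
    if aug.p != p:
        raise ValueError(f"augmentation is for p={aug.p} markers, data has p={p}")
    if aug.source_hash is not None and aug.source_hash != genotype_hash(X):
        raise ValueError("augmentation provenance hash does not match genotypes")

    aug.attach_phenotype(X, y)
    Wa = aug.W_a
    WaT = np.ascontiguousarray(Wa.T)
    Jt = aug.J_tilde
    d = aug.d
    yty = float(y @ y)
    sum_y = float(y.sum())
    Xt1 = X.sum(axis=0)

    rng0 = np.random.default_rng(np.random.SeedSequence((seed, chain_index)))
    base = draw_initial_state(G, y, hyper, rng0) if initial_state is None \
        else initial_state.copy()
    state = XiiState(mu=base.mu, a=base.a, delta=base.delta, pi=base.pi,
                     sigma2_a=base.sigma2_a, sigma2_e=base.sigma2_e)
    state.y_tilde = Wa @ np.concatenate(([state.mu], state.a))

    trace = ChainTrace(
        length=length, thin=thin, seed=seed, chain_index=chain_index,
        variant="xii",
        mu=np.empty(length), pi=np.empty(length), sigma2_a=np.empty(length),
        sigma2_e=np.empty(length), n_included=np.empty(length, dtype=np.int64),
        a_samples=np.empty((length // thin if thin else 0, p)),
        a_mean=np.zeros(p),
        initial={"mu": state.mu, "pi": state.pi, "sigma2_a": state.sigma2_a,
                 "sigma2_e": state.sigma2_e, "a": state.a.copy()},
    )

    a_sum = np.zeros(p)
    for t in range(1, length + 1):
        rng_t = iteration_rng(seed, chain_index, t)
        u = rng_t.random(p)
        z = rng_t.standard_normal(p)
        z_mu = rng_t.standard_normal()
        z_yt = rng_t.standard_normal(p + 1)

        sample_effects_xii(state, aug, y, (u, z, z_mu), workers, _WaT=WaT)
        s2e_old = state.sigma2_e
        mean_t = sample_missing_phenotypes(state, aug, z_yt, workers, _Wa=Wa)

        # variances and pi (crossproduct route for e'e, O(p))
        m = int(state.delta.sum())
        a, mu = state.a, state.mu
        if hyper.fix_sigma2_a is None:
            ss = float(a @ a)
            state.sigma2_a = (hyper.nu_a * hyper.S2_a + ss) / rng_t.chisquare(
                hyper.nu_a + m)
        if hyper.fix_sigma2_e is None:
            xa_t = mean_t - Jt * mu  # X_tilde a
            aXtXa = d * float(a @ a) - float(xa_t @ xa_t)
            ete = (yty + n * mu * mu + aXtXa - 2.0 * mu * sum_y
                   - 2.0 * float(a @ aug.xty) + 2.0 * mu * float(Xt1 @ a))
            ete_t = s2e_old * float(z_yt @ z_yt)
            state.sigma2_e = (hyper.nu_e * hyper.S2_e + ete + ete_t) / \
                rng_t.chisquare(hyper.nu_e + n + p + 1)
        if hyper.estimate_pi:
            state.pi = float(rng_t.beta(p - m + 1, m + 1))

        if not (np.isfinite(state.sigma2_a) and np.isfinite(state.sigma2_e)
                and np.isfinite(state.mu)):
            raise RuntimeError(f"non-finite state at iteration {t}")

        i = t - 1
        trace.mu[i] = state.mu
        trace.pi[i] = state.pi
        trace.sigma2_a[i] = state.sigma2_a
        trace.sigma2_e[i] = state.sigma2_e
        trace.n_included[i] = m
        a_sum += a
        if thin and t % thin == 0:
            trace.a_samples[t // thin - 1] = a
        if callback is not None and callback_every and t % callback_every == 0:
            callback(t, trace)

    trace.a_mean = a_sum / length if length else trace.initial["a"].copy()
    return trace


def run_chain_xii_grouped(
    G: GenotypeData,
    y: np.ndarray,
    gaug: GroupedAugmentation,
    hyper: Hyperparameters,
    length: int,
    thin: int = 10,
    seed: int = 0,
    chain_index: int = 0,
) -> ChainTrace:
    """BayesXII with per-group orthogonalization for large marker panels.

    Groups are processed sequentially; within a group all effects are drawn
    at once from independent conditionals (group-level parallel contract),
    using the observed-data residual for the cross-group part of the right
    hand side and the group's latent phenotypes for the augmented part.
    The general mean is drawn from its observed-data conditional, and the
    residual-variance update uses nu_e + n + p degrees of freedom (p
    augmented rows in total, no augmented intercept row).
    """
    y = np.asarray(y, np.float64)
    X = np.asarray(G.X, np.float64)
    n, p = X.shape
    if gaug.p != p:
        raise ValueError("grouped augmentation does not match marker count")

    Xg = [np.ascontiguousarray(X[:, g]) for g in gaug.groups]
    XtXg = [x.T @ x for x in Xg]
    Btg = [np.ascontiguousarray(b.T) for b in gaug.blocks]

    rng0 = np.random.default_rng(np.random.SeedSequence((seed, chain_index)))
    state = draw_initial_state(G, y, hyper, rng0)
    y_tildes = [b @ state.a[g] for b, g in zip(gaug.blocks, gaug.groups)]
    e = y - state.mu - X @ state.a

    trace = ChainTrace(
        length=length, thin=thin, seed=seed, chain_index=chain_index,
        variant="xii-grouped",
        mu=np.empty(length), pi=np.empty(length), sigma2_a=np.empty(length),
        sigma2_e=np.empty(length), n_included=np.empty(length, dtype=np.int64),
        a_samples=np.empty((length // thin if thin else 0, p)),
        a_mean=np.zeros(p),
        initial={"mu": state.mu, "pi": state.pi, "sigma2_a": state.sigma2_a,
                 "sigma2_e": state.sigma2_e, "a": state.a.copy()},
    )

    a_sum = np.zeros(p)
    for t in range(1, length + 1):
        rng_t = iteration_rng(seed, chain_index, t)
        u = rng_t.random(p)
        z = rng_t.standard_normal(p)
        z_mu = rng_t.standard_normal()
        z_yt = rng_t.standard_normal(p)

        # general mean from the observed-data conditional
        mu_new = float(np.mean(e)) + state.mu \
            + z_mu * np.sqrt(state.sigma2_e / n)
        e += state.mu - mu_new
        state.mu = mu_new

        s2a, s2e, pi = state.sigma2_a, state.sigma2_e, state.pi
        sse_t = 0.0
        for gi, g in enumerate(gaug.groups):
            d_i = gaug.ds[gi]
            a_old = state.a[g]
            r = Xg[gi].T @ e + XtXg[gi] @ a_old + Btg[gi] @ y_tildes[gi]
            t1 = d_i * s2a + s2e
            ell = -0.5 * np.log(t1 / s2e) + r * r * s2a / (2.0 * s2e * t1)
            if pi <= 0.0:
                p1 = np.ones(g.size)
            elif pi >= 1.0:
                p1 = np.zeros(g.size)
            else:
                q = np.clip(np.log(pi / (1.0 - pi)) - ell, -700.0, 700.0)
                p1 = 1.0 / (1.0 + np.exp(q))
            incl = u[g] < p1
            v = d_i + s2e / s2a
            a_new = np.where(incl, r / v + z[g] * np.sqrt(s2e / v), 0.0)
            e -= Xg[gi] @ (a_new - a_old)
            state.a[g] = a_new
            state.delta[g] = incl.astype(np.int8)
            # refresh this group's latent phenotypes
            mean_i = gaug.blocks[gi] @ a_new
            noise = z_yt[g] * np.sqrt(s2e)
            y_tildes[gi] = mean_i + noise
            sse_t += float(noise @ noise)

        m = int(state.delta.sum())
        if hyper.fix_sigma2_a is None:
            ss = float(state.a @ state.a)
            state.sigma2_a = (hyper.nu_a * hyper.S2_a + ss) / rng_t.chisquare(
                hyper.nu_a + m)
        if hyper.fix_sigma2_e is None:
            state.sigma2_e = (hyper.nu_e * hyper.S2_e + float(e @ e) + sse_t) / \
                rng_t.chisquare(hyper.nu_e + n + p)
        if hyper.estimate_pi:
            state.pi = float(rng_t.beta(p - m + 1, m + 1))

        if not np.isfinite(state.sigma2_e):
            raise RuntimeError(f"non-finite state at iteration {t}")

        i = t - 1
        trace.mu[i] = state.mu
        trace.pi[i] = state.pi
        trace.sigma2_a[i] = state.sigma2_a
        trace.sigma2_e[i] = state.sigma2_e
        trace.n_included[i] = m
        a_sum += state.a
        if thin and t % thin == 0:
            trace.a_samples[t // thin - 1] = state.a
        if t % 1000 == 0:
            e = y - state.mu - X @ state.a  # refresh against drift

    trace.a_mean = a_sum / length if length else trace.initial["a"].copy()
    return trace
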