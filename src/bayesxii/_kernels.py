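"""Inner-loop kernels for the single-site marker sweeps.

Both sweep variants draw the inclusion indicator and effect of each marker
in ascending index order from pre-drawn uniform/normal arrays, so the two
variants (and a pure-Python fallback) consume an identical random stream
and can be compared draw by draw.

Variant I maintains the n-vector residual e = y - 1*mu - X a and costs
O(n) per marker; variant II works from the cached crossproducts X'X, X'y
and costs O(p) per marker.  The kernels are compiled with numba when it is
importable and run as plain Python otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _incl_prob(ell: float, pi: float) -> float:
    """P(delta=1) from the log marginal-likelihood ratio ell and prior pi."""
    if pi <= 0.0:
        return 1.0
    if pi >= 1.0:
        return 0.0
    # log-odds of exclusion over inclusion, guarded against overflow
    q = np.log(pi / (1.0 - pi)) - ell
    if q > 700.0:
        return 0.0
    if q < -700.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(q))


@njit(cache=False)
def sweep_variant1(X, colsq, e, a, delta, u, z, pi, s2a, s2e):
    """Residual-updating sweep; X must be Fortran-ordered, e is updated in place.

    Returns the number of included markers.
    """
    n, p = X.shape
    lam = s2e / s2a
    m = 0
    for j in range(p):
        cj = colsq[j]
        xj = X[:, j]
        rhs = np.dot(xj, e) + cj * a[j]
        t1 = cj * s2a + s2e
        ell = -0.5 * np.log(t1 / s2e) + rhs * rhs * s2a / (2.0 * s2e * t1)
        p1 = _incl_prob(ell, pi)
        old = a[j]
        if u[j] < p1:
            v = cj + lam
            anew = rhs / v + z[j] * np.sqrt(s2e / v)
            delta[j] = 1
            m += 1
        else:
            anew = 0.0
            delta[j] = 0
        diff = anew - old
        if diff != 0.0:
            for i in range(n):
                e[i] -= xj[i] * diff
        a[j] = anew
    return m


@njit(cache=False)
def sweep_variant2(XtX, Xty, Xt1, mu, a, delta, u, z, pi, s2a, s2e):
    """Crossproduct sweep: rhs_j = X_j'y - X_j'1 mu - sum_{j' != j} (X'X)_{jj'} a_j'."""
    p = a.shape[0]
    lam = s2e / s2a
    m = 0
    for j in range(p):
        cj = XtX[j, j]
        rhs = Xty[j] - Xt1[j] * mu - (np.dot(XtX[j, :], a) - cj * a[j])
        t1 = cj * s2a + s2e
        ell = -0.5 * np.log(t1 / s2e) + rhs * rhs * s2a / (2.0 * s2e * t1)
        p1 = _incl_prob(ell, pi)
        if u[j] < p1:
            v = cj + lam
            a[j] = rhs / v + z[j] * np.sqrt(s2e / v)
            delta[j] = 1
            m += 1
        else:
            a[j] = 0.0
            delta[j] = 0
    return m
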