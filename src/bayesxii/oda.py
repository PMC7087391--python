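"""Orthogonal data augmentation (ODA) of a regression design matrix.

Given the incidence matrix W_o = [1 X] of a whole-genome regression, ODA
appends a square block W_a of p+1 synthetic rows such that the stacked
matrix W_c = [W_o; W_a] has mutually orthogonal columns:

    W_c' W_c = W_o' W_o + W_a' W_a = I d,

with d chosen as the largest eigenvalue of W_o' W_o plus a small jitter
(default 0.001) for numerical stability.  W_a is any matrix square root of
M = I d - W_o' W_o, obtained here by Cholesky factorization with a symmetric
eigendecomposition fallback (M is positive semidefinite by construction but
nearly singular along the top eigenvector).

Once columns are orthogonal, the full conditionals of all regression
coefficients become mutually independent, which is what makes the
marker-effect draws of the augmented Gibbs sampler parallelizable.

For very large p, the grouped variant orthogonalizes each block of a marker
partition separately with its own d_i, trading full independence for a
p x (group size) memory footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "Augmentation",
    "GroupedAugmentation",
    "compute_d",
    "build_augmentation",
    "build_grouped_augmentation",
    "orthogonality_defect",
    "augment_design",
]

DEFAULT_JITTER = 1e-3


@dataclass
class Augmentation:
    """The augmented block W_a = [J_tilde X_tilde] and its scalar d.

    ``J_tilde`` is the augmented intercept column (p+1 rows), ``X_tilde``
    the (p+1) x p augmented marker block.  ``xty``/``one_ty`` optionally
    cache the observed-data crossproducts X'y and 1'y used by the sampler.
    """

    d: float
    jitter: float
    J_tilde: np.ndarray
    X_tilde: np.ndarray
    xty: np.ndarray | None = None
    one_ty: float | None = None
    source_hash: str | None = None

    @property
    def p(self) -> int:
        return self.X_tilde.shape[1]

    @property
    def W_a(self) -> np.ndarray:
        return np.hstack([self.J_tilde[:, None], self.X_tilde])

    def attach_phenotype(self, X: np.ndarray, y: np.ndarray) -> None:
        self.xty = X.T @ np.asarray(y, float)
        self.one_ty = float(np.sum(y))


@dataclass
class GroupedAugmentation:
    """Per-group square augmentation blocks for a marker partition."""

    groups: list[np.ndarray]
    ds: list[float]
    blocks: list[np.ndarray]
    jitter: float

    @property
    def p(self) -> int:
        return sum(g.size for g in self.groups)


def compute_d(W_o: np.ndarray, jitter: float = DEFAULT_JITTER) -> float:
    """Largest eigenvalue of W_o' W_o plus ``jitter``.

    Computed on the symmetric crossproduct so the cost is O(n m^2 + m^3)
    for an n x m input.
    """
    W_o = np.asarray(W_o, dtype=np.float64)
    if W_o.size == 0:
        raise ValueError("empty design matrix")
    if not np.all(np.isfinite(W_o)):
        raise ValueError("design matrix contains non-finite entries")
    C = W_o.T @ W_o
    m = C.shape[0]
    lam_max = scipy.linalg.eigvalsh(C, subset_by_index=[m - 1, m - 1])[0]
    return float(lam_max) + jitter


def build_augmentation(
    W_o: np.ndarray,
    d: float | None = None,
    jitter: float = DEFAULT_JITTER,
) -> Augmentation:
    """Factor M = I d - W_o' W_o into W_a' W_a and split off [J_tilde X_tilde].

    ``d`` defaults to compute_d(W_o, jitter), which guarantees M is positive
    semidefinite with smallest eigenvalue equal to the jitter.  Cholesky is
    attempted first; if it fails, a symmetric eigendecomposition is used,
    clamping eigenvalues in [-1e-8 d, 0) to zero.  A more negative
    eigenvalue raises, with the offending value in the message.
    """
    W_o = np.asarray(W_o, dtype=np.float64)
    if d is None:
        d = compute_d(W_o, jitter)
    C = W_o.T @ W_o
    m = C.shape[0]
    M = d * np.eye(m) - C
    try:
        L = np.linalg.cholesky(M)
        W_a = L.T
    except np.linalg.LinAlgError:
        w, V = scipy.linalg.eigh(M)
        tol = 1e-8 * d
        if w[0] < -tol:
            raise ValueError(
                f"M = I*d - W_o'W_o has eigenvalue {w[0]:.3e} < -{tol:.1e}; "
                f"not positive semidefinite. Increase the jitter (currently "
                f"{jitter:g}) added to d."
            )
        w = np.clip(w, 0.0, None)
        W_a = np.sqrt(w)[:, None] * V.T
    return Augmentation(d=float(d), jitter=float(jitter),
                        J_tilde=W_a[:, 0].copy(), X_tilde=W_a[:, 1:].copy())


def augment_design(X: np.ndarray, jitter: float = DEFAULT_JITTER) -> Augmentation:
    """Convenience wrapper: prepend the intercept column and augment [1 X]."""
    X = np.asarray(X, dtype=np.float64)
    W_o = np.hstack([np.ones((X.shape[0], 1)), X])
    return build_augmentation(W_o, jitter=jitter)


def build_grouped_augmentation(
    X: np.ndarray,
    groups: list[np.ndarray] | list[list[int]],
    jitter: float = DEFAULT_JITTER,
) -> GroupedAugmentation:
    """Augment each column group of X separately.

    ``groups`` must partition {0..p-1}.  Each group i gets its own scalar
    d_i = lambda_max(X_i' X_i) + jitter and a square block X_tilde_i with
    X_i' X_i + X_tilde_i' X_tilde_i = I d_i.  Columns in different groups
    remain non-orthogonal.
    """
    X = np.asarray(X, dtype=np.float64)
    p = X.shape[1]
    idx_groups = [np.asarray(g, dtype=int) for g in groups]
    if any(g.size == 0 for g in idx_groups):
        raise ValueError("empty marker group")
    flat = np.concatenate(idx_groups)
    if flat.size != p or not np.array_equal(np.sort(flat), np.arange(p)):
        raise ValueError("groups must partition the marker indices exactly once")
    ds, blocks = [], []
    for g in idx_groups:
        Xg = X[:, g]
        dg = compute_d(Xg, jitter)
        aug = build_augmentation(Xg, d=dg, jitter=jitter)
        ds.append(dg)
        blocks.append(aug.W_a)  # square, g.size x g.size
    return GroupedAugmentation(groups=idx_groups, ds=ds, blocks=blocks,
                               jitter=float(jitter))


def orthogonality_defect(W_c: np.ndarray, d: float | None = None) -> float:
    """Relative off-diagonality of W_c' W_c.

    Returns max |off-diagonal of W_c'W_c| / d.  With ``d`` omitted, the mean
    diagonal of the crossproduct is used as the scale.
    """
    W_c = np.asarray(W_c, dtype=np.float64)
    C = W_c.T @ W_c
    if d is None:
        d = float(np.mean(np.diag(C)))
    off = C - np.diag(np.diag(C))
    if C.shape[0] == 1:
        return 0.0
    return float(np.max(np.abs(off)) / d)
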