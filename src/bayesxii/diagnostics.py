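"""Convergence and prediction diagnostics.

PSRF (potential scale reduction factor, Gelman-Rubin) across parallel
chains, prediction accuracy as the correlation between genomic estimated
breeding values and mean-adjusted phenotypes in a test set, and the
between-sampler agreement of test-set breeding values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conventional import ChainTrace

__all__ = [
    "DiagnosticsReport",
    "psrf",
    "prediction_accuracy",
    "method_agreement",
    "report_text",
]


@dataclass
class DiagnosticsReport:
    psrf: dict = field(default_factory=dict)
    accuracy: float | None = None
    ebv_correlation: float | None = None
    n_iterations_used: int = 0
    burn_in: int = 0


def psrf(chains: list[np.ndarray] | np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor of one scalar parameter.

    With m chains of length n: W is the mean within-chain variance (ddof 1),
    B = n * var(chain means) (ddof 1), Vhat = (n-1)/n W + B/n, and the PSRF
    is sqrt(Vhat / W).  Values near 1 indicate the chains have mixed.
    Returns +inf when the chains have zero within-variance but unequal
    means.
    """
    arr = np.asarray(chains, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    m, n = arr.shape
    W = float(np.mean(np.var(arr, axis=1, ddof=1)))
    means = arr.mean(axis=1)
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    vhat = (n - 1) / n * W + B / n
    # Vhat underestimates the stationary variance when B ~ 0, which would
    # push the factor below 1; floor it so 1.0 always means "converged"
    return float(max(1.0, np.sqrt(vhat / W)))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero variance in correlation input; returning nan")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def prediction_accuracy(
    a_posterior_mean: np.ndarray,
    mu_posterior_mean: float,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> float:
    """Correlation between test-set EBVs and mean-adjusted phenotypes.

    EBV = X_test @ a_hat; the adjusted phenotype subtracts the estimated
    general mean (the model's only fixed effect).  ``X_test`` must be
    centered with the training-set column means.
    """
    ebv = np.asarray(X_test, float) @ np.asarray(a_posterior_mean, float)
    adj = np.asarray(y_test, float) - mu_posterior_mean
    return _pearson(ebv, adj)


def method_agreement(
    trace_a: ChainTrace,
    trace_b: ChainTrace,
    X_test: np.ndarray,
    burn_in_frac: float = 0.2,
) -> float:
    """Correlation between two samplers' test-set EBV vectors.

    Posterior-mean effects are taken from the thinned samples after the
    given burn-in fraction.  Traces must come from the same marker set.
    """
    if trace_a.a_mean.shape != trace_b.a_mean.shape:
        raise ValueError("traces have mismatched marker sets")
    ebv_a = X_test @ trace_a.posterior_mean_a(burn_in_frac)
    ebv_b = X_test @ trace_b.posterior_mean_a(burn_in_frac)
    return _pearson(ebv_a, ebv_b)


def report_text(report: DiagnosticsReport) -> str:
    """Flat ``key = value`` rendering of a diagnostics report."""
    lines = []
    for name, val in report.psrf.items():
        lines.append(f"psrf_{name} = {val:.6g}")
    if report.accuracy is not None:
        lines.append(f"accuracy = {report.accuracy:.6g}")
    if report.ebv_correlation is not None:
        lines.append(f"ebv_correlation = {report.ebv_correlation:.6g}")
    lines.append(f"n_iterations_used = {report.n_iterations_used}")
    lines.append(f"burn_in = {report.burn_in}")
    return "\n".join(lines) + "\n"
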