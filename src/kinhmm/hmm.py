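"""Scaled forward-backward and Viterbi over windowed genome chains.

The hidden chain runs along genomic windows and is re-initialized with the
stationary distribution at the start of every chromosome; the total
log-likelihood is the sum over per-chromosome chains.  Emissions arrive as
log-probabilities (one row per window), which keeps the machinery shared
between the pair IBD HMM and the ROH HMM.
"""

from __future__ import annotations

import numpy as np

__all__ = ["stationary_distribution", "forward_backward", "viterbi"]


def _check_stochastic(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(A < -1e-12) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return A


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Left eigenvector of a row-stochastic matrix for eigenvalue 1."""
    A = _check_stochastic(A)
    k = A.shape[0]
    if k == 1:
        return np.array([1.0])
    # solve pi (A - I) = 0 with sum(pi) = 1 via least squares
    M = np.vstack([A.T - np.eye(k), np.ones(k)])
    rhs = np.zeros(k + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _scale_emissions(log_e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window rescaled linear emissions plus the log of the factor removed."""
    shift = np.max(log_e, axis=1)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    e = np.exp(log_e - shift[:, None])
    return e, shift


def forward_backward(
    log_emissions: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    chrom_slices: list[slice] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior state probabilities, expected transition counts, log-likelihood.

    Returns ``(gamma, xi_sum, loglik)`` where ``gamma`` is L x K with rows
    summing to 1 and ``xi_sum`` accumulates expected within-chromosome
    transition counts (for Baum-Welch updates).
    """
    log_e = np.asarray(log_emissions, dtype=float)
    L, K = log_e.shape
    A = _check_stochastic(A)
    pi = np.asarray(pi, dtype=float)
    if chrom_slices is None:
        chrom_slices = [slice(0, L)]
    if np.any(np.isnan(log_e)):
        raise ValueError(f"non-finite emission at window {int(np.argwhere(np.isnan(log_e))[0][0])}")
    e, shift = _scale_emissions(log_e)
    gamma = np.empty((L, K))
    xi_sum = np.zeros((K, K))
    loglik = float(shift.sum())
    for sl in chrom_slices:
        eb = e[sl]
        n = eb.shape[0]
        if n == 0:
            continue
        alpha = np.empty((n, K))
        c = np.empty(n)
        a = pi * eb[0]
        c[0] = a.sum()
        if c[0] <= 0:
            raise ValueError(f"zero forward probability at window {sl.start}")
        alpha[0] = a / c[0]
        for t in range(1, n):
            a = (alpha[t - 1] @ A) * eb[t]
            c[t] = a.sum()
            if c[t] <= 0:
                raise ValueError(f"zero forward probability at window {sl.start + t}")
            alpha[t] = a / c[t]
        beta = np.empty((n, K))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (A @ (eb[t + 1] * beta[t + 1])) / c[t + 1]
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        gamma[sl] = g
        for t in range(n - 1):
            xi = (alpha[t][:, None] * A) * (eb[t + 1] * beta[t + 1])[None, :] / c[t + 1]
            xi_sum += xi
        loglik += float(np.log(c).sum())
    return gamma, xi_sum, loglik


def viterbi(
    log_emissions: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    chrom_slices: list[slice] | None = None,
) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index."""
    log_e = np.asarray(log_emissions, dtype=float)
    L, K = log_e.shape
    A = _check_stochastic(A)
    with np.errstate(divide="ignore"):
        logA = np.log(A)
        logpi = np.log(np.asarray(pi, dtype=float))
    if chrom_slices is None:
        chrom_slices = [slice(0, L)]
    path = np.empty(L, dtype=np.int64)
    for sl in chrom_slices:
        eb = log_e[sl]
        n = eb.shape[0]
        if n == 0:
            continue
        score = logpi + eb[0]
        back = np.empty((n, K), dtype=np.int64)
        for t in range(1, n):
            cand = score[:, None] + logA  # K x K
            back[t] = np.argmax(cand, axis=0)  # first max -> lower index
            score = cand[back[t], np.arange(K)] + eb[t]
        states = np.empty(n, dtype=np.int64)
        states[-1] = int(np.argmax(score))
        for t in range(n - 2, -1, -1):
            states[t] = back[t + 1][states[t + 1]]
        path[sl] = states
    return path
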