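"""Pair IBD HMM: ROH-mixture emissions and EM over the over-dispersions.

One HMM is fitted per (pair, relatedness case).  Hidden state ``Z_w`` is
the number of chromosomes shared IBD in window ``w``; the ROH status
``H_w`` (how many of the two individuals are homozygous) is marginalized
using externally supplied probabilities ``h_w``.  The free parameters are
the per-level over-dispersions ``delta_i``, estimated by EM: the E-step is
forward-backward, the M-step maximizes the posterior-weighted log
emission independently per level with a bounded scalar search inside the
variance-constraint interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from . import hmm
from .counts import PairWindowData
from .emissions import (
    P_LEVEL,
    EmissionParams,
    betabinom_logpmf,
    delta_constraint_interval,
)
from .models import RelatednessModel

__all__ = ["KinFit", "window_log_emissions", "g_weights", "maximize_delta", "em_fit", "viterbi_path"]

DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-4


@dataclass
class KinFit:
    """Result of fitting one relatedness model to one pair."""

    model: RelatednessModel
    loglik: float
    gamma: np.ndarray  # L x |states| posterior over Z
    delta_hat: dict[int, float]
    viterbi_path: np.ndarray  # IBD state per window (values in model.states)
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def gamma_full(self) -> np.ndarray:
        """Posterior over the full Z in {0,1,2} space (zeros off-model)."""
        out = np.zeros((self.gamma.shape[0], 3))
        for k, z in enumerate(self.model.states):
            out[:, z] = self.gamma[:, k]
        return out

    def k_hat(self) -> tuple[float, float, float]:
        """Genome-wide IBD fractions from mean posterior state frequencies."""
        m = self.gamma_full().mean(axis=0)
        return float(m[0]), float(m[1]), float(m[2])


def _level_logpmf(data: PairWindowData, params: EmissionParams, levels) -> dict[int, np.ndarray]:
    """Log beta-binomial of (D, N) per window for each requested level."""
    return {
        i: betabinom_logpmf(data.D, data.N, params.p[i], params.delta[i])
        for i in levels
    }


def model_levels(model: RelatednessModel) -> tuple[int, ...]:
    """Emission levels reachable given the model's state space."""
    used = sorted({int(P_LEVEL[z, h]) for z in model.states for h in range(3)})
    return tuple(used)


def window_log_emissions(
    data: PairWindowData,
    h: np.ndarray,
    model: RelatednessModel,
    params: EmissionParams,
) -> np.ndarray:
    """L x |states| log emissions, H marginalized in probability space.

    ``P(D_w | Z_w=z) = sum_omega h_w[omega] BB(D_w; p(z,omega), delta(z,omega), N_w)``;
    windows with ``N_w = 0`` emit probability 1 in every state so the chain
    still traverses them.
    """
    h = np.asarray(h, dtype=float)
    if h.shape != (data.L, 3):
        raise ValueError("h must be L x 3")
    lp = _level_logpmf(data, params, model_levels(model))
    with np.errstate(divide="ignore"):
        log_h = np.log(h)
    out = np.empty((data.L, len(model.states)))
    for k, z in enumerate(model.states):
        terms = np.stack([log_h[:, w] + lp[int(P_LEVEL[z, w])] for w in range(3)])
        out[:, k] = logsumexp(terms, axis=0)
    return out


def g_weights(gamma_full: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Per-window weights over emission levels (columns 0,1,2,3,4).

    Collapses the joint (Z, H) posterior-times-prior weight onto the level
    index (number of identical-chromosome comparisons); level 3 never
    occurs and stays 0.  Rows sum to 1 when both inputs are normalized.
    """
    g = np.zeros((gamma_full.shape[0], 5))
    g[:, 0] = gamma_full[:, 0]
    g[:, 1] = gamma_full[:, 1] * h[:, 0]
    g[:, 2] = gamma_full[:, 2] * h[:, 0] + gamma_full[:, 1] * h[:, 1]
    g[:, 4] = (
        gamma_full[:, 2] * h[:, 1]
        + gamma_full[:, 2] * h[:, 2]
        + gamma_full[:, 1] * h[:, 2]
    )
    return g


def maximize_delta(
    data: PairWindowData,
    g_i: np.ndarray,
    p_i: float,
    bounds: tuple[float, float],
    prev: float,
) -> float:
    """Arg-max of the level cost ``sum_w g_wi log BB(D_w; p_i, delta, N_w)``.

    Bounded scalar search; if the optimizer does not beat the previous
    value (or all weights vanish) the previous delta is kept, which keeps
    the EM ascent monotone.
    """
    w = np.asarray(g_i, dtype=float)
    mask = (w > 1e-12) & (data.N > 0)
    if not np.any(mask):
        return prev
    D, N, w = data.D[mask], data.N[mask], w[mask]

    # cache the delta-independent part outside the search
    from scipy.special import betaln, gammaln

    base = gammaln(N + 1.0) - gammaln(D + 1.0) - gammaln(N - D + 1.0)

    def neg_cost(delta: float) -> float:
        a, b = p_i * delta, (1.0 - p_i) * delta
        ll = base + betaln(D + a, N - D + b) - betaln(a, b)
        return -float(np.dot(w, ll))

    lo, hi = bounds
    # search on log(delta): better conditioned, and precision 1% in delta
    # is far below anything the likelihood can resolve
    res = minimize_scalar(lambda t: neg_cost(float(np.exp(t))),
                          bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-2})
    best = float(np.exp(res.x))
    prev_clipped = min(max(prev, lo), hi)
    if neg_cost(prev_clipped) < res.fun:
        return prev_clipped
    return best


def _init_deltas(
    params: EmissionParams, levels, rng: np.random.Generator
) -> dict[int, float]:
    """Random start in (0, 1000], clipped into each level's admissible interval."""
    out = {}
    for i in levels:
        lo, hi = delta_constraint_interval(params, i)
        raw = rng.uniform(0.0, 1000.0)
        out[i] = min(max(raw, lo), min(hi, 1000.0) if lo <= 1000.0 else hi)
        out[i] = min(max(out[i], lo), hi)
    return out


def em_fit(
    data: PairWindowData,
    h: np.ndarray,
    model: RelatednessModel,
    params: EmissionParams,
    chrom_slices: list[slice] | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int | np.random.Generator = 0,
) -> KinFit:
    """EM fit of the over-dispersions for one (pair, relatedness) HMM."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    levels = model_levels(model)
    params = EmissionParams(params.p0, dict(params.delta))
    # random restart per fit; caller-supplied deltas act as the start value
    for i, d in _init_deltas(params, levels, rng).items():
        params.delta.setdefault(i, d)
    bounds = {i: delta_constraint_interval(params, i) for i in levels}

    loglik_trace: list[float] = []
    gamma = np.full((data.L, len(model.states)), 1.0 / len(model.states))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_e = window_log_emissions(data, h, model, params)
        gamma, _, loglik = hmm.forward_backward(log_e, model.A, model.pi, chrom_slices)
        loglik_trace.append(loglik)
        if len(loglik_trace) > 1 and abs(loglik_trace[-1] - loglik_trace[-2]) < tol:
            converged = True
            break
        gamma_full = np.zeros((data.L, 3))
        for k, z in enumerate(model.states):
            gamma_full[:, z] = gamma[:, k]
        g = g_weights(gamma_full, h)
        for i in levels:
            params.delta[i] = maximize_delta(
                data, g[:, i], params.p[i], bounds[i], params.delta[i]
            )
    log_e = window_log_emissions(data, h, model, params)
    path_idx = hmm.viterbi(log_e, model.A, model.pi, chrom_slices)
    path = np.asarray(model.states, dtype=np.int64)[path_idx]
    return KinFit(
        model=model,
        loglik=loglik_trace[-1],
        gamma=gamma,
        delta_hat={i: params.delta[i] for i in levels},
        viterbi_path=path,
        n_iter=n_iter,
        converged=converged,
        loglik_trace=loglik_trace,
    )


def viterbi_path(
    data: PairWindowData,
    h: np.ndarray,
    model: RelatednessModel,
    params: EmissionParams,
    chrom_slices: list[slice] | None = None,
) -> np.ndarray:
    """Most likely IBD state per window at fixed over-dispersions."""
    log_e = window_log_emissions(data, h, model, params)
    idx = hmm.viterbi(log_e, model.A, model.pi, chrom_slices)
    return np.asarray(model.states, dtype=np.int64)[idx]
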