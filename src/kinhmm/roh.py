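"""Two-state HMM locating long runs of homozygosity in one individual.

Hidden state ``Y_w`` is 2 (non-homozygous; four distinct chromosomes in a
within-individual comparison count) or 4 (homozygous).  Emission means are
fixed at ``p2 = p0/2`` and ``p4 = p0/4``; over-dispersions and the
transition matrix are both estimated (Baum-Welch for transitions, bounded
scalar search for deltas).  Windows whose observed mismatch proportion
exceeds ``p2`` are forced into the non-homozygous state, which keeps the
homozygous beta from drifting up to absorb high-variance windows.

Per-individual posteriors combine into the pairwise ROH prior
``h_w = P(H_w = omega)`` consumed by the pair IBD HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hmm
from .counts import PairWindowData, ROHInput
from .emissions import EmissionParams, betabinom_logpmf, delta_constraint_interval
from .kin_hmm import maximize_delta

__all__ = [
    "ROHFit",
    "roh_em_fit",
    "baum_welch_transition_update",
    "pair_roh_prior",
    "uniform_roh_prior",
    "roh_eval",
    "MIN_ROH_DEPTH",
]

MIN_ROH_DEPTH = 0.1  # mean reads/site below which the ROH HMM is not run
STATE_NONHOM, STATE_HOM = 0, 1  # indices for Y=2 and Y=4
DEFAULT_OFFDIAG_INIT = 0.2


@dataclass
class ROHFit:
    """Fitted ROH HMM for one individual."""

    individual: str
    Gamma: np.ndarray  # L x 2 posterior, columns (Y=2, Y=4)
    A_hat: np.ndarray
    delta_hat: dict[int, float]
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def q(self) -> np.ndarray:
        """Per-window posterior probability of the homozygous state."""
        return self.Gamma[:, STATE_HOM]


def baum_welch_transition_update(
    xi: np.ndarray, previous: np.ndarray | None = None
) -> np.ndarray:
    """Row-normalized expected transition counts; zero rows keep the old row."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("expected transition counts must be non-negative")
    rows = xi.sum(axis=1)
    A = np.array(previous, dtype=float) if previous is not None else np.eye(xi.shape[0])
    nz = rows > 0
    A[nz] = xi[nz] / rows[nz, None]
    return A


def _log_emissions(inp: ROHInput, params: EmissionParams, forced: np.ndarray) -> np.ndarray:
    log_e = np.column_stack(
        [
            betabinom_logpmf(inp.Delta, inp.M, params.p[2], params.delta[2]),
            betabinom_logpmf(inp.Delta, inp.M, params.p[4], params.delta[4]),
        ]
    )
    log_e[forced, STATE_HOM] = -np.inf
    return log_e


def roh_em_fit(
    inp: ROHInput,
    p0: float,
    chrom_slices: list[slice] | None = None,
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
    tol: float = 1e-4,
    offdiag_inits: tuple[float, ...] = (DEFAULT_OFFDIAG_INIT, 0.01),
) -> ROHFit:
    """EM fit of transitions and over-dispersions for one individual.

    Baum-Welch has data-dependent local optima: from a mobile start (0.2
    off-diagonal) the unused homozygous state can latch onto randomly low
    windows of ROH-free genomes.  The EM therefore runs once per start in
    ``offdiag_inits`` (mobile and sticky) and keeps the highest-likelihood
    solution.
    """
    if inp.M.sum() <= 0:
        raise ValueError(f"{inp.individual}: no sites with >= 2 reads")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    best: ROHFit | None = None
    for offdiag in offdiag_inits:
        fit = _roh_em_once(inp, p0, chrom_slices, rng, max_iter, tol, offdiag)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _roh_em_once(
    inp: ROHInput,
    p0: float,
    chrom_slices: list[slice] | None,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    offdiag: float,
) -> ROHFit:
    params = EmissionParams(p0)
    bounds = {i: delta_constraint_interval(params, i) for i in (2, 4)}
    for i in (2, 4):
        lo, hi = bounds[i]
        params.delta[i] = min(max(rng.uniform(0.0, 1000.0), lo), hi)

    with np.errstate(invalid="ignore"):
        rate = np.where(inp.M > 0, inp.Delta / np.maximum(inp.M, 1.0), 0.0)
    forced = (inp.M > 0) & (rate > params.p[2])

    A = np.array([[1.0 - offdiag, offdiag], [offdiag, 1.0 - offdiag]])
    data = PairWindowData((inp.individual, inp.individual), inp.Delta, inp.M)
    trace: list[float] = []
    Gamma = np.full((inp.L, 2), 0.5)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pi = hmm.stationary_distribution(A)
        log_e = _log_emissions(inp, params, forced)
        Gamma, xi, loglik = hmm.forward_backward(log_e, A, pi, chrom_slices)
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        A = baum_welch_transition_update(xi, previous=A)
        A = np.clip(A, 1e-10, None)  # keep the chain ergodic
        A /= A.sum(axis=1, keepdims=True)
        for i, col in ((2, STATE_NONHOM), (4, STATE_HOM)):
            params.delta[i] = maximize_delta(
                data, Gamma[:, col], params.p[i], bounds[i], params.delta[i]
            )
    return ROHFit(
        individual=inp.individual,
        Gamma=Gamma,
        A_hat=A,
        delta_hat={2: params.delta[2], 4: params.delta[4]},
        loglik=trace[-1],
        converged=converged,
        n_iter=n_iter,
        loglik_trace=trace,
    )


def pair_roh_prior(q_i: np.ndarray | ROHFit, q_j: np.ndarray | ROHFit) -> np.ndarray:
    """L x 3 table ``h_w = P(H_w = omega)`` assuming independent individuals."""
    q_i = q_i.q if isinstance(q_i, ROHFit) else np.asarray(q_i, dtype=float)
    q_j = q_j.q if isinstance(q_j, ROHFit) else np.asarray(q_j, dtype=float)
    if q_i.shape != q_j.shape:
        raise ValueError("posterior length mismatch")
    h = np.column_stack(
        [
            (1.0 - q_i) * (1.0 - q_j),
            q_i * (1.0 - q_j) + (1.0 - q_i) * q_j,
            q_i * q_j,
        ]
    )
    return h


def uniform_roh_prior(L: int) -> np.ndarray:
    """ROH-free prior h = (1, 0, 0); the pair HMM reduces to the no-ROH model."""
    h = np.zeros((L, 3))
    h[:, 0] = 1.0
    return h


def roh_eval(
    posterior_q: np.ndarray,
    truth_fraction: np.ndarray,
    call_threshold: float = 0.2,
    truth_threshold: float = 0.2,
) -> tuple[float, float]:
    """Window-level (sensitivity, specificity) at the 20%/20% thresholds.

    A window is truly ROH if at least ``truth_threshold`` of it lies in a
    homozygous tract, and called ROH if the posterior is at least
    ``call_threshold``.  Empty cells yield NaN.
    """
    q = np.asarray(posterior_q, dtype=float)
    t = np.asarray(truth_fraction, dtype=float)
    call = q >= call_threshold
    true = t >= truth_threshold
    tp = int(np.sum(call & true))
    fn = int(np.sum(~call & true))
    tn = int(np.sum(~call & ~true))
    fp = int(np.sum(call & ~true))
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    return se, sp
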