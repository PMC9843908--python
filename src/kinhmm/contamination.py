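"""Correction of windowed counts for present-day DNA contamination.

Contamination from a diverged population inflates pairwise differences and
biases relatedness downward.  Given known, small contamination proportions
``C_i`` per individual and the divergence ``phi`` between the target and
contaminant populations, each window's difference and match counts are
shrunk to their expected endogenous-only values: a comparison of two
random reads from a pair involves a contaminant read with probability
``C_ij = C_i + C_j`` (contaminant-contaminant comparisons are ignored),
in which case it shows a difference with probability ``phi``; otherwise
it is endogenous, with genome-wide difference rate

    rho = (sum D / sum N - C_ij phi) / (1 - C_ij).

Bayes' rule per observed difference / match then rescales ``D_w`` and
``S_w = N_w - D_w`` window by window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .counts import PairWindowData, ROHInput

__all__ = ["ContaminationParams", "estimate_rho", "correct_pair_counts", "correct_roh_counts"]

_EPS = 1e-9


@dataclass
class ContaminationParams:
    """Per-individual contamination proportions and contaminant divergence."""

    C: dict[str, float]
    phi: float
    # probability that a within-individual read pair includes a contaminant
    # read, as a multiple of C_i (one contaminant among two reads -> 2)
    within_factor: float = field(default=2.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi={self.phi} outside (0, 1)")
        for ind, c in self.C.items():
            if c < 0:
                raise ValueError(f"negative contamination for {ind}")
            if c >= 0.05:
                warnings.warn(
                    f"contamination {c:.3f} for {ind} is >= 5%; the correction "
                    "assumes small rates", stacklevel=2,
                )

    def rate(self, individual: str) -> float:
        return float(self.C.get(individual, 0.0))

    def pair_rate(self, i: str, j: str) -> float:
        cij = self.rate(i) + self.rate(j)
        if cij >= 0.1:
            warnings.warn(f"pair contamination C_ij={cij:.3f} >= 0.1", stacklevel=2)
        return cij


def estimate_rho(sum_d: float, sum_n: float, c_ij: float, phi: float) -> float:
    """Genome-wide endogenous difference rate, clamped into (0, 1)."""
    if sum_n <= 0:
        raise ValueError("sum N must be positive")
    rho = (sum_d / sum_n - c_ij * phi) / (1.0 - c_ij)
    if not _EPS < rho < 1.0 - _EPS:
        warnings.warn(
            f"endogenous rate rho={rho:.4g} outside (0,1); clamped "
            "(contamination parameters likely inconsistent with the data)",
            stacklevel=2,
        )
        rho = min(max(rho, _EPS), 1.0 - _EPS)
    return float(rho)


def _correct(D: np.ndarray, N: np.ndarray, c: float, phi: float) -> tuple[np.ndarray, np.ndarray]:
    if c == 0.0:
        return D.copy(), N.copy()
    sum_d, sum_n = float(D.sum()), float(N.sum())
    rho = estimate_rho(sum_d, sum_n, c, phi)
    S = N - D
    d_factor = rho * (1.0 - c) / (rho * (1.0 - c) + c * phi)
    s_factor = (1.0 - rho) * (1.0 - c) / ((1.0 - rho) * (1.0 - c) + c * (1.0 - phi))
    D2 = D * d_factor
    S2 = S * s_factor
    return D2, D2 + S2


def correct_pair_counts(data: PairWindowData, params: ContaminationParams) -> PairWindowData:
    """Endogenous-only expected (D', N') per window for one pair."""
    c_ij = params.pair_rate(*data.pair)
    D2, N2 = _correct(data.D, data.N, c_ij, params.phi)
    return PairWindowData(data.pair, D2, N2)


def correct_roh_counts(inp: ROHInput, params: ContaminationParams) -> ROHInput:
    """Same correction for within-individual mismatch counts.

    The comparison-level contamination probability is ``within_factor * C_i``
    (default 2: either of the two reads drawn at a site may be the
    contaminant one).
    """
    c = params.within_factor * params.rate(inp.individual)
    D2, M2 = _correct(inp.Delta, inp.M, c, params.phi)
    return ROHInput(inp.individual, D2, M2, mean_depth=inp.mean_depth)
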