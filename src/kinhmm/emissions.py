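"""Beta-binomial (Balding-Nichols) emission machinery shared by both HMMs.

The expected proportion of pairwise differences in a window depends on the
number of comparisons between identical chromosomes, indexed by a level
``i in {0, 1, 2, 4}``:

* ``p0`` — all four cross-chromosome comparisons are between unrelated
  chromosomes (IBD state 0, any ROH status);
* ``p1 = 3/4 p0`` — one of four comparisons identical (IBD 1, no ROH);
* ``p2 = 1/2 p0`` — two identical comparisons (IBD 2, or IBD 1 with one
  individual homozygous);
* ``p4 = 1/2 p2`` — all comparisons identical.  The fully-inbred
  expectation would be 0, but windows only partially overlap ROH tracts,
  so a soft mean of ``p2/2`` fits windowed data better.

Counts are modelled as beta-binomial with mean ``p_i`` and over-dispersion
``delta_i > 0`` (variance of the underlying beta: ``p(1-p)/(delta+1)``),
generalized through log-Gamma so non-integer D and N are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "LEVELS",
    "P_LEVEL",
    "EmissionParams",
    "emission_means",
    "build_p_matrix",
    "betabinom_logpmf",
    "delta_constraint_interval",
]

LEVELS = (0, 1, 2, 4)

# level index per (Z, H): rows IBD state Z, columns number of homozygous
# individuals H.  Row Z=0 is constant: differences between unrelated
# chromosomes do not depend on ROH.
P_LEVEL = np.array([[0, 0, 0], [1, 2, 4], [2, 4, 4]])

DELTA_FLOOR = 1e-6
DELTA_CEILING = 1e6


def emission_means(p0: float) -> dict[int, float]:
    """Means ``p_i`` per level from the background rate ``p0``."""
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0={p0} outside (0, 1)")
    return {0: p0, 1: 0.75 * p0, 2: 0.5 * p0, 4: 0.25 * p0}


@dataclass
class EmissionParams:
    """Level means plus current over-dispersion values."""

    p0: float
    delta: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = emission_means(self.p0)
        for i, d in self.delta.items():
            if i not in LEVELS:
                raise ValueError(f"unknown level {i}")
            if d <= 0:
                raise ValueError(f"delta_{i} must be positive")

    def mean(self, z: int, h: int) -> float:
        return self.p[int(P_LEVEL[z, h])]

    def level(self, z: int, h: int) -> int:
        return int(P_LEVEL[z, h])


def build_p_matrix(p0: float) -> EmissionParams:
    """Emission parameters with means set and over-dispersions unset."""
    return EmissionParams(p0)


def betabinom_logpmf(D, N, p: float, delta: float):
    """Log beta-binomial probability with Gamma-generalized binomial coefficient.

    Accepts scalar or array ``D, N`` with ``0 <= D <= N`` (non-integer
    allowed).  Windows with ``N = 0`` carry no information and return 0.
    """
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    if not 0.0 < p < 1.0:
        raise ValueError(f"p={p} outside (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if np.any(D < 0) or np.any(N < 0) or np.any(D > N + 1e-12):
        raise ValueError("require 0 <= D <= N")
    a = p * delta
    b = (1.0 - p) * delta
    with np.errstate(invalid="ignore"):
        out = (
            gammaln(N + 1.0)
            - gammaln(D + 1.0)
            - gammaln(N - D + 1.0)
            + betaln(D + a, np.maximum(N - D, 0.0) + b)
            - betaln(a, b)
        )
    return np.where(N > 0, out, 0.0) if out.ndim else (float(out) if N > 0 else 0.0)


def delta_constraint_interval(
    params: EmissionParams, level: int, floor: float = DELTA_FLOOR,
    ceiling: float = DELTA_CEILING, gap_fraction: float = 1 / 3,
) -> tuple[float, float]:
    """Admissible (lower, upper) bounds for ``delta_level``.

    Over-dispersions are constrained so the level beta distributions stay
    well separated.  Without a bound, a case with fewer states absorbs
    data from a case with more states by inflating its variance — and,
    symmetrically, an unused extra state with a wide beta becomes a
    garbage collector for outlier windows, letting the wrong case win the
    model comparison confidently.  Each level's sd may claim at most
    ``gap_fraction`` of the gap ``g`` to the nearest other level mean,
    i.e. with sd = sqrt(p(1-p)/(delta+1)),

        delta >= p(1-p) / (gap_fraction * g)^2 - 1,

    floored at a small positive value.  The default 1/3 is the loosest of
    the candidate separation margins that suppresses both absorption
    directions in practice; ``gap_fraction=1`` gives the per-distribution
    reading (sd <= g), which demonstrably does not.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level}")
    p_i = params.p[level]
    gaps = [abs(p_i - params.p[j]) for j in LEVELS if j != level]
    gap = min(gaps)
    if gap <= 0:
        raise ValueError("degenerate level means: two levels coincide")
    lower = max(floor, p_i * (1.0 - p_i) / (gap_fraction * gap) ** 2 - 1.0)
    return lower, ceiling
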