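"""Relatedness cases: IBD state spaces and fixed transition matrices.

Ten cases are fitted per pair: unrelated, 5th/4th/3rd degree,
grandparent-grandchild, avuncular, half-siblings, parent-child, siblings
and identical.  Unrelated, parent-child and identical are single-state
chains (Z = 0, 1, 2 respectively).  Siblings and grandparent-grandchild
have closed-form transition matrices ``e^{Qb}`` from recombination rate
matrices; the remaining cases use transition matrices estimated
empirically from simulated pedigrees (shipped as text files, regenerable
with :func:`kinhmm.simulate.estimate_empirical_transitions`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.linalg import expm

from .hmm import stationary_distribution

__all__ = [
    "RelatednessModel",
    "CASES",
    "GROUP_OF_CASE",
    "READ_COMPARABLE_GROUP",
    "analytic_transition",
    "empirical_transition",
    "model_registry",
    "load_transition_file",
    "save_transition_file",
]

DEFAULT_R = 1e-8  # recombination rate per bp per generation
DEFAULT_B = 10_000_000  # window size bp

CASES = (
    "unrelated",
    "fifth_degree",
    "fourth_degree",
    "third_degree",
    "grandparent_grandchild",
    "avuncular",
    "half_siblings",
    "parent_child",
    "siblings",
    "identical",
)

# fine case -> reported category
GROUP_OF_CASE = {
    "unrelated": "unrelated",
    "fifth_degree": "unrelated",
    "fourth_degree": "unrelated",
    "third_degree": "third_degree",
    "grandparent_grandchild": "second_degree",
    "avuncular": "second_degree",
    "half_siblings": "second_degree",
    "parent_child": "parent_child",
    "siblings": "siblings",
    "identical": "identical",
}

# coarser grouping where 3rd degree also counts as unrelated (comparable
# with pseudo-haploid distance methods that stop at 2nd degree)
READ_COMPARABLE_GROUP = {
    g: ("unrelated" if g == "third_degree" else g) for g in set(GROUP_OF_CASE.values())
}

EXPECTED_K = {
    "unrelated": (1.0, 0.0, 0.0),
    "fifth_degree": (0.9375, 0.0625, 0.0),
    "fourth_degree": (0.875, 0.125, 0.0),
    "third_degree": (0.75, 0.25, 0.0),
    "grandparent_grandchild": (0.5, 0.5, 0.0),
    "avuncular": (0.5, 0.5, 0.0),
    "half_siblings": (0.5, 0.5, 0.0),
    "parent_child": (0.0, 1.0, 0.0),
    "siblings": (0.25, 0.5, 0.25),
    "identical": (0.0, 0.0, 1.0),
}

_SINGLE_STATE = {"unrelated": 0, "parent_child": 1, "identical": 2}
_ANALYTIC = ("grandparent_grandchild", "siblings")
_EMPIRICAL = ("fifth_degree", "fourth_degree", "third_degree", "avuncular", "half_siblings")


@dataclass(frozen=True)
class RelatednessModel:
    """One relatedness case: allowed IBD states and chain parameters."""

    label: str
    states: tuple[int, ...]
    A: np.ndarray
    pi: np.ndarray
    expected_k: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"{self.label}: transition rows must sum to 1")
        if len(self.states) != self.A.shape[0]:
            raise ValueError(f"{self.label}: states/matrix size mismatch")

    @property
    def group(self) -> str:
        return GROUP_OF_CASE[self.label]


def rate_matrix(case: str, r: float) -> np.ndarray:
    """Per-bp IBD transition rate matrix for cases with a closed form."""
    if case == "grandparent_grandchild":
        return np.array([[-r, r], [r, -r]])
    if case == "siblings":
        return np.array(
            [[-4 * r, 4 * r, 0.0], [2 * r, -4 * r, 2 * r], [0.0, 4 * r, -4 * r]]
        )
    raise ValueError(f"no analytic rate matrix for case {case!r}")


def analytic_transition(case: str, r: float = DEFAULT_R, b: float = DEFAULT_B) -> np.ndarray:
    """Window-scale transition matrix ``e^{Qb}`` for siblings or GP-GC."""
    if r <= 0 or b < 0:
        raise ValueError("require r > 0 and b >= 0")
    A = expm(rate_matrix(case, r) * b)
    A = np.clip(A, 0.0, None)
    return A / A.sum(axis=1, keepdims=True)


def empirical_transition(paths: list[np.ndarray], n_states: int) -> np.ndarray:
    """Row-normalized transition counts from true per-window IBD state paths.

    Each path covers one chromosome (transitions are never counted across
    chromosome boundaries); rows with no observed exits keep a
    self-transition of 1.
    """
    if not paths:
        raise ValueError("no paths supplied")
    counts = np.zeros((n_states, n_states))
    for p in paths:
        p = np.asarray(p, dtype=np.int64)
        if p.size and (p.min() < 0 or p.max() >= n_states):
            raise ValueError("state outside range")
        np.add.at(counts, (p[:-1], p[1:]), 1.0)
    A = np.eye(n_states)
    rows = counts.sum(axis=1)
    nz = rows > 0
    A[nz] = counts[nz] / rows[nz, None]
    return A


# ------------------------------------------------------- matrix text store

_DATA_DIR = "data/transitions"


def save_transition_file(
    path: str | Path, A: np.ndarray, case: str, r: float, b: float,
    source: str, seed: int | None = None, n_sims: int | None = None,
) -> None:
    header = [f"case: {case}", f"r: {r}", f"b: {b}", f"source: {source}"]
    if seed is not None:
        header.append(f"seed: {seed}")
    if n_sims is not None:
        header.append(f"n_sims: {n_sims}")
    np.savetxt(path, A, header="\n".join(header))


def load_transition_file(path_or_name: str | Path) -> np.ndarray:
    """Load a matrix file, either by filesystem path or bundled case name."""
    p = Path(path_or_name)
    if p.exists():
        A = np.loadtxt(p)
    else:
        ref = resources.files("kinhmm").joinpath(f"{_DATA_DIR}/{path_or_name}.tsv")
        with resources.as_file(ref) as fp:
            A = np.loadtxt(fp)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    return A / A.sum(axis=1, keepdims=True)


def model_registry(
    r: float = DEFAULT_R,
    b: float = DEFAULT_B,
    store: dict[str, np.ndarray] | None = None,
) -> dict[str, RelatednessModel]:
    """All ten relatedness models with stationary initial distributions.

    ``store`` optionally overrides the empirical matrices (case -> matrix);
    by default the bundled matrices (estimated from 1000 simulated
    pedigrees at r = 1e-8, b = 10 Mb) are used.  Empirical matrices are
    only valid at the (r, b) they were estimated for; pass a regenerated
    store when changing either.
    """
    registry: dict[str, RelatednessModel] = {}
    for case in CASES:
        if case in _SINGLE_STATE:
            states: tuple[int, ...] = (_SINGLE_STATE[case],)
            A = np.array([[1.0]])
        elif case in _ANALYTIC:
            A = analytic_transition(case, r, b)
            states = (0, 1) if case == "grandparent_grandchild" else (0, 1, 2)
        else:
            if store is not None and case in store:
                A = np.asarray(store[case], dtype=float)
            else:
                try:
                    A = load_transition_file(case)
                except FileNotFoundError as err:
                    raise FileNotFoundError(
                        f"no empirical transition matrix for {case!r}; "
                        "regenerate with kinhmm.simulate.estimate_empirical_transitions"
                    ) from err
            states = tuple(range(A.shape[0]))
        registry[case] = RelatednessModel(
            label=case,
            states=states,
            A=A,
            pi=stationary_distribution(A),
            expected_k=EXPECTED_K[case],
        )
    return registry
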