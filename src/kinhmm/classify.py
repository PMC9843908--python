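"""Model comparison: fit every relatedness case, pick and group the best.

All ten relatedness HMMs are fitted to a pair; the maximum-likelihood case
wins.  Fine cases collapse into reported categories (4th/5th degree into
unrelated; half-siblings, avuncular and grandparent-grandchild into second
degree), and confidence is the log-likelihood ratio between the best model
and the best model from a *different* reported category, so near-ties
inside a category (half-siblings vs avuncular) do not destroy confidence.
The recommended confidence cutoff is 1.0 log-likelihood units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import PairWindowData
from .emissions import EmissionParams
from .kin_hmm import KinFit, em_fit
from .models import GROUP_OF_CASE, READ_COMPARABLE_GROUP, RelatednessModel

__all__ = ["PairResult", "fit_all", "classify", "evaluate_classification", "evaluate_ibd"]

DEFAULT_CUTOFF = 1.0


@dataclass
class PairResult:
    """Classification summary for one pair."""

    pair: tuple[str, str]
    best_case: str
    second_case: str
    best_group: str
    second_group: str
    delta_ll: float  # best vs best-of-other-group
    delta_ll_fine: float  # best vs second-best overall
    confident: bool
    k_hat: tuple[float, float, float]
    logliks: dict[str, float]
    tied: bool = False

    @property
    def r_hat(self) -> float:
        """Coefficient of relatedness r = k1/2 + k2."""
        return self.k_hat[1] / 2.0 + self.k_hat[2]


def fit_all(
    data: PairWindowData,
    h: np.ndarray,
    registry: dict[str, RelatednessModel],
    params: EmissionParams,
    chrom_slices: list[slice] | None = None,
    seed: int = 0,
    **em_kwargs,
) -> dict[str, KinFit]:
    """One EM fit per relatedness model; deterministic under a fixed seed."""
    if data.N.sum() <= 0:
        raise ValueError(f"pair {data.pair}: no overlapping sites in any window")
    fits: dict[str, KinFit] = {}
    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(len(registry))
    for child, (label, model) in zip(children, registry.items()):
        fits[label] = em_fit(
            data, h, model, params, chrom_slices,
            seed=np.random.default_rng(child), **em_kwargs,
        )
    return fits


def classify(
    fits: dict[str, KinFit],
    pair: tuple[str, str] = ("i", "j"),
    cutoff: float = DEFAULT_CUTOFF,
) -> PairResult:
    """Pick the maximum-likelihood case and attach grouped confidence."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to compare")
    order = sorted(fits, key=lambda c: (-fits[c].loglik, _rank(c)))
    best = order[0]
    second = order[1]
    # ties resolve toward the less-related case
    tied = abs(fits[best].loglik - fits[second].loglik) < 1e-9
    if tied and _rank(second) < _rank(best):
        best, second = second, best
    best_group = GROUP_OF_CASE[best]
    other = next(c for c in order if GROUP_OF_CASE[c] != best_group)
    delta_ll = fits[best].loglik - fits[other].loglik
    return PairResult(
        pair=pair,
        best_case=best,
        second_case=second,
        best_group=best_group,
        second_group=GROUP_OF_CASE[other],
        delta_ll=float(delta_ll),
        delta_ll_fine=float(fits[best].loglik - fits[second].loglik),
        confident=bool(delta_ll > cutoff),
        k_hat=fits[best].k_hat(),
        logliks={c: float(f.loglik) for c, f in fits.items()},
        tied=tied,
    )


def regroup_confidence(
    result: PairResult,
    cutoff: float = DEFAULT_CUTOFF,
    remap: dict[str, str] | None = None,
) -> tuple[str, float, bool]:
    """Reported group and cross-group confidence under a coarser grouping.

    With the comparable-methods grouping (3rd-5th degree folded into
    unrelated), the confidence gap must be measured against the best model
    *outside* the folded group — near-ties between, say, the 4th-degree
    and unrelated models are within-group and do not weaken the call.
    Returns ``(group, delta_ll, confident)``.
    """
    remap = READ_COMPARABLE_GROUP if remap is None else remap

    def group(case: str) -> str:
        g = GROUP_OF_CASE[case]
        return remap.get(g, g)

    best_group = group(result.best_case)
    others = [
        ll for case, ll in result.logliks.items() if group(case) != best_group
    ]
    if result.best_case not in result.logliks or not others:
        # per-model likelihoods unavailable: keep the fine-grouping call
        return best_group, result.delta_ll, result.confident
    delta_ll = result.logliks[result.best_case] - max(others)
    return best_group, float(delta_ll), bool(delta_ll > cutoff)


_RELATEDNESS_ORDER = [
    "unrelated", "fifth_degree", "fourth_degree", "third_degree",
    "grandparent_grandchild", "avuncular", "half_siblings",
    "parent_child", "siblings", "identical",
]


def _rank(case: str) -> int:
    return _RELATEDNESS_ORDER.index(case)


def evaluate_classification(
    results: dict[tuple[str, str], PairResult],
    truth: dict[tuple[str, str], str],
    read_comparable: bool = True,
) -> dict[str, dict[str, float]]:
    """True/false-positive rates per reported category under confident calls.

    ``truth`` maps pairs to reported categories.  With ``read_comparable``
    the third-degree category is folded into unrelated on both sides (the
    protocol comparable with pseudo-haploid distance methods); otherwise
    third degree is scored separately.
    """
    remap = READ_COMPARABLE_GROUP if read_comparable else {}
    table: dict[str, dict[str, float]] = {}
    cats = sorted({remap.get(g, g) for g in truth.values()})
    for cat in cats:
        tp = fn = fp = n_true = n_other = 0
        for pair, true_group in truth.items():
            tg = remap.get(true_group, true_group)
            res = results.get(pair)
            if res is None:
                continue
            if read_comparable:
                called, _, confident = regroup_confidence(res, remap=remap)
            else:
                called, confident = res.best_group, res.confident
            hit = confident and called == cat
            if tg == cat:
                n_true += 1
                tp += hit
                fn += not hit
            else:
                n_other += 1
                fp += hit
        table[cat] = {
            "tp_rate": tp / n_true if n_true else float("nan"),
            "fp_rate": fp / n_other if n_other else float("nan"),
            "n_true": n_true,
        }
    return table


def evaluate_ibd(path: np.ndarray, true_center_state: np.ndarray) -> float:
    """Fraction of windows whose predicted IBD state matches the truth at
    the window's central bp."""
    path = np.asarray(path)
    true_center_state = np.asarray(true_center_state)
    if path.shape != true_center_state.shape:
        raise ValueError("path/truth length mismatch")
    return float(np.mean(path == true_center_state))
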