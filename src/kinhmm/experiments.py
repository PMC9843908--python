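"""Simulation experiments: the evaluation protocols behind the headline numbers.

Each experiment simulates cohorts under stated study conditions, runs the
inference end to end on the simulated read counts, and scores it against
the exact simulation truth:

* :func:`classification_experiment` — per-category true/false-positive
  rates of the confident-call classifier (cutoff 1 log-likelihood unit);
* :func:`ibd_accuracy_experiment` — per-window IBD-state accuracy of the
  Viterbi path against the true state at each window's central bp;
* :func:`roh_experiment` — window-level sensitivity/specificity of the
  ROH HMM at the 20%/20% thresholds.

Problem sizes (pedigree counts, replicate counts, chromosome numbers) are
arguments so the same protocols serve quick checks and full evaluations.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classify import classify, evaluate_ibd, fit_all, regroup_confidence
from .contamination import ContaminationParams, correct_pair_counts
from .counts import (
    aggregate_pair_windows,
    cohort_pair_totals,
    within_individual_diffs,
)
from .emissions import EmissionParams
from .kin_hmm import em_fit
from .models import model_registry
from .roh import pair_roh_prior, roh_em_fit, roh_eval, uniform_roh_prior
from .simulate import (
    Cohort,
    SimConfig,
    ascertain_sites,
    build_pedigree,
    generate_reads,
    simulate_founders,
    true_roh_fraction,
    true_states,
)

__all__ = [
    "simulate_cohort",
    "classification_experiment",
    "ibd_accuracy_experiment",
    "roh_experiment",
    "EVALUATED_PAIRS",
]

# pairs scored in the classification protocol, one truth category each;
# "unrelated" truth follows the comparable-methods grouping, so 3rd-5th
# degree pairs count as unrelated truth there
EVALUATED_PAIRS: dict[str, list[tuple[str, str]]] = {
    "identical": [("C1", "C1b")],
    "parent_child": [("F1", "C1"), ("F2", "C2"), ("G1", "H1")],
    "siblings": [("C1", "C2"), ("H1", "H2")],
    "second_degree": [("C1", "C3"), ("C1", "G1"), ("F1", "G1")],
    "unrelated": [("F3", "F4"), ("F5", "F6"), ("F7", "F8"),
                  ("C1", "H1"), ("C1", "I1"), ("F1", "J1")],
}


def simulate_cohort(config: SimConfig, seed) -> Cohort:
    """Founders (ascertained if configured) mated through the template."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founders = simulate_founders(config, rng)
    if config.ascertainment:
        founders = founders.subset(ascertain_sites(founders))
    return build_pedigree(founders, config, rng)


def _cohort_reads(cohort: Cohort, individuals, coverage: float, rng) -> dict:
    return {i: generate_reads(cohort, i, coverage, rng) for i in individuals}


def _estimate_p0(counts: dict, contam: ContaminationParams | None = None) -> float:
    """Cohort-median pairwise rate (contamination-corrected totals)."""
    totals = cohort_pair_totals(list(counts.values()), max_sites=600_000)
    ratios = []
    for (i, j), (d, n) in totals.items():
        if n <= 0:
            continue
        if contam is not None:
            c_ij = contam.rate(i) + contam.rate(j)
            rho = (d / n - c_ij * contam.phi) / (1.0 - c_ij)
            ratios.append(min(max(rho, 1e-9), 1 - 1e-9))
        else:
            ratios.append(d / n)
    return float(np.median(ratios))


def classification_experiment(
    coverage: float,
    n_pedigrees: int = 20,
    config: SimConfig | None = None,
    seed: int = 0,
    cutoff: float = 1.0,
    use_roh_hmm: str = "auto",
    correct_contamination: bool = True,
    categories: tuple[str, ...] | None = None,
) -> dict[str, dict[str, float]]:
    """Per-category TP/FP rates over simulated pedigrees at one coverage.

    Scores the evaluated pairs of each pedigree with the full pipeline:
    p0 from all cohort pairs, ROH HMM when coverage allows (and enabled),
    contamination correction with the true simulated rates and divergence
    when the scenario includes contamination.
    """
    config = config or SimConfig()
    grid = config.layout()
    cs = grid.chrom_slices()
    registry = model_registry(r=config.r, b=config.window_size)
    master = np.random.SeedSequence(entropy=seed)
    eval_pairs = {
        c: v for c, v in EVALUATED_PAIRS.items()
        if categories is None or c in categories
    }
    counts_cat: dict[str, list[bool]] = {}
    for ped_seed in master.spawn(n_pedigrees):
        rng = np.random.default_rng(ped_seed)
        cohort = simulate_cohort(config, rng)
        individuals = sorted({i for ps in eval_pairs.values() for p in ps for i in p})
        # spare founders keep the p0 median anchored on unrelated pairs
        individuals += [f"F{k}" for k in (4, 5, 6, 7, 8) if f"F{k}" not in individuals]
        counts = _cohort_reads(cohort, individuals, coverage, rng)
        contam = None
        if cohort.contamination and correct_contamination:
            contam = ContaminationParams(dict(cohort.contamination), cohort.phi())
        p0 = _estimate_p0(counts, contam)
        params = EmissionParams(p0)
        q = {}
        if use_roh_hmm == "auto" and coverage >= 0.1:
            for ind in individuals:
                inp = within_individual_diffs(counts[ind], grid)
                if contam is not None:
                    from .contamination import correct_roh_counts

                    inp = correct_roh_counts(inp, contam)
                q[ind] = roh_em_fit(inp, p0, cs, seed=rng).q
        for cat, pairs in eval_pairs.items():
            for i, j in pairs:
                data = aggregate_pair_windows(counts[i], counts[j], grid)
                if contam is not None:
                    data = correct_pair_counts(data, contam)
                if q:
                    h = pair_roh_prior(q[i], q[j])
                else:
                    h = uniform_roh_prior(grid.L)
                fits = fit_all(data, h, registry, params, cs,
                               seed=int(rng.integers(2**31 - 1)))
                res = classify(fits, pair=(i, j), cutoff=cutoff)
                # comparable-methods protocol: 3rd-5th degree fold into
                # unrelated, confidence measured across the folded groups
                called, _, confident = regroup_confidence(res, cutoff=cutoff)
                counts_cat.setdefault(cat, []).append(bool(confident and called == cat))
    return {
        cat: {"tp_rate": float(np.mean(v)), "n": len(v)}
        for cat, v in counts_cat.items()
    }


def ibd_accuracy_experiment(
    coverages,
    relations: tuple[str, ...] = ("siblings",),
    n_pedigrees: int = 10,
    config: SimConfig | None = None,
    seed: int = 0,
) -> dict[str, dict[float, float]]:
    """Mean window-center IBD accuracy of the matched-relation model fits.

    For each simulated pair of each requested relation, fits the
    relatedness model matching the truth and scores its Viterbi path
    against the true IBD state at window centers.  Cohorts and reads are
    shared across relations and coverages within a pedigree.
    """
    config = config or SimConfig()
    grid = config.layout()
    cs = grid.chrom_slices()
    registry = model_registry(r=config.r, b=config.window_size)
    master = np.random.SeedSequence(entropy=seed)
    acc: dict[str, dict[float, list[float]]] = {
        r: {c: [] for c in coverages} for r in relations
    }
    for ped_seed in master.spawn(n_pedigrees):
        rng = np.random.default_rng(ped_seed)
        cohort = simulate_cohort(config, rng)
        pair_of = {r: cohort.relations[r] for r in relations}
        individuals = sorted({i for ps in pair_of.values() for p in ps for i in p})
        # include some unrelated individuals so the p0 median is clean
        individuals += [f"F{k}" for k in (4, 5, 6, 7, 8) if f"F{k}" not in individuals]
        for cov in coverages:
            counts = _cohort_reads(cohort, individuals, cov, rng)
            p0 = _estimate_p0(counts)
            params = EmissionParams(p0)
            h = uniform_roh_prior(grid.L)
            for rel in relations:
                for i, j in pair_of[rel]:
                    data = aggregate_pair_windows(counts[i], counts[j], grid)
                    fit = em_fit(data, h, registry[rel], params, cs,
                                 seed=int(rng.integers(2**31 - 1)))
                    truth, _ = true_states(cohort, i, j, grid)
                    acc[rel][cov].append(evaluate_ibd(fit.viterbi_path, truth))
    return {
        r: {c: float(np.mean(v)) for c, v in cov_acc.items()}
        for r, cov_acc in acc.items()
    }


def roh_experiment(
    coverages,
    scenario: str = "roh",
    n_replicates: int = 10,
    config: SimConfig | None = None,
    seed: int = 0,
) -> dict[float, tuple[float, float]]:
    """ROH HMM window-level (Se, Sp) per coverage over seeded replicates.

    ``scenario`` is "roh" (founders carry simulated ROH) or "control"
    (no ROH; sensitivity is undefined and returned as NaN).
    """
    base = config or SimConfig(n_chromosomes=10)
    config = replace(base, roh=(scenario == "roh"))
    grid = config.layout()
    cs = grid.chrom_slices()
    inds = [f"F{k}" for k in range(1, 9)]
    master = np.random.SeedSequence(entropy=seed)
    out: dict[float, tuple[float, float]] = {}
    ses: dict[float, list[float]] = {c: [] for c in coverages}
    sps: dict[float, list[float]] = {c: [] for c in coverages}
    for rep_seed in master.spawn(n_replicates):
        rng = np.random.default_rng(rep_seed)
        cohort = simulate_cohort(config, rng)
        for cov in coverages:
            counts = _cohort_reads(cohort, inds, cov, rng)
            p0 = _estimate_p0(counts)
            for ind in inds:
                inp = within_individual_diffs(counts[ind], grid)
                fit = roh_em_fit(inp, p0, cs, seed=rng)
                se, sp = roh_eval(fit.q, true_roh_fraction(cohort, ind, grid))
                if not np.isnan(se):
                    ses[cov].append(se)
                if not np.isnan(sp):
                    sps[cov].append(sp)
    for cov in coverages:
        out[cov] = (
            float(np.mean(ses[cov])) if ses[cov] else float("nan"),
            float(np.mean(sps[cov])) if sps[cov] else float("nan"),
        )
    return out
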