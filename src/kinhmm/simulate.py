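"""Pedigree, genome and read simulator with known truth.

The generator emulates the study conditions the method is built for:

* eight unrelated diploid founders with background diversity matching a
  target pairwise difference rate ``p0`` (coalescent engine via msprime,
  or the default frequency model: independent sites whose derived-allele
  frequencies follow a 1/f-weighted neutral spectrum calibrated to
  ``p0``, with Balding-Nichols drift for the diverged ascertainment-panel
  and contaminant populations);
* a fixed pedigree template mating the founders into nine further
  individuals (17 total) so that every relatedness case up to 5th degree
  is present, with Poisson recombination (breakpoint count ~ Poisson(rL),
  uniform positions);
* optional long runs of homozygosity in the founders from a two-state
  Markov chain over windows with transition probabilities 10/L out of ROH
  and 2/L into ROH (L = design window count; stationary ROH fraction 1/6,
  mean tract L/10 windows);
* optional SNP ascertainment on an out-of-sample two-individual panel;
* optional contamination of eight individuals by a deeply diverged
  population at per-individual rates in [0.5%, 3%];
* Poisson read depth per site at coverages from 4x down to 0.03x, reads
  drawn from a random chromosome of the endogenous (or, with probability
  c, contaminant) genome, without sequencing error.

Haplotypes are stored as founder-labelled segment lists, so the true IBD
state between any two individuals and the true ROH tracts are known
exactly at every base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .counts import SiteReadCounts
from .layout import GenomeLayout
from .models import empirical_transition

__all__ = [
    "SimConfig",
    "FounderSet",
    "PedigreeGenome",
    "Cohort",
    "simulate_founders",
    "mate",
    "apply_roh",
    "ascertain_sites",
    "build_pedigree",
    "generate_reads",
    "true_ibd_segments",
    "true_states",
    "true_roh_fraction",
    "estimate_empirical_transitions",
    "PEDIGREE_RELATIONS",
    "CONTAMINATED_IDS",
]

# The founder ROH process is a two-state Markov chain over the analysis
# windows: with L the number of windows of the reference genome design
# (22 chromosomes x 96 Mb at 10 Mb windows -> 220), the per-step exit
# probability out of ROH is ROH_EXIT / L and the entry probability is
# ROH_ENTER / L, giving a stationary ROH fraction of 1/6 and window-aligned
# tracts whose mean length is L/10 windows.  L is a fixed property of the
# tract process, not of the simulated genome, so scaled-down genomes keep
# the same tract geometry.
ROH_EXIT = 10.0
ROH_ENTER = 2.0
ROH_CHAIN_WINDOWS = 220


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_chromosomes: int = 22
    chrom_length: int = 96_000_000  # roughly chromosome 13
    window_size: int = 10_000_000  # analysis windows; also the ROH-chain step
    r: float = 1e-8  # recombination, per bp per generation
    mu: float = 1e-8  # mutation, per bp per generation (coalescent engine)
    Ne: int = 10_000
    # Frequency-engine calibration.  The defaults reproduce what the
    # coalescent engine realizes under the demography above: ~2600
    # segregating sites per Mb across the whole four-population sample, of
    # which about half are polymorphic within the target population; a
    # pairwise difference rate p0 ~ 0.15 over all tabulated sites; and a
    # target-contaminant divergence phi ~ 0.30.
    target_p0: float = 0.15
    target_phi: float = 0.30
    sites_per_mb: float = 2600.0
    pop1_poly_fraction: float = 0.5  # sites polymorphic in the target pop
    roh: bool = False
    roh_chain_windows: int = ROH_CHAIN_WINDOWS  # L of the tract Markov chain
    ascertainment: bool = False
    contamination: bool = False
    contamination_range: tuple[float, float] = (0.005, 0.03)
    engine: str = "frequency"  # "frequency" | "msprime"
    # Balding-Nichols drift (F_ST) from the target-population frequency for
    # the ascertainment-panel populations (Pop2, Pop3) and the contaminant
    # source (Pop4), frequency engine only
    fst_pop2: float = 0.12
    fst_pop3: float = 0.12
    fst_pop4: float = 0.85

    def chromosomes(self) -> list[tuple[str, int]]:
        return [(str(i + 1), self.chrom_length) for i in range(self.n_chromosomes)]

    def layout(self, window_size: int | None = None) -> GenomeLayout:
        return GenomeLayout(tuple(self.chromosomes()), window_size or self.window_size)

    def n_windows(self) -> int:
        per_chrom = -(-self.chrom_length // self.window_size)
        return self.n_chromosomes * per_chrom


@dataclass
class FounderSet:
    """Site table plus allele matrices for founders, panel and contaminants.

    ``alleles[chrom]`` is (16, S) for the founder haplotypes (haplotype
    ``2k, 2k+1`` belong to founder ``k``); ``panel`` is (4, S) and
    ``contaminant`` (10, S): five diploid contaminant individuals.
    """

    positions: dict[str, np.ndarray]
    alleles: dict[str, np.ndarray]
    panel: dict[str, np.ndarray]
    contaminant: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def subset(self, masks: dict[str, np.ndarray]) -> "FounderSet":
        def cut(mat: np.ndarray, m: np.ndarray) -> np.ndarray:
            return mat[:, m] if mat.shape[1] else mat

        return FounderSet(
            positions={c: self.positions[c][m] for c, m in masks.items()},
            alleles={c: self.alleles[c][:, m] for c, m in masks.items()},
            panel={c: cut(self.panel[c], m) for c, m in masks.items()},
            contaminant={c: cut(self.contaminant[c], m) for c, m in masks.items()},
        )

    def realized_p0(self) -> float:
        """Mean probability that two distinct founder chromosomes differ."""
        tot, n = 0.0, 0
        for c in self.chroms:
            x = self.alleles[c].sum(axis=0).astype(float)
            k = self.alleles[c].shape[0]
            tot += float((x * (k - x)).sum()) / (k * (k - 1) / 2.0)
            n += len(x)
        return tot / n

    def realized_phi(self) -> float:
        """Mean mismatch rate between founder and contaminant chromosomes."""
        tot, n = 0.0, 0
        for c in self.chroms:
            f1 = self.alleles[c].mean(axis=0)
            f4 = self.contaminant[c].mean(axis=0)
            tot += float((f1 * (1 - f4) + f4 * (1 - f1)).sum())
            n += len(f1)
        return tot / n


# haplotype = (ends, labels): segment k covers [ends[k-1], ends[k]) in
# 0-based bp and carries the founder-haplotype label labels[k]
Hap = tuple[np.ndarray, np.ndarray]


@dataclass
class PedigreeGenome:
    """Diploid genome as founder-labelled segments, per chromosome."""

    id: str
    haps: dict[str, tuple[Hap, Hap]]


def _spectrum_eps(target: float, moment: str) -> float:
    """Lower cutoff of the 1/f frequency spectrum hitting a target moment.

    With density proportional to 1/f on [eps, 1], the mean of 2f(1-f)
    (pairwise difference rate) is (1-eps)^2 / ln(1/eps) and the mean of f
    is (1-eps) / ln(1/eps); both are increasing in eps on (0, ~0.3), which
    is the branch used for root finding.
    """
    if moment == "het":
        fn = lambda eps: (1 - eps) ** 2 / np.log(1 / eps)  # noqa: E731
    elif moment == "mean":
        fn = lambda eps: (1 - eps) / np.log(1 / eps)  # noqa: E731
    else:
        raise ValueError(moment)
    if not fn(1e-12) < target < fn(0.3):
        raise ValueError(f"target {moment}={target} outside the calibratable range")
    return float(brentq(lambda eps: fn(eps) - target, 1e-12, 0.3))


def _bn_freq(f: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols drifted population frequency around ancestral f."""
    if fst <= 0:
        return f.copy()
    lam = (1.0 - fst) / fst
    return rng.beta(np.maximum(f * lam, 1e-12), np.maximum((1 - f) * lam, 1e-12))


def simulate_founders(
    config: SimConfig, seed: int | np.random.Generator = 0, n_diploid: int = 8
) -> FounderSet:
    """Unrelated founder diversity plus panel and contaminant genomes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config.engine == "msprime":
        return _simulate_founders_msprime(config, rng, n_diploid)
    if config.engine != "frequency":
        raise ValueError(f"unknown engine {config.engine!r}")
    # Two site classes emulate the coalescent site table:
    # * class A (weight w): polymorphic in the target population, frequency
    #   from a 1/f spectrum with cutoff eps_A so that the overall pairwise
    #   rate over ALL sites is target_p0;
    # * class B (weight 1-w): monomorphic ancestral in the target population
    #   (deep outgroup-branch variants), derived in the contaminant source
    #   with spectrum cutoff eps_B so that the realized target-contaminant
    #   divergence is target_phi.
    w = config.pop1_poly_fraction
    if not 0.0 < w <= 1.0:
        raise ValueError("pop1_poly_fraction must be in (0, 1]")
    if config.target_phi <= config.target_p0:
        raise ValueError("target_phi must exceed target_p0")
    eps_a = _spectrum_eps(config.target_p0 / w, "het")
    eps_b = _spectrum_eps((config.target_phi - config.target_p0) / (1.0 - w), "mean")
    positions, alleles, panel, contaminant = {}, {}, {}, {}
    for name, length in config.chromosomes():
        S = int(round(config.sites_per_mb * length / 1e6))
        pos = np.unique(rng.integers(1, length + 1, size=S))
        S = len(pos)
        in_a = rng.random(S) < w
        f1 = np.where(in_a, eps_a ** (1.0 - rng.random(S)), 0.0)
        positions[name] = pos
        alleles[name] = (rng.random((2 * n_diploid, S)) < f1).astype(np.uint8)
        # panel/contaminant genomes are only materialized for scenarios
        # that use them; empty arrays otherwise
        if config.ascertainment:
            f2 = np.where(in_a, _bn_freq(f1, config.fst_pop2, rng), 0.0)
            f3 = np.where(in_a, _bn_freq(f1, config.fst_pop3, rng), 0.0)
            panel[name] = np.vstack(
                [(rng.random((2, S)) < f2), (rng.random((2, S)) < f3)]
            ).astype(np.uint8)
        else:
            panel[name] = np.empty((4, 0), np.uint8)
        if config.contamination:
            f4 = np.where(in_a, _bn_freq(f1, config.fst_pop4, rng),
                          eps_b ** (1.0 - rng.random(S)))
            contaminant[name] = (rng.random((10, S)) < f4).astype(np.uint8)
        else:
            contaminant[name] = np.empty((10, 0), np.uint8)
    return FounderSet(positions, alleles, panel, contaminant)


def _simulate_founders_msprime(
    config: SimConfig, rng: np.random.Generator, n_diploid: int
) -> FounderSet:
    """Coalescent founder engine (four-population demography)."""
    import msprime

    demography = msprime.Demography()
    for pop in ("Pop1", "Pop2", "Pop3", "Pop4"):
        demography.add_population(name=pop, initial_size=config.Ne)
    for anc, t, derived in (
        ("anc12", 3500, ("Pop1", "Pop2")),
        ("anc123", 4500, ("anc12", "Pop3")),
        ("anc1234", 20000, ("anc123", "Pop4")),
    ):
        demography.add_population(name=anc, initial_size=config.Ne)
        demography.add_population_split(time=t, derived=list(derived), ancestral=anc)
    samples = [
        msprime.SampleSet(n_diploid, population="Pop1", time=2500, ploidy=2),
        msprime.SampleSet(1, population="Pop2", time=2000, ploidy=2),
        msprime.SampleSet(1, population="Pop3", time=4000, ploidy=2),
        msprime.SampleSet(5, population="Pop4", time=0, ploidy=2),
    ]
    positions, alleles, panel, contaminant = {}, {}, {}, {}
    seeds = rng.integers(1, 2**31 - 1, size=2 * config.n_chromosomes)
    for i, (name, length) in enumerate(config.chromosomes()):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=length,
            recombination_rate=config.r,
            random_seed=int(seeds[2 * i]),
        )
        ts = msprime.sim_mutations(
            ts, rate=config.mu, random_seed=int(seeds[2 * i + 1]),
            model=msprime.BinaryMutationModel(),
        )
        G = ts.genotype_matrix().T.astype(np.uint8)  # haplotypes x sites
        pos = ts.tables.sites.position.astype(np.int64) + 1
        keep = np.concatenate([[True], np.diff(pos) > 0])
        nf = 2 * n_diploid
        positions[name] = pos[keep]
        alleles[name] = np.ascontiguousarray(G[:nf, keep])
        panel[name] = np.ascontiguousarray(G[nf : nf + 4, keep])
        contaminant[name] = np.ascontiguousarray(G[nf + 4 : nf + 14, keep])
    return FounderSet(positions, alleles, panel, contaminant)


# ----------------------------------------------------------- segment algebra


def _extract(hap: Hap, start: int, end: int) -> tuple[list[int], list[int]]:
    """Segment (ends, labels) of ``hap`` restricted to [start, end)."""
    ends, labels = hap
    i = int(np.searchsorted(ends, start, side="right"))
    out_e: list[int] = []
    out_l: list[int] = []
    while True:
        e = int(ends[i])
        if e >= end:
            out_e.append(end)
            out_l.append(int(labels[i]))
            break
        out_e.append(e)
        out_l.append(int(labels[i]))
        i += 1
    return out_e, out_l


def _compact(ends: list[int], labels: list[int]) -> Hap:
    e = np.asarray(ends, dtype=np.int64)
    l = np.asarray(labels, dtype=np.int64)
    if len(l) > 1:
        keep = np.concatenate([l[1:] != l[:-1], [True]])
        e, l = e[keep], l[keep]
    return e, l


def _gamete(pair: tuple[Hap, Hap], length: int, r: float, rng: np.random.Generator) -> Hap:
    """One recombined haplotype: Poisson(rL) breakpoints, uniform positions."""
    n_bp = rng.poisson(r * length)
    cuts = np.unique(rng.integers(1, length, size=n_bp)) if n_bp else np.empty(0, np.int64)
    edges = np.concatenate([cuts, [length]]).astype(np.int64)
    cur = int(rng.integers(2))
    ends: list[int] = []
    labels: list[int] = []
    start = 0
    for end in edges:
        e, l = _extract(pair[cur], start, int(end))
        ends.extend(e)
        labels.extend(l)
        start = int(end)
        cur = 1 - cur
    return _compact(ends, labels)


def mate(
    a: PedigreeGenome, b: PedigreeGenome, config: SimConfig,
    rng: np.random.Generator, child_id: str,
) -> PedigreeGenome:
    """Child genome from one recombined gamete of each parent."""
    haps = {}
    for name, length in config.chromosomes():
        haps[name] = (
            _gamete(a.haps[name], length, config.r, rng),
            _gamete(b.haps[name], length, config.r, rng),
        )
    return PedigreeGenome(child_id, haps)


def apply_roh(
    genome: PedigreeGenome, config: SimConfig, rng: np.random.Generator
) -> PedigreeGenome:
    """Overwrite one haplotype with the other inside Markov-chain ROH tracts.

    The chain steps over the analysis windows with exit probability 10/L
    and entry probability 2/L (L = window count of the reference genome
    design, default 220), so tracts are window-aligned with geometric
    window counts (mean L/10 windows) and a stationary ROH fraction of
    1/6.  Copying the segment labels along with the alleles makes the
    tract visible to the exact IBD/ROH truth computations.
    """
    L = config.roh_chain_windows
    p_exit, p_enter = ROH_EXIT / L, ROH_ENTER / L
    b = config.window_size
    haps = {}
    for name, length in config.chromosomes():
        h0, h1 = genome.haps[name]
        state = rng.random() < (p_enter / (p_enter + p_exit))  # stationary
        pos = 0
        ends: list[int] = []
        labels: list[int] = []
        while pos < length:
            tract_windows = int(rng.geometric(p_exit if state else p_enter))
            end = min(pos + tract_windows * b, length)
            src = h0 if state else h1  # inside ROH copy hap0 over hap1
            e, l = _extract(src, pos, end)
            ends.extend(e)
            labels.extend(l)
            pos = end
            state = not state
        haps[name] = (h0, _compact(ends, labels))
    return PedigreeGenome(genome.id, haps)


# ------------------------------------------------------------ the pedigree

# template topology: founders F1..F8, derived C1..J1, C1b a second sample
# of C1's genome.  Every relatedness case up to 5th degree occurs.
_MATINGS = (
    ("C1", "F1", "F2"),
    ("C2", "F1", "F2"),
    ("C3", "F2", "F3"),
    ("G1", "C2", "F4"),
    ("H1", "G1", "F5"),
    ("H2", "G1", "F5"),
    ("I1", "H1", "F6"),
    ("J1", "I1", "F7"),
)

PEDIGREE_RELATIONS: dict[str, list[tuple[str, str]]] = {
    "identical": [("C1", "C1b")],
    "parent_child": [("F1", "C1"), ("F2", "C2"), ("G1", "H1")],
    "siblings": [("C1", "C2"), ("H1", "H2")],
    "half_siblings": [("C1", "C3")],
    "avuncular": [("C1", "G1"), ("H2", "I1")],
    "grandparent_grandchild": [("F1", "G1"), ("C2", "H1")],
    "third_degree": [("F1", "H1"), ("C1", "H1")],
    "fourth_degree": [("F1", "I1"), ("C1", "I1")],
    "fifth_degree": [("F1", "J1")],
    "unrelated": [("F3", "F4"), ("F4", "F5"), ("F5", "F6"), ("F6", "F7"), ("F7", "F8")],
}

CONTAMINATED_IDS = ("F1", "F2", "F5", "F7", "C2", "G1", "H2", "I1")


@dataclass
class Cohort:
    """Simulated cohort: genomes, truth, and read-generation machinery."""

    config: SimConfig
    founders: FounderSet
    genomes: dict[str, PedigreeGenome]
    relations: dict[str, list[tuple[str, str]]]
    contamination: dict[str, float] = field(default_factory=dict)
    contaminant_of: dict[str, int] = field(default_factory=dict)
    _genotype_cache: dict[str, dict[str, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    @property
    def individuals(self) -> list[str]:
        return list(self.genomes)

    def phi(self) -> float:
        return self.founders.realized_phi()

    def genotypes(self, ind: str) -> dict[str, np.ndarray]:
        """Diploid genotype (0/1/2 derived copies) at every site (cached)."""
        if ind in self._genotype_cache:
            return self._genotype_cache[ind]
        g = self.genomes[ind]
        for other, og in self.genomes.items():  # genome aliases share entries
            if other != ind and og.haps is g.haps and other in self._genotype_cache:
                self._genotype_cache[ind] = self._genotype_cache[other]
                return self._genotype_cache[ind]
        out = {}
        for chrom, pos in self.founders.positions.items():
            pos0 = pos - 1
            tot = np.zeros(len(pos), dtype=np.uint8)
            site_idx = np.arange(len(pos))
            for ends, labels in g.haps[chrom]:
                idx = np.searchsorted(ends, pos0, side="right")
                tot = tot + self.founders.alleles[chrom][labels[idx], site_idx]
            out[chrom] = tot
        self._genotype_cache[ind] = out
        return out


def build_pedigree(
    founders: FounderSet, config: SimConfig, seed: int | np.random.Generator = 0
) -> Cohort:
    """Mate the founders through the fixed template into a 17-sample cohort."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if founders.alleles[founders.chroms[0]].shape[0] != 16:
        raise ValueError("pedigree template requires 8 diploid founders")
    genomes: dict[str, PedigreeGenome] = {}
    for k in range(8):
        haps = {}
        for name, length in config.chromosomes():
            haps[name] = (
                (np.array([length], dtype=np.int64), np.array([2 * k], dtype=np.int64)),
                (np.array([length], dtype=np.int64), np.array([2 * k + 1], dtype=np.int64)),
            )
        genomes[f"F{k + 1}"] = PedigreeGenome(f"F{k + 1}", haps)
    if config.roh:
        for k in range(8):
            fid = f"F{k + 1}"
            genomes[fid] = apply_roh(genomes[fid], config, rng)
    for child, pa, pb in _MATINGS:
        genomes[child] = mate(genomes[pa], genomes[pb], config, rng, child)
    genomes["C1b"] = PedigreeGenome("C1b", genomes["C1"].haps)

    contamination: dict[str, float] = {}
    contaminant_of: dict[str, int] = {}
    if config.contamination:
        lo, hi = config.contamination_range
        for k, ind in enumerate(CONTAMINATED_IDS):
            contamination[ind] = float(rng.uniform(lo, hi))
            contaminant_of[ind] = k % 5
    return Cohort(
        config=config,
        founders=founders,
        genomes=genomes,
        relations={k: list(v) for k, v in PEDIGREE_RELATIONS.items()},
        contamination=contamination,
        contaminant_of=contaminant_of,
    )


def ascertain_sites(founders: FounderSet) -> dict[str, np.ndarray]:
    """Mask of sites polymorphic among the four panel chromosomes."""
    masks = {}
    for chrom in founders.chroms:
        x = founders.panel[chrom].sum(axis=0)
        masks[chrom] = (x > 0) & (x < founders.panel[chrom].shape[0])
    return masks


def generate_reads(
    cohort: Cohort,
    ind: str,
    coverage: float,
    seed: int | np.random.Generator,
    contamination_rate: float | None = None,
) -> SiteReadCounts:
    """Poisson-depth read counts, optionally mixed with contaminant reads.

    Each read picks a random chromosome of the endogenous genome with
    probability 1-c, else of the assigned contaminant individual; there is
    no sequencing-error model.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    c = cohort.contamination.get(ind, 0.0) if contamination_rate is None else contamination_rate
    if not 0.0 <= c <= 1.0:
        raise ValueError("contamination rate outside [0, 1]")
    genotypes = cohort.genotypes(ind)
    data = {}
    k = cohort.contaminant_of.get(ind, 0)

    def _derived(n_reads: np.ndarray, g: np.ndarray) -> np.ndarray:
        """Reads carrying the derived allele; genotype-wise (g in 0/1/2)."""
        der = np.zeros(len(n_reads), dtype=np.int32)
        hom = g == 2
        der[hom] = n_reads[hom]
        het = (g == 1) & (n_reads > 0)
        der[het] = rng.binomial(n_reads[het], 0.5)
        return der

    for chrom, pos in cohort.founders.positions.items():
        g = genotypes[chrom]
        tot = rng.poisson(coverage, size=len(pos)).astype(np.int32)
        if c > 0:
            endo = rng.binomial(tot, 1.0 - c)
            gc = (
                cohort.founders.contaminant[chrom][2 * k]
                + cohort.founders.contaminant[chrom][2 * k + 1]
            )
            der = _derived(endo, g) + _derived(tot - endo, gc)
        else:
            der = _derived(tot, g)
        data[chrom] = (pos, der, tot)
    return SiteReadCounts(ind, data, validate=False)


# ----------------------------------------------------------------- truth


def _pair_state_segments(
    gi: PedigreeGenome, gj: PedigreeGenome, chrom: str
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant IBD state along one chromosome: (ends, states)."""
    haps = [gi.haps[chrom][0], gi.haps[chrom][1], gj.haps[chrom][0], gj.haps[chrom][1]]
    ends = np.unique(np.concatenate([h[0] for h in haps]))
    mids = ends - 1  # any position inside each merged segment
    lab = []
    for e, l in haps:
        lab.append(l[np.searchsorted(e, mids, side="right")])
    x, y, u, v = lab
    mxu = (u == x).astype(np.int64) + (v == x)
    mxy = (u == y).astype(np.int64) + (v == y)
    state = np.where(
        x == y,
        np.minimum(2, mxu),
        np.minimum(1, mxu) + np.minimum(1, mxy),
    )
    return ends, state


def true_ibd_segments(
    cohort: Cohort, i: str, j: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Exact IBD state segments (ends, states) per chromosome for a pair."""
    return {
        chrom: _pair_state_segments(cohort.genomes[i], cohort.genomes[j], chrom)
        for chrom, _ in cohort.config.chromosomes()
    }


def _occupancy(
    ends: np.ndarray, values: np.ndarray, length: int, window_size: int,
    n_values: int,
) -> np.ndarray:
    """Fraction of each window covered by each value of a step function."""
    n_win = -(-length // window_size)
    out = np.zeros((n_win, n_values))
    start = 0
    for e, v in zip(ends, values):
        w0, w1 = start // window_size, (int(e) - 1) // window_size
        for w in range(w0, w1 + 1):
            lo = max(start, w * window_size)
            hi = min(int(e), (w + 1) * window_size, length)
            out[w, int(v)] += hi - lo
        start = int(e)
    widths = np.minimum(
        (np.arange(n_win) + 1) * window_size, length
    ) - np.arange(n_win) * window_size
    return out / widths[:, None]


def true_states(
    cohort: Cohort, i: str, j: str, grid: GenomeLayout
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window true IBD: state at the window's central bp, and occupancy.

    Returns ``(center_state, occupancy)`` with occupancy an L x 3 matrix of
    the fraction of each window in IBD state 0/1/2.
    """
    segs = true_ibd_segments(cohort, i, j)
    centers = grid.window_centers()
    center_state = np.empty(grid.L, dtype=np.int64)
    occ = np.zeros((grid.L, 3))
    for chrom, sl in zip(grid.chrom_names, grid.chrom_slices()):
        ends, states = segs[chrom]
        c = centers[sl] - grid.window_start[sl][0]
        center_state[sl] = states[np.searchsorted(ends, c, side="right")]
        occ[sl] = _occupancy(
            ends, states, grid.chrom_length(chrom), grid.window_size, 3
        )
    return center_state, occ


def true_roh_fraction(cohort: Cohort, ind: str, grid: GenomeLayout) -> np.ndarray:
    """Fraction of each window where the individual's haplotypes are IBD."""
    g = cohort.genomes[ind]
    out = np.zeros(grid.L)
    for chrom, sl in zip(grid.chrom_names, grid.chrom_slices()):
        (e0, l0), (e1, l1) = g.haps[chrom]
        ends = np.unique(np.concatenate([e0, e1]))
        mids = ends - 1
        same = (
            l0[np.searchsorted(e0, mids, side="right")]
            == l1[np.searchsorted(e1, mids, side="right")]
        )
        occ = _occupancy(
            ends, same.astype(np.int64), grid.chrom_length(chrom), grid.window_size, 2
        )
        out[sl] = occ[:, 1]
    return out


# ----------------------------------------- empirical transition estimation


def estimate_empirical_transitions(
    cases: tuple[str, ...] = (
        "fifth_degree", "fourth_degree", "third_degree", "avuncular", "half_siblings",
    ),
    n_sims: int = 1000,
    config: SimConfig | None = None,
    window_size: int = 10_000_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Transition matrices from true window-center IBD paths of simulated pairs.

    Segment-level only (no sites or reads), so a 1000-pedigree training set
    runs in seconds.  Transitions are counted within chromosomes.
    """
    config = config or SimConfig()
    grid = config.layout(window_size)
    rng = np.random.default_rng(seed)
    dummy = FounderSet(
        positions={c: np.empty(0, np.int64) for c, _ in config.chromosomes()},
        alleles={c: np.empty((16, 0), np.uint8) for c, _ in config.chromosomes()},
        panel={c: np.empty((4, 0), np.uint8) for c, _ in config.chromosomes()},
        contaminant={c: np.empty((10, 0), np.uint8) for c, _ in config.chromosomes()},
    )
    paths: dict[str, list[np.ndarray]] = {c: [] for c in cases}
    for _ in range(n_sims):
        cohort = build_pedigree(dummy, config, rng)
        for case in cases:
            for i, j in cohort.relations[case]:
                center, _ = true_states(cohort, i, j, grid)
                for sl in grid.chrom_slices():
                    paths[case].append(center[sl])
    return {case: empirical_transition(paths[case], n_states=2) for case in cases}
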