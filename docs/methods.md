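# Methods

## Problem and model

`kinhmm` infers how two low-coverage diploid genomes are related from the
pattern of identity-by-descent (IBD) sharing along the genome.  At any
position two individuals share 0, 1 or 2 chromosomes IBD; the genome-wide
proportions (k0, k1, k2) determine the relationship (siblings share
0.25/0.5/0.25, a parent and child 0/1/0, and so on), and the coefficient
of relatedness is r = k1/2 + k2.

Because IBD is not observable from a handful of reads per site, the
genome is cut into large windows (default 10 Mb) and, for each pair, two
summary vectors are formed from the per-site read counts:

* `N_w` — the number of sites in window `w` covered by at least one read
  in both individuals;
* `D_w` — the expected number of pseudo-haploid differences at those
  sites, summing `nu_i (1 - nu_j) + (1 - nu_i) nu_j` over sites, where
  `nu` is each individual's derived-read proportion.  This is the
  expectation of the classic sample-one-read-per-site comparison over all
  possible samplings, so no data are discarded.

A hidden Markov model runs over the windows with hidden state
`Z_w ∈ {0,1,2}` (chromosomes shared IBD).  The expected mismatch rate in
a window depends on how many of the four cross-individual chromosome
comparisons are between identical chromosomes, indexed by a level
`i ∈ {0,1,2,4}`:

    p0  (background pairwise rate),  p1 = 3/4 p0,  p2 = 1/2 p0,  p4 = 1/2 p2.

Runs of homozygosity (ROH) inside either individual move a window to a
higher level (the `(Z, H)` level matrix in `kinhmm.emissions`), because a
homozygous individual contributes two identical chromosomes to the
comparison.  `p4` would be 0 for a fully inbred, fully IBD window; the
value `p2/2` is a deliberate compromise for windows that only partially
overlap ROH tracts.

`p0` is estimated as the cohort median of genome-wide `D/N` over all
pairs, which is robust as long as most pairs are unrelated; a user
override exists for heavily related cohorts.  The estimate must fall in
(0, 0.5) or the run aborts with advice.

Emissions are beta-binomial in the Balding–Nichols parameterization
(mean `p_i`, over-dispersion `delta_i`, variance of the underlying beta
`p(1-p)/(delta+1)`), generalized through log-Gamma functions so that the
non-integer `D_w`, `N_w` produced by read-proportion sums and
contamination correction are handled exactly.  Windows with `N_w = 0`
emit probability 1 in every state so chains still traverse them.

## Relatedness cases and transitions

Ten cases are fitted per pair: unrelated, 5th/4th/3rd degree,
grandparent–grandchild, avuncular, half-siblings, parent–child, siblings,
identical.  Unrelated, parent–child and identical are single-state
chains.  Siblings and grandparent–grandchild have closed-form transition
matrices `exp(Qb)` with recombination-rate matrices

    GP-GC:    Q = [[-r, r], [r, -r]]
    siblings: Q = [[-4r, 4r, 0], [2r, -4r, 2r], [0, 4r, -4r]]

(`r` = 1e-8 /bp/gen, `b` = window size).  The remaining two-state cases
have no convenient closed form; their matrices are estimated by counting
window-to-window transitions of the *true* IBD state in 1000 simulated
pedigrees (segment-level only, seconds of compute) and are shipped as
text files under `kinhmm/data/transitions/` with the generation seed in
the header.  They can be regenerated with
`kinhmm.simulate.estimate_empirical_transitions` or
`kinhmm estimate-transitions`.  Initial distributions are always the
stationary distribution of the case's transition matrix, and chains
restart there at every chromosome boundary.

## Fitting

Only the over-dispersions `delta_i` are free per (pair, case) fit.  They
are estimated by EM: the E-step is scaled forward–backward; the M-step
collapses the posterior over `(Z, H)` onto levels (the `g`-weights, with
level 3 structurally empty) and maximizes each level's weighted
log-emission independently with a bounded scalar search over log(delta)
(tolerance 1% — far below anything the likelihood can resolve).
`delta` starts at a
seeded uniform draw in (0, 1000]; convergence is declared at 1e-4
log-likelihood units, with a cap of 100 iterations.  If the scalar search
fails to beat the previous value, the previous value is kept, which makes
the ascent monotone when the ROH prior is degenerate; with an informative
ROH prior the level weights are an approximation (the prior is not
re-weighted by the emission) and the ascent is monotone only to ~1e-2.

### Variance constraint

Unconstrained `delta` lets a case with fewer states absorb data from a
case with more states by inflating its variance — and, symmetrically,
lets an unused extra state with a wide beta become a garbage collector
for the outlier windows every realistic genome has (tract-boundary
windows whose rates sit between the level means), so that the wrong case
can win the model comparison confidently.  The over-dispersions are
therefore constrained so that level distributions stay well separated:
each level's standard deviation may claim at most a third of the gap to
the nearest other level mean,

    delta_i >= p_i (1 - p_i) / (gap_i / 3)^2 - 1,

floored at 1e-6 and capped at 1e6 (bounds of the scalar search).  The
separation margin was chosen as the loosest of the candidate readings of
"distributions overlap by at most one standard deviation" that actually
achieves the constraint's purpose: with `sd <= gap` the non-homozygous
ROH state swallows true ROH dips at low coverage (detection collapses)
and the sibling model's unused IBD-2 state confidently steals
grandparent-grandchild pairs at high coverage; `sd <= gap/2` fixes the
former but not the latter; `sd <= gap/3` suppresses both without
degrading any other protocol.  `gap_fraction` in
`kinhmm.emissions.delta_constraint_interval` exposes the choice.

## ROH HMM

Per individual, sites with at least two reads contribute a within-
individual mismatch probability per site — by default the unbiased
without-replacement form `2 d (n - d) / (n (n - 1))`, whose expectation
at a heterozygous site is 1/2 at *every* depth, matching the fixed
non-homozygous emission mean `p2 = p0/2`.  (The plug-in form
`2 nu (1 - nu)` is available but biased low by `1/(2n)`, which at the
2-read depths that dominate low-coverage data would contradict the fixed
means.)  A two-state HMM (non-homozygous mean `p2`, homozygous mean `p4`,
both means fixed; over-dispersions and the full transition matrix
estimated, the latter by Baum–Welch) yields per-window posterior
probabilities of homozygosity.  Windows whose observed mismatch
proportion exceeds `p2` are forced into the non-homozygous state by an
emission override, so transitions stay coherent.  The initial
distribution is the stationary distribution of the current transition
matrix at each iteration (which is why the ascent is approximate, to
~1e-2 log-likelihood units).

Baum–Welch here has data-dependent local optima: from the mobile start
(off-diagonal 0.2) the unused homozygous state can latch onto randomly
low windows of ROH-free genomes.  The EM therefore runs from two starts
(0.2 and a sticky 0.01) and keeps the higher-likelihood solution.

The ROH HMM runs only for individuals with mean depth >= 0.1 reads/site
(configurable); below that, and whenever it is disabled, the pair prior
is `h = (1, 0, 0)` and the pair HMM reduces exactly to the no-ROH model.
Two individuals' posteriors combine independently into
`h_w = P(H_w = omega)`.

## Contamination correction

Present-day contamination at known small rates `C_i` (< 5% assumed,
warned otherwise) with known target–contaminant divergence `phi` is
corrected before anything else.  A cross-individual read comparison
involves a contaminant read with probability `C_ij = C_i + C_j`
(contaminant–contaminant comparisons ignored); the genome-wide endogenous
rate is `rho = (ΣD/ΣN − C_ij φ) / (1 − C_ij)`, and each window's
difference and match counts are shrunk by the posterior probability that
the comparison was endogenous given its outcome.  Within-individual
counts are corrected identically with comparison-level contamination
`2 C_i` (either of the two reads drawn at a site may be contaminant); the
factor is configurable.  `rho` is computed once per pair from genome-wide
totals; the correction is per-window linear.

## Classification

All ten fits are compared by final log-likelihood.  Fine cases collapse
into six reported categories (4th/5th degree → unrelated; half-siblings,
avuncular, GP–GC → second degree).  The confidence statistic ΔLL is the
log-likelihood gap between the best model and the best model of a
*different* category, so near-ties inside a category (half-siblings vs
avuncular, which are barely distinguishable) do not destroy confidence;
the plain best-vs-second gap is also reported.  Calls with ΔLL above the
cutoff (default 1.0 log-likelihood units) are flagged confident.  Exact
likelihood ties resolve toward the less related case and are flagged.
`k_hat` comes from mean posterior state frequencies of the winning model
(not Viterbi), which degrades more gracefully at low coverage.

## Simulator

The generator reproduces the validation conditions end to end: 8 founder
diploids, a fixed mating template producing 17 individuals covering every
case up to 5th degree (including a duplicated genome for the
identical-pair case, read twice independently), Poisson recombination
(breakpoint count ~ Poisson(rL), uniform positions), optional founder
ROH, optional ascertainment on a 2-individual out-of-sample panel,
optional contamination of a fixed subset of 8 individuals at rates
drawn from [0.5%, 3%], and Poisson read depth per site with no
sequencing-error model.  Haplotypes are founder-labelled segment lists,
so true IBD states and ROH tracts are exact by construction; relation
labels are verified against realized genome-wide IBD fractions in the
test suite rather than trusted from the template.

Founder diversity comes from either engine:

* **msprime** (optional extra): four populations of Ne = 10,000; the
  target population sampled 2500 generations ago; panel populations
  splitting 3500 and 4500 generations ago (sampled 2000 and 4000
  generations ago); the contaminant source splitting 20,000 generations
  ago; mutation and recombination at 1e-8 per bp per generation.
* **frequency model** (default, dependency-free): independent sites in
  two classes — sites polymorphic in the target population with
  derived-allele frequencies from a 1/f spectrum, and sites monomorphic
  in the target but derived in the contaminant source.  Class weights and
  spectrum cutoffs are calibrated by root-finding so the realized site
  density (~2600/Mb), pairwise difference rate over all sites (p0 ≈
  0.15), and target–contaminant divergence (phi ≈ 0.30) match what the
  coalescent engine realizes under the demography above.  Panel and
  contaminant frequencies drift from the target frequency by
  Balding–Nichols sampling (F_ST 0.12 / 0.85).

  What the frequency model does *not* emulate: linkage disequilibrium and
  local genealogical correlation (window-to-window variation in true
  diversity is purely binomial), recombination-rate and site-density
  heterogeneity, sequencing error and ancient-DNA damage.  Passing tests
  therefore demonstrate correctness of the inference machinery under the
  model's own assumptions, not robustness to every property of real
  ancient DNA.

Founder ROH follows a two-state Markov chain over windows with exit
probability 10/L and entry 2/L per window, where L = 220 is the window
count of the reference genome design (22 chromosomes × 96 Mb at 10 Mb).
The stationary ROH fraction is 1/6 (~17% of the genome) and tracts are
window-aligned with mean length L/10 windows.  L is a property of the
tract process, not of the simulated genome: scaled-down genomes keep the
same tract geometry (recomputing L from a smaller genome would double
tract-boundary density and mechanically depress window-level
specificity).  Tracts are realized by overwriting one haplotype with the
other — labels included — so they are visible to the exact truth
computations.

## Problem sizes used in the checks

The shipped test suite and the acceptance script run scaled-down versions
of the full validation protocols, chosen once as a compromise between
statistical resolution and an ordinary test run: 20 pedigrees for
simulator-fidelity and classification checks (10 in the test suite),
10 replicates × 10 chromosomes for ROH detection, 10 pedigrees ×
5 coverages for IBD accuracy, and 5 pedigrees × 12 chromosomes for the
contamination-robustness comparison.  Sensitivity/specificity bounds are
asserted at the reference table's printed two-decimal precision.

## Numerical choices and degenerate inputs

* Forward–backward uses per-window scaling with per-window max-shift of
  log emissions; per-chromosome log-likelihoods add exactly.
* Viterbi breaks ties toward the lower IBD state (argmax-first
  convention), and is invariant to per-window emission scaling.
* Stationary distributions come from a least-squares solve of
  `pi (A - I) = 0` with the normalization row appended — robust to the
  near-reducible matrices of the 5th-degree case.
* Forbidden states (forced ROH windows) use `-inf` log emissions, which
  the scaled recursions propagate exactly as zero probability.
* Zero-coverage windows, windows with no overlap, pairs with no shared
  sites, and all-forced ROH inputs all have defined behaviour (tested).
* Contamination corrections clamp `rho` into (0, 1) with a warning when
  the supplied parameters contradict the data.

## Known limitations

* A single panmictic source population is assumed; structured cohorts
  bias `p0` and hence every level mean.
* The cohort-median `p0` fails when most pairs are related; supply `p0`
  explicitly in that case.
* Contamination rates and divergence are inputs, not estimated; strongly
  misspecified values propagate into the correction.
* Double-first-cousin and inbred-pedigree IBD patterns are not in the
  model registry.
* Empirical transition matrices are tied to the (r, b) they were
  generated at; regenerate them when changing either.
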