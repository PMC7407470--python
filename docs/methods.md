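# Methods

This note documents the models, estimators, parameter choices and
numerical conventions behind `kinlr`, and what its synthetic benchmarks
do and do not demonstrate about real forensic data.

## Kinship likelihood ratios with coancestry correction

At one locus, the joint probability of an unordered genotype pair under a
relatedness hypothesis (Δ0, Δ1, Δ2) is obtained by conditioning on the
number S ∈ {0, 1, 2} of allele pairs shared identical by descent. Given
S, the pair's four allele copies reduce to 4−S founder draws from the
reference population. Founder draws are priced sequentially under the
coancestry sampling formula

P(type a | m prior copies of a among j prior draws)
  = (mθ + (1−θ)p_a) / (1 + (j−1)θ),

the Dirichlet ("Balding–Nichols") urn in which θ is the probability that
two alleles drawn from the population are identical by descent. At θ = 0
this reduces to independent Hardy–Weinberg draws.

Rather than transcribing the published case-by-case formulas (which
historically contained a typographical slip — a missing factor of 4 in
the all-alleles-distinct sibling case), `kinlr` enumerates all ordered
configurations consistent with the two unordered genotypes and, under
Δ1, with the choice of shared allele. The combinatorial coefficients (2
per heterozygote, 4 for four distinct alleles, the 1/2 weight on which of
the first individual's copies is shared) then arise mechanically. The
enumeration is closed over at most three founder-draw prices, so it
vectorises over millions of pairs; the test suite pins it to an
independent brute-force enumeration of every ordered founder sequence and
IBD assignment on a 3-allele locus to 1e-12, and checks that
probabilities over all unordered genotype pairs sum to 1 for θ up to 0.1.

Multilocus log-LRs are sums of per-locus terms (loci treated as
independent). Logarithms are natural throughout. θ enters numerator and
denominator with the same value; the default for likelihood evaluation is
θ = 0.01, with θ = 0 as the standard comparison setting.

**Zero-frequency policy.** A query allele can be absent from a
misspecified reference table. Frequencies are floored at
f_min = 1/(2·n_ref + 2), where n_ref is the diploid sample size behind
the table (the frequency the allele would have if observed once in a
sample one individual larger), and the vector is renormalised. This keeps
LRs finite while preserving the ordering of observed frequencies.

## Sibling simulation

A relative of individual i is simulated locus by locus: S is drawn from
(Δ0, Δ1, Δ2) — (1/4, 1/2, 1/4) for full siblings — S alleles are copied
from i (the single copy chosen uniformly when S = 1), and the remaining
2−S alleles are drawn from i's mixture allele frequency distribution
p̂_{ℓ,a} = Σ_k q̂_{ik} p̂_{k,ℓ,a}. Simulation itself assumes no background
coancestry (θ = 0); θ is applied only when likelihoods are evaluated.
The per-locus IBD trace is retained for validation only and never used in
inference.

## Admixture ancestry inference

The admixture likelihood treats each of an individual's 2L allele copies
as drawn by choosing cluster k with probability q_{ik}, then allele a
with probability p_{k,ℓ,a}. `kinlr` maximises this likelihood by EM
rather than sampling its Bayesian posterior by MCMC: the downstream
pipeline consumes only point estimates of Q and P, the EM is
deterministic given a seed, and it runs at desk scale (the 978 × 791
design takes minutes). No correlated-allele-frequencies prior is used;
cluster frequencies are plain maximum-likelihood estimates. Within EM,
frequencies and memberships are floored at 1e-12 to avoid log 0, and the
log-likelihood is asserted non-decreasing at every iteration (tolerance
1e-8 relative, to absorb the flooring). Convergence is declared when the
relative log-likelihood change falls below 1e-7 (default); a
non-convergent run returns its best-so-far state with a warning flag.
Supervised mode holds a supplied P fixed and estimates Q only.

**Replicates and label alignment.** Cluster labels are arbitrary, so
replicate runs (default 10, independently initialised) are aligned before
averaging. Each replicate's labels are permuted to minimise the squared
Frobenius distance of its Q to the first replicate's Q, by exhaustive
search over all K! permutations — exact, and cheap for the K ≤ 8 range
enforced; for membership matrices this selects the same optimum as
similarity-statistic criteria used by greedy multi-replicate aligners.
Ties resolve to the lexicographically smallest permutation. The consensus
is the element-wise mean of aligned Q and P; consensus P is renormalised
per locus after averaging (the averaging-then-renormalising order is a
convention of this package).

**Cross-model alignment.** The full/codis scenario combines P from the
full-locus inference with Q from the forensic-only inference. These two
ensembles carry independent label sets, so the forensic-only consensus is
relabelled onto the full-data consensus by the same exhaustive
permutation search on Q (`ancestry.align_to`) before mixing. Without this
step the scenario would pair memberships with the wrong clusters'
frequencies.

## Summary statistics

* **Distinguishability.** D~VH = (mean_r − mean_u)² / (s_r² + s_u²) over
  the related/unrelated log-LR samples, with unbiased (n−1) sample
  variances; central 95% intervals are empirical 2.5%/97.5% quantiles
  with linear interpolation between order statistics.
* **Gene diversity.** H̃ = 2n/(2n−1)(1 − Σ p̃²) per locus from the 2n
  observed allele copies; the panel value H̄ is the unweighted mean over
  loci. Loci with missing data are rejected rather than silently
  reweighted, so one shared n applies within a population.
* **Coancestry.** Pairwise θ̂ uses the Weir & Cockerham (1984)
  three-component (a, b, c) analysis of variance per allele per locus,
  combined as a ratio of sums Σa / Σ(a+b+c) across alleles and loci —
  never a mean of per-locus ratios. The estimator is validated against an
  independently written transcription of the same formulas and against
  closed-form cases (fixed differences give θ̂ = 1; identical samples
  give θ̂ ≤ 0).
* **ROC.** Curves threshold the log-LR with ties grouped (records at one
  value move together); AUC is the trapezoid area, which equals the
  concordance statistic on tie-grouped curves (property-tested).

## Synthetic data generator

The generator emulates a worldwide STR reference panel. Defaults are the
study design of interest: K = 4 populations of (94, 532, 269, 83)
diploid individuals, 791 loci with 13 forensic markers, mostly-unadmixed
individuals.

* Ancestral allele frequencies per locus: one symmetric Dirichlet(1)
  draw — maximally uninformative, giving a realistic spread of diversity
  across loci. Allele labels are integer repeat counts from 6.
* Population frequencies: Dirichlet centred on the ancestral vector with
  concentration (1−F_k)/F_k, so F_k is the population's Fst-like
  divergence. Default F = 0.08, inside the 0.03–0.10 band spanned by
  pairwise θ̂ among worldwide human groups.
* Forensic loci take the top of the allele-count range (default 12 of a
  4–12 range) **and drift with attenuated effective divergence**
  F_k × 0.6. The high mutation rate of forensic STRs both keeps them
  highly polymorphic and holds their between-population differentiation
  below the genome-wide level; mutation is not modelled explicitly (see
  limitations), so its differentiation-suppressing effect is represented
  by this attenuation. With it, forensic-subset θ̂ runs systematically
  below all-locus θ̂ at a ratio comparable to the real panel's; without
  it the contrast does not emerge.
* Memberships: "unadmixed" mode assigns degenerate one-hot vectors;
  default admixed mode draws q from a Dirichlet with weight 2.0 on the
  individual's own group and 0.1 elsewhere (mean own-group membership
  ≈ 0.87 — mostly unadmixed with visible mixing).
* Genotypes: every allele copy independently picks a source population
  from q, then an allele from that population's locus frequencies — the
  same mixture model the EM inverts.
* Reproducibility: one integer seed drives a stage-keyed hierarchy of RNG
  streams (ancestral draws, drift, memberships, genotypes), so each stage
  and the whole dataset are bit-reproducible.

The generator does **not** emulate: mutation processes, linkage or
within-group substructure (each group is panmictic; real groups can carry
substructure-induced disequilibrium), genotyping error, or missing data
at forensic loci. Passing tests on synthetic data therefore demonstrate
correctness of the estimators and the direction and rough magnitude of
the misspecification effects, not calibrated false-positive rates for any
real population.

## Experiments

Siblings (default 10 per individual) are simulated once per study from
the full-data consensus mixture frequencies and reused across all
frequency scenarios, so scenario contrasts are free of simulation noise.
Within each true population every individual is paired with every
simulated sibling of that population: n individuals and m siblings each
give n·(m·n) pairs, n·m related and n·(m·n − m) unrelated; an individual
is never counted as unrelated to its own siblings.

The Predefined-Population experiment scores all pairs under each
population's observed sample allele frequencies (the default reading of
"a predefined population's frequencies"; cluster frequencies can be
substituted through the same interface). The Ancestry-Estimation
experiment scores them under per-query mixture frequencies in the
full/full, full/codis and codis/codis data-availability scenarios.
Down-sampling mode redraws balanced subsets (without replacement) of each
prior group and reruns everything; a subset that contains every
individual delegates to the standard seed path, so it reproduces the
plain run exactly.

## Problem sizes in the test suite

The bundled tests exercise the pipeline at reduced scale chosen for quick
iteration: the ordering checks use four groups of 20/25/20/15 individuals
at 60 loci across three seeds; ancestry recovery uses 4 × 100 individuals
at 791 loci with two aligned replicates; simulator calibration uses 10^4
loci. The full 978 × 791 design runs through the same code paths (the
generator and I/O round-trip it directly).

## Known limitations

* EM point estimates carry no posterior uncertainty; replicate spread is
  the only variability measure.
* The exhaustive K! alignment is exact but limited to K ≤ 8.
* Likelihoods assume locus independence and no genotyping error; a
  parent-offspring hypothesis is provided (Δ = (0, 1, 0)) but exclusion
  logic and mutation-aware kinship are out of scope.
* Confidence intervals for θ̂ are not computed.
* The zero-frequency floor is a pragmatic convention; results for alleles
  unseen in the reference sample depend on it.
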