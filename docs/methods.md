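# Methods

This note records the model, the numerical choices, and the limits of what
the package's tests demonstrate. It is written for a maintainer or
reviewer who wants to know *why* the code is the way it is.

## Genetic model

The simulator implements an infinitesimal additive model with two traits
(an early and a late recordable one) and two genetic effects per trait: a
**worker effect**, expressed collectively by a colony's workers, and a
**queen effect**, expressed by its queen. Every genetic entity carries a
4-vector of effects ordered (W1, Q1, W2, Q2). The base-population
covariance is the Kronecker product of a 2×2 between-trait correlation
matrix and a 2×2 worker/queen block. Defaults (in units of the
worker-effect additive variance):

| parameter | default | meaning |
|---|---|---|
| σ²_AW | 1.0 | worker-effect additive variance, per trait |
| σ²_AQ | 0.5 | queen-effect additive variance (half the worker effect) |
| σ²_ε | 1.5 | residual variance (three times the queen effect) |
| r_WQ | 0 or −0.5 | worker–queen genetic correlation within trait |
| r_T1T2 | −0.6 … 0.6 | between-trait genetic correlation (0.3 steps) |
| n_drones | 8 | polyandry level per mating |
| σ²_apiary | 1.0 / 2.0 | apiary-by-year variance, early / late trait |

The apiary-by-year variances are set to 1/3 and 2/3 of the phenotypic
variance, taking σ²_P := σ²_AW + σ²_AQ + σ²_ε = 3 as the reference. σ²_P
has no unique definition in a colony model (the worker term enters
phenotypes with variance ≈ 0.53 σ²_AW, not σ²_AW); we fix this convention
once so scenarios stay comparable and document it here.

### Inheritance

Gametes live on the half-genome scale: a gamete of a parent with breeding
value *a* and pedigree inbreeding *F* is `0.5 a + δ`,
`δ ~ N(0, 0.25 (1−F) G)`, so Mendelian sampling variance shrinks linearly
in *F* and a fully inbred parent transmits deterministically. A drone *is*
one such gamete of its mother and fathers every daughter with that genome
clonally; a daughter queen is her dam's gamete plus one father drone picked
uniformly from the mating's 8 drones. The worker group uses the
infinite-worker approximation: maternal Mendelian deviations average out
and the 8 drones contribute equal paternal shares, so the worker-group mean
is exactly `0.5 a_queen + mean(drones)`. Open matings draw the 8 drones
from dams sampled (with replacement) out of a private pool of 100
unrelated, non-inbred dummy drone-producing queens.

## Relationship matrix and its inverse

The pedigree holds queens, per-mating drone groups (`SIRE` nodes),
open-mating pseudo-sires, and worker groups. Two facts make an exact
sparse treatment possible:

1. With an equal-probability pick among the 8 drones, the covariance
   between the paternal contributions of two daughters of one mating
   equals the variance of the drone-group mean (an exchangeability
   identity). Conditional on the drone-group node, sibling residuals are
   therefore uncorrelated, and the directed (Henderson) factorization
   `A = (I−B)⁻¹ D (I−B)⁻ᵀ` over {queens, drone groups, pseudo-sires} is
   exact — including the super-sister/half-sister mixture
   (sibling relationship `0.25(1+F_dam) + 0.5/8 + (7/8)·0.25(1+F_sire)`).
2. Under the infinite-worker approximation a worker group is an exact
   linear combination `0.5·queen + drone-group` of two generating rows.
   Jointly with its generators it would make A singular, so worker groups
   carry no row in A⁻¹; their relationships, EBVs, and phenotype incidences
   are formed from the two generating rows with coefficients (0.5, 1).

Node recursion coefficients: a queen regresses 0.5 on her dam and 1.0 on
her mating's drone group, with conditional variance
`0.25(1−F_dam) + (7/8)·0.25(1−F_sire)`; a drone group regresses 0.5 on its
DPQ with conditional variance `0.25(1−F_DPQ)/8`; a pseudo-sire is a base
node with variance `0.5/8 + (7/8)(1/100)(0.25)`. A queen's inbreeding
coefficient is the relationship between her dam and her mating node
(equivalently `0.5 · A(dam, sire DPQ)` for inseminated matings). Pairwise
relationships and F are computed by a memoized recursion that only ever
touches ancestors of the queried pair, so full-scheme pedigrees (~10⁵
nodes) never materialize a dense A.

All coefficients are validated against a gene-dropping oracle that uses
*discrete* single-locus inheritance (allelic value picks, drone sharing,
dummy-dam collisions) so that identity-by-descent — and hence inbreeding —
emerges from value identity rather than from any (1−F) formula.

## Genetic evaluation

Phenotypes enter a 2-trait mixed colony model: fixed apiary-by-year cell
means per trait, and for each colony record the queen effect of its queen
plus `0.5 u_W(queen) + u_W(drone group)` for the worker term, with
`Var(u) = G ⊗ A`. Missing late-trait records (candidate dams in the
accelerated scheme) simply contribute no row. Henderson's equations are
assembled sparse; solves use sparse LU (SuperLU with the symmetric
`MMD_AT_PLUS_A` ordering — about 8× less fill than the default on these
matrices) or Jacobi-preconditioned conjugate gradients with warm starts
for the large in-loop systems, with a `1e-8` relative-residual acceptance
check either way.

REML maximizes the exact restricted likelihood
`−2 lnL = log|R| + log|G ⊗ A| + log|C| + y′Py + const`, where every term
comes from one sparse LU of the mixed-model matrix (`log|A|` is a
by-product of the Henderson construction). The optimizer is quasi-Newton
(L-BFGS-B) over Cholesky factors of G and R, which keeps both PSD and
lets genetic variances hit the zero boundary cleanly; parameters are
scaled by their start values. Start values follow the simulation protocol:
0.9× the true genetic and 1.1× the true residual covariances. We chose
the exact-likelihood quasi-Newton route over average-information updates
deliberately: AI first derivatives need traces of the inverse coefficient
matrix at the A⁻¹ sparsity pattern (selected sparse inversion), which the
scientific Python stack does not provide; the likelihood itself needs only
log-determinants, which the LU factorization yields for free. The nominal
convergence criterion of 1e-11 on the relative parameter change is
reported with each fit; the convergence flag itself is the optimizer's
success status at `ftol = 1e-13`, and a failed fit voids the replicate
(the caller records the failure and draws a new one).

A **known-parameters mode** (BLUP with the true G and R) is provided and
used for most tests and the scheme-comparison runs: it removes estimation
noise, which the full protocol deliberately includes, so comparisons run
in this mode slightly overstate selection accuracy in both schemes alike.

## Scheme engine

Years 1–10 initialize a closed population: 24 founder queens open-mated,
then biennial cycles of 24 selected dams × (18 candidate dams + 18
candidate sires), truncation selection on the weighted sum of both
phenotypes in realized cohort-SD units, instrumental insemination from
year-4 births onward. Mortality removes an exact 25% of each cohort before
phenotyping and again before selection (432 → 324 → 243); exact-fraction
removal (not binomial) is what reproduces the design's candidate and
record counts deterministically. Sister groups are split 6+6+6 over 3 of
18 apiaries with 4 groups per apiary (the 36-parent variant splits 12
offspring 4+4+4 over 3 of 18 with 6 groups per apiary); the assignment is
a random regular bipartite design built by slot-dealing with swap repair.

From year 11 the two branches fork from a deep copy of the same state,
each with fresh named random substreams (genetics, mortality, allocation,
mating, phenotypes, selection) derived from (seed, branch, stream), so the
shared initialization is bit-identical and the branches diverge
independently. Base selects 2-year-old dams and sires every even year on
EBV indices. Alt selects dams at 1 year old every year (324 candidates,
early trait only), keeps sires on 2-year complete phenotyping — which
requires a new candidate sire cohort every year from year 11 on
(overlapping cohorts) — and in the transition year re-uses the
initialization's last selected sire pool, since no sires were born in
year 9. Early records of 1-year-old candidate sires stay out of the
performance file until they become 2-year-old candidates. These rules
reproduce the protocol's record counts exactly: 3,264 per trait at the
first Base evaluation and 9,096 at the last; 2,940 early/2,616 late at
the first Alt evaluation and 15,252/8,772 at the last.

Selection indices sum worker and queen EBVs within trait before applying
the goal weights; dams are ranked on their worker group's EBVs (a mated
queen's mating is irreversible, so her offspring share her worker group's
expected breeding value), sires on their own. Ties break by id. Zero
weights on both traits switch to uniformly random selection — the
drift-only control. Two auxiliary modes exist for validation: `dry`
(random selection, bookkeeping only) and `phenotypic` (own-phenotype index
selection, the comparator that EBV selection must beat).

## Summary statistics

Relative differences are `(Alt − Base)/|Base|` computed within a replicate
pair and then averaged across replicates (never the ratio of means). The
empirical probability that Alt strictly beats Base carries the binomial
standard error `sqrt(p(1−p)/n)`, reported as non-estimable at p ∈ {0, 1}.
Expected truncation-selection intensities are exact means of top-k
standard normal order statistics by adaptive quadrature (the best 24 of
243 gives 1.75; of 324, 1.88). Inbreeding rates are reported per year and
per generation; generation counts over years 10–30 are 10 (Base) and the
dam/sire average 15 (Alt), configurable since only totals are defined.

## Problem sizes used in the tests

The full design (24+24 parents, 432-queen cohorts, 18 apiaries, 30 years)
is used for all bookkeeping checks and for the scheme-comparison runs,
which use known-parameters mode with 3+3+2 paired replicates; every
quantitative assertion combines the published uncertainty of the target
value with the Monte-Carlo standard error of our own replicate mean, so
the checks are exact in expectation but deliberately few in replicates.
REML parameter recovery runs single-trait fits on ~5,200 records × 20
seeds; the 5%-bias bound is asserted for the residual variance, where 20
seeds give adequate power, and the genetic components are checked against
three standard errors of their across-seed mean (the worker-effect
variance has a per-seed sampling SD of ≈0.26 at this size, so a 5% bound
on its mean is not resolvable from 20 seeds). The two-trait REML
convergence rate is measured on one full-size initialization dataset plus
six third-size populations of identical structure. Gene-dropping
oracles use 1.2–1.5×10⁵ replicates with per-entry 3-SE bounds and an
explicit multiplicity allowance.

## What the synthetic data do and do not show

The generator *is* the study design: infinitesimal additive genetics,
random mortality, a closed nucleus, balanced matings, honest in-loop
evaluation. It does not model non-additive effects, explicit genomes or
the sex locus (csd) brood loss, inbreeding depression on phenotypes or
survival, genotype-by-environment interaction, or non-random queen loss.
Passing tests therefore demonstrate internal consistency of the simulator,
estimator, and bookkeeping under the stated model — not that a real
breeding program will realize these gains; in real populations inbreeding
depression and queen-longevity effects would erode the accelerated
scheme's advantage.

## Known limitations

* Worker groups are single averaged entities; finite worker-group
  sampling noise is not modelled (assumed absorbed in the residual).
* The REML implementation targets the test scales (≈10³–10⁴ records per
  fit); full-size 30-year in-loop REML batches are overnight jobs, not
  unit tests.
* The comparison statistics assume paired replicates; unpaired designs
  are not supported.
* Drift-only effective size follows Wright's equal-contribution
  approximation (Ne ≈ 2N) in this design because balanced matings, equal
  sibship sizes, and polyandry near-equalize parental contributions; the
  tests check the realized rate against 1/(4N) within 20%.
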