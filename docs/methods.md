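# Methods

## Model

`fstrat` computes f-statistics on dated genome-wide genealogies rather
than on observed genotypes.  For a pair of groups A, B the building block
is the branch-resolved f2-statistic: every branch of every marginal tree
contributes

    f2 contribution = [ (w_A - w_B)^2 - h_A - h_B ] * mu * l_eff * span

where `w_X` is the fraction of group X's samples descending from the
branch, `h_X = w_X (1 - w_X) / (n_X - 1)` is the finite-sample
heterozygosity correction (zero when n = 1, where it cannot be
estimated), `mu` the assumed mutation rate per bp per generation, `span`
the genomic extent of the tree and `l_eff` the branch length clipped to
the ascertainment window `[t_low, t_high)` in generations before present.
A branch crossing a threshold contributes only the portion inside the
window (proportional truncation); clipping is measured from time 0, not
from a sample's age.  The correction makes branch, mutation and genotype
modes estimates of the same population quantity, and it makes singleton
tip branches contribute exactly zero to cross-group f2 — the explicit
`internal_only` exclusion therefore only changes uncorrected analyses.

The point of the time window is statistical power: coalescences older
than the divergence of two admixing sources carry no information about a
recent admixture event and only add drift noise to the f-statistics.
Restricting to branches below a cut-off `t` concentrates the statistic on
the informative recent coalescences.  For a simple two-way admixture the
standard-error-minimizing cut-off sits near 1.4 times the source split
time; the simulation study exposes this optimum empirically
(`simstudy.power_study` + `optimal_cutoff`).

Three ascertainment modes share one interface (`AscertainmentSpec`):

* `branch` — clipped branch lengths times `mu` (requires dated trees);
* `mutation_age` — mutations whose branch-interval midpoint falls in the
  window (useful for samples not built into a genealogy); the midpoint is
  a deterministic, unbiased point in the branch interval;
* `genotype` — all mutations regardless of age (the classical estimator),
  with optional derived-allele-frequency windows (`min_daf`, `max_daf`);
  `max_daf = 0.05` reproduces rare-variant ascertainment.

All f2 values are accumulated in contiguous genomic blocks (default 5 Mb
physical; any boundary vector is accepted, and `blocks_from_rate_map`
yields centimorgan blocks).  Derived statistics recombine per-block
values:

    f3(O; A, B)    = [f2(O,A) + f2(O,B) - f2(A,B)] / 2
    f4(A, B; C, D) = [f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)] / 2
    alpha          = f4(PI, PO; P1, PX) / f4(PI, PO; P1, P2)

where the f4-ratio assumes PX was formed by a pulse of proportion `alpha`
from P2 into a population cladal with P1, PI is a non-admixed sister of
P1 and PO an outgroup.  (Note the argument structure: the denominator
must carry the shared-drift segment between the P1/PI split and the
P1/P2 split; orderings that pair the outgroup with P2 have zero
expectation and cannot normalize the ratio.)

## Uncertainty

Standard errors come from a weighted delete-one-block jackknife (Busing,
Meijer & van der Leeden 1999): with block weights `w_j` (bp spans or
site counts), `h_j = W / w_j`,

    theta_J = g*theta_hat - sum_j (1 - w_j/W) theta_(j)
    var     = (1/g) sum_j (tau_j - theta_J)^2 / (h_j - 1),
    tau_j   = h_j theta_hat - (h_j - 1) theta_(j).

Ratios (f4-ratio, qpAdm weights) are jackknifed as whole refits on the
delete-one aggregates rather than via the delta method, matching the
block structure of the inputs.

## qpWave / qpAdm

For a left set (target and sources) and a right (reference) set the
matrix `F_ij = f4(l_0, l_i; r_0, r_j)` is estimated per block together
with the jackknife covariance `Q` of its entries.  qpWave tests
`rank(F) <= r` by generalized least squares under `Q` (rank 0 is a
closed-form quadratic form; higher ranks use alternating GLS on the
factors), with `(L-1-r)(R-1-r)` degrees of freedom.  qpAdm fits weights
`beta` with `sum(beta) = 1` solving `beta' F = 0` by iterated constrained
GLS (the covariance of the working residual depends on `beta`, so the
quadratic solve is iterated from uniform weights); the model p-value uses
`R - S` degrees of freedom.  Weights are normalized but never clamped:
infeasibility (a weight outside [0, 1]) is a property of the fit that
rotation filters on, not something to hide.

Because the covariance itself is estimated from `B` blocks, the naive
chi-square reference for the GLS quadratic form is anticonservative at
desk-scale block counts.  p-values therefore use the Hotelling-type F
reference `stat * (B-d) / (d*(B-1)) ~ F(d, B-d)`, which is exact for the
rank-0 case under Gaussian block means, converges to the chi-square as B
grows, and is monotone in the statistic (model rankings are identical
under either convention).  Null calibration is verified by simulation
(KS uniformity of p-values for cladal pairs).

Covariances are regularized by flooring eigenvalues at 1e-12 of the
trace.  This matters in a specific, scientifically real situation: under
a strict time cut-off, two references whose lineages never reach the
window become statistically interchangeable, their f4 columns identical
and the covariance singular.  Such fits are flagged (`collinear`) rather
than rejected.

Rotational model search enumerates all source subsets of size
1..`max_sources` from a pool, using unused pool members as references —
penalizing models that relegate a true source to the reference side.
Models with any weight outside [0, 1] are excluded by the feasibility
filter; reporting tiers mirror common practice (all models with
p > 0.05, else the single best if p > 0.01).  The stepping-stone
experiment scores the "best" model as the highest p-value among all
two-source models, ranked on log10 p so the ranking stays exact when
every model is strongly rejected.

Pairwise cladality clustering runs UPGMA (average linkage) on
`-log10 p` from rank-0 qpWave between individuals, cuts the dendrogram
at `-log10(0.01)`, then iteratively splits off the member farthest from
its cluster's mean age until all members lie within 500 years of it
(ties resolved deterministically; split-off members are re-clustered
among themselves by the same rule).  Clusters below 3 members are
flagged, not deleted.

The outgroup-f3 MDS stores `1 - f3(outgroup; i, j)` in a symmetric
matrix and applies classical (Torgerson) scaling: eigen-decomposition of
the double-centred squared-dissimilarity matrix; axes with negative
eigenvalues (the non-Euclidean part) are reported and suppressed.

## First-coalescence painting and NNLS

For a subject haplotype, each genomic position is assigned to the
reference population whose samples the subject coalesces with first in
the local tree (walking rootward; a node involving several reference
populations splits the event weight proportionally to their sample
counts; non-reference lineages, including the subject's own population
mates when not in the reference list, are ignored).  Aggregating
span-weighted events gives a profile vector `a` over the k references,
normalized over the covered genome (coverage is reported separately so
`sum(a) = 1` is a hard invariant).  A subject that belongs to a
reference population is held out of its own painting automatically.

A target profile is fitted as `min ||a_target - A beta||_2` subject to
`beta >= 0, sum(beta) <= 1` (unconstrained NNLS first; if the sum
constraint binds, an SLSQP solve on the simplex polished by an exact
equality-constrained least-squares step on the active set).  This
estimator is the genealogical idealization of chromosome-painting /
IBD-profile mixture models.  It is included deliberately as a
comparison point: when a source has undergone strong recent drift (the
bottleneck scenario), its painting profile is distorted and the NNLS
weights are systematically biased, whereas the f4-ratio on the same
genealogies is not — the simulation suite asserts this contrast.

## Simulation study

All validation data are simulated with msprime from a catalogue of
scenarios (`simstudy.CATALOG`); every scenario is deterministic given a
seed (per-replicate seeds are derived from one base seed by a
counter-based scheme, `subseed`).  Scenario parameters follow the study
conditions described in the package overview: the two-way admixture
(sources split 250 or 500 generations ago, pulse 50 generations ago,
diploid size 5,000, mu 1.25e-8, 20 haploids per population; variants
with a P2 bottleneck to 1,000 in the last 50 generations, a
transversions-like mutation rate of 4e-9, and 100 haploids), a
rotating-reference admixture model (sources split 1,200, admixture 40,
with a /5 variant), a nine-deme 1D stepping stone (adjacent migration
0.001/0.005), archaic pulse versus deep structure, and a 5x5 fine-scale
grid (25 demes of size 500, migration 0.01, structure emerging 100
generations ago from an ancestral population of 10,000).

Choices the printed parameterizations leave open, fixed here once:

* stepping stone: demes split from a panmictic ancestor 2,000
  generations ago with deme size 5,000 — old enough for migration-drift
  equilibrium; simulated adjacent-deme Hudson F_ST is 0.0105 at
  m = 0.001 and 0.0027 at m = 0.005, matching the 0.01 / 0.002
  calibration the scenario is defined by.  Population 4 (the fitted
  target) is the 1-based fourth deme, `D3`, with an off-centre position.
* rotating-reference model: reference ladder at 1350/1500/1800/2400/
  3000 generations, outgroup at 6,000, Ne 5,000, alpha 0.5.
* archaic scenarios: pulse fraction 3% at 2,000 generations from the
  Vindija-like population; archaic samples at 1,700 (VIN) and 4,000
  (ALT) generations; the deep-structure variant connects the two modern
  subgroups (split 30,000) by symmetric migration 4e-5..2e-4 (default
  1e-4) from 30,000 until 3,000 generations before present; both
  variants carry a 40,000-generation outgroup so the archaic-affinity
  statistic f4(AFR, NOA; VIN, OUT) can be formed.
* recombination: a deterministic hotspot-like map (flat background with
  ~2 kb hotspots every ~60 kb, 12x intensity, mean 1.2e-8) standing in
  for a human chromosome map; `uniform` is available per scenario.

The genotype/phasing error model flips each haploid genotype with a
per-individual probability drawn uniformly on [1e-4, 1e-3] (high-error
variant [1e-3, 1e-2]) and can diploidize haplotype pairs with
phase-switch errors at one switch per 5 cM — a parametric stand-in for
reference-free rephasing that stresses the same failure mode.  The
closed-form accuracy curve is

    r^2(e, p) = p (1-p) (1-2e)^2 / (q (1-q)),  q = p(1-e) + (1-p)e,

verified against Monte-Carlo simulation.

`power_study` runs the estimator battery (genotype, branch and
mutation-age time-stratified, rare-variant DAF <= 5%, painting + NNLS)
across a cut-off grid and replicates, reporting per-cell mean alpha,
jackknife s.e. and the fold improvement of s.e. relative to genotype
mode; `optimal_cutoff` locates the s.e. minimum (ties toward the smaller
cut-off, boundary minima warned).

### Problem sizes

The default scenario length is 50 Mb.  The test suite scales lengths
per experiment — 50 Mb where the claim concerns the cut-off/split-time
ratio or stepping-stone model selection, 20-25 Mb for power and
estimator-bias contrasts and the fine-scale grid, 2-10 Mb for
calibration and estimator-identity checks — keeping every run at desk
scale while preserving each claim's regime.  Replicate counts default
to 20 for unbiasedness checks and 10 for model-selection rates.  Two
stepping-stone quantities are length-limited at this scale and are
documented as such where asserted: the genotype-based adjacent-pair
selection rate at migration 0.005 (higher at 50 Mb than on a full
chromosome, where many near-adjacent models become statistically
separable competitors), and the continued-migration rejection at
migration 0.005 (below the noise floor at 50 Mb; asserted at 0.001,
where it is decisive).

## What the simulations do and do not show

The generator produces true, error-free genealogies.  Passing tests
therefore validate the statistics on known genealogies; they do not
measure the additional error introduced by genealogy inference on real
sequence data (Relate or similar), imputation of low-coverage genomes,
or ancient-DNA damage.  The genotype error model perturbs genotypes,
not trees, so branch-mode results are structurally immune to it here —
robustness of tree inference itself is outside this package's scope.
Reported power gains are specific to the simulated demographies and
sample sizes.

## Numerical notes

* Branch-mode fast path: time clipping via tree-sequence decapitation,
  statistics via tskit's C kernels; a per-tree Python reference path
  (any n, uncorrected mode, branch-level DAF ascertainment) is
  cross-checked against it in the tests.
* Window boundaries are half-open `[t_low, t_high)`; ties at the
  boundary are deterministic.
* Covariance eigenvalue floor 1e-12 of trace; source condition numbers
  above 1e8 flag collinearity.
* UPGMA ties and age-subdivision removal order are deterministic
  (lexicographic / farthest-first).
* NNLS solutions are polished to satisfy the active-set KKT system
  exactly; rank-deficient source matrices are flagged as
  non-identifiable rather than rejected.
* All stochastic entry points take explicit integer seeds; derived
  seeds stay below 2^31.

## Known limitations

* The Relate-style text dialect targets one documented column layout
  (see `fstrat.relate`); other dialect variants are rejected with a
  parse error rather than guessed at.
* Branch-mode DAF ascertainment uses the slower reference path.
* qpWave ranks above 0 rely on alternating GLS, which can find a local
  optimum for badly conditioned covariances (not observed at the tested
  scales).
* Sample-age interaction with time windows is surfaced as a warning
  (a group whose youngest common window is empty contributes nothing)
  rather than an age-shifted clipping rule.
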