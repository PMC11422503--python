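# Methods

## Observation model

A pangenome over *N* genomes assigns each gene cluster a true population
frequency θ ∈ [0, 1]: the probability that a randomly drawn member of the
species carries the gene. An assembly with completeness *c<sub>i</sub>*
(the fraction of genome *i* recovered, conventionally estimated from
conserved single-copy marker genes) retains any given gene independently
with probability *c<sub>i</sub>*. The observation count of a gene is then

X = Σᵢ Bernoulli(θ·cᵢ),

a Poisson binomial random variable. The key assumption is that genes are
missing **completely at random** within an assembly — dropout depends only
on *c<sub>i</sub>*, not on which gene it is. Repetitive regions, uneven
coverage, or genes conserved across species violate this and bias the
method (see Limitations).

True frequencies are given a Beta(*a*, *b*) prior. Bacterial gene-frequency
spectra are strongly bimodal (most genes near-universal or rare), so both
shapes default to 0.5, a symmetric U. Both are configurable and every
statistical guarantee in the test suite is exercised at several (*a*, *b*)
settings.

## Threshold adjustment

A gene is *truly core* when θ ≥ t_core (default 0.95). The classifier
observes only X, so we pick the largest integer X\* with

P(X ≤ X\* | θ ≥ t_core) ≤ α,

and call core every gene with X > X\*. The left side marginalises θ over
the prior truncated to [t_core, 1]: the rule controls the false-negative
rate (FNR) α for a core gene of *unknown* frequency drawn from the prior,
not for the single worst case θ = t_core. A `fixed_theta` option replaces
the prior with a point mass, which with complete genomes reduces the rule
to the binomial α-quantile (the N = 3, p = 0.95 worked example gives
X\* = 1 because P(X ≤ 1) = 0.00725 ≤ 0.05 < P(X ≤ 2) = 0.142625).

If even X\* = 0 violates the bound the sentinel −1 is returned, meaning
every observed gene is core; no downstream special case is needed because
"core" is always `count > x_core`.

The rare side mirrors the rule: the smallest X\* with
P(X ≥ X\* | θ ≤ t_rare) ≤ α, rare meaning `count < x_rare`. The mirrored
bound is this package's extension — only the core-side rule is canonical —
and the classical unadjusted rule (`count < ceil(t_rare·N)`) remains
available via `adjust=False` / `--no-adjust`.

### Estimators

* **Monte Carlo** (default): draw θ from the truncated prior by inverse CDF
  on the restricted quantile interval (rejection sampling would be
  hopeless when the region holds little prior mass), then one Poisson
  binomial realisation per draw; the marginal count CDF is the empirical
  CDF of the draws. Default 100 000 draws; the standard error of a tail
  probability near 0.05 is then ≈ 0.0007. A single seeded generator is
  consumed in a fixed order (all θ draws, then all count realisations), so
  results are bit-reproducible per seed.
* **Exact**: the Poisson binomial pmf is computed by the standard O(N²)
  dynamic-programming convolution (fold one trial in at a time), and the
  marginal CDF by Gauss–Legendre quadrature with 64 nodes placed in the
  *quantile* space of the truncated prior — uniform-mass placement keeps
  the rule accurate even where the U-shaped density diverges at the
  endpoints. Practical to N ≈ 2000; it is also the oracle against which
  the Monte Carlo route is tested.

### Numerical conventions

* Cutoffs follow the "observe ≤ X times" phrasing exactly: X\*_core is the
  largest count still classified non-core.
* Comparisons with α use ≤ (a probability exactly at the bound is
  admissible).
* Count CDFs are clipped to [0, 1] against float drift; the rare-side
  survival function is defined with sf(0) = 1 and sf(N+1) = 0 so a cutoff
  always exists.
* Prior mass below 1e−12 in a conditioning region is an error advising a
  prior change rather than a silent near-empty sample.
* Completeness exactly 0 is rejected at parse time: a genome contributing
  nothing is almost surely an upstream failure, and silently assuming
  anything (including c = 1 for genomes missing from the completeness
  table) would bias the cutoff. Genome sets must match exactly unless
  `intersect` alignment is requested explicitly.

## Synthetic pangenome generator

`simulate_pangenome` draws θ_g ~ Beta(a, b) i.i.d., true presence
(g, i) ~ Bernoulli(θ_g), and observed presence by thinning each true cell
with an independent Bernoulli(c_i) — exactly the missing-completely-at-
random mechanism the model assumes. Defaults are G = 5000 genes and
N = 500 genomes, a desk-scale mirror of a 500-genome species collection;
completeness defaults to uniform on [0.7, 1.0], a stand-in for empirical
MAG completeness distributions (an empirical value file can be supplied
instead). Because generator and model share the thinning mechanism,
passing tests demonstrate internal consistency of the calibration, not
robustness to real-data violations; the `correlated_loss` option (one
contiguous block of genes lost per genome) exists precisely to demonstrate
the failure mode when dropout is *not* at random.

Observed counts are stochastically dominated by true counts by
construction (thinning only removes), reproducing the left shift of
observed frequency spectra seen in real MAG collections.

## Assembly degradation simulator

`plan_degradation` removes round((1 − target) · total_length) bp from an
assembly as `n_blocks` contiguous blocks (default 10): the budget is split
by uniform stick-breaking with rounding applied to the cumulative cuts so
block lengths sum to the budget exactly; each block lands uniformly on a
contig chosen proportionally to length, redrawn on overlap up to 100
times, then shrunk to the largest free gap (an empty gap is an error).
Coordinates are 0-based half-open throughout. `apply_degradation` offers
`excise` (delete and join flanks) and the default `split` (cut into
`_part1`, `_part2`, … records), the latter mimicking real MAG
fragmentation. Realized completeness is written in the same table dialect
the classifier reads, so degraded collections feed the workflow unchanged.

## Design choices where the design was open

* Prior hyperparameters: only "U-shaped" is canonical; (0.5, 0.5) is the
  symmetric default and both shapes are exposed everywhere.
* Marginalised vs fixed-θ conditioning: the marginalised rule is the
  default (it matches "unknown true frequency ≥ t_core"); the fixed-θ rule
  is slightly more liberal (lower cutoff) because it ignores the prior
  mass near 1 where genes are rarely missed.
* The "middle" label names the region between the cutoffs explicitly
  rather than leaving it implicit as not-core-not-rare.
* Matrix cells > 1 (paralog counts) are truncated to presence with a
  warning; zero-count genes are retained, labelled by the cutoffs, and
  warned about.

## Limitations

* FNR control is calibrated, not conservative: the cutoff sits as close to
  the α bound as the count lattice allows, so per-replicate empirical FNR
  fluctuates around (just under) α with binomial noise; control holds in
  the mean across replicates.
* When the frequency spectrum has appreciable mass just below t_core,
  bounding the FNR necessarily admits boundary false positives: genes with
  θ slightly below the threshold are frequently observed above the
  lowered cutoff. With a Beta(0.5, 0.5) spectrum this inflates the
  adjusted core count increasingly as t_core → 1 (where the true core
  shrinks faster than the false-positive inflow); real bacterial spectra,
  with almost no genes at intermediate frequencies, suffer far less. The
  trade-off is tunable: a smaller α lowers the cutoff further (fewer
  false negatives, more false positives) and vice versa.
* Completeness estimates are taken as known constants; their own error is
  not propagated.
* The missing-completely-at-random assumption fails under systematically
  low coverage; the `correlated_loss` stress test shows the resulting
  degradation in core recovery.

## Problem sizes in the test suite

Unit tests run at small N (≤ 200) with exact oracles (2^N enumeration for
N ≤ 12, binomial closed forms, quadrature); end-to-end statistical checks
use the default study scale (G = 5000, N = 500) with 20 replicates for the
FNR result and one replicate for the threshold sweep, sizes chosen to give
sub-percent Monte Carlo error on the quantities asserted while keeping the
whole suite fast on a single CPU.
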