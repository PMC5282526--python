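# Methods

This note records the models implemented in `revsig`, their assumptions,
the parameters that matter, and the numerical choices made where the
design was genuinely open.  It states no empirical result that the test
suite does not itself compute.

## Signature selection

**Background filter.** A gene is retained when its intensity reaches
`factor × local background` (default 1.4) in at least one sample
(`scope="any"`); requiring all samples is available.  The "any" default
keeps genes expressed in any condition, which matches a disease/dose
design where a gene may be silent in control and induced later.

**Quantile normalization** forces every sample column onto the mean
sorted distribution.  Ties within a column receive the mean of the
reference values at the tied ranks, which makes the transform idempotent.
Exactness caveat: the reference distribution is a column mean, so
renormalizing is bit-identical only when the column count keeps that mean
exact in floating point (any power of two, or already-identical columns).

**Log ratios** are log2((x+ε)/(x_ref+ε)) with ε = 1.0 on the intensity
scale, a standard guard against near-zero intensities.  With multiple
reference samples the reference is their mean.  Noise-free synthetic data
should be analysed with ε = 0 when exact fold-change arithmetic matters
(the tests do this).

**Fold-change rule.** |log2 ratio| ≥ log2(fold) with the boundary
*inclusive* (a gene at exactly 2-fold is selected).  A gene qualifying up
in one condition and down in another has no single direction to query;
it is excluded from both tag lists and reported separately.  Because of
this exclusion, selection is monotone in the fold threshold only within a
single condition — a conflicted gene can re-enter one list at a higher
threshold once its weaker direction falls away.

**Model profiles** (a desk-scale simplification of short-time-series
mining): candidate templates are all per-step changes in {−1, 0, +1}
over the ordered conditions, scaled to the data's median absolute step,
deduplicated, flat template dropped, capped at `n_profiles` by greedy
farthest-point selection.  Genes are assigned to the best Pearson
correlate (ties → lower index); zero-variance genes are unassignable and
counted.  Significance permutes each gene's condition labels and compares
per-profile occupancy counts, BH-adjusted.  Note a resolution floor: with
m retained profiles and B permutations the smallest attainable q is
m/(B+1), so q < 0.01 at B = 1000 needs m ≤ 10 profiles.

**Two-class d-statistic**: d = (mean₂ − mean₁)/(s + s0) with s the pooled
standard error of the mean difference and s0 a quantile (default median)
of the {s} or a fixed value.  No exchangeability-grid calibration of s0
is attempted; thresholds are user-supplied (conventional |d| cutoffs of
2.0 or 4.0).

## Connectivity scoring

Rank direction is fixed package-wide: rank 1 = most up-regulated by the
treatment, and library files must declare this in a header line — the
single most common source of sign errors in connectivity scoring.

The enrichment score is the two-sided KS-type statistic (see README for
the formula); it lies in [−1, 1], positive for tags concentrated at the
top.  Query tags missing from an instance's universe are dropped with a
logged count (an error mode exists).  The combined instance score is
c = ES_up − ES_down when the two scores disagree in sign and 0 otherwise;
with a single tag list, c is that list's score (down tags contribute with
flipped sign).  Display scaling divides positive c by the maximum
positive c and negative c by |min negative c|.

Drug-level aggregation orders all N instances by descending c and applies
the same KS statistic to each drug's k instance positions.  **Ties in c
are broken by a seeded random key**, not by instance id: under a null
query roughly half the instances have c = 0 (same-sign tag scores), and
id-ordered ties would cluster same-drug instances, biasing the drug score
away from its permutation null.  The permutation null resamples k-subsets
of positions (as the reference tool does), two-sided on |ES|, with the
add-one estimator p = (1 + #exceed)/(1 + B) so p is never 0.  The
statistic is discrete: with k instances per drug among N, meaningful
p-values require C(N, k) to be large (k = 2 needs roughly N ≥ 50 for
p ≤ 0.01 to be attainable; the calibration tests use k = 4).

Profile correlation filters to drugs significant (p < 0.05) in *either*
query — the union rule, configurable to intersection — and reports
Pearson r with its t-distribution p over the common drugs.

## Pathway activity

A_P = (1/|P|) Σ_{g∈P, measured} w_g r_g with w_g = −1 for repressors.
The divisor is the full membership size even when members are unmeasured
(a literal reading of size normalization; a measured-only divisor is an
option).  The permutation null redraws gene sets of pathway size from the
measured genes and randomly reassigns the pathway's role-weight multiset,
preserving weight composition; p is two-sided on |A| with the add-one
estimator, BH-adjusted across the pathways of a run.  When some members
are unmeasured the null sets (all drawn from measured genes) are slightly
better-measured than the pathway itself; at the default synthetic
missingness this bias is negligible.  Term enrichment is standard
one-sided Fisher; the EASE variant (one hit subtracted) is behind a flag
and not the default.  BH over permutation p-values stands in for any
permutation-specific FDR.

## Network efficacy

The largest connected component of the interaction subgraph induced on
the differential genes is the core cluster (size ties broken toward the
component containing the smallest gene id).  W = Σ d_g r_g uses
full-network degrees by default — positional importance is a global
property — with within-cluster degrees behind a flag; cluster genes
missing from the ratio matrix contribute 0 and are counted.  No size
normalization by default; W/|cluster| is available for cross-study
comparison.  The permutation null draws gene sets of cluster size from
measured network genes with degree ≥ 1, each drawn gene carrying its own
network degree; degree-0 genes can never contribute to any W, and
excluding them also keeps the null identical whether the network came
from memory or from an edge-list file (which cannot represent isolated
nodes).  Per-gene weighted terms (d_g r_g) of two conditions can be
correlated, with a permutation p from shuffling one condition's terms.

## Functional modules

The functional graph links genes whose log-ratio trajectories (≥ 3
conditions) have Pearson r ≥ 0.8, applied to *signed* r — a literal
reading of the correlation threshold; an |r| mode exists.  When a
backbone interaction network is supplied only its edges are candidates.

MCL follows the classic recipe: self-loops of weight 1 (prevents
bipartite oscillation), column-stochastic normalization, then alternate
expansion (matrix power 2) and inflation (entrywise power 2.0 +
renormalization), pruning entries below 1e-5, until the maximum entry
change is below 1e-8 or 100 iterations (non-convergence returns the
current clustering with a flag).  Clusters are connected components of
the limit matrix's support; a node attracted to several systems goes to
the lowest-labeled module so modules stay disjoint.  Modules below 3
genes are discarded and counted.

Module overlap uses the hypergeometric upper tail; term-map edges use the
overlap coefficient |A∩B|/min(|A|,|B|) with an inclusive 0.5 cutoff, and
optionally carry a hypergeometric edge weight against an external gene
list (0.01 cutoff).  Cross-dataset shared functions are terms enriched
(q < 0.01) in at least one module of each dataset; the intersection size
is itself scored hypergeometrically over the term universe.

## Literature association

Counts are binarized to presence/absence before any statistic — this
removes the influence of a few heavily cited items entirely, and the
tests verify that inflating any single count 1000-fold leaves the seeded
p unchanged.  The randomized-set test compares the query's binarized
total with same-size item sets drawn without replacement from the
id-sorted item universe (sorting makes p invariant to file row order);
one-sided ≥, add-one estimator.  The incremental curve repeats the test
on prefixes of the citation-ranked item list (ties lexical), each prefix
with its own derived seed so prefix k reproduces a standalone test.

## Synthetic world

The generator emulates: a control/disease contrast with a planted two-fold
signature (defaults: 2000 genes, 15% up + 15% down, effect 1.5 log2 ≈
2.8-fold, log-scale Gaussian noise sd 0.2 — comfortably above the 2-fold
cut so selection recovers the plant while noise creates realistic margin
effects); a three-step dose series removing 50% of the remaining effect
per step; a library of 50 drugs × 2 instances with 5 reversal and 5 mimic
drugs (planted rankings place tag genes at the extremes, then `rank_noise
× n` random adjacent transpositions); pathways of 20 genes with planted
up/down direction plus one exact role-flipped duplicate; an interaction
network of 4 planted 8-gene near-cliques (p_within 0.9, p_between 0.02)
over the differential genes plus a sparse background; and a literature
matrix where the planted (reversal + mimic) drugs have citation
probability 0.9 per keyword against a 0.1 background.

Intensities are 2^(baseline + effect + noise) with the baseline drawn
once per gene — strictly positive, and fold-changes exact when noise is
zero.  A 5% fraction of null genes is planted below the background filter
so the filter stage has work to do.  Each generator draws from its own
RNG stream derived from the master seed by a fixed offset, so stages
reproduce in isolation.

What the generator does **not** model: probe-level microarray structure,
pooling variance (the emulated design pools RNA per group, one array per
group — per-condition columns are generated directly), ortholog-mapping
divergence, cross-platform tag loss, and correlated (batch) noise.  Green
planted-recovery tests therefore establish the statistics' correctness
and calibration, not robustness to real-data artifacts.

## Determinism and provenance

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage seeds from the master seed by fixed offsets.  Float sums over
gene sets iterate in sorted order so results do not depend on set or
graph insertion order; expression TSVs are written with `%.17g` and read
with round-trip float parsing so a file round-trip is bit-exact.  Two
runs from the same config and seed produce identical output files; stage
runtimes go to a separate `runlog.json` excluded from that guarantee.
The analytic config hash (output path excluded) is stamped into every
result file header.

## Known limitations

- The drug-level permutation p is coarse for drugs with very few
  instances in small libraries (see above); interpret p near its floor
  accordingly.
- The profile-assignment q-value has the m/(B+1) resolution floor.
- MCL is run dense (numpy); graphs beyond a few thousand nodes need a
  sparse implementation.
- The union rule for the profile-correlation drug filter is a choice; the
  intersection rule can be selected and gives a smaller, cleaner drug set.
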