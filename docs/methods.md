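# Methods

## Model and procedure

`crmscan` tests whether a short DNA motif (CRE) or an unordered motif pair
(CRM) is associated with a specific expression category, using only (a) a
fixed-length promoter per gene, the 3' end abutting the TSS, and (b) an
expression catalog assigning each gene exactly one category. The catalog can
be supplied directly (e.g. from an upstream rhythmicity analysis) or derived
from a gene x condition matrix by binning each gene at its
maximum-expression condition (`categorize_by_max`; ties go to the earliest
category in the ordered label list and are logged).

The test statistic is the distribution of expression maxima, DEM: the
percentage of the query's genes per category. The sampling spread of a DEM
under no association is estimated empirically rather than parametrically:
`n_random` (default 100) random concrete CREs, lengths uniform on 5–8 bp
with i.i.d. uniform bases, are matched against the same promoter set and the
per-category standard deviation of their DEMs is taken (sample sd, ddof=1).
Random draws that do not themselves clear the occurrence filter
(`min_matches`, default 20 promoters) are rejected and replaced, so the sd
describes admissible queries. A background flags a query when some
category's absolute deviation |DEM_c − background_c|/σ_c reaches
`threshold_sd` (default 1); `n_backgrounds` (default 100) independent
backgrounds vote, and a candidate needs a strict majority plus the
occurrence filter. The comparison baseline is the catalog background (the
all-genes category percentages); the mean DEM of random CREs coincides with
it up to resampling error, which the test suite asserts.

Pair queries are genes containing at least one occurrence of *both*
members; their backgrounds are built from random CRE *pairs* under the same
co-occurrence filter, so the null is arity-matched.

### Matching

IUPAC queries are expanded to concrete component sequences (cardinality =
product of per-position degeneracies). In the default orientation mode each
concrete sequence is also searched reversed, complemented and
reverse-complemented; palindromic duplicates are deduplicated keeping one
record per distinct string. Matching is exact: a k-mer index (k = min(variant
length, 8)) seeds candidate positions and longer variants are verified
against the sequence, which is property-tested equal to a naive scan.
Promoter `N` bases match nothing — an unknown base is not evidence.
Coordinates are 0-based from the distal end; TSS distance of an occurrence
is measured at its TSS-proximal edge.

### Positional features of a candidate pair

Per co-occurring promoter: the spacing is the minimum |d_A − d_B| over
occurrence pairs (TSS-proximal edges), the module position is the smallest
TSS distance of any constituent occurrence, and the order records which
member's TSS-nearest occurrence is proximal (exact ties drop the promoter
from the order test only).

* **Order test.** Exact binomial, null probability 0.5 per promoter,
  two-sided by doubling the upper tail and capping at 1. Doubling (rather
  than the minimum-likelihood construction) is stated explicitly because the
  two conventions differ; it reproduces p = 3.86·10⁻⁵ for 29 concordant
  promoters of 34.
* **Distance test.** The null spacing distribution is simulated: each
  member is dropped at ⌈expected occurrences per promoter⌉ (rates below 1
  floored at 1 — a co-occurrence requires at least one of each) integer
  positions uniform in [0, L), and the smallest absolute pairwise
  difference is kept; 10,000 iterations. Integer positions match the
  discreteness of observed spacings, avoiding a spurious KS offset. The
  observed spacings are compared to this sample by a two-sided two-sample
  Kolmogorov–Smirnov test (scipy); under its own null the rejection rate at
  α = 0.05 is 5% (asserted over 500 simulated fixtures). Fewer than 3
  observed spacings yield a not-computed marker.
* **Bowley skewness.** S = (Q₃+Q₁−2Q₂)/(Q₃−Q₁) with linear-interpolation
  ("type 7") quartiles, computed on promoter *coordinates* (TSS at L), so
  TSS-proximal clustering gives S < 0. S is clipped to its exact range
  [−1, 1] against ~1e-15 floating-point overshoot; fewer than 4 positions or
  Q₃ = Q₁ yield a not-computed marker.

### Network categorization

Each candidate pair contributes the input triple (bowley, distance_p,
order_p), fed raw — the three negative-control points (p-values of 1,
skewness −1/0/1) are defined on these raw scales, so no standardization is
applied. Networks have a fixed structure (default 3 hidden sigmoid neurons,
one Heaviside output with h(0) = 1, fixed for determinism); evolution
touches only weights and biases. Fitness is lexicographic: any network
containing a negative control scores lowest; otherwise the ratio
positives/max(randoms, 1), ties broken toward more included points (wider
categories preferred at equal ratio). Each round keeps the top-k networks
and refills the population with single-parameter mutants (incremental
±step, or a resample from the init range) and per-parameter crossovers of
two parents, plus fresh random networks; a cycle ends after `patience`
rounds without improvement of the best score. Subsequent cycles veto
networks that cover no previously uncovered positive; training ends at full
coverage or a cycle cap (warned, partial ensemble returned). Reports
include per-network member tables, Spearman correlations among the three
inputs of each network's members (not computed below 2 members), and the
pairwise category-distance matrix 1 − |A∩B|/min(|A|,|B|). Ensembles persist
as human-readable JSON.

Defaults (all overridable): population 50, top-k 10, 10 fresh networks per
round, patience 15, init range U(−5, 5), incremental step 0.1, cycle cap 50.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `region_length` | 1000 bp | promoter length, TSS at the right end |
| `len_min`–`len_max` | 5–8 bp | random background CRE lengths |
| `n_random` | 100 | random CREs per background model |
| `n_backgrounds` | 100 | background models voting per run |
| `threshold_sd` | 1.0 | flagging threshold in background sd units |
| `min_matches` | 20 | minimum promoters containing the query |
| `iters` | 10,000 | distance-null simulation size |

A zero-sd category (degenerate catalogs) contributes deviation 0 when the
query's DEM equals the background there and +∞ otherwise.

## What the synthetic data emulates — and what it does not

`simulate.standard_fixtures` builds 200-promoter, 1000-bp studies with six
ZT categories mirroring the circadian case study. Plants overwrite windows
(never insert), keeping positional arithmetic exact, and every plant is
recorded in a manifest so downstream statistics can be checked against
construction parameters.

* `single-cre`: the evening element in 50 promoters, 90% of planted genes
  in one category — an effect far above 1 background sd.
* `pair-order`: a 9+8 bp pair in 60 promoters; the proximal member's TSS
  distance is truncated-exponential (scale 120 bp), the spacing is drawn as
  |U−V| for two iid uniform positions — i.e. *exactly* the distance-test
  null, resampled only on physical overlap — and the first member is
  proximal with probability 0.95. By construction the pair shows a strong
  order preference and left-skewed positions but no spacing preference.
* `pair-spacing`: the same pair at a rigid 50 bp spacing.
* `null`: no plants. Its calibration query set consists of degenerate
  heptamers (two N positions, ~16 expansions each), whose promoter
  occupancy sits at the saturated end of the random background pool — the
  occupancy profile of curated plant CRE collections, which are dominated
  by short/degenerate motifs. This matters: the empirical background sd is
  pooled over 5–8-mers whose DEM variances differ by an order of magnitude,
  so a query's false-positive rate at a fixed sd threshold depends on its
  occupancy relative to that pool. High-occupancy queries are calibrated
  (few false candidates); rare concrete 7-mers exceed 1 pooled sd often and
  are flagged at high rates. A separate mixed-length concrete query set on
  the same fixture exercises the threshold and occurrence-filter sweeps
  where counts actually decrease.
* `two-cluster`: a network-training set with 25+25 positives in the two
  module archetypes the features distinguish — order-preferring
  TSS-proximal pairs (order_p ≈ 0.005, S ≈ −0.8) and spacing-preferring
  pairs (distance_p ≈ 0.005, S ≈ +0.75) — over 600 uniform random points.
  The random density is chosen so that a single network merging both
  clusters includes ~20 randoms while a per-cluster network includes ~1:
  under the ratio score the intended two-category solution is also the
  optimum. (Real runs default to 200 random pairs; the training set of a
  synthetic benchmark needs a denser cloud because its clusters hug the
  p ≈ 0 faces where uniform randoms are sparse.)

What passing these fixtures does *not* show about real data: promoters here
are i.i.d. uniform sequences without compositional bias, repeats, or motif
clustering; category assignments of unplanted genes are independent of
sequence; and planted effects are large and homogeneous. Calibration rates
on real promoter sets will differ with base composition and with the
occupancy spectrum of the query collection.

## Numerical and design choices

* "Inversed" orientation is read as string reversal; with complementation
  this spans four readings, and the default mode searches all of them.
* Deviations are absolute (two-sided); the flagged category list reports
  categories flagged by a majority of backgrounds.
* Quartiles everywhere (Bowley, quartile dispersion coefficient) use linear
  interpolation between order statistics.
* The mutational scan samples unique pair mutants with a per-mutant
  mutation count uniform on [0, max_mutations], positions without
  replacement, alternative bases uniform; a *survivor* is a mutant still
  called candidate with every originally flagged category still flagged.
  The survivor profile reports per-position base frequencies over survivors
  and an importance vector (fraction of survivors retaining the original
  base).
* Run-level reproducibility: all stochastic steps consume one seeded
  generator hierarchy; identical configurations give byte-identical
  outputs. Repeat-level stability is summarized by the candidate-set
  overlap |∩|/|∪| and the quartile dispersion coefficient
  (Q₃−Q₁)/(Q₃+Q₁) of candidate counts.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on 200-promoter, 1000-bp
fixtures with full-scale decision machinery (100 random CREs x 100
backgrounds), 20 repeated runs for recovery rates, 500 simulated fixtures
for KS calibration, and the complete n ≤ 20 enumeration for the order-test
oracle. These sizes were chosen as the smallest at which the calibration
properties are statistically sharp; the method itself has no dependence on
them.

## Known limitations

* Only pairwise modules get positional features; an order test for k > 2
  members would need a multinomial construction.
* The sd-threshold-plus-majority-vote scheme is the method's only error
  control; there is no multiple-testing correction across queries, and the
  false-candidate rate is occupancy-dependent (see the `null` fixture
  discussion above).
* The distance null assumes uniform placement and at least one occurrence
  of each member per simulated promoter; expected counts below one are
  floored, which overweights rare motifs' nulls toward single-occurrence
  geometry.
* Networks are fixed-topology; categories are unions of what 3 hidden
  units can carve, and the positives/randoms ratio is sensitive to the
  random cloud's density in the region of interest.
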