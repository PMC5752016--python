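# crmscan

Discovery and prioritization of cis-regulatory elements (CREs) and pairwise
cis-regulatory modules (CRMs) in fixed-length promoter sets, driven by
categorized gene-expression maxima.

## Who this is for

Regulatory genomicists with (a) promoters cut to a fixed length upstream of
the transcription start site (TSS), (b) an expression experiment in which
each gene peaks in exactly one condition (circadian time courses are the
archetype: six 4-hour Zeitgeber-time bins), and (c) a list of known or
suspected motifs in IUPAC code. `crmscan` answers: *which motifs — and which
motif pairs — sit preferentially in the promoters of genes peaking at a
particular time*, and *how are the members of a significant pair arranged
relative to each other and the TSS*.

## The method

**Candidate calling.** Every gene is assigned one expression category (by the
condition of its maximum expression). For a query motif *q*, the percentage
of *q*-containing genes per category is its distribution of expression
maxima, DEM(*q*). The null spread is estimated empirically: 100 random CREs
of 5–8 bp are matched against the same promoters and the per-category
standard deviation σ_c of their DEMs is recorded. The query is *flagged* by
that background when

&nbsp;&nbsp;&nbsp;&nbsp;|DEM_c(q) − background_c| ≥ t·σ_c&nbsp;&nbsp;for some category c,

with threshold t (default 1). Because each background is itself random, 100
independent backgrounds are drawn and the query is a **candidate** only if a
strict majority flags it and it occurs in at least 20 promoters. Pair
queries (`motifA,motifB`, genes containing both members) are compared to
backgrounds built from random CRE *pairs*.

**Positional features** for a candidate pair, over its co-occurring
promoters:

* *order test* — exact binomial test of which member's TSS-nearest
  occurrence is proximal: p = min(1, 2·Σ_{i=X..n} C(n,i)·0.5ⁿ);
* *distance test* — two-sided two-sample Kolmogorov–Smirnov test of the
  observed member spacings against 10,000 simulated spacings of uniformly
  placed occurrences;
* *Bowley skewness* of module position, S = (Q₃+Q₁−2Q₂)/(Q₃−Q₁) on promoter
  coordinates, so TSS-proximal clustering gives S < 0.

**Network prioritization.** The triples (S, p_distance, p_order) of all
candidate pairs are categorized by an ensemble of small two-class networks
(3 inputs, sigmoid hidden layer, Heaviside output) trained by
neuroevolution: a network's score is (positives included)/(randoms
included), vetoed outright if it includes any of the three negative-control
points (p-values 1, S ∈ {−1, 0, 1}), ties broken toward larger categories.
Training cycles must each cover a previously uncovered positive and stop
when every positive is categorized.

## Worked example

Synthetic fixtures with known ground truth are built into the package. The
`single-cre` fixture plants the evening element (AAAATATCT) in 50 of 200
promoters of 1000 bp and puts 90% of the planted genes into the ZT8–ZT12
category:

```python
import numpy as np
from crmscan import (standard_fixtures, build_backgrounds, evaluate_query,
                     find_matches, pair_positional_stats)

fx = standard_fixtures(7)
f = fx["single-cre"]
rng = np.random.default_rng(0)
backgrounds = build_backgrounds(f.promoters, f.catalog, rng)   # 100 x 100 random CREs
call = evaluate_query("AAAATATCT", f.promoters, f.catalog, backgrounds=backgrounds)
print("candidate:", call.candidate)
print("votes:", f"{call.votes}/{call.n_backgrounds}")
print("matching promoters:", call.n_matching_promoters)
print("DEM (%):", np.round(call.dem, 1))
```

prints

```
candidate: True
votes: 100/100
matching promoters: 52
DEM (%): [ 1.9  0.  90.4  1.9  1.9  3.8]
```

— the motif occurs in 52 promoters, 90.4% of whose genes peak in ZT8–ZT12
(background ≈ 16.7% per bin), and all 100 random backgrounds flag it. The
`pair-order` fixture plants a module with 95% order bias and TSS-proximal
positions but unconstrained spacing:

```python
p = fx["pair-order"]
q = p.queries[0]
ma = find_matches(q.members[0], p.promoters)
mb = find_matches(q.members[1], p.promoters)
print(q.label, pair_positional_stats(ma, mb, p.promoters, rng))
```

```
CCACGTGGC,AGATATTT PositionalStats(order_p=4.85494457136415e-13,
    distance_p=0.042443681700781354, bowley=-0.2892561983471074, n_promoters=61)
```

— strong order preference, left-skewed (TSS-proximal) module positions, and
a spacing distribution close to the uniform null.

The same analyses run from the shell:

```bash
crmscan simulate --name single-cre --seed 7 --out fixture/
crmscan edcc --promoters fixture/promoters.fasta --catalog fixture/catalog.tsv \
             --queries fixture/queries.txt --seed 0 --out run/
crmscan pairs --queries fixture/queries.txt --count-only
crmscan cng  --positional run/positional.tsv --promoters fixture/promoters.fasta \
             --seed 0 --out cng_run/
```

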