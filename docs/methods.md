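# Methods

## The composition algebra

All quantities derive from the single-strand tallies of the four bases.
For a genome (possibly many FASTA records, summed), the profile holds
*P*(A), *P*(T), *P*(G), *P*(C) over **unambiguous** bases, plus the
derived contents of the four two-base subsets: S = G∪C (GC content),
W = A∪T = Sᶜ, R = A∪G (purine content), Y = T∪C = Rᶜ. Because {S, W} and
{R, Y} each partition the alphabet, *P*(S) + *P*(W) = *P*(R) + *P*(Y) = 1
holds identically; tests assert it to 1e−12.

Counting is on the strand as given. No canonical-strand selection is
attempted: the single-strand reading is the object of study, and the
package's own property tests verify that concatenating a strand with its
reverse complement restores exact pairing (counts of A equal T and G
equal C), which is the double-strand limit of the pairing rule.

**Ambiguity handling.** IUPAC codes outside {A, C, G, T} are tallied
separately and excluded from the proportion denominator. Assemblies often
carry long N runs at gaps; including them in the denominator would deflate
every proportion by an amount unrelated to composition. The excluded
fraction is reported (`ambiguous_fraction`, relative to total length) so
users can judge assembly quality. This is a documented choice, not a
universal convention.

**Normalization.** The reader uppercases soft-masked bases (masking marks
repeats, not composition), maps U→T so RNA genomes are analyzable
(count reported per record), and strips alignment gaps `-`/`.` with a
count rather than failing. Record id is the first header token. Anything
else outside the IUPAC set is a hard format error with record and offset.

## Law scoring

Per genome, the report carries:

- **Pairing deviations** |*P*(A) − *P*(T)| and |*P*(G) − *P*(C)|. Unit:
  proportion difference; 0 is perfect conformity. Typical genome-scale
  values are O(10⁻³).
- **Purine imbalance** |*P*(R) − 0.5|.
- **Factorization residuals**: observed minus estimated proportion per
  base, where the estimate is `estimate_profile(p_s, p_r)` evaluated at
  the genome's own contents:
  *P̂*(A) = (1−s)r, *P̂*(T) = (1−s)(1−r), *P̂*(G) = sr, *P̂*(C) = s(1−r).
  These four products sum to 1 algebraically for any (s, r) in the unit
  square, so the residuals sum to 0.
- **2×2 independence test** of S ⟂ R on the table rows {S, W} × columns
  {R, Y} with cells (G, C / A, T). The expected counts under independence
  are n·*P̂*(base) — deliberately computed through `estimate_profile`
  rather than the generic margins formula, which is algebraically
  identical but makes the link to the factorization explicit (and is
  tested against the margins formula by exhaustive enumeration of all
  2×2 tables with cells ≤ 6). Default statistic is Pearson's chi-square
  without continuity correction: at genome-scale n the Yates correction
  is negligible, and omitting it preserves the exact equivalence
  "statistic = 0 ⇔ counts factorize (n_G·n_T = n_A·n_C)". A
  likelihood-ratio G statistic is available (`method="g"`) for small toy
  tables. A zero margin (e.g. a purine-free sequence) raises a
  degenerate-table error naming the margin rather than returning NaN.
- **Outlier score** = max of the two pairing deviations. The chi-square
  statistic is *not* used for ranking because it scales linearly with
  genome length and would conflate size with deviation; the pairing
  disparity is a size-free effect measure, and the canonical published
  anomaly is characterized precisely by a large G/C disparity.

No multiple-testing correction is applied inside the law module; p-values
are descriptive. Profiles loaded from proportion-only tables cannot carry
the contingency test (no integer counts); those fields are `None`, never
silently zero.

**Rounding.** Proportions are kept at full float precision internally and
rounded only at report time, default 4 decimals with Python's
round-half-even. JSON serializations are full precision.

## Cohort analysis

`panel_regressions` fits eight ordinary-least-squares panels: T on A and
C on G (pairing), purine excess (*P*(R) − *P*(Y)) on *P*(S) and *P*(R) on
*P*(S) (independence of GC and purine content: slope ≈ 0, intercept ≈
0.5), and observed on estimated proportion per base (factorization:
slope ≈ 1, intercept ≈ 0, R² ≈ 1). OLS with vertical residuals is used
throughout; the symmetric panels (A vs T) arguably call for
errors-in-variables regression, but OLS matches standard practice for
these diagnostics and the choice only matters when the x-variable noise
is comparable to its spread. R² is reported as undefined (`None`) when
the response is constant — any numeric stand-in (0 or 1) would be
arbitrary and misleading. The engine is cross-checked in tests against
statsmodels and against a brute-force grid minimization of the residual
sum of squares.

Input tables may give proportions as fractions or percentages; a table
whose maximum proportion exceeds 1.5 is treated as percent and divided by
100 (a fraction can never exceed 1, a percentage table of genomes in
practice always does). Row proportions must sum to 1 within 0.005 —
loose enough for 4-decimal published values, tight enough to catch a
dropped column.

## Sequence design

`design_sequence` turns the factorization generative: targets (s, r)
define per-base probabilities ((1−s)r, (1−s)(1−r), sr, s(1−r)).

- **iid mode** draws each position independently — the minimal model
  consistent with marginal probabilities; no dinucleotide or higher-order
  structure is imposed because the factorization constrains only
  marginals.
- **exact mode** fixes the base counts by largest-remainder (Hamilton)
  apportionment of length × probabilities — floors, then leftovers by
  descending fractional remainder, ties broken in base order A, T, G, C —
  and shuffles the multiset. Counts always sum to the requested length,
  and each achieved content is within 2/length of its target.

The PRNG is numpy's PCG64; the seed is mandatory (a design use case is
meaningless without reproducibility) and identical specs produce
byte-identical FASTA. The header records all spec fields and the PRNG.

`verify_design` passes a sequence when each achieved content is within
2/length (exact mode) or 4 binomial standard errors
4·√(p(1−p)/length) (iid mode, false-alarm rate ~10⁻⁴ per target) of its
target.

## What the synthetic data does and does not emulate

Tests and the cohort examples use designer-generated sequences as the
synthetic data source. These match real genomes in their *marginal*
composition (any GC and purine content is reachable) but are iid at every
position: they have no repeats, no N runs, no codon structure, no GC skew
along the replication axis, and their pairing deviations are pure
sampling noise O(1/√length). Passing tests therefore demonstrate the
correctness of the algebra, the test statistics, and the regression
engine — not that real genomes obey the laws; that is an empirical claim
the package measures rather than assumes. Cohort simulations use
r = 0.5 with s uniform on [0.2, 0.8], mimicking the observed cross-species
pattern of tightly balanced purine content and widely varying GC content.

## Problem sizes and numerical choices

Simulation-based checks use lengths of 10⁴–10⁵ bases and cohorts of
50 genomes with 200–500 seeded replicates — large enough that binomial
standard errors (~1.6×10⁻³ at length 10⁵) separate signal from noise by
an order of magnitude, and small enough that the full suite runs in
seconds. Algebraic identities are asserted to 1e−12; oracle comparisons
(scipy, statsmodels, enumeration) to 1e−9 or tighter.

## Known limitations

- Proportion-only inputs lose the contingency test and genome size.
- The 2×2 test treats bases as iid draws; real genomes are autocorrelated,
  so its p-value is anti-conservative there and should be read as a
  descriptive index, not an inference.
- OLS panels do not correct for phylogenetic non-independence of genomes.
- No windowed/regional analysis (GC skew, isochores) — the laws target
  whole-genome composition only.
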