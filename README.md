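# genolaws

Genome-wide nucleotide composition obeys striking regularities. Within a
single strand of a genome, the proportion of adenine approximates that of
thymine and guanine that of cytosine (Chargaff's second parity rule); as a
consequence, purines and pyrimidines each make up about half the strand,
*P*(R) ≈ *P*(Y) ≈ 0.5, while GC content *P*(S) varies freely between
roughly 0.2 and 0.8 across species. Treating a base's strong/weak (S/W)
status and purine/pyrimidine (R/Y) status as statistically independent
events then predicts every base proportion from just two numbers:

    P(A) = P(W)·P(R)    P(T) = P(W)·P(Y)
    P(G) = P(S)·P(R)    P(C) = P(S)·P(Y)

with W = Sᶜ and Y = Rᶜ. `genolaws` is a library and CLI for working with
this algebra. It is aimed at comparative genomicists and synthetic
biologists who want to

- compute the eight composition proportions (A, T, G, C, S, W, R, Y) of
  genome assemblies from FASTA;
- score each genome's conformity to the pairing rule, the purine balance,
  and the independence factorization (including a 2×2 contingency test of
  S ⟂ R whose expected counts are exactly the factorization estimates);
- run cross-genome regression panels (T vs A, C vs G, purine content vs
  GC content, observed vs estimated proportions) and rank compositional
  outliers;
- design random sequences with prescribed GC and purine content under the
  independence model, reproducibly from a seed.

These regularities hold at the genome level; they are not expected for
individual genes or local regions.

## Worked example

The genome of *Saccharomyces cerevisiae* S288C has GC content
*P*(S) = 0.3815 and purine content *P*(R) = 0.5004. The factorization
predicts its base proportions:

```python
>>> from genolaws import estimate_profile
>>> est = estimate_profile(0.3815, 0.5004)
>>> [round(p, 4) for p in (est.p_a, est.p_t, est.p_g, est.p_c)]
[0.3095, 0.309, 0.1909, 0.1906]
```

i.e. estimated *P*(A) = 0.3095, *P*(T) = 0.3090, *P*(G) = 0.1909,
*P*(C) = 0.1906 — within 0.0003 of the observed yeast proportions
(0.3098, 0.3087, 0.1906, 0.1909).

The same algebra runs end-to-end from the shell. Design a 50 kb sequence
with yeast-like composition, then score it against all three laws:

```bash
genolaws design --gc 0.3815 --purine 0.5004 --length 50000 --seed 7 --out demo.fasta
genolaws laws demo.fasta
```

Selected columns of the report for seed 7:

| p_a | p_t | p_g | p_c | law1_delta_at | law1_delta_gc | law2_delta | max_abs_residual | chi2 |
|-----|-----|-----|-----|---------------|---------------|------------|------------------|------|
| 0.3090 | 0.3057 | 0.1918 | 0.1935 | 0.0032 | 0.0018 | 0.0007 | 0.0012 | 1.15 |

The pairing deviations (`law1_delta_*`, absolute differences of the paired
base proportions) and the purine imbalance (`law2_delta`, |*P*(R) − 0.5|)
are at the few-per-mille level expected from sampling noise at 50 kb; the
factorization residuals (`max_abs_residual`) are of the same order; and
the 2×2 independence statistic (chi2 = 1.15 on 1 df, p = 0.28) shows no
detectable association between S/W and R/Y status — the sequence behaves
exactly as the model that generated it predicts.

For a cohort, `genolaws cohort DIR --out-dir results/` writes the
per-genome table, the eight regression panels (slope, intercept, R²), and
an outlier ranking by the largest pairing disparity. The published
anomaly *Candidatus* Chazhemtobacterium aquaticus, with
*P*(G) = 0.1497 vs *P*(C) = 0.2983, scores 0.1486 against 0.0011 for
yeast and tops such a ranking.

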