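# metareduce

Remove one cohort's contribution from inverse-variance-weighted (IVW)
fixed-effect GWAS meta-analysis summary statistics — algebraically, without
access to any other cohort's data.

## The problem

Polygenic risk scores (PRS) are trained on GWAS summary statistics, ideally
from the largest available meta-analysis. But when the cohort you want to
score *also contributed* to that meta-analysis, the sample overlap inflates
the apparent predictive accuracy. The clean fix — re-running the
meta-analysis without your cohort — requires every contributing study's
summary statistics, which are often inaccessible.

You do, however, have two things: the published pooled statistics and your
own cohort's statistics. That is enough. Under fixed-effect IVW pooling
with weights w_i = 1/se_i², the pooled effect B and standard error SE
satisfy

```
B = Σ β_i w_i / Σ w_i        SE² = 1 / Σ w_i
```

so one cohort's term (β_n, se_n) can be subtracted back out in closed form.
With w_n = 1/se_n²:

```
B_adj  = (B − SE²·β_n·w_n) / (1 − SE²·w_n)
SE²_adj = SE² / (1 − SE²·w_n)
```

The result is *identical* to re-running the meta-analysis with the cohort
left out — not an approximation. The package verifies this against a
brute-force leave-one-out oracle at every level, from single markers to
100,000-marker tables.

Around the core formula sit the pieces a real pipeline needs: configurable
summary-statistics parsing (METAL- and PLINK-style column dialects, plus
user-defined mappings), allele harmonization (swaps, strand flips,
palindromic-marker policies), a standalone IVW meta-analysis engine, a
seeded synthetic multi-cohort generator, and a validation harness.

## Worked example

```python
from metareduce import adjust_marker, ivw_pool

meta = ivw_pool([(0.1, 0.1), (0.2, 0.1), (0.3, 0.1)])
removed = adjust_marker(meta.B, meta.SE, beta_n=0.3, se_n=0.1)
oracle = ivw_pool([(0.1, 0.1), (0.2, 0.1)])
```

Running `python examples/adjust_single_marker.py` prints:

```
pooled:    B = 0.200000  SE^2 = 0.00333333  (k = 3)
adjusted:  B_adj = 0.150000  SE^2_adj = 0.00500000  status = adjusted
oracle:    B = 0.150000  SE^2 = 0.00500000  (direct re-pool)
```

Three equal-weight cohorts pool to B = 0.2; removing the third (β = 0.3)
shifts the estimate to 0.15 and widens SE² from 1/300 to 1/200 — exactly
the direct meta-analysis of the two remaining cohorts.

The table-level experiment (`python examples/loo_validation.py`, 4 cohorts
× 10,000 markers) prints, for every excluded cohort:

```
excluded cohort 0: r(B_adj, B_loo) = 1.000000000000000  r(SE2_adj, SE2_loo) = 1.000000000000000  max rel diff B = 1.18e-15
```

Pearson correlation 1.0 and marker-wise differences at round-off level:
the closed form and the leave-one-out re-analysis are the same computation.

The other examples show table-level adjustment with allele harmonization
(`adjust_cohort_table.py`) and the calibrated synthetic-data generator
(`simulate_and_meta.py`).

## Command line

```
metareduce simulate --cohorts 4 --markers 100000 --n 20000,8000,45000,6000 --seed 7 --out-prefix sim/cohort
metareduce meta     --in sim/cohort_1.tsv --in sim/cohort_2.tsv --out meta.tsv
metareduce adjust   --meta meta.tsv --cohort sim/cohort_2.tsv --out adjusted.tsv
metareduce validate --cohorts 4 --markers 100000 --seed 7 --out report/
```

`adjust` writes an adjusted summary-statistics table (with recomputed z and
p per marker and a status column), a harmonization report, and a run log.

## Scope

Fixed-effect IVW is the only pooling model in scope: the closed form is
exact for it and for nothing else. Random-effects pooling, z-score
(sample-size-weighted) meta-analysis, genomic control, covariance-aware
removal of partially overlapping cohorts, and PRS construction itself are
out of scope. See `docs/methods.md` for the model, assumptions, numerical
choices and limitations.
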