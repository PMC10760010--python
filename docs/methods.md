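# Methods

## Model

A fixed-effect inverse-variance-weighted (IVW) meta-analysis of n cohorts
pools per-marker estimates β_i with weights w_i = 1/se_i²:

    B = Σ β_i w_i / Σ w_i,        SE² = 1 / Σ w_i.

Both B and SE are sufficient for the removal of any one contributing
cohort n: the total weight is recoverable as 1/SE², the cohort's weight as
w_n = 1/se_n², so the weight of everything else is

    Σ_{i≠n} w_i = (1 − SE²·w_n) / SE²,

and subtracting the cohort's term β_n w_n from the weighted sum B/SE²
gives the leave-one-out estimate in closed form:

    B_adj  = (B − SE²·β_n·w_n) / (1 − SE²·w_n)
    SE²_adj = SE² / (1 − SE²·w_n).

This is an algebraic identity, not an approximation: given exact inputs it
reproduces the re-run meta-analysis bit for bit. Equivalently B_adj =
B + SE²(B·w_n − β_n·w_n)/(1 − SE²·w_n); the denominator applies to the
whole expression including the leading B — the other grouping fails the
forced identity that removing one of two cohorts must return the other
cohort unchanged, and is rejected by a dedicated test.

Assumptions inherited from the fixed-effect model: a common true effect
per marker, independent cohorts (no overlapping individuals *between* the
contributing studies), and weights formed from the same standard errors
the meta-analysis used. A meta-analysis run with genomic-control-corrected
or otherwise rescaled standard errors breaks the identity silently; see
Limitations.

## Degenerate inputs

Let d = 1 − SE²·w_n, the removed cohort's complementary weight share.

- d > ε (default ε = 1e-12): adjust normally; status `adjusted`.
- |d| ≤ ε: the cohort carries essentially the entire meta-analysis weight;
  nothing remains to estimate. Status `dominant_cohort`, no numeric output.
- d < −ε: the cohort claims more weight than the whole meta-analysis,
  which exact IVW arithmetic cannot produce — it indicates rounded or
  mismatched inputs. Status `inconsistent_inputs`, no numeric output;
  clamping would fabricate precision.
- Marker absent from the cohort: the cohort contributed zero weight, so
  the meta values pass through verbatim (`passthrough_not_in_cohort`)
  rather than shrinking the marker panel.

p-values are always recomputed as the two-sided standard-normal tail
probability of B_adj/SE_adj; input p-values refer to the unadjusted
estimate and are never carried over.

## Harmonization

Before removal, the cohort's effect must refer to the meta-analysis's
effect allele. Markers are matched on marker id; allele reconciliation
tries, in order, the as-written orientation, the effect/other swap (beta
negated), the strand complement, and the complemented swap (negated).
As-written matches take precedence over strand interpretations. Only the
sign of the cohort beta ever changes.

Palindromic pairs (A/T, C/G) are their own strand complement, so swap and
flip are indistinguishable. The default `drop-if-flip` policy keeps them
only when the alleles match as written; `drop` excludes them all; `keep`
resolves them as written. Multi-base (indel) alleles are never
strand-complemented — complementing an indel is ill-defined — and match
only exactly or swapped. Anything unresolvable is excluded and counted,
never guessed, since a sign-flipped effect corrupts every downstream PRS
weight. When either table lacks allele columns entirely, matching falls
back to marker id with a prominent warning.

## Synthetic data generator

The generator emulates K independent cohorts measuring M shared markers,
defaults chosen as a realistic 4-study constellation: K = 4, M = 100,000,
unequal sizes (20,000 / 8,000 / 45,000 / 6,000), 1% causal markers with
effect s.d. τ = 0.02, effect-allele frequencies uniform on (0.01, 0.5).
Per marker j and cohort i:

    p_j ~ U(maf_range);  β_true,j = 0 w.p. 1 − causal_fraction,
                                   else N(0, τ²)
    se_ij = 1/√(2 p_j (1−p_j) n_i);  β̂_ij ~ N(β_true,j, se_ij²)

The standard-error model is the unit-variance quantitative-trait
approximation, chosen over a case-control log-odds model for closed-form
transparency; the adjustment itself is agnostic to trait type — only
(β, se) pairs enter. Allele pairs are drawn non-palindromic by default,
mirroring standard PRS practice of excluding strand-ambiguous markers.
A single seed drives one `SeedSequence`; per-cohort substreams are
spawned from it, so identical configs are bit-identical.

What the generator does *not* emulate: linkage disequilibrium between
markers (every marker is independent), population stratification,
case-control imbalance, between-cohort heterogeneity of true effects, and
overlapping individuals between cohorts. Passing tests therefore
demonstrate the algebra and the pipeline plumbing under the fixed-effect
model's own assumptions; they do not certify behaviour on real data where
those assumptions fail (notably, the identity is with respect to whatever
fixed-effect IVW run produced the inputs — nothing more).

`perturb_alleles` deliberately mis-orients a table (seeded swaps with
negated betas, strand complements) and records the truth per marker, so
harmonization can be verified to restore every beta exactly.

## Numerical choices

- **Extended precision in the pooling/removal path.** The removal
  subtracts one cohort's term back out of the pooled sums; when the
  leave-one-out effect is near zero this is a near-total cancellation, and
  plain float64 leaves relative disagreement with a from-scratch
  re-analysis of order 1e-10 at the smallest effects in a 100,000-marker
  table. The pooled sums and the adjustment arithmetic therefore run at
  `np.longdouble`, which brings route-to-route agreement to ~1e-13
  relative while file inputs and outputs remain ordinary float64 text.
  On platforms where longdouble is float64 the code still runs, with
  agreement limited accordingly.
- **Correctly rounded parsing.** Numeric fields are coerced through
  Python's `float()` (correct rounding) rather than the fast pandas
  parser (~1 ulp error), so write-then-read reproduces every value
  bit-for-bit; floats are printed with 17 significant digits.
- **Summation order** is input order (first-appearance marker order);
  cohort permutation changes results only below 1e-14 relative.
- **ε = 1e-12** on d separates "dominant cohort" from adjustable markers;
  d < −ε is reported as inconsistent rather than clamped.
- Duplicate marker ids keep the first occurrence (deterministic,
  order-stable) with a warning count; rows with se ≤ 0 or unparseable
  numerics are dropped and tallied per reason, and retained + rejected
  always sums to rows read.

## Validation harness

`run_validation` simulates K cohorts, pools all of them, and for each
cohort compares the closed-form adjustment of the pooled table against a
brute-force leave-one-out re-analysis: Pearson correlations of B and SE²,
and max/mean element-wise relative differences, over markers with status
`adjusted` (passthrough and degenerate markers are tallied separately —
the comparison only exists where an adjustment happened). The default
experiment is 4 cohorts × 100,000 markers and completes in a few seconds.
A precision-limited mode rounds the pooled and cohort values to a chosen
number of decimals *for the adjustment's inputs only*, emulating
published files, while the oracle keeps full precision — rounding both
routes identically would leave the algebra exact and show nothing. In
that mode correlations drop below 1 (typically staying above 0.999 at
4 decimals) and the report is flagged.

Problem sizes used in the shipped tests: the equivalence experiment runs
at the full 4 × 100,000 scale; bulk invariants (fixed point,
monotonicity, round-trip re-pooling) use 10,000 random draws; calibration
checks use 40,000 standardized residuals.

## Limitations

- Exact only for fixed-effect IVW. Pooled statistics from random-effects
  models, sample-size-weighted z-score meta-analysis, or
  genomic-control-inflated standard errors do not satisfy the identity;
  the package cannot detect this from the numbers alone.
- One cohort per algebraic step. Removing several cohorts works by
  iterating (tested as a property), but overlapping individuals *between*
  the removed cohort and the remaining ones are outside the model.
- Published rounding propagates: with inputs printed to 4 decimals the
  adjusted values deviate from the true leave-one-out values roughly in
  proportion to the rounding, and markers where rounding makes
  w_n·SE² > 1 are reported as inconsistent rather than adjusted.
- Marker matching is by identifier only; build mismatches or identifier
  drift between the meta and cohort tables must be resolved upstream.
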