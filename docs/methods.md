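# Methods

`pvsignal` implements a year-stratified disproportionality analysis of
spontaneous adverse-event reports together with a hypergeometric
over-representation analysis of drug-interacting gene sets. This note
records the statistical model, the defaults and why they were chosen, what
the synthetic generators do and do not emulate, and the numerical and
design decisions a maintainer would want spelled out.

## Disproportionality model

Within an indication cohort, each report is cross-classified by drug
exposure and by whether a given reaction preferred term was reported,
giving per-year 2×2 tables (a, b; c, d). The per-year signal statistic is
the reporting odds ratio

    ROR = a·d / (b·c)

with log-scale Woolf variance `v = 1/a + 1/b + 1/c + 1/d` and Wald
(1−α) interval `exp(y ± z·√v)`, `y = log ROR`. A lower confidence bound
strictly above 1.00 flags disproportionate reporting. The ROR measures
*reporting* association among spontaneous reports, not incidence or risk;
no causal reading is implied.

Term matching is exact equality on normalized strings (uppercase, trimmed,
internal whitespace collapsed). Substring matching is deliberately not
offered: it silently inflates counts (e.g. "ANAEMIA" inside "HAEMOLYTIC
ANAEMIA"). Reports sharing an id are deduplicated keeping the last
occurrence (reporting systems supersede earlier case versions); reports
without a parseable receipt year are dropped and counted, never imputed,
because year is the stratification key. Every cohort report without the
study drug is a control; polytherapy among exposed reports is not
excluded.

### Zero cells and degenerate strata

When any cell of a yearly table is zero, 0.5 is added to all four cells
(Haldane–Anscombe) before estimation; the table is marked `corrected`.
Strata with an empty exposure margin in the raw counts (no exposed or no
unexposed reports) are excluded from pooling with a logged warning — their
corrected estimate would be an artifact of the correction alone.

## Pooling across years

Heterogeneity between years is assessed by Cochran's Q with df = k−1,
I² = 100·(Q−df)/Q floored at zero, and the DerSimonian–Laird
method-of-moments variance `tau² = max(0, (Q−df)/(Σw − Σw²/Σw))`,
`w = 1/v`. Model choice follows the classic rule: if the Q test is
significant at `het_alpha` (default 0.05, strict inequality), pool with
DerSimonian–Laird random effects on the (y, v) pairs; otherwise pool with
Mantel–Haenszel fixed effects computed from the raw stratum counts, with
the Robins–Breslow–Greenland variance for the pooled log odds ratio.
Knapp–Hartung or REML variants are intentionally not offered; the classic
DL/MH pair is the method under study. With `tau² = 0` the DL pool reduces
exactly to inverse-variance fixed pooling (tested to 1e-12).

Leave-one-out sensitivity re-pools every (k−1)-subset under the *same*
model family as the full analysis — sensitivity is a perturbation of the
chosen analysis, not a fresh model selection per subset.

Known small-sample property: DL 95% intervals undercover slightly at
k = 12 (~93% measured under the default synthetic world). This is a
property of the method, not a defect of the implementation; tests assert
coverage bands that accommodate it.

## Reporting-bias diagnostics

Funnel coordinates are (log ROR, se) per stratum, conventionally plotted
with se increasing downward; the package emits coordinates only, any
graphics are a thin layer over them. Egger's test is the classic
unweighted OLS regression of the standardized effect `y/se` on the
precision `1/se`, with a two-sided t-test of the intercept on k−2 df.

Limitation worth knowing: Egger's test presumes genuinely varying
precisions. When strata are near-equal in size (as in a cohort with a flat
yearly report volume), the variation in *estimated* precision is mostly
sampling noise correlated with the effect, and the test's type-I error is
far above nominal (≈94% measured at k = 12 equal strata of 1600 reports;
still ≈10% under a 10× volume growth across years). Its calibration is
therefore asserted at the estimate level, where the t-reference is exact;
on real yearly strata the test should be read as a descriptive diagnostic.

## Over-representation analysis

For a query of n genes from a reference universe of N, a category with K
reference genes and k query hits is scored by the enrichment ratio
`(k/n)/(K/N)` and the hypergeometric upper tail `P(X ≥ k)`, accumulated in
log space (log-binomials via `gammaln`, combined with `logsumexp`) so
tails near 1e-50 keep relative accuracy. Benjamini–Hochberg step-up
adjustment spans exactly the categories supplied; categories with adjusted
p < 0.01 are flagged. Reported ratios round half away from zero to two
decimals, computed in exact rational arithmetic so table comparisons never
hinge on binary floating point.

Published ORA tables often omit N. `recover_reference_size` inverts the
rounding: each printed two-decimal ratio constrains N to one contiguous
integer interval ((2R−1)·nK ≤ 200·kN < (2R+1)·nK for printed ratio R/100),
and the intersection over rows is the candidate set. For the bundled
carboplatin/KEGG counts (14 pathways, query n = 205) the four largest
cancer pathways pin N = 43338 uniquely in [10000, 100000], and that N
reproduces all 14 printed ratios. N is treated as a recoverable parameter
of the published analysis, not a biological constant. Because the original
multiplicity span (how many pathways were tested) is unknown, published
adjusted p-values are only ever used as upper bounds on the recomputed raw
tails — BH can only inflate — never asserted as equalities.

## Synthetic worlds

**Report stream.** Per year i, a latent log ROR `theta_i ~ Normal(mu,
tau²)`; each report is exposed with `p_exposure`; unexposed reports carry
the event with baseline probability `p0`, exposed reports with the
probability whose odds are `exp(theta_i)·odds(p0)` — so `mu` is exactly
the log ROR of the generating process and parameter recovery is a sharp
test. Defaults state the emulated study: years 2004–2015, 1600
reports/year (~19200 total), exposure 0.2 (≈3907/19901), true OR 2.27,
tau 0.2. The baseline event probability 0.05 is a typical reporting
fraction for a single hematologic preferred term in oncology spontaneous
reports; it was fixed a priori. Decoy drugs and reactions come from fixed
vocabularies; an optional `duplicate_fraction` re-emits report ids to
exercise deduplication. Not emulated: reporting-volume growth over years,
manufacturer duplicates with conflicting content, polypharmacy
correlations, missingness in fields other than receipt date. A green test
on this world establishes correct arithmetic and calibration under the
stated model — not robustness to real FAERS artifacts.

**Gene universe.** Reference ids g1..gN; categories are uniform subsets;
a planted category's hits enter the query at `fold` times its background
rate (Binomial(n_query, fold·K/N)), so the expected enrichment ratio is
the fold. All randomness flows through one seeded generator; identical
configs give byte-identical JSONL/GMT output.

## Numerical conventions

- Normal/chi-square/t quantiles and tails come from scipy; z for 95%
  intervals is the 0.975 quantile (1.959964 to 6 decimals).
- Test tolerances: 1e-9 absolute on hand-computed statistics, 1e-12 on
  algebraic identities, 1e-12 absolute on hypergeometric tails versus
  exhaustive enumeration.
- Strict inequalities at decision boundaries: signal flag at lower bound
  > 1.00, random-effects selection at p < alpha, ORA selection at
  adjusted p < alpha.
- BH adjusted values are clamped at their raw p (m·p/rank can round one
  ULP below p at rank = m).
- All output files are deterministic: stable key order, fixed float
  formatting (`%.10g`), no timestamps.

## Known limitations

- The ROR is a reporting-disproportionality measure; confounding (age,
  comorbidity, co-medication) is out of scope by design.
- DL undercoverage at small k and Egger anticonservatism on equal-sized
  strata, as noted above.
- MedDRA hierarchy rollups (SOC/HLT) are not implemented; terms are flat
  normalized strings.
- The fixed-effects family pools with Mantel–Haenszel counts; its
  leave-one-out therefore needs the stratum tables, not just (y, v) pairs.
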