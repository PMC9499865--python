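# Methods

## Cohort model and windows

The data model is three delimited tables — patients, serum samples (one row
per sample × cytokine, pg/ml), CTCAE-graded adverse events — validated into
one `CohortDataset` before any computation. Dates are ISO-8601 and all
arithmetic is in whole days; day 0 of a vaccinated patient is the first
dose. The serum-analysis subcohort takes vaccinated patients with at least
one sample in `[vax1 − 183 d, vax1)` and at least one in `(vax1, vax1 +
42 d]`; "6 months" and "6 weeks" are fixed as 183 and 42 days and both
windows are config-overridable. When several pre-dose samples qualify, the
latest (closest to exposure) is the baseline. Patients with a grade ≥3
immune-related adverse event with onset inside the baseline window are
excluded after the qualifying count is taken, and both counts are reported
(36 qualifying / 35 analyzed under the defaults). Concentrations below the
assay's lower limit of detection are encoded as literal 0 in the files,
with a companion boolean column for provenance.

## Transform, programs, bootstrap

Concentrations are transformed as `c_t = log10(c + 1)`, which keeps
below-detection zeros at 0, and post-vaccination rows are normalized by
subtracting the patient's baseline `c_t` (a log10 fold change). Cytokine ×
cytokine Pearson correlation over those rows gives the distance `d = 1 − r
∈ [0, 2]`; correlation on fewer than 3 rows is refused, and zero-variance
cytokines are excluded from clustering with a warning record rather than
given an arbitrary ±1.

UPGMA is implemented directly: at each step the pair of clusters at minimal
distance merges, and the merged cluster's distance to any third cluster is
the size-weighted arithmetic mean of its children's distances. Among
equal-height candidate merges the pair with the leftmost original index
wins, making the dendrogram deterministic; the suite cross-checks heights
and flat cuts against an independent average-linkage reference on random
matrices. Programs are the connected components after removing all merges
with height above the cophenetic threshold (default 0.75), so a higher
threshold can only coarsen the partition.

Stability: each bootstrap replicate resamples the fold-change rows with
replacement at the original size (a patient-level block bootstrap is
available by switch, default off), recomputes correlation → distance →
UPGMA → flat cut, and increments a co-occurrence count per cytokine pair;
dividing by the replicate count (default 10,000) yields the co-clustering
probability matrix — symmetric, unit diagonal, entries in [0, 1]. A
cytokine with zero variance inside a replicate gets correlation 0 (distance
1) to all others for that replicate and is tallied in a diagnostics
counter; at the default threshold it stays a singleton for that replicate.

## Program inference and responders

A patient's program score averages the log10 fold changes over the
program's members and then over the patient's post-vaccination rows (one
value per patient; a "first post sample" alternative is selectable).
Induction is tested per program with a two-sided one-sample Wilcoxon
signed-rank against zero. Zeros are dropped before ranking (Pratt handling
available by flag); |values| get midranks under ties. Up to `exact_max_n =
25` effective observations the two-sided p is exact: the null distribution
of the positive-rank sum is built by dynamic programming over all 2^n sign
assignments conditional on the observed midranks (ranks are doubled so the
lattice stays integral — equivalent to full enumeration and exact even
under ties), and `p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Above that, a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. p-values are Benjamini–Hochberg adjusted across the
program family (`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1); Cohen's D is
mean/sd with the (n−1)-denominator sd and is refused at sd = 0.

Responders are patients whose geometric-mean fold change `10^score`
exceeds the threshold (default 1.5, strict); the proportion carries an
exact Clopper–Pearson interval (`Beta⁻¹(α/2; k, n−k+1)` /
`Beta⁻¹(1−α/2; k+1, n−k)`, with the k = 0 and k = n endpoints pinned to 0
and 1). A secondary listing returns patients at or above a higher fold cut
(default 1.7) in descending order; the comparison carries a 1e-9 tolerance
so values that round-trip through `10^log10(fc)` are not dropped at the
boundary. Report tables round percentages half-up to one decimal.

## Outcome analyses

Kaplan–Meier estimation delegates to lifelines (events precede censorings
at tied times). The log-rank machinery is computed in-package because the
hazard-ratio conventions need the O/E components: at each pooled event time
the hypergeometric expectation and variance accumulate into `χ² = (O_a −
E_a)²/V` with p from a 1-df chi-squared. The hazard ratio defaults to
`(O_a/E_a)/(O_b/E_b)` with CI `HR·exp(±1.96/√V)`; exactly when one group
has zero events it switches to the Mantel–Haenszel one-step estimate
`exp((O_a − E_a)/V)` with the same CI width, and the method used is
recorded in the result.

The landmark analysis takes a required calendar date (no default — the
packaged synthetic configuration uses 2021-05-17): the pre-landmark stratum
truncates everyone's follow-up at the landmark and compares ever- vs
never-vaccinated; the post-landmark stratum keeps patients alive at the
landmark with ICI start on or before it, measures time from the landmark,
and freezes vaccination status there (vaccinated only if dose 1 preceded
the landmark), so no immortal person-time is credited to vaccination.
Degenerate strata are flagged, not raised.

Adverse-event rates are events per patient-day with half-open interval
conventions `(vax1, vax1+28]` / `(vax1+28, end]`; the numerator counts the
first qualifying event per patient per interval by default (all-events by
switch). The propensity model is a maximum-likelihood logistic regression
(GLM/IRLS) of vaccination on three covariates (age, sex, and insurance or
dichotomized ECOG); coefficients diverging past |β| > 15 are reported as
perfect separation. Each unvaccinated patient is matched to the
nearest-propensity vaccinated patient with replacement, ties broken toward
the smallest patient id, and balance is reported as the standardized mean
difference per covariate before and after matching.

## Synthetic cohort generator

The generator emulates the study conditions: 64 vaccinated and 26
unvaccinated patients; dose 1 in early 2021 with dose 2 three to six weeks
later; a 36-patient serum subcohort with one qualifying baseline and 1–2
post-dose samples each, of which one patient carries a planted baseline
grade-3 immune-related arthritis and is excluded (35 analyzed).

Cytokine responses are planted through a latent-factor construction chosen
because its correlations are known in closed form. Each block `B` of the
plant spec has a per-patient activation `A ~ Bernoulli(responder_fraction)`
and, when active, log10 fold changes `f = μ_B + σ_B(√ρ_w·u_B +
√(1−ρ_w)·ε)` with `u_B` shared within the block and `ε` independent, so the
within-block correlation is exactly ρ_w; block factors share a global
component scaled to give the cross-block correlation ρ_c < ρ_w. The default
plant is two five-cytokine blocks — the CRS-hallmark set (IL-6, CXCL8,
IL-2, CCL2, sIL-1R; μ = 0.45, σ = 0.30, responder fraction 0.45, i.e. an
expected ~40% of patients above 1.5-fold) and a second mediator set (IL-18,
sIL-2RA, IFN-gamma, IL-10, IL-16; μ = 0.25, σ = 0.25, fraction 0.5) — with
ρ_w = 0.8, ρ_c = 0.05, inside a 26-cytokine panel whose remaining members
fluctuate independently (sd 0.12). Baseline log10 concentrations are
Gaussian around per-cytokine medians spanning ~3 to ~300 pg/ml.

True concentrations pass through the measurement stage the assay uses: 1:2
dilution, evaluation of a five-parameter logistic standard curve `y = d +
(a−d)/(1+(x/c)^b)^g` (vendor-style parameterization; defaults a = 45,
d = 28000, c = 120 pg/ml, b = 1.15, g = 0.9), inversion back to
concentration, flooring below the 1 pg/ml detection limit to 0, and
un-dilution. The forward/invert pair round-trips to 1e-9 relative
precision; the curve-fitting routine (least squares with data-driven
starting values) recovers noiseless parameters to well under 1%. Signal
noise is off by default so planted correlations are exact.

Adverse events are Poisson per follow-up period at spec rates (defaults
0.004 pre-vaccination, 0.012 in the 28 days after dose 1, 0.006 later,
0.015 for unvaccinated patients — ordered to mirror the observed pattern of
higher unvaccinated propensity and an early post-dose bump). Survival is
exponential from ICI start with baseline hazard 0.002/day and a vaccinated
log hazard ratio ln(0.21), administratively censored at 2022-03-01. All
randomness flows from one root seed through three named substreams (cohort
biology, assay, outcomes), so identical configuration and seed give
identical datasets.

What the generator does not emulate: time-varying vaccination exposure
(vaccination is a fixed patient attribute, so the planted hazard contrast
exists before the landmark too and the synthetic landmark analysis shows a
pre-landmark difference — the landmark logic itself is tested on
purpose-built piecewise-hazard cohorts); serum draw dates are not
constrained to precede death (forcing long survival for the serum subcohort
would bias the planted hazard ratio); no infection process, no
flow-cytometry bead events, no missing-data mechanisms. Passing tests on
this cohort demonstrate that the analysis recovers known planted structure
at the study's sample sizes, not that real serum panels are this clean.

## Problem sizes in the test and acceptance runs

The suite exercises the full 90-patient pipeline at the default 10,000
bootstrap replicates (a run takes a few seconds); the simulation-based
properties use 35-patient two-block cohorts at 1,000 replicates over 10–20
seeds, 200-seed survival simulations, and 100-seed matching checks, sizes
at which each Monte-Carlo band spans several standard errors. The
law-of-large-numbers check of adverse-event rates uses 2,000 patients at
the generator's default rates, where every period's expected event count
keeps the 10% band above two Monte-Carlo sigma.

## Known limitations

- The Wilcoxon normal approximation is used above n = 25 by default;
  exact computation is available at any n at exponential memory in the
  rank total, not the sample count, so it remains cheap well past 35.
- The log-rank hazard-ratio CI uses the log-rank variance; it is a
  large-sample interval and can be wide or unstable with very few events
  (the Mantel–Haenszel fallback covers the zero-event case only).
- Propensity matching is 1-nearest-neighbor with replacement; no caliper,
  no trimming, and balance can worsen for covariates that were nearly
  balanced to begin with.
- The multivariable Cox model is intentionally out of scope; the survival
  surface is the log-rank family plus the landmark analysis.
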