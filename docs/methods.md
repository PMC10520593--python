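# Methods

## The profiling model

`cognorm` quantifies how common *clinically meaningful* cognitive
deviations are inside diagnostic groups, instead of only comparing group
means.  Given a battery of m tests and a designated control group, every
raw score is first **oriented** so that larger always means better:
reaction-time and error scores are reversed as

    oriented = reversal_reference − raw,

where the reversal reference is a fixed per-test constant (an instrument
cap such as the 300 s discontinuation of a timed trail-making trial).  We
deliberately use a fixed constant rather than the observed sample maximum:
a sample-dependent reference would make an individual's score depend on
who else was recruited, whereas any constant shift cancels exactly in the
z-score, so the choice of constant is immaterial to every downstream
number (the affine-invariance property in the test suite).  The only
constraint is that the reference must not be below an observed raw score;
violating it is a validation error, not a silent clip.

Each oriented score is standardized against the control group:

    z = (oriented − mu_HC) / sigma_HC,

with mu_HC and sigma_HC the control mean and sample (n−1) SD computed on
all non-missing control observations for that test (pairwise-complete,
which maximizes normative precision).  A control group with fewer than
two observations or zero variance on a test cannot anchor the scale and
raises a degenerate-normative error.  No demographic adjustment is
applied: the control sample is the norm, exactly as in single-study
normative referencing, and the composite is comparable across all tests
precisely because every test is referenced to the same controls.

The **composite** is the arithmetic mean of all m z-scores and is defined
only for participants with a complete battery.  Band thresholds are
applied to the raw composite; because it averages m correlated z-scores
its control-group SD is below 1 (≈ sqrt((1 + (m−1)ρ)/m) under an
exchangeable correlation ρ), so composite prevalence is conservative
relative to per-test prevalence.  Re-standardizing the composite is a
one-liner for callers who want it, but the default mirrors the
conventional presentation of composite deviation rates alongside per-test
rates.

## Severity bands and multi-test criteria

z-scores are partitioned into five bands: severely impaired (z < −2),
moderately impaired (−2 ≤ z < −1), average (−1 ≤ z ≤ 1), above average
(1 < z ≤ 2), extremely high (z > 2).  Ties at ±1 fall in the average band
and ties at ±2 in the moderate bands — the ">2 SD" outer bands are strict.
Ties are measure-zero events but the convention must be deterministic.

A **multi-test criterion** asks whether a participant qualifies on at
least k tests (default k = 2) at a level L (1 or 2 control SDs).  The
default counting mode is *cumulative*: impairment at level L means
z ≤ −L, so a severe deviation also counts as moderate-or-worse.  This
makes prevalence nested (non-increasing in both L and k), which is the
reading consistent with reporting "moderately impaired" and "severely
impaired" percentages where the former dominate the latter.  An exclusive
per-band mode is provided for sensitivity analysis.

The default population for multi-test and mean-count analyses is the
**complete-case** set (no missing test anywhere in the battery), the same
denominator that defines the composite; a per-test-available option
counts qualifications over whatever tests a participant has.  Every
output table carries the denominator each cell was computed on, and an
empty cell is reported as undefined, never as 0%.

## Group statistics

* **Odds ratio** (any impairment, z ≤ −1, clinical vs control):
  OR = ad/bc with the log-scale CI exp(ln OR ± 1.96·sqrt(1/a+1/b+1/c+1/d))
  (Altman's construction).  A zero cell triggers the Haldane–Anscombe
  correction (0.5 added to every cell) and is flagged in the result.
* **Chi-square**: Pearson statistic on group × qualifies tables without
  continuity correction (the conventional default for r×c tables);
  pairwise post-hocs multiply p by the number of pairwise comparisons
  within one test-and-level cell (6 for four groups), capped at 1.
* **ANOVA** on the number of qualifying tests: classical between/within
  decomposition; post-hocs are either Bonferroni pooled-variance t tests
  or Tamhane T2 — Welch t with Welch–Satterthwaite df and a Sidak-type
  adjustment (the standard meaning of "Tamhane" in statistics packages),
  appropriate because count variances differ strongly across groups.
  Pairwise mean differences are reported with CIs at the adjusted level.

## The synthetic cohort generator

No individual-level data are distributed, so the pipeline is exercised on
synthetic cohorts with the statistical structure the analysis assumes.
For participant i in group g, the oriented standardized score on test t is

    s_it = sqrt(ρ)·u_i + sqrt(1−ρ)·e_it − δ[g,t],

with u_i, e_it independent standard normals.  The single factor u_i
induces an exchangeable inter-test correlation ρ — one parameter, chosen
over a full m×m matrix because it is both realistic enough for prevalence
(which depends mainly on the average correlation) and analytically
tractable.  Deficit shifts δ are specified in control-SD units so they
are scale-free.  Oriented raw scores are mu_t + sigma_t·s_it; reversed
tests are stored as instrument-style raw scores.  Missingness is MCAR per
test, plus an optional *site block*: a fraction of participants belongs
to a site that administered an alternative instrument for one test, so
that test is missing for the entire site.

The packaged default emulates a four-group early-psychosis/depression
cohort: HC 454, CHR 270, ROD 267, ROP 295 (total 1286); ρ = 0.4 (a
typical average inter-test correlation for a broad cognitive battery);
per-test MCAR rates between 0.7% and 5.4%; and a site block covering
12.8% of the cohort on the list-learning test (that test's only source of
missingness, so its total missingness matches the blocked share).  Group
base shifts are HC 0, ROD 0.35, CHR 0.55, ROP 1.00 control-SDs, chosen
once by inverting the analytic exceedance probability so that the
≥2-test moderate-impairment prevalence of the groups lands near
62% / 71% / 88% with the expected severity ordering; per-test multipliers
(1.25 on the working-memory, processing-speed and verbal-learning tests,
0.75 elsewhere, mean 1) concentrate deficits where clinical impairment is
typically most prevalent.  These shifts are illustrative of the published
severity ordering, not estimates of any real effect sizes.

### Analytic oracle

Under the single-factor model the probability of qualifying on at least
k of m tests at level L has the closed 1-D integral form

    P = ∫ φ(u) · P[Binomial(m, p(u)) ≥ k] du,
    p(u) = Φ((−L + δ − sqrt(ρ)u) / sqrt(1−ρ)),

evaluated by adaptive Gauss–Kronrod quadrature (`scipy.integrate.quad`,
absolute target 1e-10, with the integrator's error estimate checked
against a 1e-7 tolerance).  Adaptive quadrature was chosen over a
fixed-node Gauss–Hermite rule because the integrand approaches a step
function as ρ → 1 and fixed rules fail there, while the adaptive rule
stays accurate up to ρ = 0.9999 (verified against the ρ → 1 limit
Φ(−L+δ)).  At ρ = 0 the expression collapses to a binomial tail with
p = Φ(−L+δ), which is asserted exactly.  This oracle is independent of
the pipeline (it never touches cohort data) and is what the
parameter-recovery tests compare pipeline prevalence against.

## What the synthetic data do and do not show

The generator reproduces: group-specific severity shifts, a realistic
inter-test correlation, heterogeneous missingness including a structural
site gap, and instrument-style raw scales with reversed scoring.  It does
not reproduce: non-Gaussian score distributions (floor/ceiling effects,
skewed reaction times), demographic confounding of the norms (age/sex/
education gradients), site effects on observed scores, or any
domain-specific correlation structure beyond exchangeability.  Passing
tests therefore demonstrate that the *pipeline* computes the intended
quantities correctly under the assumed data-generating process — not that
real cohorts satisfy those assumptions.

## Numerical and reporting choices

* Percentages are stored at full precision in the tidy tables and
  rounded to one decimal only at render time; rounding inside the tables
  can push the five band percentages' sum outside 100 ± 0.1.
* Rendered statistics use three decimals, p-values three decimals with a
  "<0.001" floor.
* Monte-Carlo checks in the test suite use 3-standard-error tolerances
  with frozen seeds.  The parameter-recovery comparison uses group sizes
  of 1500 (roughly five times the fixture's clinical groups), where the
  binomial standard error dominates the additional noise from estimating
  the normative mean/SD on a finite control sample.
* The ordering check runs 20 generated cohorts at the fixture's group
  sizes and requires the impairment ordering (ROP > CHR > ROD > HC) and
  the clinical strength ordering (ROD > CHR > ROP) in at least 19.
* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical config + seed reproduces cohorts
  and downstream CSVs byte-identically.

## Known limitations

* The composite is not re-standardized (see above); its band prevalence
  is systematically conservative.
* Tamhane T2 is implemented via the Sidak-adjusted Welch t; exact
  simultaneous coverage of the T2 procedure's multivariate-t critical
  values is approximated by the Sidak level, which is the common software
  interpretation and is slightly conservative.
* The chi-square post-hoc family is the narrowest defensible one (the six
  pairwise comparisons within one test-and-level cell); broader families
  require an explicit multiplicity argument from the caller.
* `band_exclusive` counting is defined only for the canonical levels
  1 and 2.
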