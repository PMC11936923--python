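# Methods

## Counting model

All disproportionality statistics are computed over *(deduplicated report,
distinct preferred term)* records, not over cases.  A report listing three
distinct PTs contributes three records, so a drug's record total exceeds
its case total (by a factor around 2.1 in typical ophthalmology cohorts).
This unit is what makes SOC-level shares internally consistent: a SOC's
count is the number of its mapped records among the drug's records, with
no per-report collapse when several PTs of one report share a SOC.  The
alternative (collapsing to one count per report per SOC) is defensible but
breaks the additivity `Σ_PT a = drug record total` that the pipeline's
manifest accounting relies on.

Deduplication follows the FDA-recommended rule: per CASEID keep the
maximal FDA_DT, ties broken by the highest PRIMARYID.  Primaryid order is
numeric when ids are digit strings (implemented by zero-padding, so a
single lexicographic sort handles mixed id styles deterministically).
Reports are attributed to a drug through its *primary suspect* rows only;
name matching upper-cases and collapses whitespace, and matches either the
free-text `drugname` or the `prod_ai` ingredient field (a report whose
drugname matches is kept even if `prod_ai` names something else — FAERS
free text is too noisy to treat a conflict as disqualifying).

## The four statistics, as printed

The package reproduces the formulas as this family of FAERS scans prints
them (see the table in the README), which implies two deliberate
departures from the methodological literature:

* **"EBGM" is the raw relative reporting ratio** `aN/((a+c)(a+b))` with a
  lognormal Wald interval, not the posterior geometric mean of a fitted
  gamma–Poisson mixture.  True MGPS shrinkage requires hyperparameter
  estimation over the whole drug–event matrix and is deliberately out of
  scope; the nomenclature is kept because the thresholds (EBGM05 > 2) are
  defined against this quantity in the tables being mirrored.  A
  consequence worth knowing: IC = log₂(EBGM) holds *exactly* here, and the
  test suite asserts it as an identity.
* **IC025 defaults to a fixed offset**: IC025 = IC − 1.67.  Published
  tables of this form show a count-independent gap of 1.66–1.67 between IC
  and IC025 on every row, which is only consistent with a constant
  2√V(IC); the default reproduces that behaviour.  A principled
  delta-method variance, `V(IC) = (1/ln2)²(1/a − 1/(a+b) + 1/(a+c) − 1/N)`,
  is available via `ic_mode="delta"` and is the better choice for new
  analyses (it tightens for large `a`, so it flags moderate signals the
  fixed offset misses).

χ² is Pearson's statistic without continuity correction, matching the
printed formula.  When any of b, c, d is zero (possible only for very rare
backgrounds; the n ≥ 3 rules make it rarer still), the Haldane–Anscombe
correction adds 0.5 to all four cells before computing statistics and CIs,
and the result carries a `zero_cell_corrected` flag.  `a = 0` yields a
not-computable result with all flags false rather than an error, keeping
bulk scans total.

`reconstruct_counts` inverts the published presentation: given a printed
row's `a`, the drug record total, the ROR and the relative reporting
ratio, the missing cells follow from `c/d = (a/b)/ROR` and a linear solve
of the ratio equation for `d`.  The exact null (ROR = EBGM = 1) leaves the
scale free — a one-parameter family — and is reported as degenerate.

## Demographics

Age units convert to years via DEC×10, YR×1, MON/12, WK/52.18, DY/365.25,
HR/8766; an absent unit is read as years.  Age bins partition as [0,18),
[18,65), [65,85], (85,∞) — the printed bin labels "18–65" and "65–85"
overlap, and closing the interval at 85 is the choice that keeps the
partition exhaustive while matching the convention that "65–85" includes
both endpoints of retirement-age cohorts.  Reporter occupations map
MD→Physician, CN→Consumer, PH→Pharmacist, and both HP and OT into "Health
professionals" (descriptive tables in this literature print only four
named categories plus missing).  Percentages are rounded half-up to one
decimal; some published tables appear to truncate instead, so exact
percentage matching is only asserted where rounding and truncation agree.

## Time to onset

TTO = event onset date (DEMO) minus the *earliest full-precision* therapy
start (THER) among the target drug's rows.  Partial dates (month or year
precision) and negative intervals are excluded with per-reason counts;
zero-day intervals are remapped to 0.5 days because Weibull support is
strictly positive.  The Weibull MLE solves the profile score equation for
the shape by bracketed root-finding (xtol 1e-12; the score is rescaled by
`t_max` to avoid overflow), with the scale in closed form.  95% CIs use
the observed information of the log-parameterized likelihood
(central-difference Hessian, step 1e-4), so bounds are always positive.
Failure classification is read from the shape CI: upper < 1 → early,
lower > 1 → wear-out, else random; exactly one class always applies.
Censoring and competing risks are not modelled — only observed onsets
enter, as in the scans being reproduced.

## Synthetic data

The generator's job is to make every pipeline stage testable against known
truth, so the reaction model is chosen for tractability: for a report on
drug *g*, each catalog PT *i* is included independently with probability
`π_i = m_g·w_i/Σw` where `w_i` multiplies a background frequency by the
configured relative risk, and empty reports are rejected.  Because a
report containing PT *i* is never empty, `E[a_i] = n·π_i/(1−P0)` with
`P0 = Π(1−π_j)` is exact, and `expected_tables` evaluates it; the
intensity `m_g` is solved per drug so the *realized* mean number of
distinct PTs per report hits the configured target (default 2.08).  A
fixed-record-total multinomial without replacement would be marginally
more FAERS-like but has no closed-form inclusion probability; exactness of
the oracle won.

Defaults emulate a young single-drug cohort: 2,735 target cases, 20%
of cases re-filed as 2–3 follow-up versions with FDA_DT shifted +1..90
days, onset intervals from Weibull(scale 133.72 d, shape 0.80) with 16.5%
of reports carrying full dates, sex/age/country/reporter mixes with
realistic missingness (42% missing age, 25% missing sex), and a bundled
60-PT / 8-SOC mini-ontology whose labels are invented (MedDRA itself is
licensed).  Comparator and pooled-background cohort sizes (6,000 / 5,000 /
15,000) are synthetic choices giving the target drug a realistically small
share of the database.  What the generator does *not* emulate: co-reporting
correlation between PTs, drug–drug interaction structure, secular reporting
trends, or informative missingness — so passing recovery tests demonstrate
correctness of the computation, not robustness to those real-data features.

## Validation experiment sizes

The recovery experiments are sized for stable verdicts at interactive
runtimes: end-to-end recovery uses 50 replicates of a 500-case target
against an 8,000-case background with five injected signals at relative
risks 14–25 (chosen by analytic power so the weakest signal clears the
binding IC025 constraint by ≈4 standard deviations of its expected count);
Weibull recovery uses 200 replicates at n = 450, the onset sample size the
generator's defaults imply.  Monte-Carlo agreement with the expectation
oracle is asserted within 3 standard errors over 40 replicates.

## Known limitations

* No multiple-comparison control — none of the four thresholds adjusts for
  scanning thousands of terms; the four-way conjunction is the only
  specificity device, as in the mirrored methodology.
* The fixed-offset IC025 under-flags strong signals with very large `a`
  relative to a genuine BCPNN posterior interval.
* Legacy (pre-2012Q4) AERS layouts and XML exports are unsupported.
* The drug comparison contrasts each drug against the whole remaining
  background, not pairwise head-to-head tables.
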