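# Methods

## Study design

The package implements a case/non-case (disproportionality) analysis of a
spontaneous-report corpus. The analysis unit is the *deduplicated report*:
quarterly FAERS releases re-publish follow-up versions of earlier cases, so
each `caseid` is collapsed to the version with the latest FDA receipt date
before anything is counted; ties are broken by the larger numeric
`primaryid`, which matches the FDA convention that version numbers increase.
The deduplication key is the case, not the (case, drug) pair.

The target cohort contains every deduplicated case with at least one DRUG
row whose name (or active ingredient) matches the target name list — by
default the generic and trade names `niraparib`/`zejula` — with role code
`PS` (primary suspect). Matching trims, case-folds and collapses whitespace
and then requires a word-boundary substring, so salt forms
("NIRAPARIB TOSYLATE MONOHYDRATE") match but accidental in-word substrings
do not. All remaining cases are the background. Mentions attached to
superseded report versions never count.

## Dates and ages

FAERS dates are digit strings of 8, 6 or 4 characters; the parser keeps the
precision explicit (day / month / year / absent) and maps calendar-invalid
strings to absent. Partial dates participate in reporting-year tabulation but
are excluded from any day-resolution arithmetic. Ages are converted to years
by unit code (DEC ×10, MON ÷12, WK ÷52.14, DY ÷365.25); a missing unit with a
value in [0, 122] is taken as years, anything else is unknown. The age bands
are `<40`, `40–50` (inclusive at both ends) and `>50` (strictly greater).

## Contingency tables

One 2×2 table per term, with the report as counting unit: a report that
lists the same PT twice counts once, and at SOC level a report counts once
per SOC however many of its PTs map there. This convention was fixed because
back-solving published PT rows (below) is numerically consistent with the
cohort report count as a+b and inconsistent with the event count. The PT→SOC
mapping is user-supplied (MedDRA is licensed and cannot be bundled); a small
demo mapping covering the test vocabulary ships with the package, and PTs
missing from the mapping are routed to an `Unmapped` pseudo-SOC rather than
dropped.

## Estimators

With margins `N = a+b+c+d` and expectation `E = (a+b)(a+c)/N`:

* **ROR** `(a·d)/(b·c)`; 95% CI `exp(ln ROR ± 1.96·se)`,
  `se = √(1/a+1/b+1/c+1/d)`. Criterion: `a ≥ 3` and CI low strictly `> 1`.
* **PRR** `[a/(a+b)]/[c/(c+d)]` with the uncorrected Pearson χ²
  `N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]`. Yates' continuity correction is not
  applied: on tables reconstructed from published rows the uncorrected
  statistic is the closer one. Criterion: `a ≥ 3`, `PRR ≥ 2`, `χ² ≥ 4`.
* **IC** `log2(a/E)`. The default lower bound is delta-method:
  `IC025 = IC − 1.96·√(1/a − 1/(a+b) − 1/(a+c) + 1/N)/ln 2`. The margin
  corrections assume `a` is small relative to the margins; if the expression
  goes non-positive (possible in small corpora where the target drug covers a
  large corpus fraction) the leading `1/a` term is used alone. A
  gamma-posterior variant (`variant="gamma"`, in the style of the shrinkage
  observed/expected bound used at the Uppsala Monitoring Centre) is available
  behind the same interface. Criterion: `IC025 > 0`.
* **EBGM**. `simplified` mode reports the raw relative ratio `a/E`
  (identically `2^IC`) with `EBGM05 = exp(ln EBGM − z·se)`; `z` defaults to
  1.645 (one-sided 95%), with 1.96 configurable — on reconstructed published
  rows the printed EBGM05/EBGM ratio matches the 1.96 convention, but 1.645
  is the common literature default, so both are exposed. `shrinkage` mode
  fits DuMouchel's two-component gamma-Poisson mixture by maximum marginal
  likelihood over the whole table collection (Nelder–Mead from the
  conventional (0.2, 0.1, 2.0, 4.0, 1/3) start) and reports the posterior
  geometric mean and 5th percentile. The fit refuses collections under 50
  tables, where the five hyperparameters are not identifiable. Criterion:
  `EBGM05 > 2`.

When any cell is zero the estimators return NaN (an undefined-signal marker
that never flags) unless the Haldane–Anscombe +0.5 correction is enabled; it
is off by default because the `a ≥ 3` gate dominates at PT level.

Numerical notes: `EBGM05 ≤ EBGM` holds identically in simplified mode. In
shrinkage mode the posterior is a two-component mixture, and near the null a
low-mass component below the bulk can push the geometric mean slightly below
the 5th percentile; the percentile is reported as computed rather than
clamped. Published IC and EBGM columns of this study design are typically
produced by unstated shrinkage variants and are not mutually consistent at
two printed decimals, so they are validated as approximate invariants
(±0.03 on IC for large-count reconstructed rows) rather than as exact
targets; PRR, which is pinned by the Wald relations, is validated exactly.

## Comparator reconstruction

Published signal tables print, per term, the target case count `a`, cohort
size `n`, and ROR with its 95% CI. With `b = n − a` fixed, the two Wald
relations

```
ROR = (a·d)/(b·c)
ln(CI_high/CI_low)/(2·1.96) = √(1/a + 1/b + 1/c + 1/d)
```

determine `c` and `d` in closed form: with `r = s² − 1/a − 1/b` (s the
log-scale half-width), `c = (1 + a/(ROR·b))/r` and `d = ROR·b·c/a`.
Reconstruction is infeasible (`r ≤ 0`) when the printed CI, rounded to two
decimals, falls below the `1/a + 1/b` width floor — which genuinely occurs
for the largest published counts and is raised as an explicit error. Cells
are returned as positive reals; printed 2-decimal inputs cannot pin
integers, so a nearest-integer variant is a separate option.

## Time-to-onset

Onset is `event_dt − earliest day-precision start_dt` of the matched
primary-suspect drug's THER rows, in days. Reports are excluded — each under
exactly one reason, checked in a fixed order (no therapy row; no
day-precision start; no day-precision event date; event before start) — and
the exclusion tallies plus included records always sum to the cohort size.
Summaries use linear-interpolation (type-7) quartiles, a convention fixed
here for reproducibility, and 30-day bins `0–30, 31–60, …, 331–360, >360`
(days are integers; each bin is right-closed at the multiple of 30).

## Synthetic corpus generator

The generator emits the six FAERS-dialect tables for a corpus matching the
independence-null structure the 2×2 analysis assumes: each report samples a
drug set from marginal probabilities (reports with no drug get one drawn
proportionally to the marginals), then samples PT mentions independently
with probability `base_rate(pt) × rr(drug, pt)` capped at 1, taking the
maximum boost over the drugs present. Reports whose draws all come up empty
receive a designated filler term ("Drug ineffective") so every report has at
least one event row while the configured vocabulary rates stay exactly
Bernoulli; only the filler's empirical rate exceeds its configured one, and
it is excluded from rate-convergence guarantees.

Defaults follow the composition reported for a real niraparib cohort where
one is stated: sex mix 78.55% F / 1.79% M, 77.43% consumer reporters, 87%
US reports, receipt years 2017–2021, ovarian cancer as the dominant
indication, 18-day median (exponential) onset with ~37% of reports carrying
a usable onset date, and the published serious-outcome rates. Values the
study design does not pin — drug marginals (target 5%), the 30-term PT
vocabulary with base rates between 0.0125 and 0.26, a 5% duplicate-version
rate, a 1% reversed-date error rate — are fixed at desk-scale values chosen
once to make cohorts of a few hundred to a few thousand reports with
non-degenerate cells.

Duplicated cases appear under two primaryids, the stale version with an
earlier receipt date and smaller version suffix, so deduplication must
recover exactly the configured case count. A single seeded NumPy generator
with a fixed call order drives all draws: identical seed and config give
byte-identical files. The generator records exact per-PT report counts as
ground truth; contingency cells are tested against this bookkeeping, not
against expectations.

What the generator does **not** emulate: PT–PT correlation within a report
(the implicit null of 2×2 disproportionality is independence), drug-name
misspellings, free-text narratives, reporting-rate drift over calendar time,
and demographic confounding of event rates. Passing tests therefore show
that the pipeline recovers planted marginal associations under the model's
own assumptions — not that those assumptions hold in real spontaneous data.

## Validation strategy

* Estimator oracle equivalence: 1,000 random small tables against
  independently coded references (statsmodels' 2×2 odds/risk ratios, scipy's
  uncorrected χ², direct closed forms) to 12 significant digits.
* Published-row reconstruction: five PT rows of a published niraparib table
  reproduce the printed PRR at two decimals from (a, n, ROR, CI) alone;
  a printed row whose rounded CI is narrower than the Wald floor raises the
  infeasibility error, as it must.
* Null calibration: on a seeded 100,000-report corpus with all true RR = 1
  (200 PTs), the all-four flag rate does not exceed any single criterion's
  rate and the ROR criterion false-flags ≤ 5% of terms with E ≥ 5.
* Recovery: a planted RR = 10 with expected count ≥ 20 is flagged by all
  four criteria in ≥ 95 of 100 seeded replicates (n = 3,000 reports each, a
  desk-scale size chosen so the full sweep stays fast).
* Golden files: the deterministic 200-report regression fixture's outputs
  are frozen after a hand-audited first run and compared byte-for-byte. At
  that scale no term passes all four criteria (the background cells are too
  small for EBGM05 > 2), which is itself the expected behaviour.

## Known limitations

* No multiple-testing correction is applied, matching standard practice for
  this design; at FAERS scale thousands of PTs are screened and individual
  flags are hypotheses, not confirmed risks.
* The expected/unexpected classification is exact-term matching against a
  user-supplied label list; a real labeledness review maps label language to
  MedDRA terms, which is out of scope.
* Country codes are reported verbatim; no harmonization is attempted.
* Legacy (pre-2012) AERS schemas and the XML dialect are unsupported.
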