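# pvsignal

Disproportionality signal detection for spontaneous adverse-event report
databases in the FAERS quarterly-file dialect.

Spontaneous-report systems such as the FDA Adverse Event Reporting System
(FAERS) collect voluntary reports of suspected drug adverse events. Because
reporting is uncontrolled, drug safety signals are screened by
*disproportionality analysis*: for a target drug and each MedDRA Preferred
Term (PT) or System Organ Class (SOC), the corpus is reduced to a 2×2 table

|                | term present | term absent |
|----------------|--------------|-------------|
| target drug    | a            | b           |
| all other drugs| c            | d           |

and the observed reporting rate is compared to the background with four
standard statistics (N = a+b+c+d, E = (a+b)(a+c)/N):

* **ROR** = (a·d)/(b·c), with Wald 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
  signal when a ≥ 3 and the CI lower bound > 1.
* **PRR** = [a/(a+b)] / [c/(c+d)], with the uncorrected Pearson χ²;
  signal when a ≥ 3, PRR ≥ 2 and χ² ≥ 4.
* **IC** = log₂(a/E) (BCPNN information component), with a lower bound IC025;
  signal when IC025 > 0.
* **EBGM**: the empirical-Bayes geometric mean of a/E — either the raw
  relative ratio (= 2^IC) with a Wald-style lower bound, or DuMouchel's
  two-component gamma-Poisson shrinkage fitted across all tables; signal when
  EBGM05 > 2.

A term is an **all-four signal** when every criterion is met, and
**unexpected** when it is absent from a user-supplied product-label term list.

The package implements the full pipeline for this kind of study:

* `pvsignal.faers_io` — parsing of the `$`-delimited DEMO/DRUG/REAC/OUTC/
  INDI/THER tables, partial-date handling, and case-version deduplication
  (latest FDA receipt date per `caseid` wins).
* `pvsignal.cohort` — primary-suspect cohort construction by generic/trade
  name matching, descriptive characteristics, and the consumer-exclusion
  sensitivity variant.
* `pvsignal.contingency` — report-level 2×2 tables at PT and SOC level, plus
  a *comparator-reconstruction oracle* that back-solves (c, d) from a
  published (a, n, ROR, CI) row via the Wald relations, so published signal
  tables can be checked without the underlying corpus.
* `pvsignal.signal_stats` — the four estimators, criteria and label
  classification.
* `pvsignal.onset` — time-to-onset (event date − therapy start date) with
  exclusion accounting, median/IQR and 30-day bins.
* `pvsignal.synthetic` — a seeded generator of FAERS-dialect corpora with
  known relative risks, demographic mixes, injected duplicate case versions
  and onset distributions, for end-to-end validation.
* `pvsignal.pipeline` / the `pvsignal` CLI — orchestration and CSV reports.

## Worked example

Simulate a 20,000-report corpus in which the target drug truly increases
thrombocytopenia reporting 8-fold and photosensitivity reaction 10-fold,
then run the pipeline:

```python
from pvsignal import SimulationConfig, simulate_corpus, RunConfig, run_pipeline

config = SimulationConfig(
    n_reports=20_000,
    seed=7,
    rr={
        ("NIRAPARIB", "Thrombocytopenia"): 8.0,
        ("NIRAPARIB", "Photosensitivity reaction"): 10.0,
    },
)
simulate_corpus(config).write("corpus/")
result = run_pipeline(RunConfig(input_dir="corpus/", output_dir="out/"))

print(result.pt_signals.query("all_four").round(2).to_string(index=False))
```

which prints (abridged):

```
                     term   a   ror  ror_low  prr    chi2  ic025  ebgm05  all_four  expected
         Thrombocytopenia 308 12.16    10.40 9.25 1496.40   2.54    5.46      True      True
Photosensitivity reaction 154 11.08     8.98 9.77  766.68   2.53    5.39      True     False
```

Both planted associations — and only those — pass all four criteria, with
estimates close to the planted relative risks (shrunk slightly toward the
margins). Thrombocytopenia is on the demo label list (`expected`);
photosensitivity reaction is flagged as an unexpected signal. The onset stage
recovers the configured 18-day median:

```
onset: n=416, median=18 d, IQR=(7, 34) d
```

The run directory contains `characteristics.csv`, `pt_signals.csv` (+
`pt_signals_full.csv` at full precision), `pt_signals_all_four.csv`,
`soc_signals.csv`, `onset_summary.csv`, `onset_bins.csv` and a `run_log.txt`
with the report-count funnel. The same run is available from the shell:

```sh
pvsignal simulate --out-dir corpus/ --n-reports 20000 --seed 7
pvsignal run --input-dir corpus/ --output-dir out/ --exclude-consumers
```

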