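# Methods

`faersig` implements a complete disproportionality study of oral bowel
cleansers (bisacodyl, polyethylene glycol [PEG], oral sulfate solutions
[OSS]) and ischemic colitis on FAERS-style spontaneous adverse-event
reports, together with a ground-truth synthetic report generator so that
every stage is verifiable without the multi-gigabyte FAERS download.

## Data model and ingestion

FAERS quarters ship as `$`-delimited ASCII files (DEMO/DRUG/REAC/OUTC/
THER/INDI) with a header row. The parser normalizes headers against a
per-era registry — the legacy (pre-2012Q4) `ISR`/`CASE`/`GNDR_COD` names
map onto `primaryid`/`caseid`/`sex` — and fails loudly, naming the file
and the era it expected, when mandatory columns are missing; silent column
misalignment would corrupt every downstream count. Two dialect quirks are
handled explicitly: a spurious trailing delimiter is stripped, and rows
broken by embedded newlines are rejoined when the combined field count
matches the header, otherwise skipped. Every skip, rejoin and orphan child
row (a DRUG/REAC/OUTC row with no DEMO parent) lands in a parse log; no
row is ever dropped silently. Orphans are excluded from analysis.

All bundle cells are plain strings with `""` for missing, which makes the
write→parse round trip an exact identity (a tested invariant). Numeric
views are derived on demand: ages normalize to years (YR×1, DEC×10,
MON÷12, WK÷52.18, DY÷365.25, HR÷8766), weights to kg (LBS×0.4536);
unparseable values become missing rather than errors.

## Deduplication

Cases are resubmitted to FAERS; within each `CASEID` the pipeline keeps
the submission maximizing `(FDA_DT, numeric PRIMARYID)` — most recent
receipt date first, ties broken by the numerically (not lexicographically)
highest `PRIMARYID`, and a missing `FDA_DT` never preferred. The rule is
idempotent and is tested against a brute-force group-by-maximum oracle on
random instances.

## Cohort construction

Drug-group assignment is dictionary-driven: case-insensitive substring
matching of brand + generic name fragments over a report's drugs,
restricted by default to the primary-suspect (PS) role. Matches imply
cleanser *components*, and a precedence rule resolves components to one
group per report: any bisacodyl component ⇒ bisacodyl (combination
regimens count as bisacodyl); else PEG without OSS ⇒ PEG; else OSS without
PEG ⇒ OSS. A PEG+OSS combination without bisacodyl falls outside both
group definitions and is excluded with a log entry. Sodium-phosphate
regimens are recognized and tagged but never grouped. The shipped
dictionaries are editable YAML; precedence is independent of drug-row
order (tested by permutation).

The target event is a flat MedDRA preferred-term list (ischemic-colitis
spelling variants) under the gastrointestinal-disorders SOC (10017947);
matching is case- and whitespace-insensitive over any REAC row
(configurable to first-listed). The calendar year for trend series comes
from the receipt date (always present); the season from the event date
when present, else the receipt date, with a source flag — the choice of
date field is not dictated by the study design, so both are recorded.

## Disproportionality statistics

Each group (and the pooled class) is tabulated against the rest of the
database in a 2×2 report-count table (a = group & event, b = group &
other events, c = other drugs & event, d = neither; every deduplicated
report counted once). Four statistics are computed:

* **ROR** = (a·d)/(b·c), CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
  signal if a ≥ 3 and the lower bound exceeds 1.
* **PRR** = [a/(a+b)]/[c/(c+d)],
  CI = exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d))); same criterion.
* **BCPNN information component** IC = log₂[aN/((a+b)(a+c))] with the
  closed-form posterior moments of the Bayesian confidence propagation
  neural network under priors α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1 and
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) (prior dependence neutral at the
  observed margins); IC025 = E(IC) − 1.96·√V(IC). Bands: `-` (≤ 0), `+`
  (≤ 1.5), `++` (≤ 3), `+++` (> 3).
* **EBGM** as the observed/expected reporting ratio aN/((a+b)(a+c)) with
  EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)); signal if EBGM05 > 2
  and a > 0. Note this follows the source methodology as published: it is
  a relative reporting ratio with a one-sided Wald bound, **not** a full
  multi-item gamma-Poisson shrinkage fit, and will exceed true MGPS
  estimates at small counts.

Zero cells: a = 0 leaves the frequentist estimates undefined and can never
signal; when a > 0 and any of b, c, d is 0, the Haldane–Anscombe +0.5
correction is applied to all four cells for ROR/PRR/EBGM and flagged
(`correction_applied`). BCPNN needs no correction — its priors regularize
empty cells — so it is computed on the raw table.

A per-PT profile ranks a group's preferred terms by case frequency and
retains the top ⌈10%·(distinct PTs)⌉, each with its own 2×2 ROR against
all other drugs (ties broken alphabetically for determinism).

All four statistics agree with an independently coded arithmetic oracle to
relative error ≤ 1e-9 on 1,000 random tables. Note that IC and EBGM are
*not* strictly monotone in a on arbitrary tables (incrementing a also
moves N and both margins; (1,1,1,6)→(2,1,1,6) decreases IC); strict
monotonicity holds — and is property-tested — in the rare-event regime
(b, c ≥ 2a, d ≥ 4(a+b+c)) that spontaneous-report tables occupy.

## Descriptive and comparative analyses

* **Severity roll-up**: one category per case, worst first: Death >
  Life-threatening > Disability > Hospitalization > Required intervention >
  Other serious; congenital anomaly (CA) folds into Other serious; no OUTC
  rows ⇒ Missing. The ranking is the conventional seriousness ordering
  (the source does not state one) and reproduces one-category-per-case
  accounting. Category counts always sum to the case count.
* **Demographics**: mean ± SD (SD undefined for n = 1) and type-7
  linear-interpolation quantiles — the convention that yields fractional
  quartiles such as 56.75 from integer ages; bins <18 / 18–64.9 / 65–85 /
  >85 years and <50 / 50–100 / >100 kg; missing counted explicitly and
  percentages taken over all cases.
* **Trends**: per-year reporting proportion = target-event cases / all
  reports with the group drug as primary suspect received that year; the
  headline figure is the median over years with ≥ 1 group report. Seasons
  follow the meteorological mapping (Mar–May spring, Jun–Aug summer,
  Sep–Nov autumn, Dec–Feb winter; missing/invalid dates are `unknown`
  and logged).
* **Exact tests**: the 2×2 Fisher test uses the point-probability
  two-sided definition — the sum of hypergeometric probabilities of all
  margin-fixed tables whose point probability does not exceed the observed
  (relative slack 1e-12). This is stated explicitly because mid-p or
  doubling variants change third decimals. The r×c generalization
  (Freeman–Halton) enumerates all margin-fixed tables exactly (guarded at
  10⁷ tables) with a seeded permutation Monte-Carlo fallback; both are
  tested against exact-Fraction enumeration oracles. Chi-square is Pearson
  without continuity correction.
* **Concomitant medications**: each reported name maps to its first
  matching Table-style category (cardiovascular, gastrointestinal,
  antibiotics, analgesics, antiallergics, antidepressants, hormonal,
  vitamins/minerals, urological, others), falling back to "Unknown or
  Unclassified"; percentages are over medications, not cases.
* **Logistic regression**: maximum-likelihood fit (statsmodels) with Wald
  95% intervals exp(β ± 1.96·se), dummy coding against explicit reference
  levels, complete-case analysis on the included covariates (the source is
  silent on missing-data handling; with ~25% missing age this choice
  matters and is therefore explicit). Non-convergence or (quasi-)complete
  separation raises an error — never silent estimates. The facility is
  validated by the closed-form 2×2 odds ratio and a null-simulation CI
  coverage check; the published regression tables themselves derive from
  the full external corpus and are out of numeric-reproduction scope.

## Synthetic corpus generator

The generator emulates the features of real spontaneous-report data that
the pipeline must survive, with every parameter in a validated config:

* **Planted associations**: for a report whose PS drug belongs to group g
  with planted multiplier r, the event probability is odds_b·r/(1+odds_b·r)
  where odds_b are the baseline odds — so the generating odds ratio equals
  r *exactly by construction*, and log-ROR recovery is unbiased up to
  sampling error (coverage-tested across 100 seeds).
* **Duplicates**: a configurable fraction of cases is resubmitted with a
  strictly later receipt date and a larger primaryid; a sub-fraction gets
  an equal date to exercise the primaryid tie-break. The dedup truth is
  therefore well defined and recorded in the ledger.
* **Demographics**: sex F/M/missing categorical; age from a truncated
  normal on [18, 85]; weight normal in kg with a configurable fraction
  stored in pounds; per-field missingness (defaults 25.3% age, 76% weight,
  5.3% sex — the published cohort's missingness).
* **Outcomes**: death/life-threatening drawn from a logistic model in
  1[age ≥ 70] and 1[cardiovascular concomitant]; the intercept is
  calibrated in-sample by bisection so the marginal outcome multiset hits
  the configured shares while the covariate shifts stay active. Non-severe
  cases distribute over the remaining categories; "missing" cases get no
  OUTC row.
* **Dates** uniform within the configured quarter range; report quarter
  follows each submission's own receipt date.

`scenario_paperlike()` is the named default matching the published
cohort's marginals: 64% female, age ≈ 66 ± 12.5 observed within [18, 85]
(the latent pre-truncation mean is 68.22 so the truncated mean is 66),
outcome multiset 40/38.7/8/4/1.3/8 (%), published missingness rates, and
planted group lifts of 237.25 / 2.18 / 3.64.

What the generator does **not** emulate — and hence what green tests do
not show about real data: real MedDRA vocabulary breadth (a ~50-PT pool
stands in for tens of thousands), free-text drug-name noise (misspellings,
compounded products), reporting-rate drift and clustering over calendar
time, correlated polypharmacy, country-specific reporting styles, and
multi-PT causal structure. Pipeline correctness on synthetic corpora does
not certify the dictionaries' recall on real FAERS text.

## Problem sizes and numeric choices

Desk-scale runs use corpora of 2,000–10,000 reports; the planted-signal
coverage study uses 100 corpora of 200,000 reports (baseline event rate
0.005, planted odds ratio 10) in a single-quarter window with the
outcome/concomitant machinery disabled, since none of it enters the 2×2
table. Published headline estimates (class ROR 1136.7, bisacodyl ROR
237.25, per-PT profile values) require the full 2004–2024 FAERS corpus and
are documented full-scale checks, not desk tests; the acceptance checks
instead verify the arithmetic engine, the criteria logic applied to the
published interval bounds, and parameter recovery on ground-truth corpora.

Reported tables round to 2 decimals; all internal computation is double
precision. Exact-test tie comparisons use 1e-12 relative slack. Random
draws all flow from one `numpy` Generator per run, so a fixed seed yields
byte-identical corpora and report bundles.

## Known limitations

* Substring drug matching cannot disambiguate salts/combination products
  beyond the dictionary's precision; the dictionaries are deliberately
  editable config rather than a normalization engine (no RxNorm/OHDSI).
* EBGM is the published observed/expected variant, not shrinkage MGPS
  (see above); at small a it overstates the association relative to MGPS.
* The published death-row comparison across the three drug groups
  (printed p = 0.012) is not reproducible by any standard exact test on
  the printed 3×2 counts; our enumeration (confirmed by an exact-Fraction
  oracle and an independent R implementation) gives 0.1438, and the
  pipeline reports its own enumeration value, flagged. The printed 0.012
  matches the separate male-vs-female mortality 2×2 (5/23 vs 1/48), which
  this package does reproduce.
* No multiple-comparison adjustment across PTs (none is applied in the
  source methodology).
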