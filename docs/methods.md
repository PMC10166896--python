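# Methods

This note documents the models, conventions and design choices behind
`faerspv`, and what the synthetic-data experiments do and do not establish.

## Study frame

The unit of analysis is the **deduplicated case**: FAERS quarterly releases
contain multiple versions of the same case (same CASEID re-submitted with a
newer FDA receipt date), so after parsing and assembly the pipeline keeps,
for each CASEID, the report with the latest FDA_DT, breaking exact ties on
(CASEID, FDA_DT) by the numerically largest PRIMARYID. Deduplication runs
over all loaded quarters at once (not per quarter); it is idempotent and
its output is sorted by CASEID. Partial FDA dates (year or year-month
precision) participate in the ordering via their zero-padded 8-digit form;
they are treated as *missing* wherever calendar arithmetic is needed.

A case is a **hepatic-failure case** when any of its reaction preferred
terms matches, by name (case-insensitive) or MedDRA code, one of five
mutually exclusive terms: hepatic failure (10019663), acute hepatic failure
(10000804), subacute hepatic failure (10056956), acute on chronic liver
failure (10077305), chronic hepatic failure (10057573). Matching accepts
either the name or the code because public REAC files carry names only;
codes are kept for documentation and for dialects that include them.

**ICI exposure** is read from drug rows in a suspect role (PS or SS) whose
verbatim name resolves, case-insensitively after trimming, in the bundled
generic+brand dictionary of the 8 approved agents (editable CSV at
`faerspv/data/ici_dictionary.csv`; brand lists are best-effort and
user-extensible). Regimens: exactly one distinct suspect ICI →
*monotherapy*; two or more with at least one primary suspect →
*combination*; two or more but none primary suspect → *ambiguous* — a
pattern the regimen definitions do not cover. Ambiguous cases are excluded
from regimen-stratified contrasts but retained in class-level ones, so no
data are silently dropped. Concomitant agents are non-ICI drugs in role C
only (not I — configurable), normalized by uppercase-trim, counted per case.

Ages are converted to years from AGE/AGE_COD (DEC ×10, YR ×1, MON ÷12,
WK ÷52.18, DY ÷365.25, HR ÷8766); values outside [0, 130] years become
missing with a warning. Countries map to six reporting regions via the
UN M49 continental grouping, with South America, Central America and the
Caribbean pooled as "South and Central America" (so Mexico falls there, not
in North America).

## Disproportionality

Every contrast reduces to a 2×2 table (a, b, c, d) whose cells are disjoint
case sets. Four designs are implemented:

1. *class_vs_all* — cases exposed to any ICI of a class (or any ICI at all)
   vs every other case in the database;
2. *mono_vs_all* — a given ICI monotherapy vs every other case;
3. *combo_vs_mono* — a given combination vs monotherapy of a named
   constituent (universe restricted to those two sets);
4. *ici_plus_agent_vs_mono* — ICI-exposed cases carrying a given
   concomitant agent vs ICI monotherapy cases *without* it. The comparator
   excludes the agent so the cells stay disjoint; the design's wording
   admits either reading and this one is the conservative, partition-true
   choice.

Statistics per table:

* ROR = (a/b)/(c/d), Wald interval exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)).
  A zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
  cells) and flags the result; an empty margin (a+b = 0 or c+d = 0) yields
  a not-computable result rather than an exception, so screens over many
  targets never abort on a sparse contrast.
* IC = log2((a+0.5)/(E+0.5)), E = (a+b)(a+c)/N. Interval: Gamma-quantile
  credible bounds log2(G_q(a+0.5)/(E+0.5)) by default; the closed-form
  expansion IC025 ≈ IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2 (and the analogous
  upper form) is available as `ic_interval="approx"`. On the reconstructed
  headline table the Gamma form gives IC025 = 1.39 and the approximation
  1.38; the Gamma form is the default. Neither variant reproduces the
  published upper bound of 1.63 exactly (both give ≈1.61); the exact
  published interval formula is not stated, so both variants' outputs are
  reported and no agreement is forced.
* Signal flag: (ROR025 > 1 and a ≥ 3) or IC025 > 0. The 3-case minimum is
  evaluated on cell a of the specific contrast, not on the drug's total
  case count. No multiple-testing adjustment is applied by default,
  matching standard practice for hypothesis-generating screens.

Subgroup contrasts (female vs male; age < 65 vs ≥ 65, missing stratifier
dropped) report the ROR only. The `DisproportionalityModel` /
`DisproportionalityResults` pair wraps the whole screen: the model holds
the per-case frame and options (designs, α, IC variant, top-k concomitant
agents, default 20), `fit()` enumerates every available target per design
and returns results with a `summary()` table and per-design CSV export.

### Back-derivation of the headline table

The database-wide margins (a = 654, a+c = 18,454, N = 9,647,655) and the
point ROR 2.92 determine the remaining margin:
b = a(N − a − c)/(ROR·c + a) ≈ 119,656 (rounded to an integer case count).
`reconstruct_two_by_two` performs this inversion; the Wald interval on the
reconstructed table reproduces the published (2.70, 3.16) to 2 decimals,
and the IC bounds follow as above. Note the rounding of b moves the point
IC by a few thousandths (1.505 vs the published 1.51).

## Descriptive analyses

* **Time to onset** = days from the earliest day-precise therapy start
  among suspect ICI mentions to the day-precise event onset date. Same-day
  onset is recorded as day 1 (the published minimum is 1, so day 0 cannot
  occur); negative intervals are logged and set missing; partial dates are
  missing. Bins: ≤28, 29–56, 57–84, >84 days; "first 3 months" means ≤84
  days. TTO percentages use the non-missing denominator.
* **Summary table**: counts and percentages per category (gender, age bins
  <18/18–44/45–64/65–74/≥75, region, reporting year, reporter type, TTO
  bins, indication groups, outcome, ICI class/substance, combination,
  concomitant-agent burden <3/3–5/6–10/>10), each section summing to the
  total with an explicit unknown level. Percentages are count/total·100
  rounded half-up to 2 decimals — the convention that reproduces every
  published percentage from its printed numerator and denominator.
* **Outcome tabulation**: when several outcome codes co-occur, one category
  is reported per case by the precedence DE > LT > HO > DS > CA > RI > OT.
  Death (for the fatality proportion) means code DE anywhere among the
  case's outcomes regardless of co-occurring codes. The precedence rule is
  a documented assumption; the source tables list one outcome per case
  without stating theirs.
* **Tests**: Kruskal–Wallis (tie-corrected, p from χ² with g−1 df) across
  exposure groups with more than 20 TTO observations, with unadjusted
  pairwise two-group tests plus a Holm-adjusted column for transparency;
  Pearson χ² without continuity correction for the r×2 fatality table over
  drugs with more than 20 cases, flagging expected cells below 1. All
  observations identical is handled as H = 0, p = 1.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes, not
FAERS verbatim. Per case it samples: at most one primary ICI exposure from
configurable marginal rates (plus a secondary-suspect partner with
probability `combo_rate`), the event from odds scaled multiplicatively by
the injected θ of every matching effect (logit-additive, so θ **is** the
case-level odds ratio the ROR estimates — this is what makes
parameter-recovery experiments well-posed), a log-normal TTO (default
median 38 days, σ = 1.1 in log-space), death given event (default 0.6865),
demographics, concomitant agents, duplicate re-emission in a later quarter
(newer FDA_DT, larger PRIMARYID) and partial event dates. Defaults mirror
the source study's database-wide conditions: background event rate 0.0019,
~1.2% total ICI exposure split in proportion to the published per-substance
case counts, and class-level θ equal to the published class RORs
(anti-PD-1 2.78, anti-PD-L1 3.62, anti-CTLA-4 3.31). Same config and seed →
byte-identical files.

What the simulator does **not** emulate: drug co-prescription correlation,
free-text name noise beyond case/whitespace, reporting-rate drift over
calendar time, indication-exposure confounding. Passing recovery tests
therefore show the estimators and plumbing are correct under the stated
sampling model, not that FAERS biases (under-reporting, notoriety effects,
duplicates evading CASEID matching) are overcome.

The **calibration experiments** use a deliberately well-posed desk-scale
design: 50,000 cases, one drug at 8% exposure, 2% background event rate,
200 seeded replicates — cell counts large enough (a ≈ 80–230) that Wald
asymptotics apply. Under θ = 1 the screen flags ≤7.5% of null databases
(measured ≈2%); under θ = 3 the mean ROR lands within 5% of 3 (measured
2.999) and the 95% CI covers 3 between 92% and 98% of the time (measured
94.5%).

The **deterministic fixture** (`fixture_table1`) hard-codes 654 cases whose
marginals reproduce the published clinical-characteristics table row for
row. Marginal columns (sex, age, region, year, reporter, TTO, indication,
outcome, concomitant burden) are assigned independently in index order —
only their margins are published, so joint structure is unconstrained —
with three exceptions: exposure blocks are constructed so the per-substance,
per-class and per-combination counts all hold simultaneously (class counts
overlap across combination cases), deaths are placed so that 8 of the 9
avelumab cases are fatal (the one published per-substance fatality), and
TTO/age values are laid out so the published medians and ranges
(38, 1–914 days; 64, 14–90 years) emerge exactly from the binned counts.

## Numerical conventions

* z-quantile from the standard normal; α ∈ (0, 1), default 0.05.
* Percentages: decimal half-up rounding at 2 dp (`Decimal`, not banker's
  rounding).
* Gamma quantiles from `scipy.stats.gamma.ppf` (shape a+0.5, unit scale).
* Parsing skips (and counts) rows whose field count disagrees with the
  header; empty strings are missing; files are read as latin-1, the FAERS
  encoding.
* Seeds: every stochastic component flows from one integer seed through
  `numpy.random.default_rng` / `SeedSequence`; replicate seeds are spawned
  deterministically and kept below 2³¹.

## Known limitations

* Brand-name coverage of the drug dictionary is a curated subset; verbatim
  FAERS drug strings with dosage suffixes or misspellings will not resolve
  (they count as unmapped concomitants when in role C).
* Indication grouping is an exact-match synonym table over a handful of
  cancer indications, not a MedDRA hierarchy traversal.
* The published upper IC bound (1.63) is not reproduced by either interval
  variant (see above); the discrepancy is documented rather than fitted.
* Legacy (pre-2012Q4) FAERS layouts and openFDA JSON are out of scope.
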