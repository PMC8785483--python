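# Methods

## Data model

Input death tables follow the WHO Mortality Database flat-file dialect:
one CSV row per country/year/ICD-list/cause/sex with 26 age-banded count
columns (`Deaths1` = all ages, `Deaths2..Deaths25` = ascending bands,
`Deaths26` = age unspecified) and an age-format code `Frmat`. Only the
full-detail format (`Frmat` 0, with 85–89/90–94/95+ terminal detail) is
accepted; any other format would need an arbitrary band-merging matrix,
so those rows are rejected with a per-row diagnostic. On load the
package:

* recomputes the all-ages total from the bands (stored totals in real
  extracts are inconsistent; mismatches are counted, never trusted);
* zeroes bands below the configured age floor (default 65) and collapses
  the 65+ detail to five groups {65–69, 70–74, 75–79, 80–84, 85+}, the
  lowest common resolution between the death data and the standard
  population weights;
* sums sexes into one record per (country, year, cause), since fall
  mortality is analysed for both sexes together;
* excludes age-unspecified deaths (`Deaths26`) from all 65+ analyses and
  logs their magnitude — the conservative default for counts that cannot
  be placed in an age stratum.

Population denominators come from a simplified UN-WPP-style CSV
(location, year, 5-year age group, count); groups above 85 are collapsed
into 85+, and a units flag handles tables stated in thousands. Income
classes are the four World Bank analytical groups (LICT/LMICT/UMICT/
HICT).

## Cause taxonomy

Classification is by fixed ICD-10 ranges on the 4-character MDB code
string (no decimal point): unspecified deaths R96/R98/R99; injury
universe V01–Y89 (external causes including sequelae Y85–Y89);
undetermined intent Y30/Y31/Y34/Y87.2/Y89.9; unintentional universe
V01–X59 (sequelae excluded); X59 unspecified unintentional; falls
W00–W19 with W19 = unspecified mechanism. Membership flags are
overlapping and obey the implication chain fall ⇒ unintentional ⇒
injury. Whether the injury denominator should include sequelae is not
settled usage; they are included here, and the category table is
exposed so a sensitivity analysis can redefine it.

A fall code's 4th character is its place of occurrence; digit 9 means
unknown place. A 3-character fall code carries no place information and
counts as unknown by default (`missing_is_unknown` policy flag), because
the indicator measures place specificity and an absent digit is exactly
a failure of specificity.

## Quality indicators

Five proportions per country-year, all kept internally as fractions in
[0, 1] (percent formatting is display-only), each undefined — never
zero — when its denominator is empty:

1. unspecified deaths / total deaths
2. undetermined-intent deaths / injury deaths
3. X59 deaths / unintentional injury deaths
4. W19 deaths / fall deaths
5. unknown-place fall deaths / fall deaths

Indicators default to the 65+ restriction (the population of interest);
an all-ages mode exists via the loader's age floor. Availability is
binned from the count of data years within 1990–2019 (0, 1–5, …, 26–30),
with the ICD revision inferred from the list tag prefix. Income-group
contrasts use the Kruskal–Wallis rank-sum test with country-years as the
analysis units (each year is one observation) and midrank tie handling;
the degenerate all-values-identical case is defined as H = 0, p = 1.
Group summaries report median and quartiles under the
linear-interpolation convention (stated because P25/P75 depend on it).

## Redistribution model

Only the first three problematic families shift the overall fall level,
so only they are redistributed. The model assumes garbage deaths follow
the same cause distribution as specifically coded deaths within the
relevant universe.

**Stages.** In order: (1) R96/R98/R99 over all causes; (2) the
undetermined-intent family over injuries V01–Y89; (3) X59 over
unintentional injuries V01–X58. Each stage's target set excludes only
that stage's own codes, and stages operate sequentially on a running
count table: garbage codes of a later stage receive their proportional
share of earlier allocations, and that inflated mass is redistributed at
their own stage. This sequential composition has two properties the
additive one-shot alternative lacks: on a single age group with
single-year windows the corrected fall count has the closed form
d_fall × Π_s (T_s + G_s) / T_s (T_s = observed targets, G_s = observed
stage garbage), and when garbage is generated by relabelling true causes
at per-death rates q1/q2/q3 the correction recovers the true count
exactly in expectation for *any* combination of rates — the stage
factors compose to 1/(1−q1) · 1/(1−q2) · 1/(1−q3). Mass is conserved at
every stage: allocations over the full target universe equal the
redistributed garbage mass (audited to 1e-9 relative).

**Adaptive windows.** Each stage's share distribution is pooled over a
centred window of years whose length follows that stage's problematic
proportion in the study year: < 30% → 1; [30%, 50%) → 3; [50%, 70%) → 5;
≥ 70% → 7 years. The printed breakpoints are treated as half-open
intervals on the continuous proportion. At series boundaries the window
is truncated to the years that exist (no data are invented) and the
truncation is flagged.

**Age resolution.** Shares are age-group specific within 65+ because the
corrected age-specific counts feed direct standardisation. An age
stratum whose pooled target denominator is zero falls back to the pooled
all-65+ share; if that is zero too the garbage is left unallocated, and
both situations are flagged in the result's audit trail. Corrected
counts are real-valued — no integer rounding, as rates are the
downstream quantity.

**Alternatives considered.** Computing every stage's share from the
original observed counts and summing the allocations (no cascade) is
simpler but drops the cross terms between stages, biasing corrected
counts downward when several families are present at once; it also has
no exact closed form to verify against. Shifting (rather than
truncating) boundary windows was rejected as inventing a different
estimand for edge years.

## Standardisation and tiers

Age-adjusted rate = 100000 × Σ_a w_a d_a / p_a over the five 65+ groups.
The weights are the WHO World Standard Population shares (the 2001
standard), with 85–89/90–94/95–99/100+ merged into 85+ and the five
values renormalised to sum to 1; the full table ships as
`src/fallqc/data/who_standard_population.csv` so an alternative standard
(e.g. a 95+ terminal band) can be substituted. Rates are per 100,000;
ratios and regressions are invariant to that choice of scale.

The per-year impact ratio is corrected/uncorrected rate (≥ 1 under the
purely additive correction); a country's tier comes from its *unrounded*
maximum ratio via the step function highest [1.00, 1.10), higher
[1.10, 1.20), high [1.20, 1.30), low [1.30, 1.40), lower [1.40, 1.50),
lowest ≥ 1.50. Years with a zero uncorrected rate have no defined ratio
and are excluded with a flag.

## Trend impact

Two views of how correction changes temporal conclusions:

* **Anchor years** (default 2005 and 2015, the years with the broadest
  country coverage in real extracts): absolute difference Δ per 100,000
  and relative change Δ/R(2005) × 100%, for both series, with a reversal
  flag when the signs differ. Strict-year matching: a country missing an
  anchor year is excluded with a reason.
* **OLS trend**: rate regressed on calendar year, classical standard
  errors (the b (S_b) reporting convention), two-sided t test,
  significance at p ≤ 0.05, minimum five data years. Degenerate fits are
  resolved exactly (zero residual variance: p = 0 for a non-zero slope,
  p = 1 for a flat one). Countries are classified by sign reversal and
  significance gained/lost between the two series; an exactly zero slope
  is "no reversal". No joinpoint or nonlinear trend models are offered.

## Synthetic data generator

The generator emulates the structure of member-state vital registration:
per country-year-age-group deaths drawn Binomial(population, rate) for a
true fall stratum (with optional additive linear time trends) and a
configurable non-fall cause mix spanning all three target universes,
plus matched population denominators and an income lookup.

Garbage is injected by **relabelling**: each death independently becomes
R99 with probability q1, else (if an injury) Y34 with probability q2,
else (if unintentional) X59 with probability q3; surviving falls are
coded W19 with probability q4 (else a uniform mechanism W00–W18) and get
place digit 9 with probability q5 (else a uniform digit 0–8). Relabelling
preserves total mortality and makes the redistribution assumption true
by construction, so parameter-recovery tests probe the implementation,
not the assumption. The stage-2 family is represented by the single code
Y34 (classification treats all five undetermined-intent codes
identically). All randomness flows from one seeded generator; identical
config + seed gives byte-identical files.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: correlated miscoding (real garbage does not
follow the specific-cause distribution, which is precisely the
proportionate method's untestable assumption), certification-system
changes mid-series, sex- or cause-dependent relabelling, migration-driven
population error, and real countries' absolute rate levels.

Shipped scenarios: `clean` (no garbage; correction must be an identity),
`tiered` (four countries at q1 = 20/40/60/75%, one per income class,
driving the four window regimes; ~11,000 deaths per country-year from
100,000 persons per age group), `improving-coding` (q1/q2/q3 decline
linearly over 2004–2016 while true rates are flat, inducing a spurious
upward uncorrected trend), and `sparse` (600 persons per age group,
exercising the zero-denominator fallbacks). These sizes keep the full
validation suite fast while leaving binomial noise far below the 5%
recovery band used in testing.

## Numerical notes

* Proportion and share arithmetic is float64 throughout; conservation is
  asserted to 1e-9 relative, standardisation oracles to 1e-12.
* Window breakpoints are compared half-open ([0.30, 0.50) → 3 years), so
  a proportion exactly at a printed boundary takes the wider window.
* Tier classification binds on the unrounded maximum; two-decimal
  display rounding happens only at output.
* The Kruskal–Wallis p-value is the asymptotic chi-square approximation
  with tie correction, adequate for the hundreds of country-years per
  group seen in practice; with a handful of observations an exact
  permutation p would be larger.

## Known limitations

* The proportionate assumption cannot be validated from the data it
  corrects; results for countries with very high problematic proportions
  (7-year windows) lean heavily on it.
* W19 and unknown-place falls are measured but not redistributed —
  mechanism- and place-specific subgroup rates remain biased.
* Only full-detail age-format rows are usable; countries reporting
  condensed tabulation lists are excluded from quality analysis.
* Unknown-age deaths are dropped from the 65+ analysis rather than
  redistributed over age.
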