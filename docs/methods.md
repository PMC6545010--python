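# Methods

## The discrimination algorithm

The unit of classification is the *dispense event*: all dispensing lines
sharing (patient, prescription date, dispense date, prescriber). The
prescriber is part of the key so that two same-day prescriptions from
different physicians are not merged; this is configurable in principle
but fixed in the implementation because nothing downstream depends on it.

Eligibility requires a GP prescriber, a recorded prescription date, a
computable age and at least one *usual* AG drug on the event. Age is
dispense-year minus birth-year: the source records carry only a year of
birth, so this is the coarsest convention consistent with the data; ages
are therefore accurate to ±1 year, which only matters at the rule-D
boundary (age ≤ 15) and at age-group edges.

The lag gate keeps events with a prescription-to-dispense lag in {0, 1}
days ("less than 2 days"): AG is disabling and acute, so prescriptions
intended for it are filled immediately. Rules are evaluated in the fixed
order A → B → C → D and the first match is recorded. The order cannot
change the AG/not-AG outcome (the event is AG iff *any* rule holds); it
only affects rule attribution, and A → D attribution gives the most
specific rule precedence (ORS is essentially pathognomonic).

Two readings of the rules deserve note:

* **Category universe.** "Categories of AG possible drugs" in rules B
  and C is read as the seven-class union of usual and possible classes.
  Read literally, "possible" drugs are a single class (antispasmodics)
  and a three-class condition could never fire, so the union is the only
  self-consistent reading. `AlgorithmParams.category_universe =
  "possible_only"` exposes the literal reading for sensitivity analyses;
  under it rules B and C never fire on realistic baskets.
* **Rule B checks no volumes and no excluding drugs.** The volume and
  excluding-drug constraints are stated for rules C and D only, and the
  implementation follows that exactly: three AG classes qualify an event
  even alongside an antibiotic or oversized boxes. The property "adding
  an excluding line can disable only rules C/D" is enforced by a test.

Volume consistency is per product: boxes of the same product code are
summed across the event's lines and compared to that product's
`max_boxes`. Rule D's "no more than 4 drugs" counts distinct product
codes, including drugs outside all three catalog roles; such *unlisted*
drugs are otherwise neutral — they neither qualify nor exclude.

Oral and injectable anti-emetics are distinct products with distinct
codes and classes; rule D's "anti-emetic" means the oral class only,
since injectables sit on the excluding list.

## Episodes and the heavy-user exclusion

AG-classified dispenses of one patient are chained in date order: a
dispense within 15 days of the chain's anchor joins as a renewal, a
larger gap opens a new episode. The default anchor is *rolling* (the
previous dispense in the chain), because the defining phrase is about
*consecutive* dispenses — a pairwise relation; anchoring at the episode
index date is available as `anchor="index"` and a test documents where
the two differ (gaps 9 + 12 days: one episode rolling, two anchored).

A patient with more than 3 episodes in one season has all episodes of
that patient-season removed — the pattern suggests chronic use of
AG-class drugs, not repeated AG. The threshold is strict (exactly 3 is
kept) and seasons are treated independently: the rule's purpose is to
clean each season's indicator, not to blacklist patients.

Seasons follow the ISO-8601 week calendar: winter = weeks 36…end of year
N plus 1…15 of N+1 (32 or 33 weeks, depending on whether N has 52 or 53
ISO weeks); summer = weeks 16–35 of N+1. An episode belongs to the
season of its index date's ISO week; renewals never create counts, so a
chain that starts in-season keeps its renewals past the season edge.

## Concordance statistics

The dispensing indicator (episode counts within a drugstore panel of
unknown catchment) and the sentinel indicator (estimated national
incidence) live on different scales, which rules out agreement
statistics such as the intraclass correlation or Bland–Altman limits.
The package therefore provides:

* **Pearson r with a Fisher-z interval**, the default two-sided 95%
  level, at lags −1, 0, +1 weeks. Back-computing the published intervals
  from the published correlations and the week counts implied by the
  published season dates reproduces them exactly at two decimals, which
  pins the interval method down; that reproduction is an acceptance
  test. (The 65+ group interval for 2016/17 does not reproduce at n=32
  under any n in 30…34; it is not asserted.)
* **Linearity**: OLS of algorithm counts on sentinel counts versus a
  natural cubic regression spline with 3 interior knots, compared by a
  nested F test. Knot placement is unstated in the field description, so
  the interior quartiles of the predictor are used — the standard
  default — and knots are a parameter. When both models interpolate
  (numerically zero residual), F is reported as 0 with p = 1: perfect
  linear fit is evidence *for* linearity, not a degenerate failure.
* **Heterogeneity across subgroups**: stacked OLS with stratum
  intercepts and stratum-specific slopes against a common-slope reduced
  model; the F test on the interaction block. Errors are homoscedastic
  OLS — the simplest model consistent with "ANOVA with interaction
  terms". Strata with zero-variance sentinel series are dropped with a
  warning.
* **Weekly rates** 100·x/y with median and quartiles (zero-sentinel
  weeks dropped with a warning), and the **peak-week comparison**
  (argmax of each series; ties break to the earliest week, logged).

Calibration of both F tests is checked by simulation: under a truly
linear generator the linearity p-values pass a Kolmogorov–Smirnov
uniformity test over 2,000 replicates at n = 32, and the heterogeneity
test's type-I error over 2,000 null replicates (four strata, equal
slopes, Gaussian noise) stays within [0.03, 0.07] at nominal 0.05.
These calibration generators are deliberately minimal linear-regression
simulators: calibration is a property of the test statistic under its
own assumptions, and burying it inside the full population simulator
would only add Monte-Carlo noise without changing what is being tested.

## The synthetic-data generator

The generator emulates the joint data-generating process the analysis
assumes, with one winter season (default 2016/17, 32 weeks) and a closed
population (default 50,000 patients — large enough for stable weekly
counts at realistic hazards while keeping the full suite fast).

* **Epidemic curve**: weekly per-patient hazard `baseline · (1 +
  (amplitude−1) · exp(−(t−t_peak)²/2σ²))` with baseline 0.003/week,
  amplitude 10 and width σ = 3 weeks, peaking at ISO week 1. This gives
  ≈0.3 AG episodes per person-season and a sharp mid-winter peak, the
  shape of French winter AG seasons. A Gaussian bump is the simplest
  unimodal choice; nothing downstream depends on its exact form.
* **Behavioural thinning**: an AG episode leads to a GP consultation
  with p = 0.31 (the published 33.4% consultation rate times the 92.8%
  GP share) and the prescription is filled inside the observed panel
  with p = 0.30 (the panel's published ~30% share of drugstores).
* **Baskets**: children draw from {A: 0.50, D: 0.35, B: 0.10, C: 0.05}
  (ORS and single-antipropulsive baskets are paediatric practice),
  adults from {B: 0.45, C: 0.55} (A is child-only and D cannot fire).
  10% of true AG baskets are "near misses" (an oversized single drug)
  that no rule accepts — prescribing heterogeneity the algorithm is not
  meant to capture. Lags are drawn from {0: 0.70, 1: 0.20, 2: 0.07,
  3: 0.03}; 2% of dispenses are renewed once after 5–14 days (renewals
  were reported below 2% of episodes on real data).
* **Contamination**: 5% of true AG baskets carry an excluding
  co-prescription (blocks rules C/D but not A/B); 1% of patients —
  drawn among the 65+ — are chronic users refilling an antipropulsive +
  antispasmodic basket every ~28 days (these classify AG per dispense,
  then trip the heavy-user exclusion, reproducing the elderly
  overestimation mechanism); 0.5% of patients generate one oversized
  two-class "travel kit" dispense that the volume rule rejects.
* **Sentinel process**: per stratum (all ages, four age groups, 13
  regions), weekly consultations are binomially sampled at
  `sentinel_fraction` = 0.25, scaled back up and multiplied by
  log-normal noise with CV 0.05, then rounded. The fraction is an
  *effective* reporting precision: the real network covers ~2% of GPs
  over tens of millions of people, a regime a 5·10⁴-patient simulation
  cannot reach; 0.25 gives the sentinel estimator a realistic relative
  error at this scale.

Every dispense event carries a ground-truth row (unique event key,
true-AG flag, episode id, contamination source), enabling sensitivity
and false-positive measurement that is impossible on real claims data.
`expected_detection_rate` gives the closed-form sensitivity: P(lag ≤ 1)
× P(conforming) × Σ (basket-mix shares, with the excluding-drug survival
factor applied only to rule-C/D baskets, since A and B ignore excluding
drugs). On rare same-day key collisions the generator slides an event by
one day to keep the event↔truth mapping exactly 1:1.

What the generator does **not** emulate: transmission dynamics and
spatial structure (regions share one epidemic curve, so regional
heterogeneity tests are calibrated under the null, not powered);
over-the-counter purchases; patient switching between panel and
non-panel drugstores; the sentinel estimator's real variance structure;
age-specific consultation behaviour. Passing tests therefore demonstrate
the pipeline's correctness and calibration under the assumed process,
not the algorithm's clinical accuracy on real prescriptions — that
requires field validation against audited prescriptions.

## Numerical choices and limitations

* Week arithmetic uses the standard library's ISO-8601 calendar
  exclusively; weeks are keyed (iso_year, iso_week).
* Correlations require n ≥ 4 and non-zero variance in both series;
  degenerate inputs raise rather than return NaN.
* Fisher intervals at |r| = 1 collapse to a point, by convention.
* The spline basis comes from patsy's natural cubic `cr()` with
  explicit knots; model ranks (not nominal column counts) set the F
  degrees of freedom, so collinear designs degrade gracefully.
* Reported correlations round to 2 decimals, matching surveillance
  reporting practice.
* The dispensing panel has no stable denominator, so no incidence rates
  per 100,000 are computed — only counts, correlations and count ratios.
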