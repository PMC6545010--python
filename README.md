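# agsurv

Syndromic surveillance of **acute gastroenteritis (AG)** from prescription
drug-dispensing records.

AG peaks every winter in temperate countries, and clinical surveillance
depends on voluntary sentinel GP networks. Pharmacy dispensing data are
collected anyway (for reimbursement), at far larger scale — but AG has no
disease-specific drug, so dispenses must be *discriminated*: is this basket
of drugs intended to treat an AG episode or something else? `agsurv`
implements a rule-based discrimination algorithm for claims-style dispensing
records, builds treatment episodes from the detected dispenses, and
cross-validates the resulting weekly epidemic signal against an independent
sentinel incidence series. Because real dispensing panels and sentinel
estimates are proprietary, the package ships a synthetic-data generator
with per-dispense ground truth, so every stage is measurable end to end.

It is aimed at epidemiologists and public-health data scientists working
with pharmacy or claims data.

## The algorithm and the statistics

Drugs are catalogued in three roles: **usual** AG drugs (oral rehydration
salts (ORS), oral anti-emetics, probiotic antidiarrhoeals, intestinal
antipropulsives, absorbents and anti-infectives), **possible** AG drugs
(antispasmodics), and **excluding** drugs that point to another indication
(antibiotics, antineoplastics, gastric antacids, IBD drugs, injectable
anti-emetics). Each usual/possible product carries a maximum number of
boxes `max_boxes` consistent with treating one self-limited AG episode.

A dispense event (one patient × prescription date × dispense date ×
prescriber) is **eligible** if prescribed by a GP with known prescription
date and patient age and containing ≥1 usual drug. An eligible event is
classified AG when the prescription-to-dispense lag is < 2 days and one of:

- **A.** an ORS is dispensed; or
- **B.** ≥ 3 AG therapeutic classes are dispensed; or
- **C.** ≥ 2 AG classes, each within its consistent volume, with no
  excluding drug; or
- **D.** age ≤ 15 years, a consistent volume of an intestinal
  antipropulsive or oral anti-emetic, no excluding drug, ≤ 4 drugs.

Consecutive AG dispenses ≤ 15 days apart are treatment **renewals** of one
episode; a longer gap starts a new episode. Patients with > 3 episodes in
one season (ISO weeks 36 → 15 of the next year) are excluded as probable
chronic users. The weekly indicator is the count of episode index dates.

Concordance with the sentinel series y uses Pearson's r with the Fisher-z
interval `tanh(atanh r ± z_{0.975}/√(n−3))` at lags −1/0/+1; a
linear-vs-natural-cubic-spline (3 interior knots) nested F test for
linearity; an interaction-ANOVA F test for slope heterogeneity across age
groups or regions; weekly rates 100·x/y; and the peak-week comparison.

## Worked example

```bash
python examples/03_simulate_and_crossvalidate.py
```

```
dispense lines: 11771, dispense events: 5720
classifier sensitivity: 77.5% (closed-form expectation 78.9%) on 1482 true AG dispenses; false positives before exclusion: 3988
episodes: 5105 built, 1120 kept after excluding 500 heavy users
weekly concordance over 32 winter weeks: r = 0.98 [95% CI 0.95; 0.99]
peak week: algorithm (2017, 1), sentinel (2017, 1), match = True
median weekly detection rate: 22% [20; 26]
```

A 50,000-patient winter is simulated; the classifier recovers 77.5% of
true AG dispenses, within 1.4 points of the closed-form expectation
implied by the generator's lag, basket and co-prescription settings. The
~4,000 false positives come almost entirely from simulated chronic users
refilling AG-class drugs monthly — the heavy-user exclusion removes all
of them before counting. The kept weekly episode series then tracks the
noisy sentinel series at r = 0.98 with the same peak week; the 22% median
weekly rate is the expected panel share (30%) times sensitivity, not a
deficiency.

`examples/01_classify_baskets.py` shows single-basket classification and
`examples/02_episodes_and_renewals.py` the episode chaining and heavy-user
exclusion. A thin CLI mirrors the stages:

```bash
agsurv simulate --seed 42 --out-dir sim
agsurv run --catalog sim/sim_catalog.csv --dispenses sim/sim_dispenses.csv \
           --sentinel sim/sim_sentinel.csv --out-dir results
```

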