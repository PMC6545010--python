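"""Synthetic dispensing panel and sentinel series with known ground truth.

The generator emulates the data-generating process the analysis assumes:

1. a winter-peaking weekly AG hazard (Gaussian bump in week index on a
   constant baseline) applied to a closed population of patients;
2. behavioural thinning — an AG episode leads to a GP consultation with
   probability ``p_consult`` (anchored to the published estimate that
   33.4% of AG cases consult, 92.8% of them a GP), and the prescription
   is filled in the observed drugstore panel with probability
   ``p_dispense_panel`` (the panel covers ~30% of drugstores);
3. prescription baskets drawn from a per-age mixture over rule-
   conforming compositions (A: ORS; B: three AG classes; C: two AG
   classes at consistent volume; D: single antipropulsive for a child)
   and near-miss baskets (oversized single drug) that no rule accepts;
4. prescription-to-dispense lags, occasional treatment renewals, and
   three contamination streams: chronic elderly users refilling an
   antipropulsive+antispasmodic basket every ~4 weeks, oversized
   "travel kit" dispenses, and excluding-drug co-prescriptions on true
   AG baskets;
5. a sentinel observation process: per-stratum binomial sampling of the
   week's consultations at ``sentinel_fraction``, scaled back up and
   perturbed with multiplicative log-normal noise.

Every dispense event carries a ground-truth label, so classifier
sensitivity and false-positive behaviour are measurable — impossible on
the real proprietary data.  ``expected_detection_rate`` gives the
closed-form sensitivity implied by a configuration; rules A and B are
immune to excluding-drug co-prescriptions, which the formula accounts
for.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .claims import DISPENSE_HEADER, SENTINEL_HEADER
from .weeks import AGE_GROUPS, SeasonWindow, age_group, winter_window

TRUTH_HEADER = [
    "patient_id",
    "dispense_date",
    "prescription_date",
    "is_true_ag",
    "true_episode_id",
    "contamination_source",
]

REGIONS = tuple(f"R{i:02d}" for i in range(1, 14))

#: Basket compositions by rule type; (drug_code, n_boxes) pairs from the
#: toy catalog.  "near_miss" is an oversized single-drug basket no rule
#: accepts (max_boxes of U-APR is 2).
BASKETS: Dict[str, Tuple[Tuple[str, int], ...]] = {
    "A": (("U-ORS", 1), ("U-PRO", 1)),
    "B": (("U-AEO", 1), ("U-ABS", 1), ("P-ASP", 1)),
    "C": (("U-AEO", 1), ("P-ASP", 1)),
    "D": (("U-APR", 1),),
    "near_miss": (("U-APR", 3),),
}

#: Rules that ignore excluding-drug co-prescriptions.
IMMUNE_TYPES = frozenset({"A", "B"})

CHRONIC_BASKET = (("U-APR", 1), ("P-ASP", 1))  # fires rule C in adults
TRAVEL_BASKET = (("U-AEO", 3), ("U-ABS", 4))  # two classes, both oversized


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    n_patients: int = 50_000
    start_year: int = 2016  # winter season start (weeks 36..15 of next year)
    baseline_weekly_risk: float = 0.003
    peak_week: Optional[Tuple[int, int]] = None  # default: ISO week 1 of start_year+1
    peak_amplitude: float = 10.0
    peak_width_weeks: float = 3.0
    p_consult: float = 0.31  # 33.4% consult x 92.8% of those see a GP
    p_dispense_panel: float = 0.30
    lag_distribution: Tuple[Tuple[int, float], ...] = ((0, 0.70), (1, 0.20), (2, 0.07), (3, 0.03))
    p_renewal: float = 0.02
    near_miss_rate: float = 0.10
    p_comedication: float = 0.05
    chronic_user_rate: float = 0.01
    travel_kit_rate: float = 0.005
    sentinel_fraction: float = 0.25
    sentinel_noise_cv: float = 0.05
    age_group_weights: Tuple[float, ...] = (0.06, 0.12, 0.62, 0.20)
    basket_mix_child: Tuple[Tuple[str, float], ...] = (
        ("A", 0.50),
        ("D", 0.35),
        ("B", 0.10),
        ("C", 0.05),
    )
    basket_mix_adult: Tuple[Tuple[str, float], ...] = (("B", 0.45), ("C", 0.55))

    def __post_init__(self) -> None:
        for name in (
            "baseline_weekly_risk",
            "p_consult",
            "p_dispense_panel",
            "p_renewal",
            "near_miss_rate",
            "p_comedication",
            "chronic_user_rate",
            "travel_kit_rate",
            "sentinel_fraction",
            "sentinel_noise_cv",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.peak_amplitude < 1.0:
            raise ValueError("peak_amplitude must be >= 1")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        total = sum(p for _, p in self.lag_distribution)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("lag_distribution must sum to 1")
        for mix in (self.basket_mix_child, self.basket_mix_adult):
            if abs(sum(p for _, p in mix) - 1.0) > 1e-9:
                raise ValueError("basket mixture must sum to 1")
        if abs(sum(self.age_group_weights) - 1.0) > 1e-9:
            raise ValueError("age_group_weights must sum to 1")

    @property
    def window(self) -> SeasonWindow:
        return winter_window(self.start_year)

    def p_lag_ok(self, max_lag_days: int = 1) -> float:
        return sum(p for lag, p in self.lag_distribution if lag <= max_lag_days)


@dataclass
class SimulationOutput:
    lines: pd.DataFrame  # claims dispense-line dialect
    sentinel: pd.DataFrame  # sentinel dialect, strata: all, age groups, regions
    truth: pd.DataFrame  # one row per dispense event


def expected_detection_rate(config: SimulationConfig, max_lag_days: int = 1) -> float:
    """Closed-form classifier sensitivity under the generator.

    A true AG dispense is detected iff its lag passes the gate, its
    basket is rule-conforming, and — for rule types C and D only — no
    excluding drug was co-prescribed (rules A and B ignore excluding
    drugs).  Near-miss baskets are never detected.
    """
    p_lag = config.p_lag_ok(max_lag_days)
    child_share = config.age_group_weights[0] + config.age_group_weights[1]
    total = 0.0
    for share, mix in (
        (child_share, config.basket_mix_child),
        (1.0 - child_share, config.basket_mix_adult),
    ):
        for btype, p in mix:
            survive = 1.0 if btype in IMMUNE_TYPES else (1.0 - config.p_comedication)
            total += share * p * survive
    return p_lag * (1.0 - config.near_miss_rate) * total


def _week_hazards(config: SimulationConfig) -> np.ndarray:
    window = config.window
    peak = config.peak_week or (config.start_year + 1, 1)
    if peak not in window:
        raise ValueError(f"peak_week {peak} outside the simulated window")
    t = np.arange(len(window.weeks), dtype=float)
    tp = float(window.index_of(peak))
    bell = np.exp(-0.5 * ((t - tp) / config.peak_width_weeks) ** 2)
    return config.baseline_weekly_risk * (1.0 + (config.peak_amplitude - 1.0) * bell)


def _empty_output() -> SimulationOutput:
    return SimulationOutput(
        lines=pd.DataFrame(columns=DISPENSE_HEADER),
        sentinel=pd.DataFrame(columns=SENTINEL_HEADER),
        truth=pd.DataFrame(columns=TRUTH_HEADER),
    )


def simulate(config: SimulationConfig) -> SimulationOutput:
    """Run the generator; identical config and seed give identical tables."""
    if len(config.window.weeks) == 0:
        raise ValueError("empty simulation window")
    if config.n_patients == 0:
        return _empty_output()

    window = config.window
    n = config.n_patients
    rng = np.random.default_rng([config.seed, 0])
    rng_chronic = np.random.default_rng([config.seed, 1])
    rng_travel = np.random.default_rng([config.seed, 2])
    rng_sentinel = np.random.default_rng([config.seed, 3])

    # --- population ------------------------------------------------------
    group_idx = rng.choice(4, size=n, p=np.asarray(config.age_group_weights))
    lo = np.array([0, 5, 15, 65])
    hi = np.array([4, 14, 64, 89])
    ages = rng.integers(lo[group_idx], hi[group_idx] + 1)
    base_year = window.start_date.year
    birth_years = base_year - ages
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    region_idx = rng.choice(len(REGIONS), size=n)

    lag_values = np.array([lag for lag, _ in config.lag_distribution])
    lag_probs = np.array([p for _, p in config.lag_distribution])
    monday = [dt.date.fromisocalendar(y, w, 1) for (y, w) in window.weeks]

    child_types = [t for t, _ in config.basket_mix_child]
    child_probs = np.array([p for _, p in config.basket_mix_child])
    adult_types = [t for t, _ in config.basket_mix_adult]
    adult_probs = np.array([p for _, p in config.basket_mix_adult])

    line_rows: List[tuple] = []
    truth_rows: List[tuple] = []
    consult_keys: List[Tuple[int, int, int]] = []  # (week_idx, age_grp, region_idx)
    used_keys: set = set()

    def emit_event(pid_i, presc, disp, basket, is_ag, episode_id, source, prescriber="GP"):
        pid = f"P{pid_i:06d}"
        # Event keys must be unique so each dispense event maps to exactly
        # one ground-truth row; on the rare same-day collision, slide the
        # whole event (lag preserved) to the next free day.
        while (pid, disp, presc) in used_keys:
            disp += dt.timedelta(days=1)
            presc += dt.timedelta(days=1)
        used_keys.add((pid, disp, presc))
        for code, boxes in basket:
            line_rows.append(
                (
                    pid,
                    int(birth_years[pid_i]),
                    sexes[pid_i],
                    disp.isoformat(),
                    presc.isoformat(),
                    prescriber,
                    REGIONS[region_idx[pid_i]],
                    code,
                    int(boxes),
                )
            )
        truth_rows.append(
            (pid, disp.isoformat(), presc.isoformat(), is_ag, episode_id, source)
        )

    # --- AG events, consultations, panel dispenses -----------------------
    hazards = _week_hazards(config)
    episode_counter = 0
    for wi, h in enumerate(hazards):
        n_events = rng.binomial(n, h)
        if n_events == 0:
            continue
        patients = rng.choice(n, size=n_events, replace=False)
        day_offsets = rng.integers(0, 7, size=n_events)
        consults = rng.random(n_events) < config.p_consult
        in_panel = rng.random(n_events) < config.p_dispense_panel
        for j in range(n_events):
            if not consults[j]:
                continue
            pid_i = int(patients[j])
            consult_keys.append((wi, int(group_idx[pid_i]), int(region_idx[pid_i])))
            if not in_panel[j]:
                continue
            presc = monday[wi] + dt.timedelta(days=int(day_offsets[j]))
            age = int(ages[pid_i])
            if age <= 15:
                btype = child_types[int(rng.choice(len(child_types), p=child_probs))]
            else:
                btype = adult_types[int(rng.choice(len(adult_types), p=adult_probs))]
            conforming = rng.random() >= config.near_miss_rate
            episode_counter += 1
            episode_id = f"E{episode_counter:07d}"

            def one_dispense(presc_date):
                basket_key = btype if conforming else "near_miss"
                basket = list(BASKETS[basket_key])
                source = "none"
                if rng.random() < config.p_comedication:
                    basket.append(("X-ATB", 1))
                    source = "comedication"
                lag = int(rng.choice(lag_values, p=lag_probs))
                disp = presc_date + dt.timedelta(days=lag)
                emit_event(pid_i, presc_date, disp, basket, True, episode_id, source)
                return disp

            disp = one_dispense(presc)
            if rng.random() < config.p_renewal:
                delay = int(rng.integers(5, 15))
                renewal_presc = disp + dt.timedelta(days=delay)
                one_dispense(renewal_presc)

    # --- contamination: chronic users ------------------------------------
    elderly = np.flatnonzero(ages >= 65)
    if elderly.size:
        order = rng_chronic.permutation(elderly)
        n_chronic = min(int(round(config.chronic_user_rate * n)), elderly.size)
        start_days = rng_chronic.integers(0, 28, size=n_chronic)
        season_days = (window.end_date - window.start_date).days
        for k in range(n_chronic):
            pid_i = int(order[k])
            day = int(start_days[k])
            while day <= season_days:
                presc = window.start_date + dt.timedelta(days=day)
                emit_event(pid_i, presc, presc, list(CHRONIC_BASKET), False, "", "chronic_user")
                day += 28 + int(rng_chronic.integers(-3, 4))

    # --- contamination: travel kits ---------------------------------------
    n_travel = int(round(config.travel_kit_rate * n))
    if n_travel:
        travel_patients = rng_travel.choice(n, size=n_travel, replace=False)
        season_days = (window.end_date - window.start_date).days
        travel_days = rng_travel.integers(0, season_days + 1, size=n_travel)
        for k in range(n_travel):
            pid_i = int(travel_patients[k])
            presc = window.start_date + dt.timedelta(days=int(travel_days[k]))
            emit_event(pid_i, presc, presc, list(TRAVEL_BASKET), False, "", "travel_kit")

    # --- sentinel observation process -------------------------------------
    n_weeks = len(window.weeks)
    consult_counts: Dict[str, np.ndarray] = {"all": np.zeros(n_weeks, dtype=int)}
    for g in AGE_GROUPS:
        consult_counts[g] = np.zeros(n_weeks, dtype=int)
    for r in REGIONS:
        consult_counts[r] = np.zeros(n_weeks, dtype=int)
    for wi, gi, ri in consult_keys:
        consult_counts["all"][wi] += 1
        consult_counts[AGE_GROUPS[gi]][wi] += 1
        consult_counts[REGIONS[ri]][wi] += 1

    sentinel_rows = []
    for stratum, counts in consult_counts.items():
        sampled = rng_sentinel.binomial(counts, config.sentinel_fraction)
        scaled = sampled / config.sentinel_fraction
        if config.sentinel_noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + config.sentinel_noise_cv**2))
            noise = rng_sentinel.lognormal(-0.5 * sigma**2, sigma, size=n_weeks)
        else:
            noise = np.ones(n_weeks)
        estimates = np.round(scaled * noise).astype(int)
        for wi, (y, w) in enumerate(window.weeks):
            sentinel_rows.append((y, w, stratum, int(estimates[wi])))

    lines = pd.DataFrame(line_rows, columns=DISPENSE_HEADER)
    sentinel = pd.DataFrame(sentinel_rows, columns=SENTINEL_HEADER)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_HEADER)
    return SimulationOutput(lines=lines, sentinel=sentinel, truth=truth)


def write_output(out: SimulationOutput, directory, prefix: str = "sim") -> Dict[str, str]:
    """Write the three tables as CSV; returns the paths written."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dispenses": directory / f"{prefix}_dispenses.csv",
        "sentinel": directory / f"{prefix}_sentinel.csv",
        "truth": directory / f"{prefix}_truth.csv",
    }
    out.lines.to_csv(paths["dispenses"], index=False)
    out.sentinel.to_csv(paths["sentinel"], index=False)
    out.truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}
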