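"""The AG discrimination algorithm: classify dispense events as AG or not.

A dispense event is *eligible* when it was prescribed by a GP, both the
prescription date and the patient's age are known, and the basket
contains at least one AG *usual* drug.  An eligible event is classified
as intended to treat an acute-gastroenteritis episode when the
prescription-to-dispense lag is strictly less than 2 days and one of
four conditions holds, evaluated in order (first match is recorded):

A. the basket contains an ORS product;
B. the basket spans at least three AG therapeutic classes;
C. the basket spans at least two AG therapeutic classes, each dispensed
   in a volume consistent with AG treatment, and contains no excluding
   drug;
D. the patient is 15 or younger, the basket contains a consistent volume
   of an intestinal antipropulsive or an oral anti-emetic, no excluding
   drug, and no more than 4 distinct drugs.

"AG therapeutic classes" are the union of the usual and possible
classes (the seven-class universe); taken literally, "possible" drugs
form a single class (antispasmodics) and a three-class condition would
be unsatisfiable, so the union reading is the only consistent one.  It
is exposed as ``category_universe`` for sensitivity analyses.  Rule B
deliberately performs neither a volume check nor an excluding-drug
check: those constraints apply to rules C and D only.

"Consistent volume" is per product: the boxes of one product on the
event, summed across its lines, must not exceed that product's
``max_boxes``.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .catalog import AG_CLASSES, RULE_D_CLASSES, DrugCatalog, Role, TherapeuticClass
from .claims import DispenseEvent


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable thresholds of the discrimination algorithm.

    Defaults implement the published rule set: lag < 2 days, three
    classes for rule B, two for rule C, age <= 15 and <= 4 drugs for
    rule D, 15-day renewal window and at most 3 episodes per season
    before a patient is excluded as a probable chronic user.
    """

    max_lag_days: int = 1
    min_classes_rule_b: int = 3
    min_classes_rule_c: int = 2
    rule_d_age_max: int = 15
    rule_d_max_drugs: int = 4
    renewal_window_days: int = 15
    max_episodes_per_season: int = 3
    category_universe: str = "union"  # union | possible_only
    anchor: str = "rolling"  # rolling | index

    def __post_init__(self) -> None:
        for name in (
            "min_classes_rule_b",
            "min_classes_rule_c",
            "rule_d_age_max",
            "rule_d_max_drugs",
            "renewal_window_days",
            "max_episodes_per_season",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.max_lag_days < 0:
            raise ValueError("max_lag_days must be >= 0")
        if self.category_universe not in ("union", "possible_only"):
            raise ValueError("category_universe must be 'union' or 'possible_only'")
        if self.anchor not in ("rolling", "index"):
            raise ValueError("anchor must be 'rolling' or 'index'")


class Rule(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    NONE = "none"


@dataclass
class ClassificationResult:
    event: DispenseEvent
    eligible: bool
    lag_days: Optional[int]
    fired_rule: Rule
    is_ag: bool
    reasons: List[str] = field(default_factory=list)


def eligibility(event: DispenseEvent, catalog: DrugCatalog) -> Tuple[bool, List[str]]:
    """GP prescriber, known prescription date and age, >=1 usual drug."""
    reasons = []
    if event.prescriber_specialty != "GP":
        reasons.append("not-GP")
    if event.prescription_date is None:
        reasons.append("no-prescription-date")
    if event.age_years is None:
        reasons.append("no-age")
    if not any(catalog.role_of(ln.drug_code) == "usual" for ln in event.lines):
        reasons.append("no-usual-drug")
    return (not reasons, reasons)


def lag_days(event: DispenseEvent) -> int:
    """Whole days between prescription and dispense; must be non-negative."""
    if event.prescription_date is None:
        raise ValueError("lag undefined without a prescription date")
    lag = (event.dispense_date - event.prescription_date).days
    if lag < 0:
        raise ValueError("negative prescription-to-dispense lag")
    return lag


def _event_features(event: DispenseEvent, catalog: DrugCatalog, params: AlgorithmParams):
    """Per-event aggregates the rules consume."""
    boxes_per_code: dict = defaultdict(int)
    for ln in event.lines:
        boxes_per_code[ln.drug_code] += ln.n_boxes

    if params.category_universe == "union":
        universe = AG_CLASSES
    else:
        universe = frozenset({TherapeuticClass.ANTISPASMODIC})

    ag_classes = set()
    consistent_classes = set()
    has_ors = False
    has_excluding = False
    rule_d_ok_class = False
    for code, total in boxes_per_code.items():
        product = catalog.get(code)
        if product is None:
            continue
        if product.role is Role.EXCLUDING:
            has_excluding = True
            continue
        if product.therapeutic_class is TherapeuticClass.ORS:
            has_ors = True
        consistent = total <= product.max_boxes
        if product.therapeutic_class in universe:
            ag_classes.add(product.therapeutic_class)
            if consistent:
                consistent_classes.add(product.therapeutic_class)
        if consistent and product.therapeutic_class in RULE_D_CLASSES:
            rule_d_ok_class = True
    return {
        "n_drugs": len(boxes_per_code),
        "ag_classes": ag_classes,
        "consistent_classes": consistent_classes,
        "has_ors": has_ors,
        "has_excluding": has_excluding,
        "rule_d_ok_class": rule_d_ok_class,
    }


def classify_event(
    event: DispenseEvent, catalog: DrugCatalog, params: AlgorithmParams = AlgorithmParams()
) -> ClassificationResult:
    """Apply eligibility, the lag gate, then rules A-D (first match wins)."""
    ok, reasons = eligibility(event, catalog)
    if not ok:
        return ClassificationResult(event, False, None, Rule.NONE, False, reasons)

    lag = lag_days(event)
    if lag > params.max_lag_days:
        return ClassificationResult(event, True, lag, Rule.NONE, False, ["lag-too-long"])

    f = _event_features(event, catalog, params)

    if f["has_ors"]:
        return ClassificationResult(event, True, lag, Rule.A, True, [])
    if len(f["ag_classes"]) >= params.min_classes_rule_b:
        return ClassificationResult(event, True, lag, Rule.B, True, [])
    if len(f["consistent_classes"]) >= params.min_classes_rule_c and not f["has_excluding"]:
        return ClassificationResult(event, True, lag, Rule.C, True, [])
    if (
        event.age_years <= params.rule_d_age_max
        and f["rule_d_ok_class"]
        and not f["has_excluding"]
        and f["n_drugs"] <= params.rule_d_max_drugs
    ):
        return ClassificationResult(event, True, lag, Rule.D, True, [])

    reasons = []
    if f["has_excluding"]:
        reasons.append("excluding-present")
    if f["ag_classes"] and not f["consistent_classes"]:
        reasons.append("volume-exceeded")
    if f["n_drugs"] > params.rule_d_max_drugs:
        reasons.append("too-many-drugs")
    if not reasons:
        reasons.append("no-rule-matched")
    return ClassificationResult(event, True, lag, Rule.NONE, False, reasons)


def classify_events(
    events: List[DispenseEvent],
    catalog: DrugCatalog,
    params: AlgorithmParams = AlgorithmParams(),
) -> List[ClassificationResult]:
    return [classify_event(e, catalog, params) for e in events]


def results_to_frame(results: List[ClassificationResult]):
    """One output row per event: eligibility, lag, rule, is_ag, reasons."""
    import pandas as pd

    rows = []
    for r in results:
        e = r.event
        rows.append(
            {
                "patient_id": e.patient_id,
                "dispense_date": e.dispense_date.isoformat(),
                "prescription_date": (
                    "" if e.prescription_date is None else e.prescription_date.isoformat()
                ),
                "prescriber_specialty": e.prescriber_specialty,
                "region_code": e.region_code,
                "age_years": "" if e.age_years is None else e.age_years,
                "eligible": r.eligible,
                "lag_days": "" if r.lag_days is None else r.lag_days,
                "fired_rule": r.fired_rule.value,
                "is_ag": r.is_ag,
                "reasons": ";".join(r.reasons),
            }
        )
    return pd.DataFrame(rows)
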