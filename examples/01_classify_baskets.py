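"""Classify a handful of dispense baskets with the AG discrimination rules.

Builds five small prescription baskets against the built-in toy drug
catalog and prints, for each, whether the algorithm flags it as an
acute-gastroenteritis (AG) treatment and which rule fired.
"""

import datetime as dt

from agsurv import AlgorithmParams, classify_event, toy_catalog
from agsurv.claims import DispenseEvent, DispenseLine


def make_event(basket, age, lag):
    disp = dt.date(2017, 1, 9)
    presc = disp - dt.timedelta(days=lag)
    lines = [
        DispenseLine("P1", disp.year - age, "F", disp, presc, "GP", "R01", code, boxes)
        for code, boxes in basket
    ]
    return DispenseEvent("P1", disp, presc, "GP", "R01", age, lines)


catalog = toy_catalog()
params = AlgorithmParams()

cases = [
    ("ORS for a toddler", [("U-ORS", 1)], 2, 1),
    ("three AG classes, adult", [("U-AEO", 1), ("U-ABS", 1), ("P-ASP", 1)], 40, 0),
    ("two classes + antibiotic", [("U-AEO", 1), ("P-ASP", 1), ("X-ATB", 1)], 40, 0),
    ("child anti-emetic, modest volume", [("U-AEO", 1), ("ZZZ", 1)], 10, 1),
    ("oversized anti-emetic (travel kit?)", [("U-AEO", 3)], 10, 1),
]

for label, basket, age, lag in cases:
    r = classify_event(make_event(basket, age, lag), catalog, params)
    verdict = f"AG (rule {r.fired_rule.value})" if r.is_ag else f"not AG ({';'.join(r.reasons)})"
    print(f"{label:38s} age={age:2d} lag={lag}d -> {verdict}")

print()
print(
    "Rules: A = any ORS; B = >=3 AG drug classes; C = 2 classes at\n"
    "consistent volume without excluding drug; D = child with a\n"
    "consistent antipropulsive/anti-emetic volume, <=4 drugs, no\n"
    "excluding drug.  An antibiotic on the same prescription blocks\n"
    "rules C and D; oversized volumes suggest stocking, not AG."
)
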