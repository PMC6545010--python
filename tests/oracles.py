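"""Independent brute-force oracles for the classifier and episode builder.

These are deliberately written as literal transcriptions of the rule
text, sharing no code with the package implementation: the classifier
oracle re-derives every quantity from a flat product table, and the
episode oracle builds chains by repeated linear scans instead of a
single pass.
"""

# Flat product table for the oracle: code -> (class, role, max_boxes).
ORACLE_PRODUCTS = {
    "U-ORS": ("ors", "usual", 2),
    "U-AEO": ("antiemetic_oral", "usual", 2),
    "U-PRO": ("probiotic_antidiarrhoeal", "usual", 2),
    "U-APR": ("intestinal_antipropulsive", "usual", 2),
    "U-ABS": ("intestinal_absorbent", "usual", 3),
    "U-AIF": ("intestinal_antiinfective", "usual", 2),
    "P-ASP": ("antispasmodic", "possible", 2),
    "X-ATB": ("antibiotic", "excluding", None),
    "X-ONC": ("antineoplastic", "excluding", None),
    "X-ANT": ("gastric_antacid", "excluding", None),
    "X-IBD": ("ibd_drug", "excluding", None),
    "X-AEI": ("antiemetic_injectable", "excluding", None),
}

AG_CLASS_NAMES = {
    "ors",
    "antiemetic_oral",
    "probiotic_antidiarrhoeal",
    "intestinal_antipropulsive",
    "intestinal_absorbent",
    "intestinal_antiinfective",
    "antispasmodic",
}


def oracle_classify(basket, age, lag, prescriber="GP", has_prescription_date=True):
    """Return (is_ag, fired_rule) for a basket of (code, n_boxes) pairs.

    Transcribed independently from the published rule text:
    eligibility = GP + prescription date + age + at least one usual
    drug; then lag < 2 days and the first of rules A-D to hold.
    """
    # sum boxes per product
    totals = {}
    for code, boxes in basket:
        totals[code] = totals.get(code, 0) + boxes

    # eligibility
    any_usual = False
    for code in totals:
        info = ORACLE_PRODUCTS.get(code)
        if info is not None and info[1] == "usual":
            any_usual = True
    if prescriber != "GP" or not has_prescription_date or age is None or not any_usual:
        return (False, "none")

    if lag >= 2:
        return (False, "none")

    any_excluding = any(
        ORACLE_PRODUCTS.get(code, ("", "", None))[1] == "excluding" for code in totals
    )

    # Rule A: dispensing of an ORS.
    for code in totals:
        info = ORACLE_PRODUCTS.get(code)
        if info is not None and info[0] == "ors":
            return (True, "A")

    # Rule B: at least three AG therapeutic classes on the dispense.
    classes = set()
    for code in totals:
        info = ORACLE_PRODUCTS.get(code)
        if info is not None and info[0] in AG_CLASS_NAMES and info[1] != "excluding":
            classes.add(info[0])
    if len(classes) >= 3:
        return (True, "B")

    # Rule C: consistent volume of at least two AG classes, no excluding drug.
    consistent_classes = set()
    for code, total in totals.items():
        info = ORACLE_PRODUCTS.get(code)
        if (
            info is not None
            and info[0] in AG_CLASS_NAMES
            and info[1] != "excluding"
            and total <= info[2]
        ):
            consistent_classes.add(info[0])
    if len(consistent_classes) >= 2 and not any_excluding:
        return (True, "C")

    # Rule D: age <= 15, consistent volume of an antipropulsive or an
    # (oral) anti-emetic, no excluding drug, no more than 4 drugs.
    if age <= 15 and not any_excluding and len(totals) <= 4:
        for code, total in totals.items():
            info = ORACLE_PRODUCTS.get(code)
            if (
                info is not None
                and info[0] in ("intestinal_antipropulsive", "antiemetic_oral")
                and info[1] != "excluding"
                and total <= info[2]
            ):
                return (True, "D")

    return (False, "none")


def oracle_episodes(dates, window_days=15, anchor="rolling"):
    """Quadratic chain construction over a sorted date list.

    Returns a list of chains (lists of dates): the first date of each
    chain is the episode index, the rest are renewals.  Repeatedly
    takes the earliest unassigned dispense as a new index and extends
    its chain by scanning the remaining dispenses in order.
    """
    remaining = list(dates)
    chains = []
    while remaining:
        index = remaining.pop(0)
        chain = [index]
        anchor_date = index
        i = 0
        while i < len(remaining):
            if (remaining[i] - anchor_date).days <= window_days:
                d = remaining.pop(i)
                chain.append(d)
                if anchor == "rolling":
                    anchor_date = d
                # restart the scan: list is sorted, so position i is next
            else:
                i += 1
        chains.append(chain)
    return chains
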