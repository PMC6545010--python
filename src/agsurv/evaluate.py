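"""Evaluate the detection pipeline against synthetic ground truth.

On real claims data the classifier's operating characteristics are
unobservable; the synthetic generator labels every dispense event, so
sensitivity, false positives and the recovery of the weekly epidemic
signal can be measured directly.
"""

from __future__ import annotations

import datetime as dt
from typing import Dict, List, Optional

from . import claims, concordance, episodes as ep
from .catalog import DrugCatalog, toy_catalog
from .classify import AlgorithmParams, ClassificationResult, classify_events
from .simulate import SimulationOutput
from .weeks import SeasonWindow, aggregate_weekly, sentinel_to_series


def lines_from_frame(lines_df) -> List[claims.DispenseLine]:
    """Materialize simulator output rows as dispense lines (no CSV hop)."""
    out = []
    for row in lines_df.itertuples(index=False):
        out.append(
            claims.DispenseLine(
                patient_id=str(row.patient_id),
                birth_year=int(row.birth_year),
                sex=str(row.sex),
                dispense_date=dt.date.fromisoformat(row.dispense_date),
                prescription_date=dt.date.fromisoformat(row.prescription_date),
                prescriber_specialty=str(row.prescriber_specialty),
                region_code=str(row.region_code),
                drug_code=str(row.drug_code),
                n_boxes=int(row.n_boxes),
            )
        )
    return out


def classify_output(
    out: SimulationOutput,
    catalog: Optional[DrugCatalog] = None,
    params: AlgorithmParams = AlgorithmParams(),
) -> List[ClassificationResult]:
    catalog = catalog or toy_catalog()
    events = claims.assemble_events(lines_from_frame(out.lines))
    return classify_events(events, catalog, params)


def sensitivity_against_truth(
    out: SimulationOutput,
    results: Optional[List[ClassificationResult]] = None,
    catalog: Optional[DrugCatalog] = None,
    params: AlgorithmParams = AlgorithmParams(),
) -> Dict[str, float]:
    """Confusion counts of per-dispense classification vs ground truth."""
    if results is None:
        results = classify_output(out, catalog, params)
    truth = {
        (r.patient_id, r.dispense_date, r.prescription_date): bool(r.is_true_ag)
        for r in out.truth.itertuples(index=False)
    }
    tp = fn = fp = tn = 0
    for r in results:
        e = r.event
        key = (e.patient_id, e.dispense_date.isoformat(), e.prescription_date.isoformat())
        is_true = truth[key]
        if is_true and r.is_ag:
            tp += 1
        elif is_true:
            fn += 1
        elif r.is_ag:
            fp += 1
        else:
            tn += 1
    total_true = tp + fn
    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "n_true_ag": total_true,
        "sensitivity": tp / total_true if total_true else float("nan"),
    }


def weekly_concordance(
    out: SimulationOutput,
    window: SeasonWindow,
    results: Optional[List[ClassificationResult]] = None,
    catalog: Optional[DrugCatalog] = None,
    params: AlgorithmParams = AlgorithmParams(),
) -> Dict:
    """Full funnel on simulator output, compared to its sentinel series.

    Returns the weekly episode series, the Pearson estimate with CI, the
    peak-week comparison and the weekly-rate summary for the ``all``
    stratum.
    """
    if results is None:
        results = classify_output(out, catalog, params)
    dispenses = ep.dispenses_from_results(results)
    episodes = ep.build_all_episodes(dispenses, params)
    kept, summaries = ep.apply_heavy_user_exclusion(episodes, params)
    series, _ = aggregate_weekly(kept, window)
    records = [
        claims.SentinelRecord(int(r.iso_year), int(r.iso_week), str(r.stratum), float(r.estimated_cases))
        for r in out.sentinel.itertuples(index=False)
    ]
    sentinel = sentinel_to_series(records, window, "all")
    estimate = concordance.pearson_with_ci(series["all"], sentinel)
    peaks = concordance.peak_comparison(series["all"], sentinel)
    rates = concordance.weekly_rates(series["all"], sentinel)
    return {
        "series": series["all"],
        "sentinel": sentinel,
        "correlation": estimate,
        "peaks": peaks,
        "rates": rates,
        "n_episodes": len(episodes),
        "n_episodes_kept": len(kept),
        "n_patients_excluded": sum(s.excluded for s in summaries),
    }
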