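"""End-to-end pipeline: catalog -> classify -> episodes -> weekly series -> concordance.

Stages mirror the analysis funnel: dispensing lines are read and grouped
into events, events are classified by the discrimination algorithm, AG
dispenses are chained into episodes, heavy users are excluded, episode
index dates are aggregated per ISO week and stratum, and the weekly
series are compared against the sentinel series (correlations at lags
-1/0/+1, linearity, subgroup heterogeneity, weekly rates, peak weeks).

Every intermediate table is written to the output directory and the
funnel counts (lines read -> events -> eligible -> classified AG ->
episodes -> episodes kept) are logged and returned, so each filtering
step is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import claims, concordance, episodes as ep
from .catalog import DrugCatalog, load_catalog
from .classify import AlgorithmParams, classify_events, results_to_frame
from .weeks import AGE_GROUPS, aggregate_weekly, sentinel_to_series, winter_window

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    catalog_path: str
    dispenses_path: str
    sentinel_path: str
    output_dir: str
    params: AlgorithmParams = field(default_factory=AlgorithmParams)
    season_start_years: Sequence[int] = (2016,)
    stratify_age: bool = True
    stratify_region: bool = True
    confidence_level: float = 0.95


def _correlation_rows(season_label, stratum, x, y, level):
    rows = []
    try:
        by_lag = concordance.lagged_correlations(x, y, level=level)
    except ValueError as exc:
        logger.warning("correlation skipped for %s/%s: %s", season_label, stratum, exc)
        return rows
    for lag, est in sorted(by_lag.items()):
        rows.append(
            {
                "season": season_label,
                "stratum": stratum,
                "lag": lag,
                "r": round(est.r, 4),
                "ci_low": round(est.ci_low, 4),
                "ci_high": round(est.ci_high, 4),
                "n": est.n,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    catalog: DrugCatalog = load_catalog(config.catalog_path)
    lines, rejects = claims.read_dispense_lines(config.dispenses_path)
    rejects.to_csv(out_dir / "rejects.csv", index=False)
    events = claims.assemble_events(lines)
    results = classify_events(events, catalog, config.params)
    results_to_frame(results).to_csv(out_dir / "classification.csv", index=False)

    n_eligible = sum(r.eligible for r in results)
    ag_dispenses = ep.dispenses_from_results(results)
    all_episodes = ep.build_all_episodes(ag_dispenses, config.params)
    kept, summaries = ep.apply_heavy_user_exclusion(all_episodes, config.params)
    ep.episodes_to_frame(kept).to_csv(out_dir / "episodes.csv", index=False)
    ep.summaries_to_frame(summaries).to_csv(out_dir / "patient_season_summary.csv", index=False)

    funnel = {
        "lines_read": len(lines),
        "lines_rejected": len(rejects),
        "events": len(events),
        "eligible_events": n_eligible,
        "ag_dispenses": len(ag_dispenses),
        "episodes": len(all_episodes),
        "episodes_kept": len(kept),
        "patients_excluded": sum(s.excluded for s in summaries),
    }
    for k, v in funnel.items():
        logger.info("funnel %s=%d", k, v)

    sentinel_records = claims.read_sentinel_series(config.sentinel_path)
    sentinel_strata = {r.stratum for r in sentinel_records}

    report: Dict = {"funnel": funnel, "seasons": {}}
    correlation_rows: List[dict] = []
    series_frames = []

    for year in config.season_start_years:
        window = winter_window(year)
        season: Dict = {"label": window.label, "n_weeks": len(window)}
        in_window = [e for e in kept if (e.index_date.isocalendar()[0], e.index_date.isocalendar()[1]) in window]

        all_series, _ = aggregate_weekly(in_window, window, None)
        series_frames.append(all_series["all"].to_frame().assign(season=window.label))

        if not in_window or "all" not in sentinel_strata:
            season["note"] = "no data"
            report["seasons"][window.label] = season
            continue

        sent_all = sentinel_to_series(sentinel_records, window, "all")
        correlation_rows += _correlation_rows(
            window.label, "all", all_series["all"], sent_all, config.confidence_level
        )
        try:
            lin = concordance.linearity_test(sent_all, all_series["all"])
            season["linearity"] = {
                "f": round(lin.f_stat, 4),
                "df_num": lin.df_num,
                "df_den": lin.df_den,
                "p": round(lin.p_value, 4),
            }
        except ValueError as exc:
            logger.warning("linearity test skipped for %s: %s", window.label, exc)

        rates = concordance.weekly_rates(all_series["all"], sent_all)
        season["weekly_rates"] = {
            "median": round(rates.median, 2),
            "q1": round(rates.q1, 2),
            "q3": round(rates.q3, 2),
        }
        peaks = concordance.peak_comparison(all_series["all"], sent_all)
        season["peak"] = {
            "algorithm": list(peaks.peak_week_algorithm),
            "sentinel": list(peaks.peak_week_sentinel),
            "match": peaks.match,
        }

        for flag, strat, strata in (
            (config.stratify_age, "age", AGE_GROUPS),
            (config.stratify_region, "region", None),
        ):
            if not flag:
                continue
            strat_series, _ = aggregate_weekly(in_window, window, strat)
            pairs = {}
            for name, series in strat_series.items():
                if name not in sentinel_strata:
                    logger.warning("no sentinel series for stratum %r; skipped", name)
                    continue
                sent = sentinel_to_series(sentinel_records, window, name)
                correlation_rows += _correlation_rows(
                    window.label, name, series, sent, config.confidence_level
                )
                pairs[name] = (series, sent)
                series_frames.append(series.to_frame().assign(season=window.label))
            if len(pairs) >= 2:
                try:
                    het = concordance.heterogeneity_test(pairs, grouping=strat)
                    season[f"heterogeneity_{strat}"] = {
                        "f": round(het.f_stat, 4),
                        "df_num": het.df_num,
                        "df_den": het.df_den,
                        "p": round(het.p_value, 4),
                    }
                except ValueError as exc:
                    logger.warning("heterogeneity (%s) skipped for %s: %s", strat, window.label, exc)

        report["seasons"][window.label] = season

    import pandas as pd

    pd.DataFrame(
        correlation_rows,
        columns=["season", "stratum", "lag", "r", "ci_low", "ci_high", "n"],
    ).to_csv(out_dir / "correlations.csv", index=False)
    if series_frames:
        pd.concat(series_frames, ignore_index=True).to_csv(
            out_dir / "weekly_series.csv", index=False
        )

    with (out_dir / "report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report
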