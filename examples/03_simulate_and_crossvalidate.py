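"""Full cross-validation on a synthetic winter season.

Simulates a 50,000-patient population through one winter (weekly AG
hazard with a mid-winter peak, GP consultations, panel dispensing,
rule-conforming and contaminated baskets, a noisy sentinel observation
process), runs the detection pipeline, and compares the weekly episode
series with the sentinel incidence series.
"""

from agsurv import SimulationConfig, expected_detection_rate, simulate
from agsurv.evaluate import classify_output, sensitivity_against_truth, weekly_concordance

config = SimulationConfig(seed=42, n_patients=50_000)
out = simulate(config)
print(f"dispense lines: {len(out.lines)}, dispense events: {len(out.truth)}")

results = classify_output(out)
metrics = sensitivity_against_truth(out, results=results)
print(
    f"classifier sensitivity: {100 * metrics['sensitivity']:.1f}% "
    f"(closed-form expectation {100 * expected_detection_rate(config):.1f}%) "
    f"on {metrics['n_true_ag']} true AG dispenses; "
    f"false positives before exclusion: {metrics['fp']}"
)

report = weekly_concordance(out, config.window, results=results)
est = report["correlation"]
print(
    f"episodes: {report['n_episodes']} built, {report['n_episodes_kept']} kept "
    f"after excluding {report['n_patients_excluded']} heavy users"
)
print(
    f"weekly concordance over {est.n} winter weeks: "
    f"r = {est.r:.2f} [95% CI {est.ci_low:.2f}; {est.ci_high:.2f}]"
)
pk = report["peaks"]
print(
    f"peak week: algorithm {pk.peak_week_algorithm}, "
    f"sentinel {pk.peak_week_sentinel}, match = {pk.match}"
)
r = report["rates"]
print(f"median weekly detection rate: {r.median:.0f}% [{r.q1:.0f}; {r.q3:.0f}]")
print()
print(
    "The weekly number of detected AG episodes tracks the sentinel\n"
    "incidence curve closely (r near 1, matching peak weeks); the median\n"
    "rate reflects the panel share times classifier sensitivity, not 100%."
)
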