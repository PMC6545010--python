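"""Chain AG-classified dispenses into episodes and apply the heavy-user rule.

A dispense within 15 days of the previous one renews the same treatment
episode; a longer gap opens a new, independent episode.  Patients with
more than three episodes in one season look like chronic users of
AG-class drugs and are removed from the surveillance indicator.
"""

import datetime as dt

from agsurv import apply_heavy_user_exclusion, build_all_episodes
from agsurv.episodes import _Dispense


def history(pid, offsets, age=30):
    start = dt.date(2016, 10, 3)
    return [
        _Dispense(pid, start + dt.timedelta(days=o), age, "R01") for o in offsets
    ]


dispenses = (
    history("alice", [0, 9, 21])        # one episode renewed twice (gaps 9 and 12 d)
    + history("bob", [0, 19])           # two independent episodes (gap 19 d)
    + history("carol", [0, 30, 60, 90], age=75)  # four episodes -> excluded
)

episodes = build_all_episodes(dispenses)
kept, summaries = apply_heavy_user_exclusion(episodes)

for e in episodes:
    print(
        f"{e.patient_id:6s} index={e.index_date} renewals={e.n_renewals} "
        f"season={e.season_label}"
    )
print()
for s in summaries:
    tag = "EXCLUDED (probable chronic user)" if s.excluded else "kept"
    print(f"{s.patient_id:6s} {s.season_label}: {s.n_episodes} episode(s) -> {tag}")
print(f"\nepisodes counted in the weekly indicator: {len(kept)}")
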