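"""EPG feeding behavior: time ratios, group tests and attainment.

Simulates 5-hour EPG recordings for two groups of aphids — one feeding
successfully (long passive phloem ingestion, E2) and one struggling (short
E2 bouts, more non-probing) — then compares the waveform time ratios.
"""

import math

from aphidfit.epg import attainment_matrix, compare_groups, group_summary
from aphidfit.synthdata import EPGSimSpec, simulate_epg

good = EPGSimSpec(n_recordings=15, group_label="favorable_host")
poor = EPGSimSpec(
    n_recordings=15,
    group_label="novel_host",
    dwell_log_mean={**dict(good.dwell_log_mean),
                    "E2": math.log(400.0), "np": math.log(1500.0)},
)
recordings = simulate_epg(good, seed=1) + simulate_epg(poor, seed=2)

summary = group_summary(recordings)
print(summary.pivot(index="waveform", columns="group", values="mean").round(3))
print()
tests = compare_groups(recordings, "pairwise")
print(tests[["waveform", "statistic", "p", "stars"]].round(4).to_string(index=False))
print()
print(attainment_matrix(recordings).round(2))
print(
    "\nTime ratios are seconds in each waveform / 18,000 s. The Welch t-test"
    " flags E2 (phloem ingestion) and np (non-probing) as the behaviors that"
    " separate the groups; the attainment matrix shows what fraction of"
    " individuals reached each feeding step at least once."
)
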