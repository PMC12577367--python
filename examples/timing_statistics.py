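"""Event-timing statistics on a synthetic two-condition cohort.

Generates per-cell abscission times for a control arm (median 16 min) and
a replication-stress arm (median 24 min), then computes the completion
fractions, the cumulative curve, a Tukey box summary and the Mann-Whitney
comparison the pipeline reports.
"""

import math

import abscission as ab

events = ab.generate_event_table(
    100,
    [
        ("control", {"t_abscission": ("lognormal", math.log(16.0), 0.35)}),
        ("stress", {"t_abscission": ("lognormal", math.log(24.0), 0.35)}),
    ],
    seed=11,
    horizon_min=120.0,
)

for label, sub in events.groupby("condition"):
    times = sub["t_abscission"].tolist()
    frac60 = ab.fraction_completed_by(times, 60.0)
    box = ab.box_summary(sub["t_abscission"].dropna())
    print(f"{label}: median {box.median:.1f} min  IQR [{box.q1:.1f}, {box.q3:.1f}]  "
          f"completed by 60 min: {100 * frac60:.0f}%")

x = events.loc[events.condition == "control", "t_abscission"].dropna()
y = events.loc[events.condition == "stress", "t_abscission"].dropna()
res = ab.mann_whitney(x, y)
print(f"Mann-Whitney U = {res['U']:.0f}, two-sided p = {res['p_two_sided']:.2e}")

# binucleation-style contingency comparison via Fisher's exact test
table = [[5, 45], [15, 35]]
print(f"Fisher's exact p for {table}: {ab.fishers_exact(table):.4f}")
# The medians recover the generating distributions; the Mann-Whitney p
# quantifies the separation between the two arms.
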