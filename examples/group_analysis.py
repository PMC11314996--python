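"""A full synthetic cohort: block-design sessions, cleaning, adherence, stats.

Simulates 16 subjects performing the 280 s joint-attention block design
(4 x [25 s AJ, 25 s NOAJ, 20 s Center]) with artifacts that nullify or
displace gaze off-screen, cleans each session, and runs the group
statistics: paired Wilcoxon on original-vs-filtered on-screen rates and
a Friedman test over the Center presentations for a temporal effect.
"""

import numpy as np

from gazemend import (
    DEFAULT_GEOMETRY,
    ArtifactSpec,
    assign_condition,
    build_default_schedule,
    clean_recording,
    default_aois,
    friedman,
    generate_group_session,
    onscreen_rate,
    posthoc_pairs,
    trial_rates,
    wilcoxon_signed_rank,
)
from gazemend.paradigm import AJ, CENTER, NOAJ

sched = build_default_schedule()
aois = default_aois()
spec = ArtifactSpec(n_spikes=6, spike_amp_px=2200, n_displacements=4, disp_offset_px=2200, n_blinks=10)
sessions = generate_group_session(
    n_subjects=16, artifact_spec=spec, decay_per_trial={CENTER: 0.15}, rate_hz=250, seed=42
)

rates = {c: {"original": [], "filtered": []} for c in (CENTER, AJ, NOAJ)}
center_rows = []
for s in sessions:
    cleaned, _ = clean_recording(s.dirty)
    for variant, rec in (("original", s.dirty), ("filtered", cleaned)):
        labels = assign_condition(rec, sched)
        for cond in rates:
            rates[cond][variant].append(onscreen_rate(rec, DEFAULT_GEOMETRY, labels, cond))
    df = trial_rates(cleaned, sched, aois)
    center_rows.append(df[df["condition"] == CENTER].sort_values("position")["rate"].to_numpy())

print("on-screen rate, mean over 16 subjects (original -> filtered):")
for cond in rates:
    ori, fil = np.mean(rates[cond]["original"]), np.mean(rates[cond]["filtered"])
    res = wilcoxon_signed_rank(np.array(rates[cond]["filtered"]), np.array(rates[cond]["original"]))
    print(f"  {cond:<7} {ori:.3f} -> {fil:.3f}   Wilcoxon p = {res.p_value:.2g}")

mat = np.vstack(center_rows)
fr = friedman(mat)
print(f"\nCenter task rate across presentations 1..4 (decay 0.15/trial injected):")
print("  means:", np.round(mat.mean(axis=0), 3))
print(f"  Friedman chi2 = {fr.statistic:.2f}, p = {fr.p_value:.2g}")
first_last = posthoc_pairs(mat)[2]  # combination order: (1,2),(1,3),(1,4),...
print(f"  post hoc trial 1 vs 4 (Bonferroni): adjusted p = {first_last.adjusted_p:.2g}")
print()
print("Filtering restores on-screen rates for every condition, and the")
print("injected attention decay on the cross is detected as a temporal effect.")
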