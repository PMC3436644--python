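"""Dendritic morphometry of the reconstructed neurons.

Applies the 50% end-point eligibility rule, computes per-neuron and
per-dendrite metrics and the 10/20/30 μm Sholl profiles, and tests
group differences: nested ANOVA for tree length, path distance,
terminal length percentage, end points and primary dendrites;
Mann–Whitney U on case means for each Sholl radius.
"""

import pandas as pd

from _common import RESULTS, COHORT_CONFIG, cohort
from striaquant.morphometry import metrics_frame, reconstruction_eligible, sholl
from striaquant.stats import NestedDesignData, mann_whitney_u, nested_anova

thickness = COHORT_CONFIG.thickness_um
bundle = cohort()

labeled, sholl_rows, n_dropped = [], [], 0
for s in bundle.sections:
    for i, neuron in enumerate(s.neurons):
        if not reconstruction_eligible(neuron, thickness):
            n_dropped += 1
            continue
        labels = {"group": s.group, "case": s.case, "section": s.section_index,
                  "neuron": i}
        labeled.append((labels, neuron))
        for r, n_int in zip(*sholl(neuron).to_frame().to_numpy().T):
            sholl_rows.append({**labels, "radius_um": r, "intersections": n_int})

neuron_df, dendrite_df = metrics_frame(labeled, thickness)
neuron_df.to_csv(RESULTS / "neuron_metrics.csv", index=False)
dendrite_df.to_csv(RESULTS / "dendrite_metrics.csv", index=False)
sholl_df = pd.DataFrame(sholl_rows)
sholl_df.to_csv(RESULTS / "sholl.csv", index=False)

print(f"{len(labeled)} neurons eligible, {n_dropped} dropped (<50% end points in section)")
print(neuron_df.groupby("group")["total_length_um"].agg(["mean", "std"]))

anova_rows = []
for col in ("total_length_um", "mean_path_distance_um", "terminal_length_pct",
            "n_endpoints", "n_primary_dendrites"):
    res = nested_anova(NestedDesignData.from_frame(neuron_df, col), strict=False)
    anova_rows.append({"measure": col, "F": res.F, "df1": res.df_num,
                       "df2": res.df_den, "p": res.p})
    print(f"{col}: F({res.df_num},{res.df_den}) = {res.F:.2f}, p = {res.p:.3f}")
pd.DataFrame(anova_rows).to_csv(RESULTS / "morphometry_anova.csv", index=False)

case_means = (sholl_df.groupby(["group", "case", "radius_um"])["intersections"]
              .mean().reset_index())
groups = sorted(case_means.group.unique())
mw_rows = []
for r in (10.0, 20.0, 30.0):
    sub = case_means[case_means.radius_um == r]
    res = mann_whitney_u(sub.loc[sub.group == groups[0], "intersections"],
                         sub.loc[sub.group == groups[1], "intersections"])
    mw_rows.append({"radius_um": r, "U": res.U, "p": res.p_two_sided})
    print(f"Sholl r={r:g}: U = {res.U:g}, p = {res.p_two_sided:.3f}")
pd.DataFrame(mw_rows).to_csv(RESULTS / "sholl_mannwhitney.csv", index=False)
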