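"""Stereology: corrected counts, packing density, volume, total number.

Counts soma profiles per section, applies the Abercrombie correction
(T = 50 μm, h = 10 μm), estimates each case's sampled-series volume by
the Cavalieri principle (every 5th section), and derives packing
density and total labeled-neuron number per case.
"""

import pandas as pd

from _common import RESULTS, COHORT_CONFIG, cohort
from striaquant.stats import NestedDesignData, nested_anova
from striaquant.stereology import (
    ProfileCount,
    abercrombie_correct,
    cavalieri_volume,
    packing_density,
    total_number,
)

T = COHORT_CONFIG.thickness_um
H = 10.0

bundle = cohort()
rows = []
for (group, case), secs in bundle.by_case().items():
    corrected = [
        abercrombie_correct(ProfileCount(len(s.somata), T, H)) for s in secs
    ]
    areas = [s.geometry.area_um2 for s in secs]
    vol = cavalieri_volume(areas, T, secs[0].geometry.sampling_interval)
    density = packing_density(corrected, sum(areas) * T)
    rows.append(
        {
            "group": group,
            "case": case,
            "n_profiles": sum(len(s.somata) for s in secs),
            "corrected_count": round(sum(corrected), 2),
            "density_per_mm3": density,
            "volume_mm3": vol.volume_mm3,
            "total_number": total_number(density, vol.volume_mm3),
        }
    )
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "stereology.csv", index=False)
print(df.groupby("group")[["density_per_mm3", "total_number"]].mean())

res = nested_anova(
    NestedDesignData.from_case_values(
        {g: df.loc[df.group == g, "density_per_mm3"].to_list()
         for g in df.group.unique()}
    )
)
print(f"packing density, nested ANOVA: F({res.df_num},{res.df_den}) = "
      f"{res.F:.2f}, p = {res.p:.3f}")
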