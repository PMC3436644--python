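"""Published case-level group summaries for the early-ethanol rat study
this pipeline models.

The original study reports three desk-recomputable comparisons between
ethanol-exposed (Et) and control (C) animals, each as group mean ±
sample SD over n = 4 cases. Because the balanced nested-design F
depends on case values only through these two moments, the printed
summaries are sufficient inputs for re-computing the F statistics (see
:func:`striaquant.stats.nested_anova_from_moments`).
"""

from __future__ import annotations

#: measure → {group: (case-level mean, case-level sample SD)}
REFERENCE_GROUP_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    # mean Voronoi polygon area per case, μm²
    "polygon_area_um2": {
        "ethanol": (17_026.03, 1_966.24),
        "control": (19_311.67, 1_034.08),
    },
    # image area covered by immunostaining, %
    "stained_fraction_pct": {
        "ethanol": (13.76, 7.84),
        "control": (28.41, 3.10),
    },
    # mean dendritic tree length per neuron, μm
    "tree_length_um": {
        "ethanol": (236.03, 42.15),
        "control": (358.20, 40.31),
    },
}

#: cases per group in the reference design
REFERENCE_N_CASES = 4
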