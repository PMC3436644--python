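"""Shared setup for the analysis drivers: one deterministic cohort and
the output locations. Tables go to results/, bulky binary artifacts
(images, serialized cohorts) to scratch/."""

from pathlib import Path

from striaquant.synthgen import CohortConfig, generate_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

ANALYSIS_SEED = 2026
COHORT_CONFIG = CohortConfig(seed=ANALYSIS_SEED)


def cohort():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return generate_cohort(COHORT_CONFIG)
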