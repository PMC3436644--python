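"""End-to-end orchestration: cohort → spatial + stereology +
morphometry + image quantification → nested inference → report bundle.

``run_pipeline`` consumes either a synthetic cohort (generated from a
seed) or a serialized cohort directory, runs every analysis stage with
the configured parameters, writes tidy CSV tables and a JSON summary
(all F, p, U values keyed by analysis name), and is byte-identical
across runs with the same config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .geometry import SectionGeometry, SomaPointSet
from .imagequant import FrameImage, frame_summary, measure_frame
from .morphometry import (
    DEFAULT_SHOLL_RADII,
    metrics_frame,
    read_swc,
    reconstruction_eligible,
    sholl,
    tree_metrics,
)
from .reference import REFERENCE_GROUP_SUMMARIES, REFERENCE_N_CASES
from .spatial import (
    DEFAULT_EXCLUSION_AREA_UM2,
    DEFAULT_HISTOGRAM_BIN_UM2,
    apply_exclusion,
    area_histogram,
    clustering_summary,
    compute_voronoi,
)
from .stats import (
    DesignError,
    NestedDesignData,
    mann_whitney_u,
    nested_anova,
    nested_anova_from_moments,
)
from .stereology import (
    DEFAULT_MEAN_HEIGHT_UM,
    ProfileCount,
    abercrombie_correct,
    cavalieri_volume,
    packing_density,
    total_number,
)
from .synthgen import CohortBundle, CohortConfig, SectionUnit, generate_cohort

log = logging.getLogger("striaquant")


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: input source, stage parameters, output location.

    All stage parameters default to the values the analyses were
    designed around (60,000 μm² polygon exclusion, 3,000 μm² histogram
    bins, Sholl radii 10/20/30 μm, 50 μm sections sampled every fifth).
    ``abercrombie_h_um`` defaults to a documented convention and should
    be set explicitly for real material.
    """

    mode: str = "synthetic"  # "synthetic" | "directory"
    cohort_config: CohortConfig | None = None
    data_dir: str | Path | None = None
    exclusion_area_um2: float = DEFAULT_EXCLUSION_AREA_UM2
    histogram_bin_um2: float = DEFAULT_HISTOGRAM_BIN_UM2
    sholl_radii: tuple[float, ...] = DEFAULT_SHOLL_RADII
    abercrombie_h_um: float = DEFAULT_MEAN_HEIGHT_UM
    seed: int | None = 0
    out_dir: str | Path = "striaquant_run"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "directory"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.seed is None:
            raise ValueError("seed is mandatory in synthetic mode")
        if self.mode == "directory" and self.data_dir is None:
            raise ValueError("data_dir is required in directory mode")


def load_cohort_dir(data_dir: str | Path) -> list[SectionUnit]:
    """Load a serialized cohort directory (see ``synthgen.write_cohort``)."""
    root = Path(data_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("um_per_pixel", "thickness_um", "sections"):
        if key not in manifest:
            raise ValueError(f"manifest.json: missing field {key!r}")
    sections = []
    for entry in manifest["sections"]:
        sec_dir = root / entry["path"]
        somata_path = sec_dir / entry["somata"]
        if not somata_path.exists():
            raise FileNotFoundError(f"missing soma table {somata_path}")
        pts = pd.read_csv(somata_path)[["x_um", "y_um"]].to_numpy(float)
        geometry = SectionGeometry.rectangle(
            manifest["section_width_um"],
            manifest["section_height_um"],
            thickness_um=manifest["thickness_um"],
            section_index=entry["section_index"],
        )
        neurons = tuple(read_swc(sec_dir / f) for f in entry["neurons"])
        frames = tuple(
            (FrameImage.open(sec_dir / f, manifest["um_per_pixel"]), None)
            for f in entry["frames"]
        )
        sections.append(
            SectionUnit(
                group=entry["group"],
                case=entry["case"],
                section_index=entry["section_index"],
                geometry=geometry,
                somata=SomaPointSet(
                    pts,
                    group_label=entry["group"],
                    case_label=entry["case"],
                    section_index=entry["section_index"],
                ),
                neurons=neurons,
                frames=frames,
            )
        )
    return sections


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the summary dictionary that is also written to
    ``summary.json`` in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        cohort_config = config.cohort_config or CohortConfig(seed=int(config.seed))
        if config.seed is not None and cohort_config.seed != config.seed:
            from dataclasses import replace

            cohort_config = replace(cohort_config, seed=int(config.seed))
        bundle = generate_cohort(cohort_config)
        sections = list(bundle.sections)
        thickness = cohort_config.thickness_um
    else:
        sections = load_cohort_dir(config.data_dir)
        thickness = sections[0].geometry.thickness_um

    by_case: dict[tuple[str, str], list[SectionUnit]] = {}
    for s in sections:
        by_case.setdefault((s.group, s.case), []).append(s)
    log.info("loaded %d sections over %d cases", len(sections), len(by_case))

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "exclusion_area_um2": config.exclusion_area_um2,
            "histogram_bin_um2": config.histogram_bin_um2,
            "sholl_radii_um": list(config.sholl_radii),
            "abercrombie_h_um": config.abercrombie_h_um,
            "thickness_um": thickness,
        },
        "analyses": {},
    }

    # ----------------------------------------------------------------- spatial
    tess_by_case: dict[tuple[str, str], list] = {}
    cell_rows = []
    n_excluded = 0
    for s in sections:
        result = apply_exclusion(
            compute_voronoi(s.somata, s.geometry), config.exclusion_area_um2
        )
        tess_by_case.setdefault((s.group, s.case), []).append(result)
        df = result.to_frame()
        df.insert(0, "group", s.group)
        df.insert(1, "case", s.case)
        df.insert(2, "section", s.section_index)
        cell_rows.append(df)
        n_excluded += int(df["excluded"].sum())
    cells_df = pd.concat(cell_rows, ignore_index=True)
    cells_df.to_csv(out / "voronoi_cells.csv", index=False)
    log.info(
        "voronoi: %d cells, %d excluded by the %.0f um^2 rule",
        len(cells_df),
        n_excluded,
        config.exclusion_area_um2,
    )

    case_df, group_df = clustering_summary(tess_by_case)
    case_df.to_csv(out / "voronoi_case_summary.csv", index=False)
    group_df.to_csv(out / "voronoi_group_summary.csv", index=False)

    pooled = np.concatenate([r.included_areas() for rs in tess_by_case.values() for r in rs])
    hist_counts = np.bincount(
        np.floor(pooled / config.histogram_bin_um2).astype(int)
    )
    pd.DataFrame(
        {
            "bin_left_um2": np.arange(len(hist_counts)) * config.histogram_bin_um2,
            "count": hist_counts,
        }
    ).to_csv(out / "voronoi_histogram.csv", index=False)

    anova_area = nested_anova(
        NestedDesignData.from_case_values(
            {
                g: case_df.loc[case_df.group == g, "mean_area_um2"].to_list()
                for g in case_df.group.unique()
            }
        )
    )
    summary["analyses"]["polygon_area"] = {
        "group_summary": group_df.set_index("group")["mean_area_um2"].to_dict(),
        "mean_cv": group_df.set_index("group")["mean_cv"].to_dict(),
        "F": anova_area.F,
        "df": [anova_area.df_num, anova_area.df_den],
        "p": anova_area.p,
        "n_cells": int(len(cells_df)),
        "n_excluded": n_excluded,
    }

    # -------------------------------------------------------------- stereology
    stereo_rows = []
    for (group, case), secs in by_case.items():
        corrected = [
            abercrombie_correct(
                ProfileCount(
                    n_profiles=len(s.somata),
                    thickness_um=thickness,
                    mean_height_um=config.abercrombie_h_um,
                )
            )
            for s in secs
        ]
        areas = [s.geometry.area_um2 for s in secs]
        sampled_volume = sum(areas) * thickness
        vol = cavalieri_volume(
            areas,
            thickness_um=thickness,
            sampling_interval=secs[0].geometry.sampling_interval,
        )
        density = packing_density(corrected, sampled_volume)
        stereo_rows.append(
            {
                "group": group,
                "case": case,
                "n_profiles": sum(len(s.somata) for s in secs),
                "corrected_count": sum(corrected),
                "density_per_mm3": density,
                "volume_mm3": vol.volume_mm3,
                "total_number": total_number(density, vol.volume_mm3),
            }
        )
    stereo_df = pd.DataFrame(stereo_rows)
    stereo_df.to_csv(out / "stereology.csv", index=False)
    stereo_anovas = {}
    for col in ("density_per_mm3", "volume_mm3", "total_number"):
        data = NestedDesignData.from_case_values(
            {
                g: stereo_df.loc[stereo_df.group == g, col].to_list()
                for g in stereo_df.group.unique()
            }
        )
        try:
            res = nested_anova(data)
            stereo_anovas[col] = {
                "F": res.F,
                "df": [res.df_num, res.df_den],
                "p": res.p,
            }
        except DesignError as exc:  # e.g. identical volumes across cases
            stereo_anovas[col] = {"F": None, "p": None, "note": str(exc)}
    summary["analyses"]["stereology"] = stereo_anovas

    # ------------------------------------------------------------- morphometry
    labeled_neurons = []
    sholl_rows = []
    n_ineligible = 0
    for s in sections:
        for i, neuron in enumerate(s.neurons):
            if not reconstruction_eligible(neuron, thickness):
                n_ineligible += 1
                continue
            labels = {
                "group": s.group,
                "case": s.case,
                "section": s.section_index,
                "neuron": i,
            }
            labeled_neurons.append((labels, neuron))
            profile = sholl(neuron, config.sholl_radii)
            for r, n_int in zip(profile.radii_um, profile.intersections):
                sholl_rows.append({**labels, "radius_um": r, "intersections": n_int})
    log.info(
        "morphometry: %d neurons eligible, %d excluded by the 50%% end-point rule",
        len(labeled_neurons),
        n_ineligible,
    )
    neuron_df, dendrite_df = metrics_frame(labeled_neurons, thickness)
    neuron_df.to_csv(out / "neuron_metrics.csv", index=False)
    dendrite_df.to_csv(out / "dendrite_metrics.csv", index=False)
    sholl_df = pd.DataFrame(sholl_rows)
    sholl_df.to_csv(out / "sholl.csv", index=False)

    morpho = {}
    for col in (
        "total_length_um",
        "mean_path_distance_um",
        "terminal_length_pct",
        "n_endpoints",
        "n_primary_dendrites",
    ):
        # eligibility filtering can unbalance the neuron-level design
        try:
            res = nested_anova(
                NestedDesignData.from_frame(neuron_df, col), strict=False
            )
            morpho[col] = {"F": res.F, "df": [res.df_num, res.df_den], "p": res.p}
        except DesignError as exc:
            morpho[col] = {"F": None, "p": None, "note": str(exc)}
    # complete dendrites only, per the per-dendrite criterion
    complete = dendrite_df[dendrite_df.complete]
    if len(complete) and complete.groupby(["group", "case"]).ngroups == len(
        by_case
    ):
        res = nested_anova(
            NestedDesignData.from_frame(complete, "length_um"), strict=False
        )
        morpho["dendrite_length_um"] = {
            "F": res.F,
            "df": [res.df_num, res.df_den],
            "p": res.p,
        }
    summary["analyses"]["morphometry"] = morpho
    summary["analyses"]["morphometry"]["n_neurons"] = len(labeled_neurons)
    summary["analyses"]["morphometry"]["n_ineligible"] = n_ineligible

    # Sholl: Mann–Whitney on case means at each radius
    sholl_tests = {}
    groups = sorted(sholl_df.group.unique())
    case_means = (
        sholl_df.groupby(["group", "case", "radius_um"])["intersections"]
        .mean()
        .reset_index()
    )
    for r in config.sholl_radii:
        sub = case_means[case_means.radius_um == r]
        res = mann_whitney_u(
            sub.loc[sub.group == groups[0], "intersections"],
            sub.loc[sub.group == groups[1], "intersections"],
        )
        sholl_tests[f"r{r:g}"] = {"U": res.U, "p": res.p_two_sided}
    summary["analyses"]["sholl"] = sholl_tests

    # --------------------------------------------------------------- imagequant
    frame_rows = []
    fractions_by_case: dict[tuple[str, str], list[float]] = {}
    for s in sections:
        for f_idx, (img, _mask) in enumerate(s.frames):
            t, pct = measure_frame(img)
            frame_rows.append(
                {
                    "group": s.group,
                    "case": s.case,
                    "section": s.section_index,
                    "frame": f_idx,
                    "threshold": t,
                    "pct_stained": pct,
                }
            )
            fractions_by_case.setdefault((s.group, s.case), []).append(pct)
    if frame_rows:
        frames_df = pd.DataFrame(frame_rows)
        frames_df.to_csv(out / "stained_fractions.csv", index=False)
        fcase_df, fgroup_df = frame_summary(fractions_by_case)
        fcase_df.to_csv(out / "stained_fraction_case_summary.csv", index=False)
        res = nested_anova(
            NestedDesignData.from_case_values(
                {
                    g: fcase_df.loc[fcase_df.group == g, "pct_stained"].to_list()
                    for g in fcase_df.group.unique()
                }
            )
        )
        summary["analyses"]["stained_fraction"] = {
            "group_summary": fgroup_df.set_index("group")["mean_pct"].to_dict(),
            "F": res.F,
            "df": [res.df_num, res.df_den],
            "p": res.p,
        }

    summary = _round_floats(summary)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("report written to %s", out)
    return summary


def reproduce_reference_statistics() -> pd.DataFrame:
    """Re-compute the three published nested-design F statistics from the
    printed case-level group summaries (mean ± SD, n = 4 per group).

    Returns a table with one row per measure: F, degrees of freedom and
    the two-sided p-value.
    """
    rows = []
    for measure, moments in REFERENCE_GROUP_SUMMARIES.items():
        res = nested_anova_from_moments(moments, REFERENCE_N_CASES)
        rows.append(
            {
                "measure": measure,
                "F": res.F,
                "df1": res.df_num,
                "df2": res.df_den,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
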