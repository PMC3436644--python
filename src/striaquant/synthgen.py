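"""Synthetic histological material with known ground truth.

Every analysis stage in this package was designed for charted sections,
camera-lucida reconstructions and microphotographs. This module
generates stand-ins for all three with known generating parameters, so
each estimator can be validated by parameter recovery:

* soma point patterns — homogeneous Poisson (complete spatial
  randomness) or a Thomas cluster process (Poisson parents, Poisson
  numbers of Gaussian-displaced offspring), the simplest stationary
  process reproducing the clustered arrangement of sparse interneuron
  populations while keeping a closed-form intensity
  (``parent_intensity × offspring_mean``);
* dendritic trees — a depth-limited stochastic bifurcation process with
  2–8 primary dendrites, whose expected segment count per primary,
  ``Σ_{d<max_depth} (2·branch_probability)^d``, makes expected total
  tree length derivable in closed form;
* section images — polylines rasterised onto a noisy bright-field
  background, returned together with the exact foreground mask;
* cohorts — two groups × cases × sections bundles with per-case random
  effects, serialisable to a directory of CSV / SWC / PNG files with a
  JSON manifest.

Every generator is a pure function of its parameters and seed; no
global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import shapely
from skimage.draw import disk, line

from .geometry import GeometryError, SectionGeometry, SomaPointSet
from .imagequant import FrameImage
from .morphometry import ReconstructedNeuron, write_swc

# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class PointPatternParams:
    """Parameters of a planar soma point process (all rates per μm²)."""

    # default overall intensity ≈ 5.4e-5 /μm², the reciprocal of the
    # ~18,500 μm² mean free-space polygon observed around these neurons
    process_kind: Literal["poisson", "thomas"] = "thomas"
    parent_intensity: float = 5.4e-6
    offspring_mean: float = 10.0
    offspring_sd: float = 150.0
    poisson_intensity: float = 5.4e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process_kind not in ("poisson", "thomas"):
            raise ValueError(f"unknown process_kind {self.process_kind!r}")
        if min(self.parent_intensity, self.offspring_mean, self.poisson_intensity) < 0:
            raise ValueError("intensities must be >= 0")
        if self.process_kind == "thomas" and self.offspring_sd <= 0:
            raise ValueError("offspring_sd must be > 0 for the thomas process")

    @property
    def intensity(self) -> float:
        """Expected points per μm²."""
        if self.process_kind == "poisson":
            return self.poisson_intensity
        return self.parent_intensity * self.offspring_mean


@dataclass(frozen=True)
class TreeGrowthParams:
    """Parameters of the stochastic dendritic growth process.

    Growth starts with ``n_primary`` dendrites drawn uniformly from
    ``n_primary_range`` (a sub-interval of [2, 8], the observed range of
    aspiny varicose dendrites per soma). Each dendrite is a chain of
    segments of Gaussian length; after every segment the tip bifurcates
    with ``branch_probability`` until ``max_depth`` branch orders.
    """

    n_primary_range: tuple[int, int] = (2, 8)
    branch_probability: float = 0.5
    segment_length_mean: float = 23.880
    segment_length_sd: float = 5.0
    max_depth: int = 3
    seed: int = 0
    angle_jitter_rad: float = 0.35
    branch_angle_rad: float = 0.6
    z_step_sd: float = 1.5

    def __post_init__(self) -> None:
        lo, hi = self.n_primary_range
        if not (2 <= lo <= hi <= 8):
            raise ValueError("n_primary_range must lie within [2, 8]")
        if not 0 <= self.branch_probability <= 1:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.segment_length_mean <= 0:
            raise ValueError("segment_length_mean must be > 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")

    def expected_segments_per_primary(self) -> float:
        """Closed-form E[#segments] per primary dendrite."""
        r = 2 * self.branch_probability
        if r == 1:
            return float(self.max_depth)
        return float((1 - r**self.max_depth) / (1 - r))

    def expected_tree_length(self) -> float:
        """Closed-form E[total length] per neuron (μm)."""
        lo, hi = self.n_primary_range
        return (
            (lo + hi) / 2
            * self.expected_segments_per_primary()
            * self.segment_length_mean
        )


def _tree_params_for_mean_length(
    mean_length_um: float, base: TreeGrowthParams | None = None
) -> TreeGrowthParams:
    base = base or TreeGrowthParams()
    lo, hi = base.n_primary_range
    seg_mean = mean_length_um / ((lo + hi) / 2 * base.expected_segments_per_primary())
    return replace(base, segment_length_mean=seg_mean)


@dataclass(frozen=True)
class CohortConfig:
    """Layout and generating parameters of a two-group synthetic cohort.

    Defaults mirror the design the analyses assume: two groups of four
    animals, four sections per animal, five reconstructed neurons and
    two sampling frames per section. ``between_case_cv`` scales each
    case's segment-length mean by a Gaussian factor, creating the
    between-animal variance a nested design exists to absorb.
    """

    group_labels: tuple[str, str] = ("ethanol", "control")
    cases_per_group: int = 4
    sections_per_case: int = 4
    neurons_per_section: int = 5
    frames_per_section: int = 2
    group_tree_params: dict[str, TreeGrowthParams] = field(default_factory=dict)
    group_pattern_params: dict[str, PointPatternParams] = field(default_factory=dict)
    between_case_cv: float = 0.07
    section_width_um: float = 1000.0
    section_height_um: float = 1000.0
    thickness_um: float = 50.0
    um_per_pixel: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_labels) != 2:
            raise ValueError("exactly two groups")
        if self.cases_per_group < 2:
            raise ValueError("cases_per_group must be >= 2")
        if self.sections_per_case < 1:
            raise ValueError("sections_per_case must be >= 1")
        if not self.group_tree_params:
            object.__setattr__(
                self,
                "group_tree_params",
                {
                    self.group_labels[0]: _tree_params_for_mean_length(236.03),
                    self.group_labels[1]: _tree_params_for_mean_length(358.20),
                },
            )
        if not self.group_pattern_params:
            object.__setattr__(
                self,
                "group_pattern_params",
                {g: PointPatternParams() for g in self.group_labels},
            )


# ---------------------------------------------------------------------------
# Point patterns


def generate_soma_pattern(
    params: PointPatternParams,
    geometry: SectionGeometry,
    rng: np.random.Generator | None = None,
    **labels,
) -> SomaPointSet:
    """Sample a soma point pattern inside the section boundary.

    The Thomas process is made stationary over the section by placing
    parents in the bounding box dilated by 4 offspring SDs, so the
    expected count inside the boundary is
    ``parent_intensity × boundary_area × offspring_mean``.
    """
    if geometry.area_um2 <= 0:  # SectionGeometry already enforces this
        raise GeometryError("degenerate boundary")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    minx, miny, maxx, maxy = geometry.boundary.bounds

    def _keep_inside(xy: np.ndarray) -> np.ndarray:
        if len(xy) == 0:
            return xy.reshape(0, 2)
        inside = shapely.contains_xy(geometry.boundary, xy[:, 0], xy[:, 1])
        return xy[inside]

    if params.process_kind == "poisson":
        bbox_area = (maxx - minx) * (maxy - miny)
        n = rng.poisson(params.poisson_intensity * bbox_area)
        xy = np.column_stack(
            [rng.uniform(minx, maxx, n), rng.uniform(miny, maxy, n)]
        )
        pts = _keep_inside(xy)
    else:
        pad = 4.0 * params.offspring_sd
        w, h = (maxx - minx) + 2 * pad, (maxy - miny) + 2 * pad
        n_parents = rng.poisson(params.parent_intensity * w * h)
        parents = np.column_stack(
            [
                rng.uniform(minx - pad, maxx + pad, n_parents),
                rng.uniform(miny - pad, maxy + pad, n_parents),
            ]
        )
        n_off = rng.poisson(params.offspring_mean, n_parents)
        centers = np.repeat(parents, n_off, axis=0)
        xy = centers + rng.normal(0.0, params.offspring_sd, centers.shape)
        pts = _keep_inside(xy)
    pts = np.unique(pts, axis=0)  # duplicate coordinates have probability 0
    return SomaPointSet(points=pts, **labels)


# ---------------------------------------------------------------------------
# Dendritic trees


def generate_neuron(
    params: TreeGrowthParams,
    soma_xy: Sequence[float],
    rng: np.random.Generator | None = None,
    soma_z: float = 25.0,
) -> ReconstructedNeuron:
    """Grow one dendritic tree from a soma position.

    Returns a rooted, acyclic reconstruction whose primary-dendrite
    count lies in ``n_primary_range`` and whose segment lengths are all
    positive (Gaussian draws are resampled into (0, ∞)).
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    lo, hi = params.n_primary_range
    n_primary = int(rng.integers(lo, hi + 1))

    coords = [[float(soma_xy[0]), float(soma_xy[1]), float(soma_z)]]
    parents = [-1]
    types = [1]

    def draw_length() -> float:
        for _ in range(100):
            val = rng.normal(params.segment_length_mean, params.segment_length_sd)
            if val > 0:
                return float(val)
        return params.segment_length_mean  # pragma: no cover - pathological sd

    base_angle = rng.uniform(0, 2 * np.pi)
    # (parent index, direction, depth) of tips still growing
    tips: list[tuple[int, float, int]] = []
    for k in range(n_primary):
        angle = base_angle + 2 * np.pi * k / n_primary + rng.normal(
            0, params.angle_jitter_rad
        )
        tips.append((0, angle, 1))

    while tips:
        parent, angle, depth = tips.pop(0)
        seg = draw_length()
        angle += rng.normal(0, params.angle_jitter_rad)
        px, py, pz = coords[parent]
        node = [
            px + seg * np.cos(angle),
            py + seg * np.sin(angle),
            pz + rng.normal(0, params.z_step_sd),
        ]
        coords.append(node)
        parents.append(parent)
        types.append(3)
        idx = len(coords) - 1
        if depth < params.max_depth and rng.random() < params.branch_probability:
            half = params.branch_angle_rad / 2
            tips.append((idx, angle - half, depth + 1))
            tips.append((idx, angle + half, depth + 1))

    return ReconstructedNeuron(
        coords=np.array(coords),
        parents=np.array(parents),
        node_types=np.array(types),
    )


# ---------------------------------------------------------------------------
# Image rendering


def render_section_image(
    neurons: Sequence[ReconstructedNeuron],
    width_um: float,
    height_um: float,
    um_per_pixel: float = 1.0,
    fg_intensity: int = 60,
    bg_intensity: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    soma_radius_um: float = 5.0,
) -> tuple[FrameImage, np.ndarray]:
    """Rasterise reconstructions into a bright-field-like frame.

    Returns ``(image, mask)`` where ``mask`` is the exact boolean
    foreground (drawn-pixel) raster — the ground truth for validating
    threshold-based area-fraction measurements.
    """
    if um_per_pixel <= 0:
        raise GeometryError("um_per_pixel must be > 0")
    if fg_intensity == bg_intensity:
        raise ValueError("fg_intensity must differ from bg_intensity")
    n_rows = round(height_um / um_per_pixel)
    n_cols = round(width_um / um_per_pixel)
    if n_rows <= 0 or n_cols <= 0:
        raise GeometryError("zero-size frame")

    mask = np.zeros((n_rows, n_cols), dtype=bool)

    def to_px(x: float, y: float) -> tuple[int, int]:
        return int(round(y / um_per_pixel)), int(round(x / um_per_pixel))

    for neuron in neurons:
        r0, c0 = to_px(neuron.coords[0, 0], neuron.coords[0, 1])
        rr, cc = disk((r0, c0), max(soma_radius_um / um_per_pixel, 1.0))
        keep = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
        mask[rr[keep], cc[keep]] = True
        for i in range(1, neuron.n_nodes):
            ra, ca = to_px(*neuron.coords[neuron.parents[i], :2])
            rb, cb = to_px(*neuron.coords[i, :2])
            rr, cc = line(ra, ca, rb, cb)
            keep = (rr >= 0) & (rr < n_rows) & (cc >= 0) & (cc < n_cols)
            mask[rr[keep], cc[keep]] = True

    rng = np.random.default_rng(seed)
    img = np.full((n_rows, n_cols), float(bg_intensity))
    img[mask] = float(fg_intensity)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return FrameImage(pixels=img, um_per_pixel=um_per_pixel), mask


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class SectionUnit:
    group: str
    case: str
    section_index: int
    geometry: SectionGeometry
    somata: SomaPointSet
    neurons: tuple[ReconstructedNeuron, ...]
    frames: tuple[tuple[FrameImage, np.ndarray], ...]


@dataclass(frozen=True)
class CohortBundle:
    config: CohortConfig
    sections: tuple[SectionUnit, ...]
    case_tree_params: dict[tuple[str, str], TreeGrowthParams]

    def by_case(self) -> dict[tuple[str, str], list[SectionUnit]]:
        out: dict[tuple[str, str], list[SectionUnit]] = {}
        for s in self.sections:
            out.setdefault((s.group, s.case), []).append(s)
        return out


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a complete two-group cohort, reproducible from its seed.

    Produces ``2 × cases_per_group × sections_per_case`` section units,
    each holding the section geometry, a soma point pattern,
    ``neurons_per_section`` reconstructions grown at somata sampled
    within the section, and ``frames_per_section`` rendered frames with
    ground-truth masks.
    """
    root_ss = np.random.SeedSequence(config.seed)
    sections: list[SectionUnit] = []
    case_tree_params: dict[tuple[str, str], TreeGrowthParams] = {}
    group_streams = root_ss.spawn(2)

    frame_w = config.section_width_um
    frame_h = config.section_height_um

    for g_idx, group in enumerate(config.group_labels):
        tree_base = config.group_tree_params[group]
        pattern = config.group_pattern_params[group]
        case_streams = group_streams[g_idx].spawn(config.cases_per_group)
        for c_idx in range(config.cases_per_group):
            case = f"{group}_{c_idx + 1}"
            case_rng = np.random.default_rng(case_streams[c_idx])
            scale = max(
                float(case_rng.normal(1.0, config.between_case_cv)), 0.2
            )
            tree_params = replace(
                tree_base,
                segment_length_mean=tree_base.segment_length_mean * scale,
            )
            case_tree_params[(group, case)] = tree_params
            for s_idx in range(config.sections_per_case):
                geometry = SectionGeometry.rectangle(
                    config.section_width_um,
                    config.section_height_um,
                    thickness_um=config.thickness_um,
                    section_index=s_idx,
                )
                somata = generate_soma_pattern(
                    pattern,
                    geometry,
                    rng=case_rng,
                    group_label=group,
                    case_label=case,
                    section_index=s_idx,
                )
                neurons = []
                for _ in range(config.neurons_per_section):
                    margin = 0.1
                    soma_xy = (
                        case_rng.uniform(
                            margin * frame_w, (1 - margin) * frame_w
                        ),
                        case_rng.uniform(
                            margin * frame_h, (1 - margin) * frame_h
                        ),
                    )
                    neurons.append(
                        generate_neuron(
                            tree_params,
                            soma_xy,
                            rng=case_rng,
                            soma_z=config.thickness_um / 2,
                        )
                    )
                frames = []
                for f_idx in range(config.frames_per_section):
                    img, fmask = render_section_image(
                        neurons,
                        width_um=config.section_width_um,
                        height_um=config.section_height_um,
                        um_per_pixel=config.um_per_pixel,
                        noise_sd=8.0,
                        seed=int(case_rng.integers(0, 2**31 - 1)),
                    )
                    frames.append((img, fmask))
                sections.append(
                    SectionUnit(
                        group=group,
                        case=case,
                        section_index=s_idx,
                        geometry=geometry,
                        somata=somata,
                        neurons=tuple(neurons),
                        frames=tuple(frames),
                    )
                )
    return CohortBundle(
        config=config,
        sections=tuple(sections),
        case_tree_params=case_tree_params,
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Serialise a cohort as a directory tree of plain files.

    Per section: a soma CSV (columns x_um, y_um), one SWC per neuron,
    one 8-bit grayscale PNG per frame; plus a single ``manifest.json``
    describing labels, scale and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": bundle.config.seed,
        "um_per_pixel": bundle.config.um_per_pixel,
        "thickness_um": bundle.config.thickness_um,
        "section_width_um": bundle.config.section_width_um,
        "section_height_um": bundle.config.section_height_um,
        "group_labels": list(bundle.config.group_labels),
        "sections": [],
    }
    for s in bundle.sections:
        rel = Path(s.group) / s.case / f"section_{s.section_index:02d}"
        sec_dir = out / rel
        sec_dir.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            sec_dir / "somata.csv",
            s.somata.points,
            delimiter=",",
            header="x_um,y_um",
            comments="",
            fmt="%.6f",
        )
        swc_files = []
        for i, neuron in enumerate(s.neurons):
            name = f"neuron_{i:02d}.swc"
            write_swc(neuron, sec_dir / name)
            swc_files.append(name)
        frame_files = []
        for i, (img, _) in enumerate(s.frames):
            name = f"frame_{i:02d}.png"
            img.save(sec_dir / name)
            frame_files.append(name)
        manifest["sections"].append(
            {
                "group": s.group,
                "case": s.case,
                "section_index": s.section_index,
                "path": str(rel),
                "somata": "somata.csv",
                "neurons": swc_files,
                "frames": frame_files,
            }
        )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
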