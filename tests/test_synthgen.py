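"""Synthetic generators: point patterns, trees, images, cohorts."""

import filecmp
from pathlib import Path

import numpy as np
import pytest
import shapely

from striaquant.geometry import SectionGeometry
from striaquant.imagequant import measure_frame
from striaquant.morphometry import tree_metrics
from striaquant.synthgen import (
    CohortConfig,
    PointPatternParams,
    TreeGrowthParams,
    generate_cohort,
    generate_neuron,
    generate_soma_pattern,
    render_section_image,
    write_cohort,
)


class TestSomaPattern:
    def test_zero_intensity_empty(self, square_section):
        p = PointPatternParams(process_kind="poisson", poisson_intensity=0.0, seed=1)
        assert len(generate_soma_pattern(p, square_section)) == 0

    def test_same_seed_identical(self, square_section):
        p = PointPatternParams(process_kind="thomas", seed=42)
        a = generate_soma_pattern(p, square_section)
        b = generate_soma_pattern(p, square_section)
        assert np.array_equal(a.points, b.points)

    @pytest.mark.parametrize("kind", ["poisson", "thomas"])
    def test_all_points_inside_boundary(self, kind, square_section):
        p = PointPatternParams(process_kind=kind, seed=3)
        sp = generate_soma_pattern(p, square_section)
        assert len(sp) > 0
        inside = shapely.contains_xy(
            square_section.boundary, sp.points[:, 0], sp.points[:, 1]
        )
        assert np.all(inside)

    def test_thomas_expected_count(self, square_section):
        # E[N] = parent_intensity × area × offspring_mean = 100
        p = PointPatternParams(
            process_kind="thomas",
            parent_intensity=1e-5,
            offspring_mean=10.0,
            offspring_sd=20.0,
        )
        counts = []
        for seed in range(1000):
            sp = generate_soma_pattern(
                PointPatternParams(**{**p.__dict__, "seed": seed}), square_section
            )
            counts.append(len(sp))
        counts = np.asarray(counts, float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 100.0) < 3 * se

    def test_dispersion_poisson_vs_thomas(self):
        # per-quadrat variance/mean ratio: ≈ 1 under CSR, > 1 when clustered
        geo = SectionGeometry.rectangle(4000, 4000)
        lam = 5e-5

        def quadrat_ratio(params, seed):
            sp = generate_soma_pattern(
                PointPatternParams(**{**params.__dict__, "seed": seed}), geo
            )
            counts, _, _ = np.histogram2d(
                sp.points[:, 0], sp.points[:, 1], bins=8, range=[[0, 4000], [0, 4000]]
            )
            return counts.var() / counts.mean()

        poisson = PointPatternParams(process_kind="poisson", poisson_intensity=lam)
        thomas = PointPatternParams(
            process_kind="thomas",
            parent_intensity=lam / 10,
            offspring_mean=10.0,
            offspring_sd=40.0,
        )
        r_poisson = np.mean([quadrat_ratio(poisson, s) for s in range(10)])
        r_thomas = np.mean([quadrat_ratio(thomas, s) for s in range(10)])
        assert 0.8 < r_poisson < 1.2
        assert r_thomas > 1.5

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            PointPatternParams(process_kind="thomas", offspring_sd=0.0)
        with pytest.raises(ValueError):
            PointPatternParams(process_kind="poisson", poisson_intensity=-1.0)


class TestNeuronGrowth:
    def test_no_branching_single_endpoint_per_dendrite(self):
        p = TreeGrowthParams(branch_probability=0.0, seed=5)
        n = generate_neuron(p, (0.0, 0.0))
        m = tree_metrics(n)
        assert all(d.n_endpoints == 1 for d in m.per_dendrite)

    def test_forced_primary_range(self):
        p = TreeGrowthParams(n_primary_range=(3, 3), seed=9)
        assert tree_metrics(generate_neuron(p, (0, 0))).n_primary_dendrites == 3

    def test_primary_count_within_range(self):
        p = TreeGrowthParams(n_primary_range=(2, 8))
        for seed in range(30):
            rng = np.random.default_rng(seed)
            m = tree_metrics(generate_neuron(p, (0, 0), rng=rng))
            assert 2 <= m.n_primary_dendrites <= 8

    def test_all_segment_lengths_positive(self):
        p = TreeGrowthParams(segment_length_mean=5.0, segment_length_sd=10.0, seed=2)
        n = generate_neuron(p, (0, 0))
        assert np.all(n.edge_lengths[1:] > 0)

    def test_same_seed_identical(self):
        p = TreeGrowthParams(seed=11)
        a, b = generate_neuron(p, (3, 4)), generate_neuron(p, (3, 4))
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.parents, b.parents)

    def test_mean_tree_length_tracks_closed_form(self):
        # E[L] = E[n_primary] · Σ_{d<D} (2p)^d · seg_mean; Monte-Carlo check
        p = TreeGrowthParams(
            n_primary_range=(2, 8),
            branch_probability=0.4,
            segment_length_mean=20.0,
            segment_length_sd=3.0,
            max_depth=3,
        )
        lengths = [
            tree_metrics(
                generate_neuron(p, (0, 0), rng=np.random.default_rng(s))
            ).total_length_um
            for s in range(500)
        ]
        lengths = np.asarray(lengths)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - p.expected_tree_length()) < 3 * se

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TreeGrowthParams(n_primary_range=(1, 4))
        with pytest.raises(ValueError):
            TreeGrowthParams(branch_probability=1.5)


class TestRenderImage:
    def test_no_neurons_uniform_background(self):
        img, mask = render_section_image([], 100, 80, 1.0, noise_sd=0.0)
        assert img.pixels.shape == (80, 100)
        assert np.all(img.pixels == 200)
        assert mask.sum() == 0

    def test_dimensions_follow_scale(self):
        img, _ = render_section_image([], 640, 380, 2.0)
        assert img.pixels.shape == (190, 320)

    def test_mask_matches_drawn_pixels_exactly(self):
        p = TreeGrowthParams(seed=8)
        n = generate_neuron(p, (100, 100))
        img, mask = render_section_image([n], 200, 200, 1.0, noise_sd=0.0)
        assert np.array_equal(img.pixels == 60, mask)

    def test_threshold_recovers_mask_fraction(self):
        p = TreeGrowthParams(seed=13)
        neurons = [generate_neuron(p, (x, 100), rng=np.random.default_rng(x))
                   for x in (60, 140)]
        img, mask = render_section_image(neurons, 200, 200, 1.0, noise_sd=0.0)
        _, pct = measure_frame(img)
        assert pct == pytest.approx(100 * mask.mean(), abs=1.0)

    def test_zero_size_frame_rejected(self):
        with pytest.raises(Exception):
            render_section_image([], 0, 100, 1.0)

    def test_equal_intensities_rejected(self):
        with pytest.raises(ValueError):
            render_section_image([], 10, 10, 1.0, fg_intensity=99, bg_intensity=99)


class TestCohort:
    def test_default_layout_counts(self):
        cfg = CohortConfig(seed=0, frames_per_section=0)
        bundle = generate_cohort(cfg)
        assert len(bundle.sections) == 2 * 4 * 4
        assert all(len(s.neurons) == 5 for s in bundle.sections)
        assert len(bundle.by_case()) == 8

    def test_group_lengths_track_targets(self):
        cfg = CohortConfig(seed=3, frames_per_section=0, between_case_cv=0.0)
        bundle = generate_cohort(cfg)
        by_group = {}
        for s in bundle.sections:
            by_group.setdefault(s.group, []).extend(
                tree_metrics(n).total_length_um for n in s.neurons
            )
        means = {g: np.mean(v) for g, v in by_group.items()}
        assert means["ethanol"] == pytest.approx(236.0, rel=0.15)
        assert means["control"] == pytest.approx(358.2, rel=0.15)
        assert means["ethanol"] < means["control"]

    def test_serialization_byte_identical(self, tmp_path):
        cfg = CohortConfig(
            seed=7, cases_per_group=2, sections_per_case=1, frames_per_section=1,
            section_width_um=300.0, section_height_um=300.0,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(cfg), d1)
        write_cohort(generate_cohort(cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(group_labels=("only",))
        with pytest.raises(ValueError):
            CohortConfig(cases_per_group=1)
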