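"""Outline extraction, PERPAR, per-ring statistics and time series."""

import numpy as np
import pandas as pd
import pytest

from raypar import (
    SectionSpec,
    WoodModelConfig,
    assemble_time_series,
    compute_perpar,
    cut_section,
    extract_outlines,
    generate_wood,
    ring_metrics,
)
from raypar.metrics import MetricsError, TimeSeries

from conftest import make_model, make_section_image


class TestExtractOutlines:
    def test_rectangular_ray_arithmetic(self):
        """150 µm (axial) x 20 µm ray on the tangential plane: area 3000 µm²,
        height 150 µm, derived width 20 µm."""
        labels = np.zeros((300, 100), dtype=np.int32)
        labels[50:200, 40:60] = 1  # 150 rows x 20 cols at 1 µm/px
        img = make_section_image(labels, pixel_size_um=1.0, plane="tangential")
        out = extract_outlines(img)
        assert len(out) == 1
        row = out.iloc[0]
        assert row.area_um2 == 3000.0
        assert row.height_um == 150.0
        assert row.width_um == pytest.approx(20.0)
        assert not row.touches_edge

    def test_lens_ray_width_follows_area_over_height(self, neutral_config):
        """For a spindle (p=1) of h=150, w=30: width = area/height = 2/3 * 30."""
        cfg = neutral_config.replace(n_rings=1, ring_width_mean=1.0, ray_height_mean=150.0, ray_width_mean=30.0)
        ray = dict(ray_id=1, t_center=1.0, z_center=1.0, r_init=0.0, r_term=1.0, height_um=150.0, width_um=30.0, lens_p=1.0)
        model = make_model(cfg, [ray])
        img = cut_section(model, SectionSpec(plane="tangential", offset=0.5, thickness=0.0, resolution=0.5))
        out = extract_outlines(img)
        assert out.iloc[0].width_um == pytest.approx(20.0, rel=0.02)
        assert out.iloc[0].height_um == pytest.approx(150.0, abs=1.0)

    def test_empty_image(self):
        img = make_section_image(np.zeros((50, 50), dtype=np.int32))
        assert len(extract_outlines(img)) == 0

    def test_edge_touching_flagged(self):
        labels = np.zeros((50, 50), dtype=np.int32)
        labels[0:10, 20:25] = 3
        img = make_section_image(labels)
        out = extract_outlines(img)
        assert bool(out.iloc[0].touches_edge)


class TestComputePerpar:
    def test_trivial_fractions(self):
        zeros = make_section_image(np.zeros((20, 20), dtype=np.int32))
        ones = make_section_image(np.ones((20, 20), dtype=np.int32))
        half = np.zeros((20, 20), dtype=np.int32)
        half[:10] = 1
        assert compute_perpar(zeros) == 0.0
        assert compute_perpar(ones) == 100.0
        assert compute_perpar(make_section_image(half)) == 50.0

    def test_zero_area_region_raises(self):
        img = make_section_image(np.zeros((20, 20), dtype=np.int32))
        with pytest.raises(MetricsError, match="zero area"):
            compute_perpar(img, region=((0.5, 0.5), (0.0, 0.02)))


def _manual_cross_image():
    """3 x 2 mm cross image at 10 µm/px: rings [0,1) and [1,3) mm with
    latewood onsets at 0.7 and 2.4 mm."""
    labels = np.zeros((300, 200), dtype=np.int32)
    # three initiating rays in ring 1 (inner ends at 1.2, 1.5, 2.5 mm)
    labels[120:300, 20:23] = 1
    labels[150:300, 60:63] = 2
    labels[250:300, 100:103] = 3  # latewood (>= 2.4)
    # a full-span ray: touches both radial edges, never initiating
    labels[:, 140:143] = 4
    # a disappearing ray in ring 0: 0.2 -> 0.8 mm
    labels[20:80, 180:183] = 5
    return make_section_image(
        labels,
        pixel_size_um=10.0,
        plane="cross",
        ring_borders=np.array([0.0, 1.0, 3.0]),
        latewood_onsets=np.array([0.7, 2.4]),
    )


class TestRingMetrics:
    def test_manual_initiation_counts(self):
        img = _manual_cross_image()
        rings = ring_metrics(img)
        r1 = rings.iloc[1]
        assert r1.newray_count == 3
        assert r1.newray_per_mm == pytest.approx(1.5)  # 3 rays over 2 mm width
        assert r1.newray_early_count == 2 and r1.newray_late_count == 1
        # the short ring-0 ray both initiates (inner end 0.2 mm) and
        # disappears (outer end 0.8 mm) within the ring
        assert rings.iloc[0].newray_count == 1
        assert rings.iloc[0].disappearing_count == 1
        # zone split sums to the total
        assert (rings.newray_early_count + rings.newray_late_count == rings.newray_count).all()

    def test_perpar_conservation(self):
        """Whole-image PERPAR equals the ring-area-weighted mean of per-ring
        PERPAR (exactly, since rows partition the image)."""
        img = _manual_cross_image()
        rings = ring_metrics(img)
        weights = rings.ring_width_mm / rings.ring_width_mm.sum()
        assert float((rings.perpar * weights).sum()) == pytest.approx(compute_perpar(img), abs=0.02)

    def test_requires_cross_plane(self):
        img = make_section_image(np.zeros((10, 10), dtype=np.int32), plane="tangential")
        with pytest.raises(MetricsError, match="cross"):
            ring_metrics(img)

    def test_requires_ring_borders(self):
        img = make_section_image(np.zeros((10, 10), dtype=np.int32), plane="cross")
        with pytest.raises(MetricsError, match="border"):
            ring_metrics(img)


@pytest.fixture(scope="module")
def tangential_section():
    cfg = WoodModelConfig(tangential_extent=4.0, axial_extent=4.0, n_rings=2, interannual_cv=0.0, rng_seed=5)
    model = generate_wood(cfg)
    return cut_section(model, SectionSpec(plane="tangential"))


class TestInternalConsistency:
    def test_density_times_area_matches_perpar(self, tangential_section):
        """ray density x mean ray area ~ PERPAR/100 (tangential plane)."""
        img = tangential_section
        out = extract_outlines(img)
        # unbiased counting frame: exclude outlines touching the first row/col
        counted = out.loc[(out.centroid_0_mm.notna())]
        first = out.loc[~out._touch_row0 & ~out._touch_left]
        density = len(first) / img.area_mm2
        mean_area = out.loc[~out.touches_edge, "area_um2"].mean()
        lhs = density * mean_area / 1e6  # mm^2 of ray per mm^2
        rhs = compute_perpar(img) / 100.0
        assert lhs == pytest.approx(rhs, rel=0.05)


class TestTimeSeries:
    def _rings(self, n=20):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"ring": np.arange(n), "perpar": 5 + rng.random(n), "newray_per_mm": rng.random(n)})

    def test_length_and_ordering(self):
        df = self._rings().sample(frac=1.0, random_state=1)  # shuffled input
        ts = assemble_time_series(df, "perpar")
        assert len(ts) == 20
        assert np.all(np.diff(ts.years) > 0)

    def test_values_match_source(self):
        df = self._rings()
        ts = assemble_time_series(df, "perpar")
        np.testing.assert_allclose(ts.values, df["perpar"].to_numpy())

    def test_unknown_metric_lists_names(self):
        with pytest.raises(MetricsError, match="perpar"):
            assemble_time_series(self._rings(), "nonexistent")

    def test_too_few_rings(self):
        with pytest.raises(MetricsError, match="2 rings"):
            assemble_time_series(self._rings(1), "perpar")

    def test_validation(self):
        with pytest.raises(MetricsError):
            TimeSeries(years=np.array([2, 1]), values=np.array([1.0, 2.0]))
        with pytest.raises(MetricsError):
            TimeSeries(years=np.array([1, 2]), values=np.array([1.0, np.nan]))

    def test_series_matches_per_ring_perpar(self):
        """Series values equal independently recomputed per-ring PERPAR."""
        cfg = WoodModelConfig(tangential_extent=2.0, axial_extent=0.6, n_rings=5, rng_seed=3)
        model = generate_wood(cfg)
        img = cut_section(model, SectionSpec(plane="cross", resolution=4.0))
        rings = ring_metrics(img)
        ts = assemble_time_series(rings, "perpar")
        borders = img.ring_borders
        for k in range(5):
            direct = compute_perpar(img, region=((borders[k], borders[k + 1]), (0.0, 2.0)))
            assert ts.values[k] == pytest.approx(direct, abs=1e-9)
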