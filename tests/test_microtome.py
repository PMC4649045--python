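"""Virtual sectioning: projection geometry, plane artifacts, raster limits."""

import numpy as np
import pytest

from raypar import (
    Ray3D,
    SectionSpec,
    WoodModelConfig,
    compute_perpar,
    cut_section,
    expected_volume_fraction,
    generate_wood,
    projected_outline,
    ring_metrics,
    true_volume_fraction,
)
from raypar.microtome import SectionError

from conftest import make_model


@pytest.fixture(scope="module")
def standard_model():
    cfg = WoodModelConfig(
        tangential_extent=3.0,
        axial_extent=2.0,
        n_rings=4,
        ring_width_cv=0.0,
        interannual_cv=0.0,
        latewood_perpar_multiplier=1.0,
        rng_seed=11,
    )
    return generate_wood(cfg)


class TestSpecValidation:
    def test_bounds(self):
        with pytest.raises(SectionError):
            SectionSpec(plane="cross", thickness=60.0)
        with pytest.raises(SectionError):
            SectionSpec(plane="cross", misalignment_deg=20.0)
        with pytest.raises(SectionError):
            SectionSpec(plane="oblique")
        with pytest.raises(SectionError):
            SectionSpec(plane="cross", resolution=0.1)

    def test_slab_outside_sector_raises(self, standard_model):
        with pytest.raises(SectionError, match="outside"):
            cut_section(standard_model, SectionSpec(plane="tangential", offset=50.0))


class TestProjection:
    def test_zero_rays_all_background(self, neutral_config):
        model = generate_wood(neutral_config.replace(ray_density=0.0))
        for plane in ("cross", "tangential", "radial"):
            image = cut_section(model, SectionSpec(plane=plane))
            assert not image.ray_mask.any()

    def test_tangential_delesse(self):
        """Zero-thickness tangential PERPAR is an unbiased estimate of the
        true volume fraction (areal = volume fraction in expectation)."""
        cfg = WoodModelConfig(
            tangential_extent=3.0,
            axial_extent=3.0,
            n_rings=2,
            interannual_cv=0.0,
            latewood_perpar_multiplier=1.0,
        )
        vals, vfs = [], []
        for s in range(30):
            m = generate_wood(cfg.replace(rng_seed=s))
            img = cut_section(m, SectionSpec(plane="tangential", thickness=0.0, resolution=4.0))
            vals.append(compute_perpar(img))
            vfs.append(true_volume_fraction(m))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - np.mean(vfs)) < max(3 * se, 0.05)

    def test_plane_ordering(self):
        """Finite thickness inflates radial most, then cross, then tangential:
        PERPAR(radial) > PERPAR(cross) > PERPAR(tangential)."""
        cfg = WoodModelConfig(tangential_extent=3.0, axial_extent=3.0, n_rings=4, interannual_cv=0.0)
        acc = {"cross": [], "tangential": [], "radial": []}
        for s in range(12):
            m = generate_wood(cfg.replace(rng_seed=100 + s))
            for plane in acc:
                img = cut_section(m, SectionSpec(plane=plane, thickness=15.0, resolution=4.0))
                acc[plane].append(compute_perpar(img))
        assert np.mean(acc["radial"]) > np.mean(acc["cross"]) > np.mean(acc["tangential"])

    def test_perpar_monotone_in_thickness(self, standard_model):
        for plane in ("cross", "tangential", "radial"):
            vals = [
                compute_perpar(cut_section(standard_model, SectionSpec(plane=plane, thickness=tau, resolution=4.0)))
                for tau in (0.0, 5.0, 15.0, 30.0)
            ]
            assert all(b >= a for a, b in zip(vals, vals[1:])), (plane, vals)

    def test_raster_convergence(self, standard_model):
        a = compute_perpar(cut_section(standard_model, SectionSpec(plane="tangential", resolution=4.0)))
        b = compute_perpar(cut_section(standard_model, SectionSpec(plane="tangential", resolution=1.0)))
        assert a == pytest.approx(b, rel=0.02)

    def test_overlap_multiplicity_flagged(self, neutral_config):
        cfg = neutral_config.replace(n_rings=1, ring_width_mean=1.0)
        rays = [
            dict(ray_id=1, t_center=1.0, z_center=1.0, r_init=0.0, r_term=1.0, height_um=200.0, width_um=25.0, lens_p=1.0),
            dict(ray_id=2, t_center=1.002, z_center=1.05, r_init=0.0, r_term=1.0, height_um=200.0, width_um=25.0, lens_p=1.0),
        ]
        model = make_model(cfg, rays)
        img = cut_section(model, SectionSpec(plane="tangential", offset=0.5, resolution=1.0))
        assert img.multiplicity_pixels > 0
        # overlap resolves to the lowest id
        both = set(np.unique(img.labels)) - {0}
        assert both == {1, 2}
        overlap_rows = img.counts > 1
        assert np.all(img.labels[overlap_rows] == 1)


@pytest.fixture(scope="module")
def artifact_images():
    cfg = WoodModelConfig(
        tangential_extent=2.0,
        axial_extent=0.8,
        n_rings=8,
        interannual_cv=0.0,
    )
    out = {}
    for angle in (0.0, 3.0, 6.0):
        counts = []
        for s in range(6):
            m = generate_wood(cfg.replace(rng_seed=200 + s))
            img = cut_section(m, SectionSpec(plane="cross", misalignment_deg=angle))
            counts.append(ring_metrics(img)["disappearing_count"].sum())
        out[angle] = sum(counts)
    return out


class TestMisalignmentArtifacts:
    def test_no_disappearing_rays_when_aligned(self, artifact_images):
        """Persistent rays cut exactly perpendicular never end within a ring."""
        assert artifact_images[0.0] == 0

    def test_disappearing_rays_increase_with_tilt(self, artifact_images):
        assert artifact_images[0.0] < artifact_images[3.0] < artifact_images[6.0]


class TestProjectedOutline:
    def _ray(self, **kw):
        base = dict(id=1, t_center=0.0, z_center=0.0, r_init=0.0, r_term=2.0, height_um=200.0, width_um=30.0, lens_p=1.0)
        base.update(kw)
        return Ray3D(**base)

    def test_planar_tangential_cut_is_a_lens(self):
        ray = self._ray()
        poly = projected_outline(ray, SectionSpec(plane="tangential", offset=1.0, thickness=0.0))
        assert poly.area == pytest.approx((2 / 3) * 0.03 * 0.2, rel=1e-3)  # w*h*B(1)
        minx, miny, maxx, maxy = poly.bounds
        assert maxx - minx == pytest.approx(0.2, rel=1e-3)  # axial extent = h
        assert maxy - miny == pytest.approx(0.03, rel=1e-3)  # width = w

    def test_cross_outline_takes_max_projection(self):
        """A slab covering part of the lens shows the widest in-slab width,
        at least the planar width at the slab edge."""
        ray = self._ray()
        tau = 0.03  # 30 µm in mm... thickness is µm in the spec
        z0 = 0.05
        planar = projected_outline(ray, SectionSpec(plane="cross", offset=z0, thickness=0.0))
        thick = projected_outline(ray, SectionSpec(plane="cross", offset=z0, thickness=30.0))
        w_planar = planar.bounds[3] - planar.bounds[1]
        w_thick = thick.bounds[3] - thick.bounds[1]
        u_best = (z0 - 0.015) / 0.1  # nearest slab face to the lens centre
        expected = 0.03 * (1 - u_best**2)
        assert w_thick == pytest.approx(expected, rel=1e-3)
        assert w_thick > w_planar

    def test_radial_graze_seen_only_with_thickness(self):
        """A slab grazing the ray's tangential edge intersects it although a
        zero-thickness plane at the same offset misses it entirely."""
        ray = self._ray()
        t_off = 0.020  # beyond w/2 = 0.015 but within w/2 + tau/2
        empty = projected_outline(ray, SectionSpec(plane="radial", offset=t_off, thickness=0.0))
        grazed = projected_outline(ray, SectionSpec(plane="radial", offset=t_off, thickness=15.0))
        assert empty.is_empty
        assert not grazed.is_empty

    def test_radial_outline_height_reaches_h(self):
        """A radial slab containing the ray centre shows the full silhouette:
        measured height h' equals the true height h."""
        ray = self._ray()
        poly = projected_outline(ray, SectionSpec(plane="radial", offset=0.0, thickness=15.0))
        miny, maxy = poly.bounds[1], poly.bounds[3]
        assert maxy - miny == pytest.approx(0.2, rel=1e-3)

    def test_no_intersection_gives_empty_outline(self):
        ray = self._ray()
        poly = projected_outline(ray, SectionSpec(plane="tangential", offset=5.0, thickness=15.0))
        assert poly.is_empty
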