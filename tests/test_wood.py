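"""Generator: placement statistics, determinism, analytic volume fraction."""

import numpy as np
import pandas as pd
import pytest

from raypar import (
    ConfigError,
    WoodModelConfig,
    calibrate_volume_fraction,
    expected_volume_fraction,
    generate_wood,
    lens_area_factor,
    true_volume_fraction,
)
from raypar.wood import placement_pads_mm

from conftest import make_model


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("ray_density", -1.0),
            ("latewood_fraction", 1.5),
            ("ring_width_mean", 0.0),
            ("ray_height_mean", float("nan")),
            ("n_rings", 0),
            ("termination_probability", 1.5),
            ("lens_shape_exponent", -0.5),
        ],
    )
    def test_invalid_values_name_the_field(self, field, value):
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            WoodModelConfig(**{field: value})

    def test_sheet_geometry_enforced(self):
        with pytest.raises(ConfigError, match="height"):
            WoodModelConfig(ray_height_mean=20.0, ray_width_mean=25.0)

    def test_lens_area_factor(self):
        assert lens_area_factor(0.0) == pytest.approx(1.0)
        assert lens_area_factor(1.0) == pytest.approx(2.0 / 3.0)
        # numeric check at p = 2.5
        u = np.linspace(-1, 1, 200001)
        assert lens_area_factor(2.5) == pytest.approx(np.trapezoid((1 - u**2) ** 2.5, u) / 2, rel=1e-6)

    def test_json_round_trip(self, neutral_config):
        assert WoodModelConfig.from_json(neutral_config.to_json()) == neutral_config


class TestGeneration:
    def test_zero_density_gives_zero_rays(self, neutral_config):
        model = generate_wood(neutral_config.replace(ray_density=0.0))
        assert model.n_rays == 0
        assert true_volume_fraction(model) == 0.0

    def test_fixed_seed_is_bit_reproducible(self, neutral_config):
        a = generate_wood(neutral_config)
        b = generate_wood(neutral_config)
        pd.testing.assert_frame_equal(a.rays, b.rays)
        np.testing.assert_array_equal(a.ring_borders, b.ring_borders)
        c = generate_wood(neutral_config.replace(rng_seed=1))
        assert not a.rays.equals(c.rays)

    def test_ray_count_matches_density(self, neutral_config):
        cfg = neutral_config.replace(ray_density=30.0)
        t_pad, z_pad = placement_pads_mm(cfg)
        area = (cfg.tangential_extent + 2 * t_pad) * (cfg.axial_extent + 2 * z_pad)
        counts = [generate_wood(cfg.replace(rng_seed=s)).n_rays for s in range(50)]
        expected = 30.0 * area
        # every replicate within the generous 4*sqrt(dA) band
        assert all(abs(c - expected) <= 4 * np.sqrt(expected) for c in counts)
        # z-test of the mean over 50 replicates (binomial counts are tighter)
        se = np.sqrt(expected) / np.sqrt(50)
        assert abs(np.mean(counts) - expected) < max(4 * se, 1.0)

    def test_poisson_counts_mode(self, neutral_config):
        cfg = neutral_config.replace(ray_density=30.0, poisson_counts=True, hard_core=False)
        counts = np.array([generate_wood(cfg.replace(rng_seed=s)).n_rays for s in range(60)])
        assert counts.std() > 0  # actually random
        t_pad, z_pad = placement_pads_mm(cfg)
        area = (cfg.tangential_extent + 2 * t_pad) * (cfg.axial_extent + 2 * z_pad)
        se = np.sqrt(30.0 * area / 60)
        assert abs(counts.mean() - 30.0 * area) < 4 * se

    def test_hard_core_keeps_tangential_gaps(self, neutral_config):
        cfg = neutral_config.replace(ray_density=25.0)
        model = generate_wood(cfg)
        df = model.rays
        t = df["t_center"].to_numpy()
        z = df["z_center"].to_numpy()
        h = df["height_um"].to_numpy() / 1000.0
        w_mm = df["width_um"].to_numpy() / 1000.0
        n = len(df)
        for i in range(n):
            for j in range(i + 1, n):
                z_overlap = abs(z[i] - z[j]) < (h[i] + h[j]) / 2
                if z_overlap:
                    assert abs(t[i] - t[j]) >= (w_mm[i] + w_mm[j]) / 2

    def test_infeasible_hard_core_density_raises(self, neutral_config):
        with pytest.raises(ConfigError, match="hard-core"):
            generate_wood(neutral_config.replace(ray_density=4000.0))

    def test_zone_neutral_initiation_is_uniform(self):
        """With a latewood multiplier of 1, initiations land in each zone in
        proportion to its radial width."""
        cfg = WoodModelConfig(
            tangential_extent=2.0,
            axial_extent=1.0,
            n_rings=10,
            ring_width_cv=0.0,
            ray_density=0.0,
            initiation_density=40.0,
            latewood_initiation_multiplier=1.0,
            latewood_fraction=0.3,
            hard_core=False,
            interannual_cv=0.0,
        )
        lw = total = 0
        for s in range(10):
            m = generate_wood(cfg.replace(rng_seed=s))
            ring = m.ring_index(m.rays["r_init"].to_numpy())
            onsets = m.latewood_onsets[ring]
            lw += int((m.rays["r_init"].to_numpy() >= onsets).sum())
            total += m.n_rays
        frac = lw / total
        se = np.sqrt(0.3 * 0.7 / total)
        assert abs(frac - 0.3) < 4 * se

    def test_latewood_multiplier_shifts_initiations(self):
        cfg = WoodModelConfig(
            tangential_extent=2.0,
            axial_extent=1.0,
            n_rings=10,
            ray_density=0.0,
            initiation_density=40.0,
            latewood_initiation_multiplier=3.0,
            latewood_fraction=0.3,
            hard_core=False,
        )
        m = generate_wood(cfg)
        ring = m.ring_index(m.rays["r_init"].to_numpy())
        frac = float((m.rays["r_init"].to_numpy() >= m.latewood_onsets[ring]).mean())
        # expected share: 3*0.3 / (0.7 + 3*0.3) = 0.5625
        assert abs(frac - 0.5625) < 0.08


class TestVolumeFraction:
    def test_single_ray_closed_form(self, single_ray_model):
        assert true_volume_fraction(single_ray_model) == pytest.approx(0.4, rel=1e-9)

    def test_voxel_oracle(self, neutral_config):
        """Analytic volume fraction matches a brute-force 2 µm voxelization."""
        cfg = neutral_config.replace(
            tangential_extent=0.8,
            axial_extent=0.8,
            n_rings=1,
            ring_width_mean=0.6,
            ray_density=30.0,
        )
        model = generate_wood(cfg)
        assert model.n_rays > 5
        vf = true_volume_fraction(model)
        vox = 0.002
        r = np.arange(vox / 2, model.radial_extent, vox)
        t = np.arange(vox / 2, cfg.tangential_extent, vox)
        z = np.arange(vox / 2, cfg.axial_extent, vox)
        tt, zz = np.meshgrid(t, z, indexing="ij")
        hits = 0
        for row in model.rays.itertuples():
            u = 2 * (zz - row.z_center) / (row.height_um / 1000.0)
            hw = (row.width_um / 2000.0) * np.where(np.abs(u) <= 1, (1 - np.minimum(u * u, 1)) ** row.lens_p, 0.0)
            lens = np.abs(tt - row.t_center) <= hw  # zone-neutral model: scale = 1
            n_r = ((r >= row.r_init) & (r < row.r_term)).sum()
            hits += lens.sum() * n_r
        vf_vox = 100.0 * hits / (len(r) * len(t) * len(z))
        assert vf == pytest.approx(vf_vox, rel=0.02)

    def test_overlapping_rays_use_union_volume(self, neutral_config):
        """Two heavily overlapping rays must not double count."""
        cfg = neutral_config.replace(n_rings=1, ring_width_mean=1.0)
        rays = [
            dict(ray_id=1, t_center=1.0, z_center=1.0, r_init=0.0, r_term=1.0, height_um=200.0, width_um=25.0, lens_p=1.0),
            dict(ray_id=2, t_center=1.001, z_center=1.0, r_init=0.0, r_term=1.0, height_um=200.0, width_um=25.0, lens_p=1.0),
        ]
        model = make_model(cfg, rays)
        vf = true_volume_fraction(model)
        one = true_volume_fraction(make_model(cfg, rays[:1]))
        assert one < vf < 1.7 * one  # union, not the 2x sum

    def test_calibration_zero_and_linearity(self, neutral_config):
        assert calibrate_volume_fraction(neutral_config, 0.0).ray_density == 0.0
        c1 = calibrate_volume_fraction(neutral_config, 2.0)
        c2 = calibrate_volume_fraction(neutral_config, 4.0)
        assert c2.ray_density == pytest.approx(2 * c1.ray_density, rel=1e-12)
        # idempotent: recalibrating to the same target changes nothing
        assert calibrate_volume_fraction(c1, 2.0).ray_density == pytest.approx(c1.ray_density)

    def test_calibration_round_trip_on_generated_model(self, neutral_config):
        cfg = calibrate_volume_fraction(neutral_config.replace(tangential_extent=4.0, axial_extent=4.0), 4.92)
        assert expected_volume_fraction(cfg) == pytest.approx(4.92, rel=1e-12)
        vfs = [true_volume_fraction(generate_wood(cfg.replace(rng_seed=s))) for s in range(8)]
        assert np.mean(vfs) == pytest.approx(4.92, abs=0.25)

    def test_infeasible_target_raises(self, neutral_config):
        with pytest.raises(ConfigError, match="infeasible"):
            calibrate_volume_fraction(neutral_config, 60.0)
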