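import numpy as np
import pandas as pd
import pytest

from raypar import SectionImage, SectionSpec, WoodModel, WoodModelConfig


def make_model(config: WoodModelConfig, rays: list[dict], ring_borders=None, latewood_onsets=None) -> WoodModel:
    """Build a WoodModel directly from explicit ray descriptions."""
    n = config.n_rings
    if ring_borders is None:
        w = config.ring_width_mean
        ring_borders = np.arange(n + 1) * w
    ring_borders = np.asarray(ring_borders, dtype=float)
    if latewood_onsets is None:
        latewood_onsets = ring_borders[:-1] + (1 - config.latewood_fraction) * np.diff(ring_borders)
    df = pd.DataFrame(rays) if rays else pd.DataFrame(
        columns=["ray_id", "t_center", "z_center", "r_init", "r_term", "height_um", "width_um", "lens_p"]
    )
    if len(df) and "ray_id" not in df:
        df.insert(0, "ray_id", np.arange(1, len(df) + 1))
    if len(df) and "lens_p" not in df:
        df["lens_p"] = config.lens_shape_exponent
    return WoodModel(
        config=config,
        ring_borders=ring_borders,
        latewood_onsets=latewood_onsets,
        year_factors=np.ones(n),
        rays=df,
    )


def make_section_image(labels, pixel_size_um=1.0, plane="tangential", ring_borders=None, latewood_onsets=None, thickness=15.0):
    labels = np.asarray(labels, dtype=np.int32)
    spec = SectionSpec(plane=plane, offset=0.0, thickness=thickness, resolution=max(pixel_size_um, 0.5))
    return SectionImage(
        labels=labels,
        counts=None,
        spec=spec,
        pixel_size_um=pixel_size_um,
        origin=(0.0, 0.0),
        ring_borders=ring_borders,
        latewood_onsets=latewood_onsets,
    )


@pytest.fixture
def neutral_config():
    """A small, zone-neutral, noise-free configuration."""
    return WoodModelConfig(
        tangential_extent=2.0,
        axial_extent=2.0,
        n_rings=2,
        ring_width_cv=0.0,
        interannual_cv=0.0,
        latewood_perpar_multiplier=1.0,
        rng_seed=0,
    )


@pytest.fixture
def single_ray_model():
    """One spindle ray (p=1, h=200 µm, w=30 µm) spanning a 10x1x1 mm sector:
    volume fraction 100 * (2/3 * 0.03 * 0.2 * 10) / 10 = 0.4 %."""
    cfg = WoodModelConfig(
        tangential_extent=1.0,
        axial_extent=1.0,
        n_rings=1,
        ring_width_mean=10.0,
        ring_width_cv=0.0,
        latewood_perpar_multiplier=1.0,
        interannual_cv=0.0,
        ray_height_mean=200.0,
        ray_height_cv=0.0,
        ray_width_mean=30.0,
    )
    ray = dict(ray_id=1, t_center=0.5, z_center=0.5, r_init=0.0, r_term=10.0, height_um=200.0, width_um=30.0, lens_p=1.0)
    return make_model(cfg, [ray])
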