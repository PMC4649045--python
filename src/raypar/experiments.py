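"""Replication experiments: calibrated simulations whose ground truth is a
known population value, used to verify that the measurement pipeline
recovers it.

Each experiment builds a generator configuration whose analytic
expectation equals the requested target, runs the full virtual-sectioning
and measurement pipeline at the stated problem size, and returns both the
recovered estimate and the target.  Problem sizes follow the core-sampling
design of a 40-tree increment-core study (40 cores x 20 rings for
cross-sectional experiments, 20 independent 4 x 4 mm tangential sections).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._rng import child_seed, substream
from .accuracy import ci95
from .calibrate import (
    calibrate_cross_sections,
    calibrate_initiation,
    calibrate_interannual_cv,
    calibrate_volume_fraction,
)
from .config import WoodModelConfig
from .metrics import compute_perpar, ring_metrics
from .microtome import SectionSpec, cut_section
from .stats import mean_sensitivity, paired_t_test
from .wood import generate_wood

__all__ = [
    "ci95_rescaled",
    "tangential_recovery",
    "zone_perpar_recovery",
    "initiation_recovery",
    "mean_sensitivity_recovery",
]


def ci95_rescaled(printed_ci95: float, n_from: int, n_to: int) -> float:
    """CI95 at ``n_to`` samples given a known CI95 at ``n_from`` samples.

    Back-derives the per-sample CV from the known value (CI95 =
    2*CV*n^-1/2, as % of the mean) and re-applies the formula.
    """
    cv = printed_ci95 * np.sqrt(n_from) / 200.0
    return ci95(cv, n_to)


def tangential_recovery(
    target_pct: float = 4.92,
    n_sections: int = 20,
    seed: int = 1,
    section_mm: float = 4.0,
    thickness_um: float = 15.0,
    resolution_um: float = 2.0,
) -> dict:
    """Mean PERPAR over independent virtual tangential sections of models
    calibrated to a true ray volume fraction of ``target_pct``.

    Tangential sectioning of radially persistent rays is unbiased (the
    maximum projection through the slab is a single lens outline), so the
    mean recovers the calibrated truth within Monte-Carlo error.  The
    inter-annual modulation is switched off to isolate sectioning bias.
    """
    base = WoodModelConfig(
        tangential_extent=section_mm,
        axial_extent=section_mm,
        n_rings=3,
        interannual_cv=0.0,
    )
    cfg = calibrate_volume_fraction(base, target_pct)
    values = []
    for i in range(n_sections):
        model = generate_wood(cfg.replace(rng_seed=child_seed(seed, f"tangential-{i}")))
        rng = substream(seed, f"offset-{i}")
        margin = thickness_um / 1000.0
        offset = rng.uniform(margin, model.radial_extent - margin)
        spec = SectionSpec(plane="tangential", offset=offset, thickness=thickness_um, resolution=resolution_um)
        values.append(compute_perpar(cut_section(model, spec)))
    values = np.asarray(values)
    return {
        "mean_perpar": float(values.mean()),
        "target": target_pct,
        "values": values,
        "n_sections": n_sections,
    }


def _core_config(width_mm: float, n_rings: int, turnover: float = 0.0) -> WoodModelConfig:
    """An increment-core-like cross-sectional sampling geometry:
    ``width_mm`` of tangential width, ``n_rings`` outermost rings, thin
    axial extent (only rays near the slab matter).  ``turnover`` is the
    per-ring termination probability; real material shows substantial ray
    initiation per ring, so a non-zero turnover (with steady-state
    initiation balancing it) decorrelates the streak sets of successive
    rings the way real cores do."""
    return WoodModelConfig(
        tangential_extent=width_mm,
        axial_extent=0.6,
        n_rings=n_rings,
        termination_probability=turnover,
    )


def zone_perpar_recovery(
    early_pct: float = 5.77,
    late_pct: float = 6.18,
    n_cores: int = 40,
    n_rings: int = 20,
    width_mm: float = 6.69,
    seed: int = 1,
    thickness_um: float = 15.0,
    resolution_um: float = 2.0,
    turnover: float = 0.25,
) -> dict:
    """Early-/latewood PERPAR recovery from simulated cross-sections.

    The generator's density and latewood cell-width multiplier are set so
    the expected measured areal fractions equal the targets; ring metrics
    on ``n_cores`` x ``n_rings`` simulated rings then estimate them, and a
    paired t-test (pairing early and late zones within each ring)
    evaluates the latewood excess.  The default width matches the average
    measured width of real cross-sections (6.69 mm).
    """
    cfg = calibrate_cross_sections(_core_config(width_mm, n_rings, turnover), early_pct, late_pct, thickness_um)
    early, late = [], []
    for i in range(n_cores):
        model = generate_wood(cfg.replace(rng_seed=child_seed(seed, f"core-{i}")))
        image = cut_section(model, SectionSpec(plane="cross", thickness=thickness_um, resolution=resolution_um))
        rings = ring_metrics(image)
        early.append(rings["perpar_early"].to_numpy())
        late.append(rings["perpar_late"].to_numpy())
    early = np.concatenate(early)
    late = np.concatenate(late)
    ttest = paired_t_test(late, early)
    return {
        "mean_early": float(early.mean()),
        "mean_late": float(late.mean()),
        "target_early": early_pct,
        "target_late": late_pct,
        "t_statistic": ttest.statistic,
        "p_value": ttest.p_value,
        "n_rings_total": len(late),
    }


def initiation_recovery(
    early_per_mm: float = 21.82,
    late_per_mm: float = 23.75,
    n_cores: int = 40,
    n_rings: int = 20,
    width_mm: float = 2.0,
    seed: int = 1,
    thickness_um: float = 15.0,
    resolution_um: float = 2.0,
) -> dict:
    """Standardized initiating-ray (NEWRAY) recovery from cross-sections.

    Per-zone initiation intensities are set so the expected visible
    initiating rays per mm of section width equal the targets.  Initiated
    rays are short transient segments with a rectangular profile: the
    printed initiation counts are far above what radially persistent
    sheets could sustain (the excess reflects transiently appearing rays),
    and the rectangular profile makes raster detection of every visible
    ray reliable at the default resolution.
    """
    base = _core_config(width_mm, n_rings).replace(
        ray_density=0.0,
        lens_shape_exponent=0.0,
        initiation_segment=0.12,
        interannual_cv=0.0,
    )
    cfg = calibrate_initiation(base, early_per_mm, late_per_mm, thickness_um)
    early, late = [], []
    ttest_pairs = ([], [])
    for i in range(n_cores):
        model = generate_wood(cfg.replace(rng_seed=child_seed(seed, f"core-{i}")))
        image = cut_section(model, SectionSpec(plane="cross", thickness=thickness_um, resolution=resolution_um))
        rings = ring_metrics(image)
        early.append(rings["newray_early_per_mm"].to_numpy())
        late.append(rings["newray_late_per_mm"].to_numpy())
    early = np.concatenate(early)
    late = np.concatenate(late)
    ttest = paired_t_test(late, early)
    return {
        "mean_early_per_mm": float(early.mean()),
        "mean_late_per_mm": float(late.mean()),
        "target_early": early_per_mm,
        "target_late": late_per_mm,
        "t_statistic": ttest.statistic,
        "p_value": ttest.p_value,
        "n_rings_total": len(late),
    }


def mean_sensitivity_recovery(
    target_ms_pct: float = 10.8,
    n_series: int = 40,
    n_rings: int = 20,
    seed: int = 1,
) -> dict:
    """Mean sensitivity recovery of the annual ray-volume series.

    The lognormal year-factor CV is derived so the expected mean
    sensitivity of an i.i.d. annual series equals the target; ``n_series``
    20-ring series are then simulated and their per-series mean
    sensitivities averaged.  The series is the model's annual relative ray
    volume (linear in the year factor), which carries the inter-annual
    signal without window-sampling noise.
    """
    cv = calibrate_interannual_cv(target_ms_pct)
    cfg = WoodModelConfig(
        tangential_extent=1.0,
        axial_extent=1.0,
        n_rings=n_rings,
        interannual_cv=cv,
    )
    per_series = []
    for i in range(n_series):
        model = generate_wood(cfg.replace(rng_seed=child_seed(seed, f"series-{i}")))
        series = model.annual_volume_fraction_series()
        per_series.append(mean_sensitivity(series))
    per_series = np.asarray(per_series)
    return {
        "mean_ms": float(per_series.mean()),
        "target": target_ms_pct,
        "per_series": per_series,
        "interannual_cv": cv,
        "n_series": n_series,
    }
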