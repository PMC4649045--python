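"""Closed-form calibration of the generator to target measurement values.

These inversions let reported population means act as generator ground
truth, so the pipeline's job is parameter *recovery*:

* ``calibrate_volume_fraction`` -- standing ray density from a target true
  ray volume fraction (what an unbiased tangential section estimates);
* ``calibrate_cross_sections`` -- density and latewood width multiplier
  from target early-/latewood areal fractions as *measured* on a
  cross-section of given thickness, inverting the exact Boolean-model
  pixel coverage 1 - exp(-lambda);
* ``calibrate_initiation`` -- per-zone initiation intensities from target
  standardized initiating-ray counts per mm of section width;
* ``calibrate_interannual_cv`` -- lognormal year-factor spread from a
  target mean sensitivity, via numeric inversion of the i.i.d. closed
  form E|2 tanh(Y/2)|, Y ~ N(0, 2 sigma^2).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq

from .config import ConfigError, WoodModelConfig, lens_area_factor

__all__ = [
    "expected_volume_fraction",
    "calibrate_volume_fraction",
    "expected_cross_perpar",
    "calibrate_cross_sections",
    "expected_newray_per_mm",
    "calibrate_initiation",
    "expected_mean_sensitivity",
    "calibrate_interannual_cv",
]

#: maximum calibratable volume fraction (%); beyond this, non-overlapping
#: placement of uniseriate sheets is infeasible
MAX_VOLUME_FRACTION = 50.0


def _mean_width_mm(config: WoodModelConfig) -> float:
    """Radially averaged effective ray width (mm), including the latewood
    cell-width multiplier (year factors have mean 1)."""
    lf = config.latewood_fraction
    m = config.latewood_perpar_multiplier
    return config.ray_width_mean / 1000.0 * ((1.0 - lf) + lf * m)


def expected_volume_fraction(config: WoodModelConfig) -> float:
    """Analytic expected true ray volume fraction (%) of standing rays."""
    B = lens_area_factor(config.lens_shape_exponent)
    h_mm = config.ray_height_mean / 1000.0
    return 100.0 * config.ray_density * _mean_width_mm(config) * h_mm * B


def calibrate_volume_fraction(config: WoodModelConfig, target_vf: float) -> WoodModelConfig:
    """Return a config whose expected true volume fraction is ``target_vf`` %.

    Only ``ray_density`` is scaled (the closed form is linear in density),
    so re-calibration is idempotent.
    """
    if target_vf < 0:
        raise ConfigError(f"target volume fraction must be >= 0, got {target_vf}")
    if target_vf > MAX_VOLUME_FRACTION:
        raise ConfigError(
            f"target volume fraction {target_vf}% exceeds {MAX_VOLUME_FRACTION}%: "
            "non-overlapping uniseriate placement is infeasible"
        )
    B = lens_area_factor(config.lens_shape_exponent)
    h_mm = config.ray_height_mean / 1000.0
    density = target_vf / 100.0 / (_mean_width_mm(config) * h_mm * B)
    return config.replace(ray_density=density)


# ---------------------------------------------------------------------------
# cross-sectional areal fraction (finite thickness, max projection)
# ---------------------------------------------------------------------------


def _coverage_intensity(config: WoodModelConfig, thickness_um: float, zone: str) -> float:
    """lambda = rho * w_zone * (B(p) E[h] + tau): expected total projected
    streak width per unit tangential width in the given zone."""
    w_mm = config.ray_width_mean / 1000.0
    if zone == "late":
        w_mm *= config.latewood_perpar_multiplier
    elif zone != "early":
        raise ValueError(f"zone must be 'early' or 'late', got {zone!r}")
    B = lens_area_factor(config.lens_shape_exponent)
    h_mm = config.ray_height_mean / 1000.0
    tau_mm = thickness_um / 1000.0
    return config.ray_density * w_mm * (B * h_mm + tau_mm)


def expected_cross_perpar(config: WoodModelConfig, thickness_um: float = 15.0, zone: str = "early") -> float:
    """Expected measured areal ray fraction (%) in a cross-section zone.

    A finite-thickness cross-section shows each ray's maximum projection
    through the slab; for independently placed rays the per-pixel coverage
    is the 1D Boolean-model value 1 - exp(-lambda).
    """
    return 100.0 * -math.expm1(-_coverage_intensity(config, thickness_um, zone))


def calibrate_cross_sections(
    config: WoodModelConfig,
    early_pct: float,
    late_pct: float,
    thickness_um: float = 15.0,
) -> WoodModelConfig:
    """Set density and latewood width multiplier so the expected measured
    early-/latewood cross-sectional areal fractions equal the targets.

    The inversion assumes independent (Poisson) ray placement, so the
    returned config sets ``hard_core=False``.
    """
    for name, v in (("early_pct", early_pct), ("late_pct", late_pct)):
        if not 0 < v < 100:
            raise ConfigError(f"{name} must be in (0, 100), got {v}")
    lam_e = -math.log1p(-early_pct / 100.0)
    lam_l = -math.log1p(-late_pct / 100.0)
    B = lens_area_factor(config.lens_shape_exponent)
    h_mm = config.ray_height_mean / 1000.0
    tau_mm = thickness_um / 1000.0
    w_mm = config.ray_width_mean / 1000.0
    density = lam_e / (w_mm * (B * h_mm + tau_mm))
    # with per-ring turnover, steady state requires the initiation rate to
    # balance the termination rate (density * q per ring)
    initiation = density * config.termination_probability
    return config.replace(
        ray_density=density,
        latewood_perpar_multiplier=lam_l / lam_e,
        initiation_density=initiation,
        hard_core=False,
    )


# ---------------------------------------------------------------------------
# initiating rays (NEWRAY) per mm of cross-section width
# ---------------------------------------------------------------------------


def _visibility_window_mm(config: WoodModelConfig, thickness_um: float) -> float:
    """Axial window (mm) within which a ray intersects the slab: E[h] + tau."""
    return (config.ray_height_mean + thickness_um) / 1000.0


def expected_newray_per_mm(config: WoodModelConfig, thickness_um: float = 15.0, zone: str = "early") -> float:
    """Expected visible initiating rays per ring, standardized per mm of
    tangential section width, for one zone.

    Exact for visibility at any lens exponent; reliable raster *detection*
    additionally wants a rectangular profile (p = 0) or a fine raster,
    because a pointed lens grazing the slab projects a sub-pixel sliver.
    """
    lf = config.latewood_fraction
    M = config.latewood_initiation_multiplier
    lw_share = M * lf / ((1.0 - lf) + M * lf)
    share = lw_share if zone == "late" else (1.0 - lw_share)
    if zone not in ("early", "late"):
        raise ValueError(f"zone must be 'early' or 'late', got {zone!r}")
    return config.initiation_density * share * _visibility_window_mm(config, thickness_um)


def calibrate_initiation(
    config: WoodModelConfig,
    early_per_mm: float,
    late_per_mm: float,
    thickness_um: float = 15.0,
) -> WoodModelConfig:
    """Set per-zone initiation intensities from target standardized
    initiating-ray counts (per mm of section width, per ring).

    ``latewood_initiation_multiplier`` is the latewood:earlywood initiation
    rate ratio per mm of radial growth; with counts n_e, n_l and latewood
    fraction f it equals (n_l/n_e) * (1-f)/f.
    """
    if early_per_mm <= 0 or late_per_mm < 0:
        raise ConfigError("initiating-ray targets must be positive (earlywood) and non-negative")
    window = _visibility_window_mm(config, thickness_um)
    kappa_e = early_per_mm / window
    kappa_l = late_per_mm / window
    lf = config.latewood_fraction
    M = (kappa_l / kappa_e) * (1.0 - lf) / lf
    return config.replace(
        initiation_density=kappa_e + kappa_l,
        latewood_initiation_multiplier=M,
        hard_core=False,
    )


# ---------------------------------------------------------------------------
# inter-annual variability -> mean sensitivity
# ---------------------------------------------------------------------------

def _ms_from_sigma(sigma: float) -> float:
    """E|2 tanh(Y/2)| * 100 for Y ~ N(0, 2 sigma^2).

    For i.i.d. lognormal annual values x_t with log-sd sigma, the ratio of
    consecutive years is lognormal with log-sd sigma*sqrt(2) and the
    relative step |2 (x_t - x_{t-1}) / (x_t + x_{t-1})| equals
    |2 tanh(ln(x_t/x_{t-1}) / 2)|.  By symmetry the expectation is a
    half-line integral of a smooth integrand.
    """
    if sigma <= 0:
        return 0.0
    from scipy.integrate import quad

    sd = sigma * math.sqrt(2.0)
    val, _err = quad(
        lambda y: 2.0 * math.tanh(y / 2.0) * math.exp(-0.5 * (y / sd) ** 2),
        0.0,
        20.0 * sd,
        limit=200,
    )
    return float(100.0 * 2.0 * val / (sd * math.sqrt(2.0 * math.pi)))


def expected_mean_sensitivity(interannual_cv: float) -> float:
    """Expected mean sensitivity (%) of an i.i.d. lognormal annual series
    with the given coefficient of variation."""
    if interannual_cv < 0:
        raise ConfigError(f"interannual_cv must be >= 0, got {interannual_cv}")
    sigma = math.sqrt(math.log1p(interannual_cv**2))
    return _ms_from_sigma(sigma)


def calibrate_interannual_cv(target_ms_pct: float) -> float:
    """Invert ``expected_mean_sensitivity``: the lognormal year-factor CV
    whose expected mean sensitivity equals ``target_ms_pct`` percent."""
    if target_ms_pct < 0:
        raise ConfigError(f"target mean sensitivity must be >= 0, got {target_ms_pct}")
    if target_ms_pct == 0:
        return 0.0
    if target_ms_pct >= 190.0:
        raise ConfigError(f"target mean sensitivity {target_ms_pct}% is not attainable")
    sigma = brentq(lambda s: _ms_from_sigma(s) - target_ms_pct, 1e-9, 10.0, xtol=1e-12)
    return math.sqrt(math.expm1(sigma * sigma))
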