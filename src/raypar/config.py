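"""Configuration of the synthetic wood model.

Unit conventions used throughout the package:

* coordinates and extents (radial r, tangential t, axial z) in **mm**,
  with r increasing pith -> bark;
* cell-scale dimensions (ray height, ray width, section thickness,
  raster resolution) in **µm**;
* areal ray fractions (PERPAR) in **percent**.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["WoodModelConfig", "ConfigError", "lens_area_factor"]


class ConfigError(ValueError):
    """Raised when a configuration value is non-finite or out of range."""


def lens_area_factor(p: float) -> float:
    """Area of the fusiform (lens) profile relative to its bounding box.

    The tangential outline of a ray of height h and maximum width w is
    ``|t| <= (w/2)(1-u^2)^p`` with ``u = 2 z/h``; its area is ``w*h*B(p)``
    with ``B(p) = 0.5 * integral_{-1}^{1} (1-u^2)^p du``.  ``B(0)=1``
    (rectangular sheet), ``B(1)=2/3`` (pointed spindle).
    """
    if p < 0:
        raise ConfigError(f"lens_shape_exponent must be >= 0, got {p}")
    # B(p) = sqrt(pi)*Gamma(p+1) / (2*Gamma(p+3/2))
    return math.sqrt(math.pi) * math.gamma(p + 1.0) / (2.0 * math.gamma(p + 1.5))


@dataclass(frozen=True)
class WoodModelConfig:
    """Parameters of a synthetic stem sector with uniseriate fusiform rays.

    The sector is a Cartesian slab (r, t, z); stem curvature is ignored,
    which is negligible for sectors a few cm wide at breast height.

    Parameters
    ----------
    tangential_extent, axial_extent : float
        Sector size in the tangential / axial direction, mm.
    radial_extent : float, optional
        If given, generated ring widths are rescaled so their sum equals
        this value; otherwise the radial extent is the sum of the
        generated ring widths.
    n_rings : int
        Number of annual rings.
    ring_width_mean, ring_width_cv : float
        Lognormal ring-width distribution, mm.  The default mean matches
        a typical mature Scots pine increment-core ring of ~1 mm.
    latewood_fraction : float
        Fraction (0-1) of each ring's radial width occupied by latewood
        (the outer zone).
    ray_density : float
        Standing density of persistent rays per mm^2 of the tangential
        (t, z) plane.  These rays span the whole radial extent (rays keep
        their cambial connection) unless ``termination_probability`` > 0.
    initiation_density : float
        Expected newly initiated rays per mm^2 of tangential plane per
        ring (default 0: only standing rays).
    latewood_initiation_multiplier : float
        Ratio of the latewood to earlywood initiation rate per mm of
        radial growth.  1 means initiation positions are uniform in r.
    latewood_perpar_multiplier : float
        Multiplier on effective ray width inside latewood bands (slightly
        larger parenchyma cells near the ring border).  The default
        reproduces a latewood:earlywood areal-fraction ratio of
        6.18:5.77.
    ray_height_mean, ray_height_cv : float
        Lognormal distribution of ray height h, µm.  Placeholder defaults
        (no species-specific distribution is prescribed): mean 180 µm,
        cv 0.3.
    ray_height_growth : float
        Optional linear increase of ray height with radial position,
        µm per mm (ray height tends to increase pith -> bark).
    ray_width_mean : float
        Maximum tangential width w of the uniseriate sheet, µm
        (placeholder default 25 µm).
    lens_shape_exponent : float
        Exponent p >= 0 of the fusiform profile (1-u^2)^p; p=1 is a
        pointed spindle, p=0 a rectangular sheet.
    interannual_cv : float
        Coefficient of variation of the multiplicative lognormal year
        factors modulating each ring's ray fraction (mean 1).  Default
        matches the observed interannual CV of annual ray fraction
        (~0.12).
    termination_probability : float
        Per-ring-boundary probability that a ray truly ends.  Default 0:
        rays persist to the outer sector boundary.
    initiation_segment : float, optional
        If set, newly initiated rays persist only for this radial
        distance (mm) instead of following the termination rule --
        used to emulate the transient/artifact-inflated initiation
        counts seen in real cross-sections.
    hard_core : bool
        If True (default), ray placement is a hard-core process: rays
        whose axial ranges overlap keep a minimum tangential gap of one
        ray width, so uniseriate rays never merge.  If False, placement
        is an independent (Poisson/binomial) process.
    poisson_counts : bool
        If True, ray counts are Poisson distributed; if False (default)
        the count is the rounded expectation (binomial point process).
    rng_seed : int
        Seed for all generator randomness.
    """

    tangential_extent: float = 4.0
    axial_extent: float = 4.0
    radial_extent: Optional[float] = None
    n_rings: int = 20
    ring_width_mean: float = 1.047
    ring_width_cv: float = 0.2
    latewood_fraction: float = 0.3
    ray_density: float = 16.4
    initiation_density: float = 0.0
    latewood_initiation_multiplier: float = 1.0
    latewood_perpar_multiplier: float = 6.18 / 5.77
    ray_height_mean: float = 180.0
    ray_height_cv: float = 0.3
    ray_height_growth: float = 0.0
    ray_width_mean: float = 25.0
    lens_shape_exponent: float = 1.0
    interannual_cv: float = 0.12
    termination_probability: float = 0.0
    initiation_segment: Optional[float] = None
    hard_core: bool = True
    poisson_counts: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _finite_pos(name, value, strict=True):
            v = float(value)
            if not math.isfinite(v) or (v <= 0 if strict else v < 0):
                raise ConfigError(f"{name} must be a finite {'positive' if strict else 'non-negative'} number, got {value!r}")

        _finite_pos("tangential_extent", self.tangential_extent)
        _finite_pos("axial_extent", self.axial_extent)
        if self.radial_extent is not None:
            _finite_pos("radial_extent", self.radial_extent)
        if int(self.n_rings) < 1:
            raise ConfigError(f"n_rings must be >= 1, got {self.n_rings}")
        _finite_pos("ring_width_mean", self.ring_width_mean)
        _finite_pos("ring_width_cv", self.ring_width_cv, strict=False)
        if not 0.0 < float(self.latewood_fraction) < 1.0:
            raise ConfigError(f"latewood_fraction must be in (0, 1), got {self.latewood_fraction}")
        _finite_pos("ray_density", self.ray_density, strict=False)
        _finite_pos("initiation_density", self.initiation_density, strict=False)
        _finite_pos("latewood_initiation_multiplier", self.latewood_initiation_multiplier, strict=False)
        _finite_pos("latewood_perpar_multiplier", self.latewood_perpar_multiplier, strict=False)
        _finite_pos("ray_height_mean", self.ray_height_mean)
        _finite_pos("ray_height_cv", self.ray_height_cv, strict=False)
        _finite_pos("ray_width_mean", self.ray_width_mean)
        if not math.isfinite(float(self.ray_height_growth)) or float(self.ray_height_growth) < 0:
            raise ConfigError(f"ray_height_growth must be finite and >= 0, got {self.ray_height_growth}")
        _finite_pos("lens_shape_exponent", self.lens_shape_exponent, strict=False)
        _finite_pos("interannual_cv", self.interannual_cv, strict=False)
        if not 0.0 <= float(self.termination_probability) <= 1.0:
            raise ConfigError(f"termination_probability must be in [0, 1], got {self.termination_probability}")
        if self.initiation_segment is not None:
            _finite_pos("initiation_segment", self.initiation_segment)
        if self.ray_height_mean <= self.ray_width_mean:
            raise ConfigError(
                "ray_height_mean must exceed ray_width_mean (sheet-like geometry): "
                f"{self.ray_height_mean} <= {self.ray_width_mean}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def lens_factor(self) -> float:
        """B(p): lens area / (w*h)."""
        return lens_area_factor(self.lens_shape_exponent)

    def replace(self, **kwargs) -> "WoodModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WoodModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "WoodModelConfig":
        return cls.from_dict(json.loads(s))
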