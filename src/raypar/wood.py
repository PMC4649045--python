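"""Synthetic 3D stem sectors with uniseriate fusiform rays.

The model is a Cartesian slab (r, t, z) = (radial, tangential, axial), r
increasing pith -> bark, carved into annual rings with an earlywood and a
latewood zone.  Rays are radially oriented fusiform sheets: at every radius
r inside its span, ray i occupies

    {(t, z) : |t - t_i| <= s(r) * (w_i/2) * (1 - u^2)^p,  u = 2 (z - z_i) / h_i(r),  |u| <= 1}

where w_i is the maximum tangential width, h_i(r) the ray height, p the
lens-shape exponent, and s(r) a piecewise-constant width modulation that
carries the latewood cell-width excess and the multiplicative year factors.

Rays either persist from the inner sector boundary to the bark (the
anatomical default: rays keep their connection to the cambium) or initiate
within rings at a configurable per-ring rate, optionally as short transient
segments emulating artifact-inflated initiation counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .config import ConfigError, WoodModelConfig, lens_area_factor

__all__ = ["Ray3D", "WoodModel", "generate_wood", "true_volume_fraction"]

#: number of standard deviations (in log space) at which ray heights are capped
_H_CAP_SIGMAS = 5.0


@dataclass(frozen=True)
class Ray3D:
    """One fusiform uniseriate ray sheet."""

    id: int
    t_center: float  # mm
    z_center: float  # mm
    r_init: float  # mm
    r_term: float  # mm
    height_um: float  # actual ray height h (at r_init if height grows)
    width_um: float  # maximum tangential width w
    lens_p: float = 1.0
    height_growth: float = 0.0  # µm per mm of radius

    def __post_init__(self):
        if not self.r_init < self.r_term:
            raise ValueError(f"ray {self.id}: r_init must be < r_term")
        if self.height_um <= 0 or self.width_um <= 0:
            raise ValueError(f"ray {self.id}: height and width must be positive")

    def height_at(self, r) -> np.ndarray:
        """Ray height h(r) in µm."""
        return self.height_um + self.height_growth * (np.asarray(r, dtype=float) - self.r_init)

    def half_width_mm(self, u, scale=1.0) -> np.ndarray:
        """Tangential half width (mm) at relative axial position u = 2(z-z_c)/h."""
        u = np.asarray(u, dtype=float)
        prof = np.where(np.abs(u) <= 1.0, (1.0 - np.minimum(u * u, 1.0)) ** self.lens_p, 0.0)
        return scale * (self.width_um / 2000.0) * prof


class WoodModel:
    """A generated stem sector: rings, latewood onsets, rays, year factors.

    Rays are stored as a table (one row per ray) plus a piecewise-constant
    tangential width-modulation profile s(r) shared by all rays, which
    combines the latewood cell-width multiplier with the per-ring year
    factors.
    """

    def __init__(
        self,
        config: WoodModelConfig,
        ring_borders: Sequence[float],
        latewood_onsets: Sequence[float],
        year_factors: Sequence[float],
        rays: pd.DataFrame,
        placement_area_mm2: Optional[float] = None,
    ) -> None:
        self.config = config
        self.ring_borders = np.asarray(ring_borders, dtype=float)
        self.latewood_onsets = np.asarray(latewood_onsets, dtype=float)
        self.year_factors = np.asarray(year_factors, dtype=float)
        self.rays = rays.reset_index(drop=True)
        self.placement_area_mm2 = placement_area_mm2
        self._validate()
        self._build_scale_profile()

    # -- structure -------------------------------------------------------
    def _validate(self) -> None:
        b = self.ring_borders
        if b.ndim != 1 or len(b) != self.config.n_rings + 1:
            raise ValueError("ring_borders must have n_rings + 1 entries")
        if not np.all(np.diff(b) > 0):
            raise ValueError("ring borders must be strictly increasing")
        on = self.latewood_onsets
        if len(on) != self.config.n_rings or np.any(on <= b[:-1]) or np.any(on >= b[1:]):
            raise ValueError("each latewood onset must lie inside its ring")
        if len(self.year_factors) != self.config.n_rings:
            raise ValueError("year_factors must have one entry per ring")
        required = {"ray_id", "t_center", "z_center", "r_init", "r_term", "height_um", "width_um", "lens_p"}
        missing = required - set(self.rays.columns)
        if missing:
            raise ValueError(f"rays table missing columns: {sorted(missing)}")
        if len(self.rays):
            r0 = self.rays["r_init"].to_numpy()
            if np.any(r0 < b[0] - 1e-9) or np.any(r0 >= b[-1]):
                raise ValueError("every ray r_init must lie inside the sector")
            if np.any(self.rays["r_term"].to_numpy() <= r0):
                raise ValueError("r_init must be < r_term for every ray")

    def _build_scale_profile(self) -> None:
        n = self.config.n_rings
        edges = np.empty(2 * n + 1)
        edges[0::2] = self.ring_borders
        edges[1::2] = self.latewood_onsets
        scale = np.empty(2 * n)
        scale[0::2] = self.year_factors  # earlywood
        scale[1::2] = self.year_factors * self.config.latewood_perpar_multiplier
        self._seg_edges = edges
        self._seg_scale = scale
        seg_len = np.diff(edges)
        self._cum_s = np.concatenate([[0.0], np.cumsum(scale * seg_len)])
        self._cum_sr = np.concatenate([[0.0], np.cumsum(scale * (edges[1:] ** 2 - edges[:-1] ** 2) / 2.0)])

    # -- geometry helpers ------------------------------------------------
    @property
    def radial_extent(self) -> float:
        return float(self.ring_borders[-1])

    @property
    def n_rays(self) -> int:
        return len(self.rays)

    def ring_index(self, r) -> np.ndarray:
        """0-based ring index containing radius r (clipped to valid rings)."""
        idx = np.searchsorted(self.ring_borders, np.asarray(r, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.config.n_rings - 1)

    def width_scale_at(self, r) -> np.ndarray:
        """Width modulation s(r) = year_factor(ring) * latewood multiplier."""
        idx = np.searchsorted(self._seg_edges, np.asarray(r, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self._seg_scale) - 1)
        return self._seg_scale[idx]

    def _cum_eval(self, x, cum, moment: int) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self._seg_edges[0], self._seg_edges[-1])
        idx = np.clip(np.searchsorted(self._seg_edges, x, side="right") - 1, 0, len(self._seg_scale) - 1)
        a = self._seg_edges[idx]
        if moment == 0:
            part = self._seg_scale[idx] * (x - a)
        else:
            part = self._seg_scale[idx] * (x * x - a * a) / 2.0
        return cum[idx] + part

    def width_scale_integral(self, a, b) -> np.ndarray:
        """integral_a^b s(r) dr (vectorized)."""
        return self._cum_eval(b, self._cum_s, 0) - self._cum_eval(a, self._cum_s, 0)

    def width_scale_r_integral(self, a, b) -> np.ndarray:
        """integral_a^b s(r) * r dr (vectorized)."""
        return self._cum_eval(b, self._cum_sr, 1) - self._cum_eval(a, self._cum_sr, 1)

    def width_scale_max(self, a: float, b: float) -> float:
        """max of s(r) over [a, b]."""
        lo = np.clip(np.searchsorted(self._seg_edges, a, side="right") - 1, 0, len(self._seg_scale) - 1)
        hi = np.clip(np.searchsorted(self._seg_edges, b, side="left") - 1, 0, len(self._seg_scale) - 1)
        hi = max(hi, lo)  # degenerate window exactly on a segment edge
        return float(self._seg_scale[lo : hi + 1].max())

    def ray_objects(self) -> list:
        """Rays as :class:`Ray3D` objects (convenience for small models)."""
        g = self.config.ray_height_growth
        return [
            Ray3D(
                id=int(row.ray_id),
                t_center=row.t_center,
                z_center=row.z_center,
                r_init=row.r_init,
                r_term=row.r_term,
                height_um=row.height_um,
                width_um=row.width_um,
                lens_p=row.lens_p,
                height_growth=g,
            )
            for row in self.rays.itertuples()
        ]

    # -- annual series ---------------------------------------------------
    def annual_volume_fraction_series(self):
        """Per-ring true relative ray volume (%), as a year-indexed series.

        For persistent full-span rays the per-ring value is the common
        geometric base times that ring's width modulation (year factor x
        zone mix), so the series carries exactly the generator's
        inter-annual signal.  Values are referenced to the padded
        placement area when available (stationary density), else to the
        sector cross-area.
        """
        from .metrics import TimeSeries  # local import to avoid cycle

        cfg = self.config
        area = self.placement_area_mm2 or (cfg.tangential_extent * cfg.axial_extent)
        B = lens_area_factor(cfg.lens_shape_exponent)
        w_mm = self.rays["width_um"].to_numpy() / 1000.0
        h_mm = self.rays["height_um"].to_numpy() / 1000.0
        r0 = self.rays["r_init"].to_numpy()
        r1 = self.rays["r_term"].to_numpy()
        vals = np.empty(cfg.n_rings)
        for k in range(cfg.n_rings):
            a, b = self.ring_borders[k], self.ring_borders[k + 1]
            lo = np.maximum(r0, a)
            hi = np.minimum(r1, b)
            mask = hi > lo
            integ = self.width_scale_integral(lo[mask], hi[mask])
            if cfg.ray_height_growth:
                h_eff = h_mm[mask] + cfg.ray_height_growth / 1000.0 * (lo[mask] + hi[mask]) / 2.0
            else:
                h_eff = h_mm[mask]
            vals[k] = 100.0 * B * np.sum(w_mm[mask] * h_eff * integ) / ((b - a) * area)
        years = np.arange(cfg.n_rings)
        return TimeSeries(years=years, values=vals, name="volume_fraction")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<WoodModel {self.config.n_rings} rings, {self.n_rays} rays, "
            f"{self.radial_extent:.2f} x {self.config.tangential_extent:.2f} x "
            f"{self.config.axial_extent:.2f} mm>"
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _sample_heights(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0 or n == 0:
        return np.full(n, mean)
    mu, sigma = _lognormal_params(mean, cv)
    cap = math.exp(mu + _H_CAP_SIGMAS * sigma)
    h = rng.lognormal(mu, sigma, size=n)
    for _ in range(10):
        bad = h > cap
        if not bad.any():
            break
        h[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
    return np.minimum(h, cap)


def height_cap_um(config: WoodModelConfig) -> float:
    """Upper bound on sampled ray heights (µm), used for placement padding."""
    if config.ray_height_cv == 0:
        cap = config.ray_height_mean
    else:
        mu, sigma = _lognormal_params(config.ray_height_mean, config.ray_height_cv)
        cap = math.exp(mu + _H_CAP_SIGMAS * sigma)
    return cap + config.ray_height_growth * (config.radial_extent or config.n_rings * config.ring_width_mean * 2)


def placement_pads_mm(config: WoodModelConfig) -> tuple[float, float]:
    """(tangential, axial) padding of the placement window beyond the sector.

    Rays centred slightly outside the sector still intersect it (tangential
    pad) or become visible in a thick section near the sector faces (axial
    pad, which also covers the thickest supported slab of 50 µm).
    """
    t_pad = 4.0 * config.ray_width_mean / 1000.0
    z_pad = height_cap_um(config) / 2000.0 + 0.05
    return t_pad, z_pad


class _HardCoreIndex:
    """Incremental conflict test: rays whose radial spans and axial ranges
    overlap must keep a tangential centre distance of at least the sum of
    their half widths plus one mean ray width."""

    def __init__(self, gap_mm: float):
        self.gap = gap_mm
        self.t = []
        self.zlo = []
        self.zhi = []
        self.rlo = []
        self.rhi = []
        self.w = []

    def conflicts(self, t, zlo, zhi, rlo, rhi, w_mm) -> bool:
        if not self.t:
            return False
        ta = np.asarray(self.t)
        near = np.abs(ta - t) < (np.asarray(self.w) + w_mm) / 2.0 + self.gap
        if not near.any():
            return False
        idx = np.nonzero(near)[0]
        z_ok = (np.asarray(self.zlo)[idx] < zhi) & (np.asarray(self.zhi)[idx] > zlo)
        r_ok = (np.asarray(self.rlo)[idx] < rhi) & (np.asarray(self.rhi)[idx] > rlo)
        return bool(np.any(z_ok & r_ok))

    def add(self, t, zlo, zhi, rlo, rhi, w_mm) -> None:
        self.t.append(t)
        self.zlo.append(zlo)
        self.zhi.append(zhi)
        self.rlo.append(rlo)
        self.rhi.append(rhi)
        self.w.append(w_mm)


def _draw_count(rng: np.random.Generator, expectation: float, poisson: bool) -> int:
    if expectation <= 0:
        return 0
    return int(rng.poisson(expectation)) if poisson else int(round(expectation))


def generate_wood(config: WoodModelConfig) -> WoodModel:
    """Generate a seeded synthetic stem sector.

    Identical configs (including seed) produce bit-identical ray tables.
    """
    config.validate()
    seed = config.rng_seed
    n = config.n_rings

    # ring structure ----------------------------------------------------
    rng = substream(seed, "rings")
    if config.ring_width_cv > 0:
        mu, sigma = _lognormal_params(config.ring_width_mean, config.ring_width_cv)
        widths = rng.lognormal(mu, sigma, size=n)
    else:
        widths = np.full(n, config.ring_width_mean)
    if config.radial_extent is not None:
        widths *= config.radial_extent / widths.sum()
    borders = np.concatenate([[0.0], np.cumsum(widths)])
    onsets = borders[:-1] + (1.0 - config.latewood_fraction) * widths
    R = float(borders[-1])

    # year factors ------------------------------------------------------
    rng = substream(seed, "years")
    if config.interannual_cv > 0:
        sigma2 = math.log1p(config.interannual_cv**2)
        factors = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=n)
    else:
        factors = np.ones(n)

    # placement windows -------------------------------------------------
    t_pad, z_pad = placement_pads_mm(config)
    t_lo, t_hi = -t_pad, config.tangential_extent + t_pad
    z_lo, z_hi = -z_pad, config.axial_extent + z_pad
    area = (t_hi - t_lo) * (z_hi - z_lo)
    gap_mm = config.ray_width_mean / 1000.0
    core = _HardCoreIndex(gap_mm) if config.hard_core else None
    w_mm = config.ray_width_mean / 1000.0

    cols = {k: [] for k in ("t_center", "z_center", "r_init", "r_term", "height_um")}

    def _place(rng, r0, r1, h_um) -> None:
        """Place one ray uniformly in the padded (t, z) window (hard-core aware)."""
        h_mm = h_um / 1000.0
        for _ in range(200):
            t = rng.uniform(t_lo, t_hi)
            z = rng.uniform(z_lo, z_hi)
            if core is None or not core.conflicts(t, z - h_mm / 2, z + h_mm / 2, r0, r1, w_mm):
                if core is not None:
                    core.add(t, z - h_mm / 2, z + h_mm / 2, r0, r1, w_mm)
                cols["t_center"].append(t)
                cols["z_center"].append(z)
                cols["r_init"].append(r0)
                cols["r_term"].append(r1)
                cols["height_um"].append(h_um)
                return
        raise ConfigError(
            "hard-core placement failed: ray_density too high for non-overlapping "
            "uniseriate rays (reduce density or set hard_core=False)"
        )

    def _terminal_radius(rng, start_ring: int) -> float:
        """Radius at which a ray truly ends: in each ring from
        ``start_ring`` on it dies with probability q, at a uniform
        position within that ring (which keeps the standing density
        exactly stationary when the initiation rate is density * q)."""
        q = config.termination_probability
        if q <= 0.0:
            return R
        for k in range(start_ring, n):
            if rng.random() < q:
                return float(rng.uniform(borders[k], borders[k + 1]))
        return R

    # standing rays (persist from the inner boundary) -------------------
    rng = substream(seed, "standing")
    n_standing = _draw_count(rng, config.ray_density * area, config.poisson_counts)
    heights = _sample_heights(rng, n_standing, config.ray_height_mean, config.ray_height_cv)
    for i in range(n_standing):
        r1 = _terminal_radius(rng, 0)
        _place(rng, 0.0, max(r1, 1e-9), heights[i])

    # per-ring initiated rays -------------------------------------------
    if config.initiation_density > 0:
        rng = substream(seed, "initiation")
        M = config.latewood_initiation_multiplier
        lf = config.latewood_fraction
        lw_share = M * lf / ((1.0 - lf) + M * lf) if (1.0 - lf) + M * lf > 0 else 1.0
        for k in range(n):
            n_k = _draw_count(rng, config.initiation_density * area, config.poisson_counts)
            if n_k == 0:
                continue
            in_lw = rng.random(n_k) < lw_share
            h_k = _sample_heights(rng, n_k, config.ray_height_mean, config.ray_height_cv)
            for j in range(n_k):
                if in_lw[j]:
                    r0 = rng.uniform(onsets[k], borders[k + 1])
                else:
                    r0 = rng.uniform(borders[k], onsets[k])
                if config.initiation_segment is not None:
                    r1 = min(r0 + config.initiation_segment, R)
                else:
                    # deaths start from the ring after initiation
                    r1 = _terminal_radius(rng, k + 1)
                    if r1 <= r0:
                        r1 = float(borders[k + 1])
                _place(rng, r0, max(r1, r0 + 1e-9), h_k[j])

    rays = pd.DataFrame(cols)
    rays.insert(0, "ray_id", np.arange(1, len(rays) + 1, dtype=np.int64))
    rays["width_um"] = config.ray_width_mean
    rays["lens_p"] = config.lens_shape_exponent

    return WoodModel(
        config=config,
        ring_borders=borders,
        latewood_onsets=onsets,
        year_factors=factors,
        rays=rays,
        placement_area_mm2=area,
    )


# ---------------------------------------------------------------------------
# exact ray volume fraction
# ---------------------------------------------------------------------------


def _point_in_rays(model: WoodModel, idx: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Boolean: is each point (r, t, z) inside any of the rays ``idx``."""
    inside = np.zeros(len(pts), dtype=bool)
    rows = model.rays.iloc[idx]
    g = model.config.ray_height_growth
    r, t, z = pts[:, 0], pts[:, 1], pts[:, 2]
    scale = model.width_scale_at(r)
    for row in rows.itertuples():
        cand = (~inside) & (r >= row.r_init) & (r < row.r_term)
        if not cand.any():
            continue
        h_mm = (row.height_um + g * (r[cand] - row.r_init)) / 1000.0
        u = 2.0 * (z[cand] - row.z_center) / h_mm
        ok = np.abs(u) <= 1.0
        hw = scale[cand] * (row.width_um / 2000.0) * np.where(ok, (1.0 - np.minimum(u * u, 1.0)) ** row.lens_p, 0.0)
        hit = ok & (np.abs(t[cand] - row.t_center) <= hw)
        inside[np.nonzero(cand)[0][hit]] = True
    return inside


def _exact_ray_volume(model: WoodModel, row, gl_nodes=None) -> float:
    """Volume (mm^3) of one ray clipped to the sector box."""
    cfg = model.config
    T, Z, R = cfg.tangential_extent, cfg.axial_extent, model.radial_extent
    B = lens_area_factor(row.lens_p)
    g = cfg.ray_height_growth
    a = max(row.r_init, 0.0)
    b = min(row.r_term, R)
    if b <= a:
        return 0.0
    w_mm = row.width_um / 1000.0
    s_max = model.width_scale_max(a, b)
    h_top_mm = (row.height_um + g * (b - row.r_init)) / 1000.0
    inside_tz = (
        row.t_center - s_max * w_mm / 2 >= 0
        and row.t_center + s_max * w_mm / 2 <= T
        and row.z_center - h_top_mm / 2 >= 0
        and row.z_center + h_top_mm / 2 <= Z
    )
    if inside_tz:
        h0_mm = row.height_um / 1000.0
        integ_s = model.width_scale_integral(a, b)
        if g:
            integ = h0_mm * integ_s + (g / 1000.0) * (
                model.width_scale_r_integral(a, b) - row.r_init * integ_s
            )
        else:
            integ = h0_mm * integ_s
        return B * w_mm * float(integ)
    # clipped: integrate the lens cross-area numerically per scale segment
    if gl_nodes is None:
        gl_nodes = np.polynomial.legendre.leggauss(64)
    u_nodes, u_weights = gl_nodes
    edges = np.unique(np.clip(model._seg_edges, a, b))
    if edges[0] > a:
        edges = np.concatenate([[a], edges])
    if edges[-1] < b:
        edges = np.concatenate([edges, [b]])
    vol = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        mid = (lo + hi) / 2.0
        s = float(model.width_scale_at(mid))
        h_mm = (row.height_um + g * (mid - row.r_init)) / 1000.0
        z = row.z_center + u_nodes * h_mm / 2.0
        hw = s * (w_mm / 2.0) * (1.0 - u_nodes**2) ** row.lens_p
        t_lo = np.maximum(row.t_center - hw, 0.0)
        t_hi = np.minimum(row.t_center + hw, T)
        width = np.where((z >= 0) & (z <= Z), np.maximum(t_hi - t_lo, 0.0), 0.0)
        area = float(np.sum(width * u_weights) * h_mm / 2.0)
        vol += area * (hi - lo)
    return vol


def true_volume_fraction(model: WoodModel, n_mc: int = 100_000, mc_seed: int = 0) -> float:
    """Exact analytic ray volume percentage of the sector.

    Non-overlapping rays are summed in closed form (lens cross-area w*h*B(p)
    times the modulated radial span, clipped to the sector).  Where ray
    bodies overlap, the union volume of each overlapping cluster is
    estimated by Monte Carlo with ``n_mc`` points per cluster.
    """
    cfg = model.config
    T, Z, R = cfg.tangential_extent, cfg.axial_extent, model.radial_extent
    V = R * T * Z
    if model.n_rays == 0:
        return 0.0
    df = model.rays
    g = cfg.ray_height_growth
    s_hi = float(model._seg_scale.max())
    w2 = s_hi * df["width_um"].to_numpy() / 2000.0
    h2 = (df["height_um"].to_numpy() + g * (df["r_term"].to_numpy() - df["r_init"].to_numpy())) / 2000.0
    t_lo, t_hi = df["t_center"].to_numpy() - w2, df["t_center"].to_numpy() + w2
    z_lo, z_hi = df["z_center"].to_numpy() - h2, df["z_center"].to_numpy() + h2
    r_lo = df["r_init"].to_numpy()
    r_hi = df["r_term"].to_numpy()

    # conservative overlap graph on bounding boxes
    order = np.argsort(t_lo)
    parent = np.arange(len(df))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    overlapping = np.zeros(len(df), dtype=bool)
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            if t_lo[j] >= t_hi[i]:
                break
            if z_lo[j] < z_hi[i] and z_hi[j] > z_lo[i] and r_lo[j] < r_hi[i] and r_hi[j] > r_lo[i]:
                overlapping[i] = overlapping[j] = True
                parent[find(i)] = find(j)

    gl = np.polynomial.legendre.leggauss(64)
    total = 0.0
    singles = np.nonzero(~overlapping)[0]
    for i in singles:
        total += _exact_ray_volume(model, df.iloc[i], gl)

    if overlapping.any():
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.rng_seed), int(mc_seed), 0x5F]))
        roots = {}
        for i in np.nonzero(overlapping)[0]:
            roots.setdefault(find(i), []).append(i)
        for members in roots.values():
            idx = np.asarray(members)
            box_r = (max(r_lo[idx].min(), 0.0), min(r_hi[idx].max(), R))
            box_t = (max(t_lo[idx].min(), 0.0), min(t_hi[idx].max(), T))
            box_z = (max(z_lo[idx].min(), 0.0), min(z_hi[idx].max(), Z))
            vol_box = max(box_r[1] - box_r[0], 0) * max(box_t[1] - box_t[0], 0) * max(box_z[1] - box_z[0], 0)
            if vol_box <= 0:
                continue
            pts = np.column_stack(
                [
                    rng.uniform(box_r[0], box_r[1], n_mc),
                    rng.uniform(box_t[0], box_t[1], n_mc),
                    rng.uniform(box_z[0], box_z[1], n_mc),
                ]
            )
            frac = _point_in_rays(model, idx, pts).mean()
            total += frac * vol_box
    return 100.0 * total / V
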