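"""Virtual microtome: cut a wood model with a finite-thickness slab and
rasterize the maximum projection of every ray through the slab.

Because thin sections are transparent, the perceived outline of a ray is
the union of its cross-sections through the entire slab thickness ("maximum
projection").  This produces the classic plane-dependent artifacts:

* radial sections inflate ray outlines most (the slab rarely misses a
  sheet-like ray once it grazes it, and then shows its full silhouette);
* cross-sections inflate moderately (projection through the tapering ray
  extremities);
* tangential sections are nearly unbiased (rays run perpendicular to the
  slab, so the projection is a single lens outline).

A misaligned slab (tilt of the cutting plane) makes rays drift in and out
of the slab along the radius, creating spurious initiating and permanently
"ending" rays in cross-sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .wood import Ray3D, WoodModel

__all__ = ["SectionSpec", "SectionImage", "cut_section", "projected_outline", "SectionError"]

PLANES = ("cross", "tangential", "radial")


class SectionError(ValueError):
    """Invalid section specification or slab placement."""


@dataclass(frozen=True)
class SectionSpec:
    """Specification of one virtual section.

    Parameters
    ----------
    plane : {'cross', 'tangential', 'radial'}
        Cutting plane: normal to the stem axis / to the radius / to the
        tangential direction, respectively.
    offset : float, optional
        Position of the slab centre along its normal, mm (default: the
        sector midpoint).
    thickness : float
        Slab thickness, µm (default 15, a typical permanent thin section).
    misalignment_deg : float
        Tilt of the slab: cross-sections tilt about the tangential axis
        (the slab drifts axially with radius), radial sections about the
        axial axis, tangential sections about the radial axis.
    resolution : float
        Raster resolution, µm per pixel.  The default (2 µm) resolves a
        25 µm ray width with >= 12 pixels.
    extent : ((float, float), (float, float)), optional
        In-plane rectangle to rasterize, mm, as (axis0, axis1) ranges;
        default is the full sector face.
    """

    plane: str
    offset: Optional[float] = None
    thickness: float = 15.0
    misalignment_deg: float = 0.0
    resolution: float = 2.0
    extent: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None

    def __post_init__(self):
        if self.plane not in PLANES:
            raise SectionError(f"plane must be one of {PLANES}, got {self.plane!r}")
        if not 0.0 <= self.thickness <= 50.0:
            raise SectionError(f"thickness must be within [0, 50] µm, got {self.thickness}")
        if not abs(self.misalignment_deg) < 15.0:
            raise SectionError(f"|misalignment_deg| must be < 15, got {self.misalignment_deg}")
        if not 0.5 <= self.resolution <= 10.0:
            raise SectionError(f"resolution must be within [0.5, 10] µm/px, got {self.resolution}")


class SectionImage:
    """Rasterized label map of one virtual section.

    ``labels[i, j]`` holds the id of the ray whose projection covers the
    pixel centre (0 = background); overlapping projections are resolved to
    the lowest id, with the per-pixel multiplicity kept in ``counts``.
    Axis 0 is radial for cross/radial sections and axial for tangential
    sections; axis 1 is tangential for cross/tangential sections and axial
    for radial sections.
    """

    AXIS_NAMES = {"cross": ("radial", "tangential"), "tangential": ("axial", "tangential"), "radial": ("radial", "axial")}

    def __init__(
        self,
        labels: np.ndarray,
        counts: Optional[np.ndarray],
        spec: SectionSpec,
        pixel_size_um: float,
        origin: Tuple[float, float],
        ring_borders: Optional[np.ndarray] = None,
        latewood_onsets: Optional[np.ndarray] = None,
    ) -> None:
        self.labels = labels
        self.counts = counts
        self.spec = spec
        self.pixel_size_um = float(pixel_size_um)
        self.origin = (float(origin[0]), float(origin[1]))
        self.ring_borders = None if ring_borders is None else np.asarray(ring_borders, dtype=float)
        self.latewood_onsets = None if latewood_onsets is None else np.asarray(latewood_onsets, dtype=float)

    @property
    def plane(self) -> str:
        return self.spec.plane

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    def axis0_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.shape[0]) + 0.5) * self.pixel_size_mm

    def axis1_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.shape[1]) + 0.5) * self.pixel_size_mm

    @property
    def ray_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def area_mm2(self) -> float:
        """Measured surface: pixel count x pixel size^2."""
        return self.labels.size * self.pixel_size_mm**2

    @property
    def width_mm(self) -> float:
        """Measured tangential width (axis 1) for cross/tangential planes."""
        return self.shape[1] * self.pixel_size_mm

    @property
    def multiplicity_pixels(self) -> int:
        """Pixels where more than one ray projection overlaps."""
        if self.counts is None:
            return 0
        return int(np.count_nonzero(self.counts > 1))

    def zone_of_axis0(self) -> np.ndarray:
        """Per-row zone for cross/radial planes: 0 = earlywood, 1 = latewood."""
        if self.ring_borders is None or self.latewood_onsets is None:
            raise SectionError("zone map requires ring borders (cross/radial section of a ringed model)")
        r = self.axis0_centers()
        ring = np.clip(np.searchsorted(self.ring_borders, r, side="right") - 1, 0, len(self.latewood_onsets) - 1)
        return (r >= self.latewood_onsets[ring]).astype(np.uint8)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<SectionImage {self.plane} {self.shape[0]}x{self.shape[1]}px @{self.pixel_size_um}µm>"


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _grid(lo: float, hi: float, px: float) -> Tuple[int, float]:
    n = max(1, int(round((hi - lo) / px)))
    return n, lo


def _profile(u: np.ndarray, p: float) -> np.ndarray:
    """(1-u^2)^p for |u| <= 1, else 0 (p = 0 gives a rectangular sheet)."""
    uu = np.minimum(u * u, 1.0)
    base = 1.0 - uu
    prof = base**p if p > 0 else np.ones_like(base)
    return np.where(np.abs(u) <= 1.0, prof, 0.0)


def cut_section(model: WoodModel, spec: SectionSpec) -> SectionImage:
    """Cut the model with the slab described by ``spec`` and rasterize the
    maximum projection of every intersected ray.

    A pixel is labeled with ray i iff the line through the pixel centre
    along the slab normal intersects ray i's body anywhere within the
    thickness.  Overlaps resolve to the lowest ray id; per-pixel
    multiplicity is recorded.
    """
    cfg = model.config
    R, T, Z = model.radial_extent, cfg.tangential_extent, cfg.axial_extent
    px = spec.resolution / 1000.0
    tau = spec.thickness / 1000.0
    tan_a = math.tan(math.radians(spec.misalignment_deg))
    g = cfg.ray_height_growth

    normal_extent = {"cross": Z, "tangential": R, "radial": T}[spec.plane]
    offset = normal_extent / 2.0 if spec.offset is None else float(spec.offset)
    if offset + tau / 2.0 < 0.0 or offset - tau / 2.0 > normal_extent:
        raise SectionError(
            f"slab at offset {offset} mm (thickness {spec.thickness} µm) lies outside "
            f"the sector extent [0, {normal_extent}] mm along the {spec.plane} normal"
        )

    default_extent = {
        "cross": ((0.0, R), (0.0, T)),
        "tangential": ((0.0, Z), (0.0, T)),
        "radial": ((0.0, R), (0.0, Z)),
    }[spec.plane]
    (u_lo, u_hi), (v_lo, v_hi) = spec.extent if spec.extent is not None else default_extent
    if u_hi <= u_lo or v_hi <= v_lo:
        raise SectionError("extent ranges must be non-empty")
    n0, _ = _grid(u_lo, u_hi, px)
    n1, _ = _grid(v_lo, v_hi, px)
    u_cent = u_lo + (np.arange(n0) + 0.5) * px
    v_cent = v_lo + (np.arange(n1) + 0.5) * px

    labels = np.zeros((n0, n1), dtype=np.int32)
    counts = np.zeros((n0, n1), dtype=np.uint8)

    df = model.rays
    if len(df):
        fill = {"cross": _fill_cross, "tangential": _fill_tangential, "radial": _fill_radial}[spec.plane]
        mid = R / 2.0 if spec.plane in ("cross", "radial") else T / 2.0
        for row in df.itertuples():
            fill(model, row, g, offset, tau, tan_a, mid, u_cent, v_cent, labels, counts)

    borders = model.ring_borders if spec.plane in ("cross", "radial") else None
    onsets = model.latewood_onsets if spec.plane in ("cross", "radial") else None
    resolved = replace(spec, offset=offset, extent=((u_lo, u_hi), (v_lo, v_hi)))
    return SectionImage(
        labels=labels,
        counts=counts,
        spec=resolved,
        pixel_size_um=spec.resolution,
        origin=(u_lo, v_lo),
        ring_borders=borders,
        latewood_onsets=onsets,
    )


def _row_slice(cent: np.ndarray, lo: float, hi: float) -> slice:
    i0 = int(np.searchsorted(cent, lo, side="left"))
    i1 = int(np.searchsorted(cent, hi, side="left"))
    return slice(i0, i1)


def _paint(labels, counts, rs: slice, cs: slice, mask: np.ndarray, rid: int) -> None:
    if not mask.any():
        return
    sub = labels[rs, cs]
    sub[mask & (sub == 0)] = rid
    csub = counts[rs, cs]
    csub[mask] = np.minimum(csub[mask].astype(np.int32) + 1, 255).astype(np.uint8)


def _fill_cross(model, row, g, offset, tau, tan_a, r_mid, r_cent, t_cent, labels, counts):
    rs = _row_slice(r_cent, row.r_init, row.r_term)
    if rs.start >= rs.stop:
        return
    r = r_cent[rs]
    slab_c = offset + tan_a * (r - r_mid)
    h_mm = (row.height_um + g * (r - row.r_init)) / 1000.0
    d = np.abs(row.z_center - slab_c) - tau / 2.0
    np.clip(d, 0.0, None, out=d)
    u = d / (h_mm / 2.0)
    vis = u < 1.0
    if not vis.any():
        return
    hw = model.width_scale_at(r) * (row.width_um / 2000.0) * _profile(u, row.lens_p)
    hw[~vis] = -1.0
    hw_max = hw.max()
    cs = _row_slice(t_cent, row.t_center - hw_max, row.t_center + hw_max)
    if cs.start >= cs.stop:
        return
    mask = np.abs(t_cent[cs][None, :] - row.t_center) <= hw[:, None]
    _paint(labels, counts, rs, cs, mask, row.ray_id)


def _fill_tangential(model, row, g, offset, tau, tan_a, t_mid, z_cent, t_cent, labels, counts):
    w_half = row.width_um / 2000.0 * float(model._seg_scale.max())
    cs = _row_slice(t_cent, row.t_center - w_half, row.t_center + w_half)
    if cs.start >= cs.stop:
        return
    t = t_cent[cs]
    win_c = offset + tan_a * (t - t_mid)
    win_lo = np.maximum(win_c - tau / 2.0, row.r_init)
    win_hi = np.minimum(win_c + tau / 2.0, row.r_term)
    # a zero-thickness plane exactly at a span endpoint still cuts the ray
    ok = win_hi >= win_lo if tau == 0.0 else win_hi > win_lo
    if not ok.any():
        return
    s_eff = np.full(len(t), -1.0)
    h_eff = np.zeros(len(t))
    for j in np.nonzero(ok)[0]:
        s_eff[j] = model.width_scale_max(win_lo[j], win_hi[j])
        h_eff[j] = row.height_um + g * (win_hi[j] - row.r_init)
    h_top = h_eff.max() / 1000.0
    rs = _row_slice(z_cent, row.z_center - h_top / 2.0, row.z_center + h_top / 2.0)
    if rs.start >= rs.stop:
        return
    z = z_cent[rs]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = 2.0 * (z[:, None] - row.z_center) / (h_eff[None, :] / 1000.0)
    u = np.where(np.isfinite(u), u, 2.0)
    hw = s_eff[None, :] * (row.width_um / 2000.0) * _profile(u, row.lens_p)
    mask = (s_eff[None, :] > 0) & (np.abs(t[None, :] - row.t_center) <= hw)
    _paint(labels, counts, rs, cs, mask, row.ray_id)


def _fill_radial(model, row, g, offset, tau, tan_a, r_mid, r_cent, z_cent, labels, counts):
    rs = _row_slice(r_cent, row.r_init, row.r_term)
    if rs.start >= rs.stop:
        return
    r = r_cent[rs]
    slab_c = offset + tan_a * (r - r_mid)
    d = np.abs(row.t_center - slab_c) - tau / 2.0
    np.clip(d, 0.0, None, out=d)
    hw_max = model.width_scale_at(r) * (row.width_um / 2000.0)
    rel = np.where(hw_max > 0, d / hw_max, 2.0)
    vis = rel < 1.0
    if not vis.any():
        return
    if row.lens_p > 0:
        umax = np.sqrt(np.clip(1.0 - rel ** (1.0 / row.lens_p), 0.0, 1.0))
    else:
        umax = np.where(vis, 1.0, 0.0)
    umax[~vis] = 0.0
    h_mm = (row.height_um + g * (r - row.r_init)) / 1000.0
    half_z = umax * h_mm / 2.0
    z_top = half_z.max()
    cs = _row_slice(z_cent, row.z_center - z_top, row.z_center + z_top)
    if cs.start >= cs.stop:
        return
    mask = np.abs(z_cent[cs][None, :] - row.z_center) <= half_z[:, None]
    mask &= vis[:, None]
    _paint(labels, counts, rs, cs, mask, row.ray_id)


# ---------------------------------------------------------------------------
# exact projected outlines (vector geometry)
# ---------------------------------------------------------------------------


def projected_outline(ray: Ray3D, spec: SectionSpec, width_scale=None, sector_extents=None, n_samples: int = 257):
    """Exact union-over-depth silhouette of one ray within the slab, as a
    shapely geometry in plane coordinates (axis0, axis1 of the section).

    ``width_scale`` is an optional callable s(r) for the tangential width
    modulation (default 1).  ``sector_extents`` = (R, T, Z) supplies slab
    midpoints for misaligned cuts; by default the ray's own span is used.
    Returns an empty polygon when the ray does not intersect the slab.
    """
    scale = width_scale if width_scale is not None else (lambda r: np.ones_like(np.asarray(r, dtype=float)))
    tau = spec.thickness / 1000.0
    tan_a = math.tan(math.radians(spec.misalignment_deg))
    if sector_extents is not None:
        R, T, Z = sector_extents
        mids = {"cross": R / 2.0, "radial": R / 2.0, "tangential": T / 2.0}
        norm_ext = {"cross": Z, "tangential": R, "radial": T}[spec.plane]
    else:
        mids = {"cross": (ray.r_init + ray.r_term) / 2.0, "radial": (ray.r_init + ray.r_term) / 2.0, "tangential": ray.t_center}
        norm_ext = None
    offset = spec.offset
    if offset is None:
        if norm_ext is None:
            raise SectionError("projected_outline requires an explicit offset or sector_extents")
        offset = norm_ext / 2.0

    if spec.plane == "tangential":
        win_lo = max(offset - tau / 2.0, ray.r_init)
        win_hi = min(offset + tau / 2.0, ray.r_term)
        if (win_hi < win_lo) or (tau > 0 and win_hi <= win_lo):
            return Polygon()
        rr = np.linspace(win_lo, win_hi, 65)
        s_eff = float(np.max(scale(rr)))
        h_mm = float(ray.height_at(win_hi)) / 1000.0
        u = np.linspace(-1.0, 1.0, n_samples)
        hw = ray.half_width_mm(u, s_eff)
        z = ray.z_center + u * h_mm / 2.0
        pts = list(zip(z, ray.t_center + hw)) + list(zip(z[::-1], ray.t_center - hw[::-1]))
        return Polygon(pts).buffer(0)

    r = np.linspace(ray.r_init, ray.r_term, n_samples)
    slab_c = offset + tan_a * (r - mids[spec.plane])
    if spec.plane == "cross":
        d = np.clip(np.abs(ray.z_center - slab_c) - tau / 2.0, 0.0, None)
        h_mm = ray.height_at(r) / 1000.0
        u = d / (h_mm / 2.0)
        hw = np.asarray(scale(r)) * ray.half_width_mm(np.minimum(u, 1.0)) * (np.abs(u) < 1.0)
        half = hw
        center = ray.t_center
    else:  # radial
        d = np.clip(np.abs(ray.t_center - slab_c) - tau / 2.0, 0.0, None)
        hw_max = np.asarray(scale(r)) * (ray.width_um / 2000.0)
        rel = np.where(hw_max > 0, d / hw_max, 2.0)
        if ray.lens_p > 0:
            umax = np.sqrt(np.clip(1.0 - rel ** (1.0 / ray.lens_p), 0.0, 1.0))
        else:
            umax = (rel < 1.0).astype(float)
        umax = np.where(rel < 1.0, umax, 0.0)
        half = umax * (ray.height_at(r) / 1000.0) / 2.0
        center = ray.z_center

    vis = half > 0
    if not vis.any():
        return Polygon()
    polys = []
    start = None
    for i, v in enumerate(np.append(vis, False)):
        if v and start is None:
            start = i
        elif not v and start is not None:
            seg = slice(start, i)
            pts = list(zip(r[seg], center + half[seg])) + list(zip(r[seg][::-1], center - half[seg][::-1]))
            if len(pts) >= 3:
                polys.append(Polygon(pts).buffer(0))
            start = None
    if not polys:
        return Polygon()
    return unary_union(polys)
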