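"""Ray metrics from section label maps.

Extracts per-ray outlines (area, extents, derived width) and per-ring
statistics for cross-sections: areal ray percentage (PERPAR) overall and
split into early-/latewood, initiating rays (NEWRAY, standardized per mm of
tangential section width), disappearing rays, and dimension means.

Counting conventions
--------------------
* Outlines touching the image boundary are flagged and excluded from
  dimension statistics (their extents are censored), but their pixels do
  count toward PERPAR, which is a pure area fraction.
* Initiating/disappearing rays use an unbiased counting-frame rule:
  outlines touching the *left* tangential image edge are excluded (the
  right edge is allowed), so the expected count per mm of width is exact
  despite clipping.  Outlines touching the radial (top/bottom) image edges
  are never counted, since their radial ends are censored.
* A ray initiates in ring k if its inner radial end lies more than one
  pixel beyond the ring's inner border (the tolerance absorbs raster
  jitter); it is assigned to earlywood or latewood by the radial position
  of that inner end.  Disappearing rays are the mirror rule at the outer
  border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .microtome import SectionImage

__all__ = [
    "TimeSeries",
    "extract_outlines",
    "compute_perpar",
    "ring_metrics",
    "assemble_time_series",
    "MetricsError",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class TimeSeries:
    """A year-indexed metric series."""

    years: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        years = np.asarray(self.years)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if len(years) != len(values):
            raise MetricsError("years and values must have equal length")
        if len(years) > 1 and not np.all(np.diff(years) > 0):
            raise MetricsError("years must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise MetricsError(f"non-finite values in series {self.name!r}")

    def __len__(self) -> int:
        return len(self.values)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"), name=self.name or "value")


# ---------------------------------------------------------------------------
# outline extraction
# ---------------------------------------------------------------------------

OUTLINE_COLUMNS = [
    "ray_id",
    "ring_id",
    "area_um2",
    "height_um",
    "length_um",
    "width_um",
    "centroid_0_mm",
    "centroid_1_mm",
    "inner_end_mm",
    "outer_end_mm",
    "initiating",
    "disappearing",
    "touches_edge",
]


def extract_outlines(image: SectionImage) -> pd.DataFrame:
    """One outline per ray label present in the image.

    Heights (tangential plane) and lengths (cross/radial planes) are
    axis-aligned extents; the derived width follows the area/height rule
    for tangential outlines and area/length for the other planes.
    ``initiating``/``disappearing`` are filled in by :func:`ring_metrics`
    for cross-sections and default to False here.
    """
    labels = image.labels
    px_um = image.pixel_size_um
    px_mm = image.pixel_size_mm
    nz = np.nonzero(labels)
    if len(nz[0]) == 0:
        return pd.DataFrame(columns=OUTLINE_COLUMNS + ["_touch_left", "_touch_row0", "_touch_rowN"])
    df = pd.DataFrame({"ray_id": labels[nz], "row": nz[0], "col": nz[1]})
    agg = df.groupby("ray_id").agg(
        n_px=("row", "size"),
        row_min=("row", "min"),
        row_max=("row", "max"),
        col_min=("col", "min"),
        col_max=("col", "max"),
        row_sum=("row", "sum"),
        col_sum=("col", "sum"),
    )
    n0, n1 = labels.shape
    area = agg["n_px"].to_numpy(dtype=float) * px_um**2
    ext0_um = (agg["row_max"] - agg["row_min"] + 1).to_numpy(dtype=float) * px_um
    ext1_um = (agg["col_max"] - agg["col_min"] + 1).to_numpy(dtype=float) * px_um
    touch0 = (agg["row_min"].to_numpy() == 0) | (agg["row_max"].to_numpy() == n0 - 1)
    touch1 = (agg["col_min"].to_numpy() == 0) | (agg["col_max"].to_numpy() == n1 - 1)
    cent0 = image.origin[0] + (agg["row_sum"].to_numpy() / agg["n_px"].to_numpy() + 0.5) * px_mm
    cent1 = image.origin[1] + (agg["col_sum"].to_numpy() / agg["n_px"].to_numpy() + 0.5) * px_mm

    if image.plane == "tangential":
        height = ext0_um  # axial extent
        length = np.full_like(height, np.nan)
        width = area / height
    else:
        length = ext0_um  # radial extent
        height = np.full_like(length, np.nan)
        width = area / length

    inner_end = image.origin[0] + (agg["row_min"].to_numpy() + 0.5) * px_mm
    outer_end = image.origin[0] + (agg["row_max"].to_numpy() + 0.5) * px_mm

    ring_id = np.full(len(agg), -1)
    if image.ring_borders is not None:
        ring_id = np.clip(
            np.searchsorted(image.ring_borders, cent0, side="right") - 1,
            0,
            len(image.ring_borders) - 2,
        )

    out = pd.DataFrame(
        {
            "ray_id": agg.index.to_numpy(),
            "ring_id": ring_id,
            "area_um2": area,
            "height_um": height,
            "length_um": length,
            "width_um": width,
            "centroid_0_mm": cent0,
            "centroid_1_mm": cent1,
            "inner_end_mm": inner_end,
            "outer_end_mm": outer_end,
            "initiating": False,
            "disappearing": False,
            "touches_edge": touch0 | touch1,
            "_touch_left": agg["col_min"].to_numpy() == 0,
            "_touch_row0": agg["row_min"].to_numpy() == 0,
            "_touch_rowN": agg["row_max"].to_numpy() == n0 - 1,
        }
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# PERPAR
# ---------------------------------------------------------------------------

Region = Tuple[Tuple[float, float], Tuple[float, float]]


def compute_perpar(
    image: SectionImage,
    region: Optional[Region] = None,
    zone: Optional[str] = None,
) -> float:
    """Percentage of ray pixels among all xylem pixels in a region/zone.

    ``region`` is an in-plane rectangle ((axis0_lo, axis0_hi),
    (axis1_lo, axis1_hi)) in mm; ``zone`` restricts cross/radial images to
    'early' or 'late' wood rows.
    """
    mask = image.ray_mask
    rows = np.ones(mask.shape[0], dtype=bool)
    cols = np.ones(mask.shape[1], dtype=bool)
    if region is not None:
        (a0, b0), (a1, b1) = region
        c0, c1 = image.axis0_centers(), image.axis1_centers()
        rows &= (c0 >= a0) & (c0 < b0)
        cols &= (c1 >= a1) & (c1 < b1)
    if zone is not None:
        if zone not in ("early", "late"):
            raise MetricsError(f"zone must be 'early' or 'late', got {zone!r}")
        rows &= image.zone_of_axis0() == (1 if zone == "late" else 0)
    sub = mask[np.ix_(rows, cols)]
    if sub.size == 0:
        raise MetricsError("region has zero area")
    return 100.0 * float(np.count_nonzero(sub)) / sub.size


# ---------------------------------------------------------------------------
# per-ring metrics (cross-sections)
# ---------------------------------------------------------------------------

RING_METRIC_COLUMNS = [
    "ring",
    "ring_width_mm",
    "perpar",
    "perpar_early",
    "perpar_late",
    "newray_count",
    "newray_per_mm",
    "newray_early_per_mm",
    "newray_late_per_mm",
    "newray_early_count",
    "newray_late_count",
    "disappearing_count",
    "mean_ray_area_um2",
    "mean_ray_length_um",
    "mean_ray_width_um",
    "n_outlines",
]


def ring_metrics(image: SectionImage, outlines: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-ring ray statistics of a cross-section image.

    Returns one row per annual ring with PERPAR (overall / earlywood /
    latewood), initiating-ray counts standardized per mm of tangential
    width and split by the zone of the inner ray end, disappearing-ray
    counts, and dimension means over non-edge outlines.
    """
    if image.plane != "cross":
        raise MetricsError(f"ring metrics require a cross-plane image, got {image.plane!r}")
    if image.ring_borders is None or image.latewood_onsets is None:
        raise MetricsError("ring metrics require ring borders and latewood onsets")
    if outlines is None:
        outlines = extract_outlines(image)

    borders = image.ring_borders
    onsets = image.latewood_onsets
    n_rings = len(onsets)
    width_mm = image.width_mm
    tol = image.pixel_size_mm  # one-pixel tolerance against raster jitter
    mask = image.ray_mask
    zone_rows = image.zone_of_axis0()
    r_cent = image.axis0_centers()

    # unbiased counting frame: the left tangential edge is the forbidden
    # line; an inner (outer) end is only trusted if the outline does not
    # touch the top (bottom) radial image edge that would censor it
    if len(outlines):
        sel = ~outlines["_touch_left"]
        init_table = outlines.loc[sel & ~outlines["_touch_row0"]]
        disap_table = outlines.loc[sel & ~outlines["_touch_rowN"]]
    else:
        init_table = disap_table = outlines
    outlines = outlines.copy()

    rows = []
    for k in range(n_rings):
        a, b = borders[k], borders[k + 1]
        in_ring = (r_cent >= a) & (r_cent < b)
        ring_mask = mask[in_ring]
        ring_zone = zone_rows[in_ring]
        n_px = ring_mask.size
        perpar = 100.0 * np.count_nonzero(ring_mask) / n_px if n_px else np.nan
        early_sel = ring_zone == 0
        late_sel = ~early_sel
        pe = 100.0 * np.count_nonzero(ring_mask[early_sel]) / max(ring_mask[early_sel].size, 1)
        pl = 100.0 * np.count_nonzero(ring_mask[late_sel]) / max(ring_mask[late_sel].size, 1)

        if len(init_table):
            inner = init_table["inner_end_mm"].to_numpy()
            init_sel = (inner > a + tol) & (inner < b)
            init_late = init_sel & (inner >= onsets[k])
            n_init = int(init_sel.sum())
            n_init_l = int(init_late.sum())
            n_init_e = n_init - n_init_l
            outlines.loc[outlines["ray_id"].isin(init_table.loc[init_sel, "ray_id"]), "initiating"] = True
        else:
            n_init = n_init_e = n_init_l = 0
        if len(disap_table):
            outer = disap_table["outer_end_mm"].to_numpy()
            disap_sel = (outer < b - tol) & (outer >= a)
            n_disap = int(disap_sel.sum())
            outlines.loc[outlines["ray_id"].isin(disap_table.loc[disap_sel, "ray_id"]), "disappearing"] = True
        else:
            n_disap = 0

        if len(outlines):
            dim_sel = (~outlines["touches_edge"]) & (outlines["centroid_0_mm"] >= a) & (outlines["centroid_0_mm"] < b)
            dims = outlines.loc[dim_sel]
        else:
            dims = outlines
        rows.append(
            {
                "ring": k,
                "ring_width_mm": b - a,
                "perpar": perpar,
                "perpar_early": pe,
                "perpar_late": pl,
                "newray_count": n_init,
                "newray_per_mm": n_init / width_mm,
                "newray_early_per_mm": n_init_e / width_mm,
                "newray_late_per_mm": n_init_l / width_mm,
                "newray_early_count": n_init_e,
                "newray_late_count": n_init_l,
                "disappearing_count": n_disap,
                "mean_ray_area_um2": dims["area_um2"].mean() if len(dims) else np.nan,
                "mean_ray_length_um": dims["length_um"].mean() if len(dims) else np.nan,
                "mean_ray_width_um": dims["width_um"].mean() if len(dims) else np.nan,
                "n_outlines": int(len(dims)),
            }
        )
    return pd.DataFrame(rows, columns=RING_METRIC_COLUMNS)


def assemble_time_series(
    metrics: Union[pd.DataFrame, Iterable[pd.DataFrame]],
    metric: str,
    years: Optional[Sequence[int]] = None,
) -> TimeSeries:
    """Year-ordered series of one named ring metric.

    ``metrics`` is a ring-metrics table (or several, concatenated); years
    default to the ring indices.  Rows may arrive unordered.
    """
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.concat(list(metrics), ignore_index=True)
    if len(metrics) < 2:
        raise MetricsError("need at least 2 rings for a time series")
    if metric not in metrics.columns:
        raise MetricsError(f"unknown metric {metric!r}; valid names: {sorted(metrics.columns)}")
    df = metrics.copy()
    if years is not None:
        if len(years) != len(df):
            raise MetricsError("years must match the number of rings")
        df["year"] = np.asarray(years)
    elif "year" not in df.columns:
        df["year"] = df["ring"]
    df = df.sort_values("year")
    if df["year"].duplicated().any():
        raise MetricsError("duplicate years in ring metrics")
    return TimeSeries(years=df["year"].to_numpy(), values=df[metric].to_numpy(dtype=float), name=metric)
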