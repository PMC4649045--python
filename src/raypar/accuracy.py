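"""Measurement-accuracy analysis: random window sampling, bootstrap CV
curves, and the CI95 sample-size planner.

The accuracy of an areal ray-fraction (PERPAR) estimate depends on the
measured wood surface and on the number of samples.  Following the
stem-disc design, PERPAR values from many randomly placed measurement
windows are pooled; resampling s of them with replacement and averaging
simulates measuring s times the window surface, and the coefficient of
variation CV(s) of those bootstrap estimates quantifies the precision.
The relative 95% confidence interval for n independent samples then is

    CI95 = 2 * CV * n^(-1/2)    (as a percentage of the mean),

since CI95 ~ 2 SE, SE = SD / sqrt(n) and SD = CV * mean.  Inverting the
formula gives the smallest sample count reaching a target CI95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .microtome import SectionImage

__all__ = [
    "WindowSamplePool",
    "AccuracyCurve",
    "sample_windows",
    "pool_windows",
    "bootstrap_accuracy",
    "ci95",
    "required_samples",
    "PerparAccuracy",
    "PerparAccuracyResults",
    "AccuracyError",
]


class AccuracyError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSamplePool:
    """PERPAR values (%) from randomly placed measurement windows.

    ``window_size`` is mm^2 for tangential windows and mm of width for
    cross-sectional full-height strips (``mode``).
    """

    values: np.ndarray
    window_size: float
    mode: str = "tangential"  # or "cross-strip"
    source_sections: tuple = ()
    seed: Optional[int] = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.window_size <= 0:
            raise AccuracyError(f"window_size must be positive, got {self.window_size}")
        if values.size and (values.min() < 0 or values.max() > 100):
            raise AccuracyError("PERPAR window values must lie in [0, 100]")

    @property
    def count(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class AccuracyCurve:
    """Bootstrap mean and CV of the PERPAR estimate per measured size.

    ``sizes`` counts pooled windows, i.e. multiples of the window surface
    (tangential) or strip width (cross).
    """

    sizes: np.ndarray
    means: np.ndarray
    cvs: np.ndarray
    reps: int
    window_size: float = 1.0
    mode: str = "tangential"

    def __post_init__(self):
        object.__setattr__(self, "sizes", np.asarray(self.sizes))
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "cvs", np.asarray(self.cvs, dtype=float))
        if not np.all(np.diff(self.sizes) > 0):
            raise AccuracyError("sizes must be strictly increasing")
        if np.any(self.cvs < 0):
            raise AccuracyError("cv must be non-negative")

    def cv_at(self, size) -> float:
        idx = int(np.nonzero(self.sizes == size)[0][0])
        return float(self.cvs[idx])

    def to_frame(self, n_grid: Sequence[int] = (5, 10, 15, 20)) -> pd.DataFrame:
        df = pd.DataFrame({"size": self.sizes, "mean": self.means, "cv": self.cvs})
        for n in n_grid:
            df[f"ci95_n{n}"] = [ci95(cv, n) for cv in self.cvs]
        return df


# ---------------------------------------------------------------------------
# window sampling
# ---------------------------------------------------------------------------


def _integral_image(mask: np.ndarray) -> np.ndarray:
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def _box_sum(ii: np.ndarray, r0, r1, c0, c1):
    return ii[r1, c1] - ii[r0, c1] - ii[r1, c0] + ii[r0, c0]


def sample_windows(
    image: SectionImage,
    window_size: float,
    count: int,
    seed: int = 0,
    mode: Optional[str] = None,
) -> WindowSamplePool:
    """Place ``count`` windows uniformly at random, fully inside the image
    (overlaps permitted), and return the PERPAR of each.

    Tangential mode places square windows of ``window_size`` mm^2;
    cross-strip mode places full-height strips of ``window_size`` mm
    width.  The mode defaults to the image's plane.
    """
    if mode is None:
        mode = "cross-strip" if image.plane == "cross" else "tangential"
    if mode not in ("tangential", "cross-strip"):
        raise AccuracyError(f"unknown sampling mode {mode!r}")
    n0, n1 = image.shape
    px = image.pixel_size_mm
    if mode == "tangential":
        side_px = int(round(math.sqrt(window_size) / px))
        rows_px, cols_px = side_px, side_px
    else:
        rows_px, cols_px = n0, int(round(window_size / px))
    if rows_px < 1 or cols_px < 1:
        raise AccuracyError("window smaller than one pixel")
    if rows_px > n0 or cols_px > n1:
        raise AccuracyError(
            f"window of {rows_px}x{cols_px} px does not fit inside the {n0}x{n1} px image"
        )
    rng = substream(seed, "windows")
    r0 = rng.integers(0, n0 - rows_px + 1, size=count)
    c0 = rng.integers(0, n1 - cols_px + 1, size=count)
    ii = _integral_image(image.ray_mask)
    hits = _box_sum(ii, r0, r0 + rows_px, c0, c0 + cols_px)
    values = 100.0 * hits / float(rows_px * cols_px)
    return WindowSamplePool(values=values, window_size=window_size, mode=mode, seed=seed)


def pool_windows(pools: Sequence[WindowSamplePool]) -> WindowSamplePool:
    """Pool window values from several sections into one exchangeable pool."""
    if not pools:
        raise AccuracyError("no pools to combine")
    sizes = {p.window_size for p in pools}
    modes = {p.mode for p in pools}
    if len(sizes) > 1 or len(modes) > 1:
        raise AccuracyError("pools must share window size and mode")
    return WindowSamplePool(
        values=np.concatenate([p.values for p in pools]),
        window_size=pools[0].window_size,
        mode=pools[0].mode,
        source_sections=tuple(range(len(pools))),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_accuracy(
    pool: WindowSamplePool,
    sizes: Sequence[int] = tuple(range(1, 16)),
    reps: int = 1000,
    seed: int = 0,
) -> AccuracyCurve:
    """Bootstrap the PERPAR estimate for increasing measured surface.

    For each size s, ``reps`` estimates are formed, each the mean of s
    values drawn from the pool with replacement ("randomly combining an
    increasing number of windows"); the curve stores the mean and the CV
    (sd with n-1 denominator over mean) of those estimates.
    """
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if reps < 2:
        raise AccuracyError(f"reps must be >= 2, got {reps}")
    if pool.count < int(sizes.max()):
        raise AccuracyError(f"pool of {pool.count} values smaller than largest size {sizes.max()}")
    if not np.any(pool.values != 0):
        raise AccuracyError("pool contains only zeros: CV of the estimate is undefined")
    rng = substream(seed, "bootstrap")
    means = np.empty(len(sizes))
    cvs = np.empty(len(sizes))
    for i, s in enumerate(sizes):
        draws = rng.choice(pool.values, size=(reps, s), replace=True)
        est = draws.mean(axis=1)
        m = est.mean()
        means[i] = m
        cvs[i] = est.std(ddof=1) / m
    return AccuracyCurve(sizes=sizes, means=means, cvs=cvs, reps=reps, window_size=pool.window_size, mode=pool.mode)


# ---------------------------------------------------------------------------
# CI95 planner
# ---------------------------------------------------------------------------


def ci95(cv: float, n: int) -> float:
    """Relative 95% confidence interval, as a percentage of the mean:
    ``100 * 2 * cv / sqrt(n)``."""
    if cv < 0:
        raise AccuracyError(f"cv must be >= 0, got {cv}")
    if n < 1:
        raise AccuracyError(f"n must be >= 1, got {n}")
    return 200.0 * cv / math.sqrt(n)


def required_samples(cv: float, target_ci95: float) -> int:
    """Smallest integer n with ``ci95(cv, n) <= target_ci95`` (percent)."""
    if cv <= 0:
        raise AccuracyError(f"cv must be > 0, got {cv}")
    if target_ci95 <= 0:
        raise AccuracyError(f"target CI95 must be > 0, got {target_ci95}")
    n = max(1, math.ceil((200.0 * cv / target_ci95) ** 2 - 1e-9))
    while n > 1 and ci95(cv, n - 1) <= target_ci95:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------


class PerparAccuracy:
    """Accuracy model for PERPAR estimation from pooled windows.

    Parameters
    ----------
    pool : WindowSamplePool
        Pooled per-window PERPAR values (exchangeable).
    sizes : sequence of int
        Measured-surface grid, in multiples of the window size.
    reps : int
        Bootstrap replications per size.

    ``fit`` bootstraps the accuracy curve and returns a results object
    with CI95 curves, a sample-size planner and a summary table.
    """

    def __init__(self, pool: WindowSamplePool, sizes: Sequence[int] = tuple(range(1, 16)), reps: int = 1000):
        self.pool = pool
        self.sizes = tuple(sizes)
        self.reps = reps

    def fit(self, seed: int = 0) -> "PerparAccuracyResults":
        curve = bootstrap_accuracy(self.pool, self.sizes, self.reps, seed=seed)
        return PerparAccuracyResults(self, curve)


class PerparAccuracyResults:
    """Fitted accuracy curves plus Eq.-style planning helpers."""

    def __init__(self, model: PerparAccuracy, curve: AccuracyCurve):
        self.model = model
        self.curve = curve

    def ci95(self, size: int, n: int) -> float:
        """CI95 (% of mean) for n samples of the given measured size."""
        return ci95(self.curve.cv_at(size), n)

    def required_samples(self, size: int, target_ci95: float) -> int:
        return required_samples(self.curve.cv_at(size), target_ci95)

    def summary(self, n_grid: Sequence[int] = (5, 10, 15, 20)) -> pd.DataFrame:
        return self.curve.to_frame(n_grid)

    def plot(self, n_grid: Sequence[int] = (5, 10, 15, 20), ax=None):
        """CI95 versus measured size, one curve per sample count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        unit = "mm²" if self.curve.mode == "tangential" else "mm"
        for n in n_grid:
            ax.plot(self.curve.sizes, [ci95(cv, n) for cv in self.curve.cvs], marker="o", label=f"n = {n}")
        ax.set_xlabel(f"measured size per sample ({unit})")
        ax.set_ylabel("CI95 (% of mean)")
        ax.legend()
        return ax
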