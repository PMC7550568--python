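"""Log-log regression and selection of the fractal scaling interval.

For a fractal object the counts follow a power law N(s) = C * s^(-FD) over
a limited interval of spatial scales [mfs, Mfs] (minimum / maximum fractal
scale); FD is the absolute slope of the ordinary least-squares line fitted
to log10 N(s) versus log10 s restricted to that interval.  Four selection
strategies are provided:

``apriori1``
    Fixed interval [4 mm, 256 mm] — head-scale upper bound, box sides well
    above cortical thickness as lower bound.
``apriori2``
    5% and 40% of the shortest side of the foreground bounding box, each
    rounded to a power of two (geometric nearest by default).
``marzi2018``
    Exhaustive search over all contiguous windows with at least 4 points;
    the window with the highest adjusted R^2 wins.
``fractalbrain``
    Exhaustive search over windows with at least 5 points, ranked by the
    adjusted R^2 *rounded to 3 decimal places*; rounding ties are broken by
    preferring the widest interval (most points on the log-log plot), and
    residual ties by the smallest mfs.  Requiring 5 dyadic points guarantees
    a width of at least log10(16) ~ 1.2 decades, the smallest span above one
    decade on this sampling, so a winning fit always covers a scale range
    wide enough to speak of fractal behaviour.

The adjustment for the number of points in a one-predictor regression is
R^2_adj = 1 - (1 - R^2) (n - 1) / (n - 2).  Rounding R^2_adj before
comparing discards non-effective decimal places: R^2 is a proportion of
explained variance, and one decimal place on the percentage scale equals
three decimals in natural scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boxcount import BoxCountCurve, ScaleSet
from .errors import (
    BoundsNotSampledError,
    DegenerateIntervalError,
    EmptyVolumeError,
    IntervalOutOfRangeError,
    InvalidBoundsError,
    TooFewScalesError,
)
from .volume_io import VoxelVolume

STRATEGY_NAMES = ("apriori1", "apriori2", "marzi2018", "fractalbrain")


@dataclass(frozen=True)
class ScaleInterval:
    """Contiguous window [mfs, Mfs] of sampled scales (indices inclusive)."""

    start: int
    stop: int
    mfs: float  # mm
    Mfs: float  # mm

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise DegenerateIntervalError(
                f"interval needs >= 2 scales, got indices [{self.start}, {self.stop}]"
            )
        if not 0 < self.mfs < self.Mfs:
            raise InvalidBoundsError(f"need 0 < mfs < Mfs, got ({self.mfs}, {self.Mfs})")

    @property
    def n_points(self) -> int:
        return self.stop - self.start + 1

    @property
    def width_decades(self) -> float:
        return width_decades(self.mfs, self.Mfs)

    @classmethod
    def from_indices(cls, scale_set: ScaleSet, start: int, stop: int) -> "ScaleInterval":
        if not (0 <= start < stop < len(scale_set)):
            raise IntervalOutOfRangeError(
                f"indices [{start}, {stop}] invalid for {len(scale_set)} scales"
            )
        mm = scale_set.scales_mm
        return cls(start=start, stop=stop, mfs=float(mm[start]), Mfs=float(mm[stop]))


@dataclass(frozen=True)
class LogLogFit:
    """OLS fit of log10 N(s) on log10 s; FD is the absolute slope."""

    slope: float
    intercept: float  # log10 of the power-law prefactor C
    fd: float
    r2: float
    r2_adj: float
    n_points: int

    @property
    def prefactor(self) -> float:
        return 10.0 ** self.intercept


def width_decades(mfs: float, Mfs: float) -> float:
    """Interval width in decades, log10(Mfs / mfs)."""
    if not 0 < mfs < Mfs:
        raise InvalidBoundsError(f"need 0 < mfs < Mfs, got ({mfs}, {Mfs})")
    return math.log10(Mfs / mfs)


def round_half_away(x: float, places: int = 3) -> float:
    """Round to `places` decimals with ties going away from zero.

    Python's built-in round is banker's rounding; selection ranks must use
    the conventional tie-away rule so a fit of exactly .9995 rounds to 1.000.
    """
    factor = 10.0 ** places
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def adjusted_r2(r2: float, n: int) -> float:
    """Adjust for the number of points in a single-predictor regression."""
    if n < 3:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_loglog(curve: BoxCountCurve, interval: ScaleInterval) -> LogLogFit:
    """OLS of log10 mean counts on log10 scale (mm) within the interval."""
    n_scales = len(curve.scale_set)
    if not (0 <= interval.start < interval.stop < n_scales):
        raise IntervalOutOfRangeError(
            f"interval [{interval.start}, {interval.stop}] outside curve"
        )
    sl = slice(interval.start, interval.stop + 1)
    counts = curve.mean_counts[sl]
    if (counts <= 0).any():
        raise DegenerateIntervalError("counts must be positive for log fit")
    x = np.log10(curve.scales_mm[sl])
    y = np.log10(counts)
    return _fit_xy(x, y)


def _fit_xy(x: np.ndarray, y: np.ndarray) -> LogLogFit:
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise DegenerateIntervalError("fewer than 2 distinct scales")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        # constant counts: a zero-slope line is an exact fit
        r2 = 1.0 if ss_res < 1e-24 else 0.0
    r2 = min(max(r2, 0.0), 1.0)
    return LogLogFit(slope=slope, intercept=intercept, fd=abs(slope),
                     r2=r2, r2_adj=adjusted_r2(r2, n), n_points=n)


def enumerate_intervals(scale_set: ScaleSet, min_points: int) -> list[ScaleInterval]:
    """All contiguous windows with at least ``min_points`` scales,
    ordered by start index then end index."""
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    n = len(scale_set)
    if n < min_points:
        raise TooFewScalesError(f"{n} scales < min_points={min_points}")
    out = []
    for start in range(n - min_points + 1):
        for stop in range(start + min_points - 1, n):
            out.append(ScaleInterval.from_indices(scale_set, start, stop))
    return out


def select_apriori_fixed(scale_set: ScaleSet, mfs: float = 4.0,
                         Mfs: float = 256.0) -> ScaleInterval:
    """Fixed a-priori interval; both bounds must be sampled scales (mm)."""
    mm = scale_set.scales_mm
    lo = np.flatnonzero(np.isclose(mm, mfs, rtol=1e-9))
    hi = np.flatnonzero(np.isclose(mm, Mfs, rtol=1e-9))
    if lo.size == 0 or hi.size == 0:
        raise BoundsNotSampledError(
            f"bounds ({mfs}, {Mfs}) mm not in sampled scales {mm.tolist()}"
        )
    return ScaleInterval.from_indices(scale_set, int(lo[0]), int(hi[0]))


def _round_pow2(x: float, mode: str = "nearest") -> float:
    """Round a positive length to a power of two.

    ``nearest`` picks the geometrically nearest power (nearest exponent in
    log2 space, ties up); ``next`` rounds up to the next power.
    """
    if x <= 0:
        raise InvalidBoundsError(f"length must be positive, got {x}")
    e = math.log2(x)
    if mode == "nearest":
        k = math.floor(e)
        k = k + 1 if (e - k) >= 0.5 else k
    elif mode == "next":
        k = math.ceil(e)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return 2.0 ** k


def select_apriori_bbox(vol: VoxelVolume, scale_set: ScaleSet,
                        rounding: str = "nearest") -> ScaleInterval:
    """Interval from 5% and 40% of the shortest bounding-box side.

    The foreground bounding box is measured in mm; mfs and Mfs are 5% and
    40% of the shortest side, each rounded to a power of two, then clipped
    to the sampled scales.
    """
    coords = np.argwhere(vol.data)
    if coords.shape[0] == 0:
        raise EmptyVolumeError("volume has no foreground voxels")
    extent_vox = coords.max(axis=0) - coords.min(axis=0) + 1
    shortest_mm = float(extent_vox.min()) * vol.spacing_mm
    mfs = _round_pow2(0.05 * shortest_mm, rounding)
    Mfs = _round_pow2(0.40 * shortest_mm, rounding)
    if mfs >= Mfs:
        raise DegenerateIntervalError(
            f"rounded bounds degenerate: mfs={mfs} >= Mfs={Mfs}"
        )
    mm = scale_set.scales_mm
    inside = np.flatnonzero((mm >= mfs * (1 - 1e-9)) & (mm <= Mfs * (1 + 1e-9)))
    if inside.size < 2:
        raise DegenerateIntervalError(
            f"fewer than 2 sampled scales inside [{mfs}, {Mfs}] mm"
        )
    return ScaleInterval.from_indices(scale_set, int(inside[0]), int(inside[-1]))


def _fit_all(curve: BoxCountCurve, min_points: int
             ) -> list[tuple[ScaleInterval, LogLogFit]]:
    intervals = enumerate_intervals(curve.scale_set, min_points)
    fitted = []
    for iv in intervals:
        counts = curve.mean_counts[iv.start:iv.stop + 1]
        if (counts <= 0).any():
            continue  # unusable window (empty boxes cannot enter the log fit)
        fitted.append((iv, fit_loglog(curve, iv)))
    if not fitted:
        raise TooFewScalesError("no window with positive counts to fit")
    return fitted


def select_auto_max_r2adj(curve: BoxCountCurve, min_points: int = 4
                          ) -> tuple[ScaleInterval, LogLogFit]:
    """Window with the highest (unrounded) adjusted R^2.

    Exact ties keep the first window in enumeration order (by start then
    end index); with floating-point fits ties essentially only arise on
    exact power-law fixtures.
    """
    best = None
    for iv, fit in _fit_all(curve, min_points):
        if best is None or fit.r2_adj > best[1].r2_adj:
            best = (iv, fit)
    return best


def select_auto_fractalbrain(curve: BoxCountCurve, min_points: int = 5,
                             round_places: int = 3
                             ) -> tuple[ScaleInterval, LogLogFit]:
    """Window with the highest rounded adjusted R^2, widest interval first.

    Ranking: rounded R^2_adj descending, then width in decades descending,
    then mfs ascending (deterministic final tie-break).
    """
    ranked = []
    for iv, fit in _fit_all(curve, min_points):
        key = (-round_half_away(fit.r2_adj, round_places),
               -iv.width_decades, iv.mfs)
        ranked.append((key, iv, fit))
    ranked.sort(key=lambda t: t[0])
    _, iv, fit = ranked[0]
    return iv, fit
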