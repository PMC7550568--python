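"""Per-subject FD estimation: volume -> box-count curve -> strategy -> report.

The box-count curve is computed once per subject over the full scale set
and shared across strategies, so a comparison between strategies for the
same subject is count-identical and differs only in the selected window.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .boxcount import BoxCountCurve, ScaleSet, boxcount_curve, DEFAULT_N_OFFSETS
from .errors import VoxelFDError
from .scaleselect import (
    STRATEGY_NAMES,
    LogLogFit,
    ScaleInterval,
    fit_loglog,
    select_apriori_bbox,
    select_apriori_fixed,
    select_auto_fractalbrain,
    select_auto_max_r2adj,
)
from .volume_io import VoxelVolume, load_mask

#: estimates above this trigger a warning (offset averaging can push local
#: slopes slightly past the embedding dimension on degenerate objects)
FD_SANITY_MAX = 3.1


@dataclass
class FDReport:
    """Full record of one FD estimate, serializable to JSON."""

    subject_id: str
    strategy: str
    fd: float
    mfs_mm: float
    Mfs_mm: float
    width_decades: float
    r2: float
    r2_adj: float
    slope: float
    intercept: float
    prefactor: float
    n_points: int
    scales_mm: list[float]
    mean_counts: list[float]
    n_offsets: int
    seed: int
    software_version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "FDReport":
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "FDReport":
        return cls.from_dict(json.loads(s))


def _select(strategy: str, curve: BoxCountCurve, vol: VoxelVolume
            ) -> tuple[ScaleInterval, LogLogFit]:
    if strategy == "apriori1":
        interval = select_apriori_fixed(curve.scale_set)
        return interval, fit_loglog(curve, interval)
    if strategy == "apriori2":
        interval = select_apriori_bbox(vol, curve.scale_set)
        return interval, fit_loglog(curve, interval)
    if strategy == "marzi2018":
        return select_auto_max_r2adj(curve)
    if strategy == "fractalbrain":
        return select_auto_fractalbrain(curve)
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGY_NAMES}")


def _report(subject_id: str, strategy: str, curve: BoxCountCurve,
            interval: ScaleInterval, fit: LogLogFit) -> FDReport:
    if fit.fd > FD_SANITY_MAX:
        warnings.warn(
            f"FD estimate {fit.fd:.3f} exceeds the embedding dimension; "
            "check the input mask", stacklevel=3)
    return FDReport(
        subject_id=subject_id, strategy=strategy, fd=fit.fd,
        mfs_mm=interval.mfs, Mfs_mm=interval.Mfs,
        width_decades=interval.width_decades,
        r2=fit.r2, r2_adj=fit.r2_adj, slope=fit.slope,
        intercept=fit.intercept, prefactor=fit.prefactor,
        n_points=fit.n_points,
        scales_mm=[float(s) for s in curve.scales_mm],
        mean_counts=[float(c) for c in curve.mean_counts],
        n_offsets=curve.n_offsets, seed=int(curve.seed or 0),
    )


def estimate_fd(vol: VoxelVolume, strategy: str = "fractalbrain",
                n_offsets: int = DEFAULT_N_OFFSETS, seed: int = 0,
                scale_set: ScaleSet | None = None,
                subject_id: str = "") -> FDReport:
    """Estimate the FD of one volume with a single strategy.

    Deterministic given (volume, strategy, n_offsets, seed).  With
    ``n_offsets=0`` the counts come from a single aligned grid, the exact
    mode used by analytic phantom checks.
    """
    vol.require_isotropic()
    curve = boxcount_curve(vol, scale_set, n_offsets=n_offsets, seed=seed)
    interval, fit = _select(strategy, curve, vol)
    return _report(subject_id, strategy, curve, interval, fit)


def estimate_fd_multi(vol: VoxelVolume, strategies: Sequence[str] = STRATEGY_NAMES,
                      n_offsets: int = DEFAULT_N_OFFSETS, seed: int = 0,
                      scale_set: ScaleSet | None = None,
                      subject_id: str = "") -> list[FDReport]:
    """Estimate FD with several strategies sharing one box-count curve."""
    vol.require_isotropic()
    curve = boxcount_curve(vol, scale_set, n_offsets=n_offsets, seed=seed)
    reports = []
    for strategy in strategies:
        interval, fit = _select(strategy, curve, vol)
        reports.append(_report(subject_id, strategy, curve, interval, fit))
    return reports


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    return zlib.crc32(f"{master_seed}:{subject_id}".encode()) & 0x7FFFFFFF


BATCH_COLUMNS = ("subject_id", "strategy", "fd", "mfs_mm", "Mfs_mm",
                 "width_decades", "r2_adj", "error")


def batch_estimate(paths: Iterable[str | os.PathLike],
                   strategies: Sequence[str] = STRATEGY_NAMES,
                   n_offsets: int = DEFAULT_N_OFFSETS,
                   seed: int = 0) -> pd.DataFrame:
    """Estimate FD for a list of mask files; one row per subject x strategy.

    Subject ids are the file names without NIfTI extensions; per-subject
    seeds are derived deterministically from the master seed and the id.
    Failures are recorded in the ``error`` column rather than raised, so a
    single bad file never aborts a cohort run.
    """
    rows = []
    for path in paths:
        sid = os.path.basename(str(path))
        for ext in (".nii.gz", ".nii"):
            if sid.endswith(ext):
                sid = sid[: -len(ext)]
                break
        def error_row(strategy, exc):
            return {"subject_id": sid, "strategy": strategy, "fd": np.nan,
                    "mfs_mm": np.nan, "Mfs_mm": np.nan,
                    "width_decades": np.nan, "r2_adj": np.nan,
                    "error": f"{type(exc).__name__}: {exc}"}

        try:
            vol = load_mask(path)
            vol.require_isotropic()
            curve = boxcount_curve(vol, n_offsets=n_offsets,
                                   seed=subject_seed(seed, sid))
        except (VoxelFDError, OSError) as exc:
            rows.append(error_row(None, exc))
            continue
        for strategy in strategies:
            try:
                interval, fit = _select(strategy, curve, vol)
                rep = _report(sid, strategy, curve, interval, fit)
            except VoxelFDError as exc:
                rows.append(error_row(strategy, exc))
                continue
            rows.append({"subject_id": sid, "strategy": rep.strategy,
                         "fd": rep.fd, "mfs_mm": rep.mfs_mm,
                         "Mfs_mm": rep.Mfs_mm,
                         "width_decades": rep.width_decades,
                         "r2_adj": rep.r2_adj, "error": ""})
    return pd.DataFrame(rows, columns=list(BATCH_COLUMNS))
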