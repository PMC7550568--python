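"""3-D box counting with random grid-origin offsets.

A grid of cubic boxes of side ``s`` voxels is superimposed on the binary
volume and the number of boxes containing at least one foreground voxel is
counted.  Because an aligned grid can systematically favour or disfavour a
particular object placement, each scale is re-counted under random integer
offsets of the grid origin, drawn uniformly from {0, ..., s-1}^3, and the
counts are averaged (20 offsets by default).  Scales are sampled as powers
of two so the points are uniformly spaced on the log axis.

Offsets are integer voxel shifts: with a binary voxel image, a sub-voxel
grid shift cannot change which voxels share a cell, so integer shifts lose
no generality and keep the count exact and enumerable (the set of distinct
grids at scale s is exactly the s^3 integer offsets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyVolumeError, OffsetOutOfRangeError
from .volume_io import VoxelVolume

#: default dyadic scale sampling, s = 2^k voxels for k = 0..8
DEFAULT_SCALES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128, 256)

#: default number of random grid offsets averaged per scale
DEFAULT_N_OFFSETS = 20


@dataclass(frozen=True)
class ScaleSet:
    """Ordered box sides in voxels plus the isotropic voxel size in mm."""

    scales: tuple[int, ...] = DEFAULT_SCALES
    spacing: float = 1.0

    def __post_init__(self) -> None:
        sc = tuple(int(s) for s in self.scales)
        if len(sc) == 0 or any(s < 1 for s in sc):
            raise ValueError("scales must be >= 1")
        if any(b <= a for a, b in zip(sc, sc[1:])):
            raise ValueError("scales must be strictly increasing")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "scales", sc)

    def __len__(self) -> int:
        return len(self.scales)

    @property
    def scales_mm(self) -> np.ndarray:
        """Physical box sides in mm (voxels times isotropic spacing)."""
        return np.asarray(self.scales, dtype=float) * self.spacing

    @classmethod
    def default(cls, spacing: float = 1.0) -> "ScaleSet":
        return cls(DEFAULT_SCALES, spacing)


@dataclass
class BoxCountCurve:
    """Offset-averaged box counts N(s) over a scale set."""

    scale_set: ScaleSet
    mean_counts: np.ndarray
    n_offsets: int
    seed: int | None = None
    per_offset_counts: np.ndarray | None = None  # (n_scales, n_offsets) ints

    def __post_init__(self) -> None:
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        if len(self.mean_counts) != len(self.scale_set):
            raise ValueError("one mean count per scale required")

    @property
    def scales_mm(self) -> np.ndarray:
        return self.scale_set.scales_mm


def _foreground_coords(vol: VoxelVolume) -> np.ndarray:
    coords = np.argwhere(vol.data)
    if coords.shape[0] == 0:
        raise EmptyVolumeError("volume has no foreground voxels")
    return coords


def _count_cells(coords: np.ndarray, shape: tuple[int, int, int],
                 s: int, offset: np.ndarray) -> int:
    """Distinct occupied cells under cell index floor((v + offset) / s).

    The grid conceptually extends beyond the volume, so the shifted cell
    indices are always valid and no voxel is lost.
    """
    cells = (coords + offset) // s
    dims = [(n + s - 1) // s + 1 for n in shape]
    lin = (cells[:, 0] * dims[1] + cells[:, 1]) * dims[2] + cells[:, 2]
    return int(np.unique(lin).size)


def count_single_offset(vol: VoxelVolume, s: int,
                        offset: tuple[int, int, int] = (0, 0, 0)) -> int:
    """Box count at scale ``s`` for one explicit grid offset."""
    s = int(s)
    if s < 1:
        raise ValueError(f"scale must be >= 1, got {s}")
    off = np.asarray(offset, dtype=np.int64)
    if off.shape != (3,) or (off < 0).any() or (off >= s).any():
        raise OffsetOutOfRangeError(
            f"offset {offset} has components outside [0, {s})"
        )
    coords = _foreground_coords(vol)
    return _count_cells(coords, vol.shape, s, off)


def _scale_rng(seed: int, s: int) -> np.random.Generator:
    # independent substream per scale keyed on (seed, s): adding or removing
    # scales from the set never perturbs the draws of the other scales
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(s)]))


def boxcount_curve(vol: VoxelVolume, scale_set: ScaleSet | None = None,
                   n_offsets: int = DEFAULT_N_OFFSETS, seed: int = 0,
                   keep_per_offset: bool = False) -> BoxCountCurve:
    """Offset-averaged box-count curve over a scale set.

    With ``n_offsets=0`` a single aligned grid (offset 0) is counted per
    scale, which is exact and deterministic — the mode used for analytic
    phantoms.  Otherwise ``n_offsets`` offsets are drawn independently per
    scale from {0..s-1}^3 and the counts averaged; reproducible from
    ``seed``.
    """
    if n_offsets < 0:
        raise ValueError("n_offsets must be >= 0")
    if scale_set is None:
        scale_set = ScaleSet.default(vol.spacing_mm)
    coords = _foreground_coords(vol)
    means = np.empty(len(scale_set), dtype=float)
    per_offset = (np.empty((len(scale_set), n_offsets), dtype=np.int64)
                  if keep_per_offset and n_offsets > 0 else None)
    for i, s in enumerate(scale_set.scales):
        if n_offsets == 0:
            means[i] = _count_cells(coords, vol.shape, s, np.zeros(3, np.int64))
            continue
        rng = _scale_rng(seed, s)
        offsets = rng.integers(0, s, size=(n_offsets, 3))
        counts = np.array([_count_cells(coords, vol.shape, s, off)
                           for off in offsets], dtype=np.int64)
        if per_offset is not None:
            per_offset[i] = counts
        means[i] = counts.mean()
    return BoxCountCurve(scale_set=scale_set, mean_counts=means,
                         n_offsets=n_offsets, seed=seed,
                         per_offset_counts=per_offset)


def exhaustive_mean_count(vol: VoxelVolume, s: int) -> float:
    """Exact mean box count over all ``s**3`` integer grid offsets.

    Feasible only for small scales; used as an oracle for the sampled
    offset average.
    """
    coords = _foreground_coords(vol)
    total = 0
    for ox in range(s):
        for oy in range(s):
            for oz in range(s):
                total += _count_cells(coords, vol.shape, s,
                                      np.array([ox, oy, oz], np.int64))
    return total / s ** 3
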