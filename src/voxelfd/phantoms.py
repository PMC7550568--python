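"""Synthetic voxel phantoms and cohorts with known ground truth.

The estimator is validated against geometric objects whose dimension is
known analytically: a solid cube (dimension 3), a one-voxel-thick plane
(dimension 2), a Menger sponge (dimension log 20 / log 3 ~ 2.7268) and a
thin perturbed spherical shell that mimics a folded cortical sheet.
A cohort simulator produces age-linked feature tables (linear trend plus
Gaussian noise) for exercising the association and age-prediction layer
without any imaging data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    InvalidParamsError,
    InvalidRadiusError,
    InvalidSizeError,
    LevelOutOfRangeError,
)
from .volume_io import VoxelVolume

#: exact box-counting dimension of the Menger sponge
MENGER_FD = np.log(20) / np.log(3)


def generate_cube(side: int, spacing: float = 1.0) -> VoxelVolume:
    """Fully foreground ``side**3`` cube (topological dimension 3)."""
    if side < 2:
        raise InvalidSizeError(f"cube side must be >= 2, got {side}")
    data = np.ones((side, side, side), dtype=np.uint8)
    return VoxelVolume(data, (spacing,) * 3)


def generate_plane(side: int, spacing: float = 1.0) -> VoxelVolume:
    """One-voxel-thick ``side x side`` slab at z = 0 of a ``side**3`` volume
    (topological dimension 2)."""
    if side < 2:
        raise InvalidSizeError(f"plane side must be >= 2, got {side}")
    data = np.zeros((side, side, side), dtype=np.uint8)
    data[:, :, 0] = 1
    return VoxelVolume(data, (spacing,) * 3)


def generate_menger(level: int, spacing: float = 1.0) -> VoxelVolume:
    """Menger sponge of the given recursion level on a ``3**level`` grid.

    Construction uses the base-3 digit test: a voxel is removed iff at some
    digit position at least two of its three base-3 coordinate digits equal
    1.  This is equivalent to the recursive remove-the-7-center-subcubes
    construction but runs in O(volume) with no recursion; the foreground
    count is exactly ``20**level``.
    """
    if not 1 <= level <= 5:
        raise LevelOutOfRangeError(f"level must be in [1, 5], got {level}")
    side = 3 ** level
    idx = np.arange(side)
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    removed = np.zeros((side, side, side), dtype=bool)
    for d in range(level):
        p = 3 ** d
        ones = ((x // p % 3 == 1).astype(np.uint8)
                + (y // p % 3 == 1).astype(np.uint8)
                + (z // p % 3 == 1).astype(np.uint8))
        removed |= ones >= 2
    return VoxelVolume((~removed).astype(np.uint8), (spacing,) * 3)


def generate_shell(radius: int, perturbation_amplitude: float = 0.0,
                   seed: int = 0, spacing: float = 1.0,
                   thickness: float = 1.2) -> VoxelVolume:
    """Thin spherical shell with seeded multi-scale radial perturbation.

    The local shell radius is ``radius + A * sum_i w_i sin(l_i th + p_i) *
    sin(m_i ph + q_i)`` with three harmonics whose integer frequencies,
    weights and phases are drawn from ``seed``; a voxel belongs to the shell
    when its centre lies within ``thickness / 2`` of the local radius.  With
    amplitude 0 this is a plain voxelized sphere surface (dimension ~ 2);
    increasing the amplitude folds the sheet and raises the estimate, which
    is the qualitative behaviour of a cortical ribbon.  Deterministic given
    the seed.
    """
    if radius < 8:
        raise InvalidRadiusError(f"radius must be >= 8, got {radius}")
    if perturbation_amplitude < 0:
        raise InvalidParamsError("perturbation amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    n_harm = 3
    weights = rng.dirichlet(np.ones(n_harm))
    l_freq = rng.integers(2, 7, size=n_harm)   # polar frequencies
    m_freq = rng.integers(2, 7, size=n_harm)   # azimuthal frequencies
    phases = rng.uniform(0, 2 * np.pi, size=(2, n_harm))

    half = int(np.ceil(radius + perturbation_amplitude + 2))
    ax = np.arange(-half, half + 1, dtype=float)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    costh = np.divide(z, r, out=np.zeros_like(r), where=r > 0)
    theta = np.arccos(np.clip(costh, -1, 1))
    phi = np.arctan2(y, x)
    local = np.zeros_like(r)
    for i in range(n_harm):
        local += weights[i] * (np.sin(l_freq[i] * theta + phases[0, i])
                               * np.sin(m_freq[i] * phi + phases[1, i]))
    r0 = radius + perturbation_amplitude * local
    data = (np.abs(r - r0) <= thickness / 2).astype(np.uint8)
    return VoxelVolume(data, (spacing,) * 3)


def generate_cohort(n: int,
                    age_range: tuple[float, float] = (19.0, 85.0),
                    feature_slope: float = -0.002,
                    feature_intercept: float = 2.6,
                    noise_sd: float = 0.02,
                    seed: int = 0,
                    feature_name: str = "FD",
                    etiv_mean: float = 1.5e6,
                    etiv_sd: float = 1.5e5) -> pd.DataFrame:
    """Synthetic subject table with an age-linked feature.

    Ages are uniform over ``age_range``; the feature follows
    ``intercept + slope * age + N(0, noise_sd**2)``.  Sex is Bernoulli(0.5)
    coded 0/1 and eTIV is Gaussian with a mean of 1.5 L, the typical adult
    intracranial volume.  Fully reproducible from ``seed``.
    """
    if n < 10:
        raise InvalidParamsError(f"need n >= 10 subjects, got {n}")
    if noise_sd < 0:
        raise InvalidParamsError("noise_sd must be >= 0")
    lo, hi = age_range
    if not (0 < lo < hi):
        raise InvalidParamsError(f"invalid age range {age_range}")
    rng = np.random.default_rng(seed)
    age = rng.uniform(lo, hi, size=n)
    feature = feature_intercept + feature_slope * age + rng.normal(0, noise_sd, n)
    sex = rng.integers(0, 2, size=n)
    etiv = rng.normal(etiv_mean, etiv_sd, size=n)
    return pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "eTIV": etiv,
        feature_name: feature,
    })
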