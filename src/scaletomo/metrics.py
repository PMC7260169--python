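"""Porous-network statistics on binary volumes.

Filling fraction (percent chitin by volume) with cube-sampling
uncertainty, directional two-point correlation functions S2, and selection
of the representative cube — the sampled cube whose directional S2 curves
have the least mean squared error against the sample-average curves.

S2(r) here is the standard two-point probability along a lattice
direction: the probability that two voxels separated by lag r are both
material.  S2(0) equals the filling fraction; cubes are physical samples,
so no wrap-around is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeMismatchError
from .volumes import MATERIAL, BinaryVolume

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class CubeSample:
    """A cubic sub-volume cut from the interior of a binary mask."""

    corner: tuple[int, int, int]
    edge: int
    data: np.ndarray  # (edge, edge, edge) uint8, material=0 / air=1


@dataclass
class CorrelationCurve:
    """Directional two-point correlation values vs lag."""

    direction: str
    lags: np.ndarray
    values: np.ndarray


@dataclass
class FillStats:
    """Mean and spread of per-cube fill fractions, in percent material."""

    mean: float
    sd: float
    n: int
    seed: int | None = None


def fill_fraction(mask: BinaryVolume | CubeSample | np.ndarray) -> float:
    """Percent of material voxels: 100 x (count material) / (total)."""
    data = np.asarray(mask.data if hasattr(mask, "data") else mask)
    return float(100.0 * np.mean(data == MATERIAL))


def sample_cubes(
    mask: BinaryVolume,
    edge: int = 200,
    n: int = 275,
    seed: int | None = None,
    interior_margin: int | tuple[int, int, int] = 0,
) -> list[CubeSample]:
    """Cut ``n`` cubes at seeded uniform-random interior corners.

    Cubes lie fully inside the volume minus ``interior_margin`` (scalar or
    per-axis, used to exclude the cuticle shell and edge artefacts);
    overlapping cubes are permitted; positions are reproducible from the
    seed.
    """
    if np.isscalar(interior_margin):
        margins = (int(interior_margin),) * 3
    else:
        margins = tuple(int(m) for m in interior_margin)  # type: ignore[assignment]
    shape = mask.shape
    los = [m for m in margins]
    his = [s - m - edge for s, m in zip(shape, margins)]
    if any(hi < lo for lo, hi in zip(los, his)):
        raise ConfigurationError(
            f"no room for a {edge}-voxel cube inside shape {shape} "
            f"with margins {margins}"
        )
    rng = np.random.default_rng(seed)
    corners = np.stack(
        [rng.integers(lo, hi + 1, size=n) for lo, hi in zip(los, his)], axis=1
    )
    data = np.asarray(mask.data)
    return [
        CubeSample(
            corner=tuple(int(c) for c in corner),  # type: ignore[arg-type]
            edge=edge,
            data=data[
                corner[0] : corner[0] + edge,
                corner[1] : corner[1] + edge,
                corner[2] : corner[2] + edge,
            ].copy(),
        )
        for corner in corners
    ]


def fill_stats(cubes: list[CubeSample], seed: int | None = None) -> FillStats:
    """Mean and sample standard deviation (ddof=1) of per-cube fill, percent."""
    if len(cubes) < 2:
        raise ConfigurationError("fill statistics need at least 2 cubes")
    fills = np.array([fill_fraction(c) for c in cubes])
    return FillStats(
        mean=float(fills.mean()), sd=float(fills.std(ddof=1)), n=len(cubes), seed=seed
    )


def directional_correlation(
    cube: CubeSample | BinaryVolume, direction: str, r_max: int = 100
) -> CorrelationCurve:
    """Two-point correlation S2 along one lattice direction, lags 0..r_max.

    S2(r) = (# in-bounds voxel pairs (p, p + r e_d) with both material) /
    (# such pairs); no wrap-around.
    """
    if direction not in _AXES:
        raise ConfigurationError(f"direction must be one of {sorted(_AXES)}")
    data = np.asarray(cube.data)
    axis = _AXES[direction]
    if r_max >= data.shape[axis]:
        raise ConfigurationError("r_max must be smaller than the cube edge")
    m = (data == MATERIAL).astype(np.float64)
    values = np.empty(r_max + 1)
    values[0] = m.mean()
    for r in range(1, r_max + 1):
        head = [slice(None)] * 3
        tail = [slice(None)] * 3
        head[axis] = slice(0, data.shape[axis] - r)
        tail[axis] = slice(r, None)
        values[r] = (m[tuple(head)] * m[tuple(tail)]).mean()
    return CorrelationCurve(
        direction=direction, lags=np.arange(r_max + 1), values=values
    )


def representative_cube(cubes: list[CubeSample], r_max: int = 100) -> int:
    """Index of the cube closest to the average directional S2 curves.

    Each cube is scored by the mean over the three directions and all lags
    of the squared deviation of its S2 curves from the cube-averaged
    curves; the least-MSE index wins, ties broken by lowest index.
    """
    if not cubes:
        raise ConfigurationError("need at least one cube")
    dirs = sorted(_AXES)
    curves = np.array(
        [
            [directional_correlation(c, d, r_max).values for d in dirs]
            for c in cubes
        ]
    )  # (n_cubes, 3, r_max + 1)
    average = curves.mean(axis=0)
    scores = ((curves - average[None]) ** 2).mean(axis=(1, 2))
    return int(np.argmin(scores))  # argmin takes the first minimum: lowest index
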