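"""Dense 3-D volume containers.

Axes are fixed as ``(x, y, z)`` with ``z`` the scan/length axis (the axis
along which overlapping tomography scans are stacked).  The voxel pitch is
isotropic; the beamline dataset these containers mirror was acquired at
25 nm/voxel.

Greyscale volumes are either 8-bit integers on a 0–254 scale or floating
point (unit interval after normalisation).  Binary volumes use a fixed
polarity: material (chitin) = 0, air = 1, matching the on-disk convention
of the thresholded matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PolarityError, ShapeMismatchError

#: Binary-volume polarity constants (fixed on disk).
MATERIAL = 0
AIR = 1

#: Maximum value of the 8-bit greyscale convention.
GREY_MAX = 254

#: Default voxel pitch in nanometres.
DEFAULT_PITCH_NM = 25.0


def _check_3d(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ShapeMismatchError(f"expected a 3-D array, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ShapeMismatchError(f"all dimensions must be >= 1, got {data.shape}")


@dataclass
class GreyVolume:
    """A dense 3-D greyscale field with voxel-pitch metadata.

    Parameters
    ----------
    data
        ``(nx, ny, nz)`` array, 8-bit integer (0–254) or floating point.
    pitch_nm
        Voxel edge length in nanometres (isotropic), default 25.
    """

    data: np.ndarray
    pitch_nm: float = DEFAULT_PITCH_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data)
        if self.pitch_nm <= 0:
            raise ValueError(f"pitch_nm must be > 0, got {self.pitch_nm}")
        if np.issubdtype(self.data.dtype, np.integer):
            vmax = int(self.data.max())
            if vmax > GREY_MAX:
                # 255 appears in some dialects of the 0-254 convention;
                # tolerate it with a warning rather than rejecting the file.
                warnings.warn(
                    f"8-bit greyscale volume contains values > {GREY_MAX} "
                    f"(max {vmax}); the canonical scale is 0-{GREY_MAX}",
                    stacklevel=2,
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def shape_um(self) -> tuple[float, float, float]:
        """Physical extent in micrometres, componentwise shape * pitch / 1000."""
        return tuple(n * self.pitch_nm / 1000.0 for n in self.data.shape)  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A two-phase 3-D field with polarity material=0 / air=1."""

    data: np.ndarray
    pitch_nm: float = DEFAULT_PITCH_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data)
        if self.pitch_nm <= 0:
            raise ValueError(f"pitch_nm must be > 0, got {self.pitch_nm}")
        bad = (self.data != MATERIAL) & (self.data != AIR)
        if bad.any():
            raise PolarityError(
                "binary volume must contain only {0, 1} "
                f"(material={MATERIAL}, air={AIR}); found other values"
            )
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def shape_um(self) -> tuple[float, float, float]:
        return tuple(n * self.pitch_nm / 1000.0 for n in self.data.shape)  # type: ignore[return-value]

    @property
    def material_mask(self) -> np.ndarray:
        """Boolean mask, True where the voxel is material (chitin)."""
        return self.data == MATERIAL
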