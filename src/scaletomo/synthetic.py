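"""Ground-truthed synthetic porous-scale tomograms.

The generator emulates the structure the beamline data shows: a disordered
two-phase network of dark chitin (volume fraction ~0.31-0.34) and light air
with one characteristic structural length, enclosed by a solid cuticle
shell, rendered to greyscale with additive noise and concentric ring
artefacts, then cut into vertically overlapping sub-scans the way the real
sample was scanned (54 µm vertical field of view, 10 µm overlap, 25 nm
voxels).

The network model is a Gaussian random field: seeded white noise smoothed
with a Gaussian kernel of width ``correlation_length``, thresholded at the
sample quantile that yields the target fill exactly.  All randomness flows
from one integer seed through a fixed stream-splitting scheme (stream 0:
field, stream 1: rendering noise, stream 2: scan jitter), so every derived
object is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateStructureError, ShapeMismatchError
from .volumes import AIR, GREY_MAX, MATERIAL, BinaryVolume, GreyVolume

_STREAM_FIELD = 0
_STREAM_NOISE = 1
_STREAM_JITTER = 2


def _stream(seed: int, index: int) -> np.random.Generator:
    """Independent generator ``index`` derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


@dataclass
class SyntheticScaleConfig:
    """Parameters of the synthetic scale and its rendering.

    Greyscale levels are on the 8-bit 0-254 convention: dark material,
    light air.  ``correlation_length_nm`` sets the Gaussian-field smoothing
    width, i.e. the characteristic structural length of the network.
    """

    shape: tuple[int, int, int] = (48, 64, 224)
    pitch_nm: float = 25.0
    target_fill: float = 0.31
    correlation_length_nm: float = 150.0
    cuticle_thickness_voxels: int = 8
    grey_material: float = 80.0
    grey_air: float = 180.0
    noise_sigma: float = 10.0
    ring_amplitude: float = 0.05
    ring_period_voxels: float = 40.0
    grey_dtype: str = "uint8"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_fill < 1.0:
            raise ConfigurationError("target_fill must lie strictly in (0, 1)")
        if not self.grey_material < self.grey_air:
            raise ConfigurationError("material must be darker than air")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    @property
    def correlation_length_voxels(self) -> float:
        return self.correlation_length_nm / self.pitch_nm


def interior_region(config: SyntheticScaleConfig, margin: int = 0):
    """Slices selecting the porous interior (cuticle shell plus ``margin`` excluded).

    The cuticle sits on the two large (x) faces; margins trim all axes.
    """
    ct = config.cuticle_thickness_voxels
    nx, ny, nz = config.shape
    return (
        slice(ct + margin, nx - ct - margin),
        slice(margin, ny - margin if margin else None),
        slice(margin, nz - margin if margin else None),
    )


def generate_truth(config: SyntheticScaleConfig) -> BinaryVolume:
    """Ground-truth binary scale: quantile-thresholded Gaussian random field.

    The threshold level is the exact sample quantile of the *interior*
    field at ``target_fill``, so the interior material fraction matches the
    target by construction; a solid cuticle shell is then stamped on the
    two large faces.
    """
    corr = config.correlation_length_voxels
    if corr >= min(config.shape) / 2:
        raise DegenerateStructureError(
            f"correlation length {corr} voxels >= half the smallest dimension"
        )
    rng = _stream(config.seed, _STREAM_FIELD)
    # generate on a padded grid and crop: smoothing a finite grid in place
    # would inflate the field variance near the faces (boundary reflection),
    # biasing the material fraction of off-centre subregions by percentage
    # points; padding by the kernel's 4-sigma truncation radius makes the
    # cropped field stationary
    pad = int(np.ceil(4.0 * corr))
    padded_shape = tuple(n + 2 * pad for n in config.shape)
    fld = rng.standard_normal(padded_shape)
    fld = ndimage.gaussian_filter(fld, sigma=corr, mode="reflect")
    fld = fld[pad:-pad, pad:-pad, pad:-pad] if pad else fld
    interior = interior_region(config)
    level = np.quantile(fld[interior], config.target_fill)
    data = np.where(fld < level, MATERIAL, AIR).astype(np.uint8)
    ct = config.cuticle_thickness_voxels
    if ct > 0:
        data[:ct] = MATERIAL
        data[-ct:] = MATERIAL
    return BinaryVolume(data, pitch_nm=config.pitch_nm)


def render_greyscale(truth: BinaryVolume, config: SyntheticScaleConfig) -> GreyVolume:
    """Render a truth volume to greyscale with rings and noise.

    Material voxels are drawn around ``grey_material`` and air around
    ``grey_air``; a multiplicative ring modulation
    ``1 + ring_amplitude * sin(2*pi*r / ring_period)`` is applied in each
    xy-slice about the slice centre (rotation axis along z); seeded
    additive Gaussian noise follows; 8-bit output is clipped to [0, 254].
    """
    if tuple(truth.shape) != tuple(config.shape):
        raise ShapeMismatchError(
            f"truth shape {truth.shape} != config shape {config.shape}"
        )
    base = np.where(
        truth.data == MATERIAL, config.grey_material, config.grey_air
    ).astype(np.float64)
    if config.ring_amplitude > 0 and config.ring_period_voxels > 0:
        nx, ny, _ = config.shape
        x = np.arange(nx) - (nx - 1) / 2.0
        y = np.arange(ny) - (ny - 1) / 2.0
        r = np.hypot(x[:, None], y[None, :])
        rings = 1.0 + config.ring_amplitude * np.sin(
            2.0 * np.pi * r / config.ring_period_voxels
        )
        base *= rings[:, :, None]
    if config.noise_sigma > 0:
        rng = _stream(config.seed, _STREAM_NOISE)
        base += config.noise_sigma * rng.standard_normal(config.shape)
    if config.grey_dtype == "uint8":
        out = np.clip(np.rint(base), 0, GREY_MAX).astype(np.uint8)
    else:
        out = np.clip(base, 0.0, float(GREY_MAX)).astype(config.grey_dtype)
    return GreyVolume(out, pitch_nm=config.pitch_nm)


def simulate_scale(config: SyntheticScaleConfig) -> tuple[BinaryVolume, GreyVolume]:
    """Convenience: generate truth and its greyscale rendering."""
    truth = generate_truth(config)
    return truth, render_greyscale(truth, config)


def embed_in_air(vol: GreyVolume, margin: int, air_value: float | None = None) -> GreyVolume:
    """Pad a rendered scale with ``margin`` voxels of air on every face.

    Mimics a scale suspended in the field of view, which is the geometry
    tilt estimation assumes (the object must not fill the whole box).
    ``air_value`` defaults to the volume maximum.
    """
    data = np.asarray(vol.data)
    if air_value is None:
        air_value = data.max()
    out = np.pad(data, margin, mode="constant", constant_values=air_value)
    return GreyVolume(out, pitch_nm=vol.pitch_nm)


# ---------------------------------------------------------------------------
# scan geometry

def scan_count(length_um: float, fov_um: float, overlap_um: float) -> int:
    """Number of overlapping scans needed to cover a sample.

    Returns 1 if the sample fits one field of view, otherwise
    ``ceil((length - fov) / (fov - overlap)) + 1``.
    """
    if fov_um <= 0:
        raise ConfigurationError("field of view must be positive")
    if not 0 <= overlap_um < fov_um:
        raise ConfigurationError("overlap must satisfy 0 <= overlap < fov")
    if length_um <= 0:
        raise ConfigurationError("sample length must be positive")
    if length_um <= fov_um:
        return 1
    # round-to-9-decimals guards against float residue in exact ratios
    return int(math.ceil(round((length_um - fov_um) / (fov_um - overlap_um), 9))) + 1


@dataclass
class ScanSet:
    """Ordered overlapping sub-scans with their true placement.

    ``z_offsets[k]`` is scan k's true start frame in the source volume;
    ``lateral_shifts[k]`` the true camera shift ``(dx, dy)`` such that
    ``scan_k[x, y, i] = source[x + dx, y + dy, z_offsets[k] + i]``.
    """

    scans: list[GreyVolume]
    z_offsets: list[int]
    lateral_shifts: list[tuple[int, int]]
    fov_voxels: int
    overlap_voxels: int
    pad_value: float

    def __post_init__(self) -> None:
        for s in self.scans:
            if s.shape[2] != self.fov_voxels:
                raise ShapeMismatchError("every scan's z-extent must equal the FOV")


def _extract_scan(data: np.ndarray, dx: int, dy: int, z0: int, fov: int, pad) -> np.ndarray:
    """Camera view shifted by (dx, dy) starting at frame z0; outside filled with pad."""
    nx, ny, nz = data.shape
    out = np.full((nx, ny, fov), pad, dtype=data.dtype)
    xs0, xs1 = max(0, dx), min(nx, nx + dx)
    ys0, ys1 = max(0, dy), min(ny, ny + dy)
    zs0, zs1 = max(0, z0), min(nz, z0 + fov)
    if xs0 < xs1 and ys0 < ys1 and zs0 < zs1:
        out[xs0 - dx : xs1 - dx, ys0 - dy : ys1 - dy, zs0 - z0 : zs1 - z0] = data[
            xs0:xs1, ys0:ys1, zs0:zs1
        ]
    return out


def split_into_scans(
    vol: GreyVolume,
    fov_voxels: int,
    overlap_voxels: int,
    lateral_jitter: int = 0,
    seed: int | None = None,
    z_jitter: int = 0,
    pad_value: float | None = None,
) -> ScanSet:
    """Cut a volume into vertically overlapping sub-scans.

    Scan k nominally covers ``z in [k*(fov-overlap), ... + fov)``; seeded
    integer jitters bounded by ``z_jitter`` / ``lateral_jitter`` perturb the
    start frame and camera position of every scan after the first.  Frames
    beyond the source extent are filled with ``pad_value`` (default: the
    volume maximum, a proxy for the light air phase).
    """
    if overlap_voxels >= fov_voxels:
        raise ConfigurationError("overlap must be smaller than the field of view")
    if overlap_voxels < 0:
        raise ConfigurationError("overlap must be >= 0")
    data = np.asarray(vol.data)
    nz = data.shape[2]
    if nz < fov_voxels:
        raise ConfigurationError("volume shorter than one field of view")
    if pad_value is None:
        pad_value = data.max()
    n = scan_count(float(nz), float(fov_voxels), float(overlap_voxels))
    rng = _stream(0 if seed is None else seed, _STREAM_JITTER)
    step = fov_voxels - overlap_voxels
    offsets: list[int] = []
    shifts: list[tuple[int, int]] = []
    scans: list[GreyVolume] = []
    for k in range(n):
        z0 = k * step
        dx = dy = 0
        if k > 0 and z_jitter > 0:
            z0 = int(np.clip(z0 + rng.integers(-z_jitter, z_jitter + 1), 0, None))
        if k > 0 and lateral_jitter > 0:
            dx = int(rng.integers(-lateral_jitter, lateral_jitter + 1))
            dy = int(rng.integers(-lateral_jitter, lateral_jitter + 1))
        scans.append(
            GreyVolume(
                _extract_scan(data, dx, dy, z0, fov_voxels, pad_value),
                pitch_nm=vol.pitch_nm,
            )
        )
        offsets.append(z0)
        shifts.append((dx, dy))
    return ScanSet(
        scans=scans,
        z_offsets=offsets,
        lateral_shifts=shifts,
        fov_voxels=fov_voxels,
        overlap_voxels=overlap_voxels,
        pad_value=float(pad_value),
    )
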