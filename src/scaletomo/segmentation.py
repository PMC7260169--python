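"""Saturation, denoising and dual-mode thresholding into a chitin/air volume.

The chain (in order): clip the darkest/lightest 0.5 % of greyscale values,
rescale the clipped range to [0, 1], denoise with a non-local means filter
run over halo-padded chunks, then threshold twice on the same denoised
volume — an adaptive Gaussian threshold that picks out the porous internal
structure, and a strict global threshold (< 0.4) that captures solid
chitin — and intersect the two air masks (union of material sets).

Chunked processing is bit-for-bit identical to monolithic processing
wherever the operator's spatial support radius fits inside the halo; the
non-local means implementation here is built from elementwise operations
and direct small-kernel correlations only, so its output at a voxel depends
solely on the voxel's neighbourhood, never on the chunk origin.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, HaloTooSmallError, ShapeMismatchError
from .parallel import parallel_map
from .volumes import AIR, MATERIAL, BinaryVolume, GreyVolume


@dataclass
class SegmentationConfig:
    """Every numeric knob of the segmentation chain.

    ``nlm_strength`` (the filter bandwidth h, in unit-interval intensity
    units) defaults to None, meaning 0.8 x the noise level estimated from
    the median absolute deviation of Laplacian residuals; the derived value
    is recorded in the provenance of every run.  The Gaussian-threshold
    kernel width is derived from ``region_size`` as (region_size - 1) / 6
    and is not stored.
    """

    sat_low_pct: float = 0.5
    sat_high_pct: float = 99.5
    patch_size: int = 5
    patch_distance: int = 7
    nlm_strength: float | None = None
    nlm_sigma: float = 0.0
    nlm_mode: str = "3d"  # "3d" | "2d" (slice-wise)
    halo: int = 10
    region_size: int = 60
    offset: float = 0.06
    global_threshold: float = 0.4
    chunk_shape: tuple[int, int, int] | None = None
    target_chunk_voxels: int = 128**3

    def __post_init__(self) -> None:
        if not 0 < self.sat_low_pct < self.sat_high_pct < 100:
            raise ConfigurationError("need 0 < sat_low_pct < sat_high_pct < 100")
        if self.patch_size % 2 == 0:
            raise ConfigurationError("patch_size must be odd")
        if self.halo < self.patch_distance:
            raise ConfigurationError(
                "halo must be >= patch_distance for interior equivalence"
            )
        if self.region_size < 2:
            raise ConfigurationError("region_size must be >= 2")
        if not 0 < self.global_threshold < 1:
            raise ConfigurationError("global_threshold must lie in (0, 1)")
        if self.nlm_mode not in ("3d", "2d"):
            raise ConfigurationError("nlm_mode must be '3d' or '2d'")


@dataclass
class IntensityScale:
    """Saturation endpoints; the linear scale behind 'normalized intensity'."""

    clip_min: float
    clip_max: float

    def __post_init__(self) -> None:
        if self.clip_min > self.clip_max:
            raise ConfigurationError("clip_min must be <= clip_max")


# ---------------------------------------------------------------------------
# saturation / normalisation

def saturate(
    vol: GreyVolume, low_pct: float = 0.5, high_pct: float = 99.5
) -> tuple[GreyVolume, IntensityScale]:
    """Clip the darkest/lightest tails to the given sample percentiles.

    Percentiles use linear interpolation over all voxels of the full volume
    (never per chunk, so the scale is independent of any chunk grid).
    """
    if not 0 < low_pct < high_pct < 100:
        raise ConfigurationError("need 0 < low_pct < high_pct < 100")
    arr = np.asarray(vol.data)
    if arr.size == 0:
        raise ShapeMismatchError("cannot saturate an empty volume")
    lo, hi = np.percentile(arr, [low_pct, high_pct])
    clipped = np.clip(arr.astype(np.float32), lo, hi)
    return GreyVolume(clipped, pitch_nm=vol.pitch_nm), IntensityScale(float(lo), float(hi))


def normalize(vol: GreyVolume, scale: IntensityScale) -> GreyVolume:
    """Map [clip_min, clip_max] linearly onto [0, 1] (constant input -> 0)."""
    arr = np.asarray(vol.data, dtype=np.float32)
    span = scale.clip_max - scale.clip_min
    if span == 0:
        return GreyVolume(np.zeros_like(arr), pitch_nm=vol.pitch_nm)
    out = (arr - np.float32(scale.clip_min)) / np.float32(span)
    return GreyVolume(out, pitch_nm=vol.pitch_nm)


def estimate_noise_sigma(vol: GreyVolume | np.ndarray) -> float:
    """Robust additive-noise scale from Laplacian residuals.

    The discrete 3-D Laplacian of iid noise has variance 42 sigma^2 (sum of
    squared stencil weights); a MAD estimate of the residual scale divided
    by sqrt(42) is nearly blind to the underlying two-phase structure.
    """
    arr = np.asarray(vol.data if isinstance(vol, GreyVolume) else vol, dtype=np.float32)
    lap = ndimage.laplace(arr)
    mad = np.median(np.abs(lap - np.median(lap)))
    return float(1.4826 * mad / np.sqrt(42.0))


# ---------------------------------------------------------------------------
# non-local means

def _nlm_nd(
    arr: np.ndarray, patch_size: int, patch_distance: int, h: float, sigma: float
) -> np.ndarray:
    """N-dimensional non-local means on a float array.

    Each voxel becomes a similarity-weighted average of voxels within
    ``patch_distance``; weights are exp(-max(d2 - 2 sigma^2, 0) / h^2) on
    patch mean-squared differences d2 (uniform patch weighting).  Built
    from elementwise ops and direct 1-D box correlations so the result at a
    voxel is a pure function of its (patch_distance + patch_size//2)-
    neighbourhood — the property the chunked runner relies on.
    """
    pr = patch_size // 2
    d = patch_distance
    radius = pr + d
    nd = arr.ndim
    shape = arr.shape
    a = np.asarray(arr, dtype=np.float32)
    pad = np.pad(a, radius, mode="reflect")
    core = tuple(slice(radius, radius + n) for n in shape)
    ext = tuple(slice(radius - pr, radius + n + pr) for n in shape)
    v0 = pad[core]
    v0e = pad[ext]
    kern = np.full(patch_size, 1.0 / patch_size, dtype=np.float32)
    num = v0.copy()  # zero offset: d2 = 0, weight exactly 1
    den = np.ones(shape, dtype=np.float32)
    two_sigma2 = np.float32(2.0 * sigma * sigma)
    neg_inv_h2 = np.float32(-1.0 / (h * h))
    crop = tuple(slice(pr, pr + n) for n in shape)
    for off in itertools.product(range(-d, d + 1), repeat=nd):
        if all(o == 0 for o in off):
            continue
        vde = pad[tuple(slice(radius - pr + o, radius + n + pr + o) for o, n in zip(off, shape))]
        w = v0e - vde
        w *= w
        for ax in range(nd):
            w = ndimage.correlate1d(w, kern, axis=ax, mode="nearest")
        w = w[crop] - two_sigma2
        np.maximum(w, 0.0, out=w)
        w *= neg_inv_h2
        np.exp(w, out=w)
        vd = pad[tuple(slice(radius + o, radius + n + o) for o, n in zip(off, shape))]
        num += w * vd
        den += w
    return num / den


@dataclass
class NonLocalMeansFilter:
    """Callable NLM operator with a declared spatial support radius.

    ``mode='2d'`` filters each xy-slice independently (for comparison with
    the volumetric default); the support radius is identical, so chunk
    halos need no adjustment.
    """

    patch_size: int = 5
    patch_distance: int = 7
    h: float = 0.1
    sigma: float = 0.0
    mode: str = "3d"

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0:
            raise ConfigurationError("patch_size must be odd")
        if self.patch_distance < 1:
            raise ConfigurationError("patch_distance must be >= 1")

    @property
    def support_radius(self) -> int:
        return self.patch_distance + self.patch_size // 2

    def __call__(self, arr: np.ndarray) -> np.ndarray:
        arr = np.asarray(arr)
        if self.h <= 0:  # zero-bandwidth limit: only identical patches count
            return arr.astype(np.float32, copy=True)
        if self.mode == "2d":
            out = np.empty(arr.shape, dtype=np.float32)
            for k in range(arr.shape[2]):
                out[:, :, k] = _nlm_nd(
                    arr[:, :, k], self.patch_size, self.patch_distance, self.h, self.sigma
                )
            return out
        return _nlm_nd(arr, self.patch_size, self.patch_distance, self.h, self.sigma)


def nlm_denoise(
    vol: GreyVolume,
    patch_size: int = 5,
    patch_distance: int = 7,
    h: float = 0.1,
    sigma: float = 0.0,
    mode: str = "3d",
) -> GreyVolume:
    """Monolithic non-local means denoising of a unit-interval volume."""
    filt = NonLocalMeansFilter(patch_size, patch_distance, h, sigma, mode)
    return GreyVolume(filt(np.asarray(vol.data)), pitch_nm=vol.pitch_nm)


# ---------------------------------------------------------------------------
# chunked application

def plan_chunk_shape(shape, target_voxels: int = 128**3) -> tuple[int, ...]:
    """Chunk shape with at most ``target_voxels`` voxels: halve the largest
    axis until the chunk fits.  Deterministic in the input."""
    chunk = [int(n) for n in shape]
    while int(np.prod(chunk)) > target_voxels:
        i = int(np.argmax(chunk))
        if chunk[i] == 1:
            break
        chunk[i] = (chunk[i] + 1) // 2
    return tuple(chunk)


def chunk_grid(shape, chunk_shape):
    """Core slices of the chunk grid covering ``shape``."""
    ranges = [range(0, n, c) for n, c in zip(shape, chunk_shape)]
    for starts in itertools.product(*ranges):
        yield tuple(
            slice(s, min(s + c, n)) for s, c, n in zip(starts, chunk_shape, shape)
        )


def chunked_apply(
    data: np.ndarray,
    operator,
    chunk_shape=None,
    halo: int = 10,
    n_jobs: int = 1,
) -> np.ndarray:
    """Apply ``operator`` over a grid of halo-padded chunks.

    Each chunk is extended by ``halo`` voxels of context (clipped at the
    volume boundary), processed independently, and only its interior
    written back.  Wherever the operator's declared ``support_radius`` is
    at most ``halo`` the result is bit-for-bit identical to applying the
    operator to the whole volume at once; a halo smaller than the support
    radius is refused outright.
    """
    data = np.asarray(data)
    radius = getattr(operator, "support_radius", None)
    if radius is not None and halo < radius:
        raise HaloTooSmallError(
            f"halo {halo} < operator support radius {radius}; "
            "interior equivalence would be violated"
        )
    if chunk_shape is None:
        chunk_shape = data.shape
    cores = list(chunk_grid(data.shape, chunk_shape))
    exts = [
        tuple(
            slice(max(0, c.start - halo), min(n, c.stop + halo))
            for c, n in zip(core, data.shape)
        )
        for core in cores
    ]
    results = parallel_map(
        operator, [data[e] for e in exts], n_jobs=n_jobs
    )
    out = None
    for core, e, res in zip(cores, exts, results):
        if out is None:
            out = np.empty(data.shape, dtype=res.dtype)
        inner = tuple(
            slice(c.start - x.start, c.stop - x.start) for c, x in zip(core, e)
        )
        out[core] = res[inner]
    return out


# ---------------------------------------------------------------------------
# thresholding

def gaussian_sigma(region_size: int) -> float:
    """Kernel width of the adaptive threshold: (region_size - 1) / 6."""
    return (region_size - 1) / 6.0


def adaptive_gaussian_threshold(
    vol: GreyVolume, region_size: int = 60, offset: float = 0.06
) -> BinaryVolume:
    """Material where the voxel is darker than its Gaussian-weighted local
    mean minus ``offset``.

    The local mean uses sigma = (region_size - 1) / 6, kernel truncated at
    4 sigma, reflecting boundaries.  Sensitive to sharp intensity changes,
    hence good at the porous interior but blind inside solid chitin.
    """
    if region_size < 2:
        raise ConfigurationError("region_size must be >= 2 (1 is degenerate)")
    arr = np.asarray(vol.data, dtype=np.float64)
    local_mean = ndimage.gaussian_filter(
        arr, sigma=gaussian_sigma(region_size), mode="reflect", truncate=4.0
    )
    data = np.where(arr < local_mean - offset, MATERIAL, AIR).astype(np.uint8)
    return BinaryVolume(data, pitch_nm=vol.pitch_nm)


def global_threshold(vol: GreyVolume, t: float = 0.4) -> BinaryVolume:
    """Material strictly below ``t`` on the normalized intensity scale."""
    arr = np.asarray(vol.data)
    data = np.where(arr < t, MATERIAL, AIR).astype(np.uint8)
    return BinaryVolume(data, pitch_nm=vol.pitch_nm)


def combine_masks(adaptive: BinaryVolume, global_: BinaryVolume) -> BinaryVolume:
    """Voxelwise product in air=1 polarity: the union of the material sets.

    A voxel is air only where both inputs call it air, which lets the
    combined mask hold both the porous interior (adaptive) and the solid
    cuticle (global).
    """
    if adaptive.shape != global_.shape:
        raise ShapeMismatchError(
            f"mask shapes differ: {adaptive.shape} vs {global_.shape}"
        )
    return BinaryVolume(adaptive.data & global_.data, pitch_nm=adaptive.pitch_nm)


# ---------------------------------------------------------------------------
# full chain

@dataclass
class SegmentationResult:
    """Segment output with the scale and full provenance of the run."""

    mask: BinaryVolume
    scale: IntensityScale
    provenance: dict


def segment(
    vol: GreyVolume,
    config: SegmentationConfig | None = None,
    n_jobs: int = 1,
    full_output: bool = False,
):
    """Run the full chain: saturate, normalize, chunked NLM, dual threshold.

    Fully deterministic; the same configuration applied to any volume uses
    byte-identical parameters (recorded in the provenance, including the
    derived NLM bandwidth h and threshold sigma).
    """
    config = config or SegmentationConfig()
    sat, scale = saturate(vol, config.sat_low_pct, config.sat_high_pct)
    norm = normalize(sat, scale)
    h = config.nlm_strength
    if h is None:
        h = 0.8 * estimate_noise_sigma(norm)
    h = max(float(h), 1e-6)
    filt = NonLocalMeansFilter(
        patch_size=config.patch_size,
        patch_distance=config.patch_distance,
        h=h,
        sigma=config.nlm_sigma,
        mode=config.nlm_mode,
    )
    chunk_shape = config.chunk_shape or plan_chunk_shape(
        norm.data.shape, config.target_chunk_voxels
    )
    den_arr = chunked_apply(
        norm.data, filt, chunk_shape=chunk_shape, halo=config.halo, n_jobs=n_jobs
    )
    den = GreyVolume(den_arr, pitch_nm=vol.pitch_nm)
    adaptive = adaptive_gaussian_threshold(den, config.region_size, config.offset)
    glob = global_threshold(den, config.global_threshold)
    mask = combine_masks(adaptive, glob)
    if not full_output:
        return mask
    prov = asdict(config)
    prov.update(
        {
            "derived_nlm_h": h,
            "derived_threshold_sigma": gaussian_sigma(config.region_size),
            "clip_min": scale.clip_min,
            "clip_max": scale.clip_max,
            "chunk_shape_used": list(chunk_shape),
        }
    )
    return SegmentationResult(mask=mask, scale=scale, provenance=prov)
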