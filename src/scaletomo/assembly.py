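"""Registration and stitching of overlapping scans, plus tilt correction.

The real scans were matched frame-by-frame by eye; here the common frame
between consecutive scans is found automatically by maximising normalized
cross-correlation (NCC) between the centre frame of the upper scan's
overlap region and candidate frames of the lower scan, over a z search
window around the nominal offset and a small lateral shift window.  Seams
are placed at the centre of the matched overlap, away from scan-edge
artefacts.  Registration is integer-voxel only: matching whole frames
never resamples the data.

Mounting tilt is estimated from the second-moment (inertia) tensor of the
dark-material voxels and corrected by cubic-spline rotation about the
volume centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigurationError,
    NoTextureError,
    ShapeMismatchError,
    TiltEstimationError,
)
from .synthetic import ScanSet
from .volumes import GreyVolume


def nominal_overlap_frames(overlap_um: float, pitch_nm: float) -> int:
    """Number of frames two consecutive scans share, overlap / pitch.

    10 µm of overlap at 25 nm/voxel gives 400 common frames.  A
    non-integral result means the stated geometry is inconsistent.
    """
    if pitch_nm <= 0:
        raise ConfigurationError("pitch_nm must be positive")
    if overlap_um < 0:
        raise ConfigurationError("overlap_um must be >= 0")
    frames = overlap_um * 1000.0 / pitch_nm
    if abs(frames - round(frames)) > 1e-6 * max(1.0, abs(frames)):
        raise ConfigurationError(
            f"overlap {overlap_um} um at {pitch_nm} nm/voxel is {frames} frames, "
            "not integral"
        )
    return int(round(frames))


@dataclass
class OverlapMatch:
    """Registration result for one junction between consecutive scans.

    ``z_offset`` is the matched start-frame difference of the lower scan
    relative to the upper (nominal value: fov - overlap frames);
    ``lateral_shift`` is the (dx, dy) translation to apply to the lower
    scan (sample it at ``x + dx, y + dy``) to align it with the upper.
    """

    pair: tuple[int, int]
    z_offset: int
    lateral_shift: tuple[int, int]
    score: float
    search_window: int


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return -np.inf
    return float(np.dot(a, b) / (na * nb))


def find_overlap(
    scan_a: GreyVolume | np.ndarray,
    scan_b: GreyVolume | np.ndarray,
    nominal_frames: int,
    search_window: int = 100,
    lateral_window: int = 20,
    pair: tuple[int, int] = (0, 1),
) -> OverlapMatch:
    """Register scan B against scan A over their common overlap region.

    The reference is the centre frame of A's nominal overlap region; the
    returned offset/shift maximise NCC over candidates, ties broken by
    smallest deviation from the nominal offset, then smallest |dx|+|dy|,
    then lowest offset.  Constant (featureless) reference frames are
    refused rather than matched arbitrarily.
    """
    a = np.asarray(scan_a.data if isinstance(scan_a, GreyVolume) else scan_a)
    b = np.asarray(scan_b.data if isinstance(scan_b, GreyVolume) else scan_b)
    if a.shape[:2] != b.shape[:2]:
        raise ShapeMismatchError("scans must share their xy shape")
    len_a, len_b = a.shape[2], b.shape[2]
    if not 1 <= nominal_frames <= min(len_a, len_b):
        raise ConfigurationError(
            "nominal_frames must be >= 1 and no larger than either scan extent"
        )
    nx, ny = a.shape[:2]
    lw = lateral_window
    if 2 * lw >= min(nx, ny):
        raise ConfigurationError("lateral_window too large for the frame size")
    i_ref = len_a - nominal_frames + nominal_frames // 2  # centre of overlap
    ref = a[lw : nx - lw, lw : ny - lw, i_ref]
    if np.ptp(ref) == 0:
        raise NoTextureError("reference frame is constant; nothing to register")
    d_nominal = len_a - nominal_frames
    best_key = None
    best = None
    for d in range(d_nominal - search_window, d_nominal + search_window + 1):
        j = i_ref - d
        if not 0 <= j < len_b:
            continue
        frame = b[:, :, j]
        for sx in range(-lw, lw + 1):
            for sy in range(-lw, lw + 1):
                cand = frame[lw + sx : nx - lw + sx, lw + sy : ny - lw + sy]
                score = _ncc(ref, cand)
                key = (score, -abs(d - d_nominal), -(abs(sx) + abs(sy)), -d)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (d, sx, sy, score)
    if best is None or not np.isfinite(best[3]):
        raise NoTextureError("no valid candidate frames in the search window")
    d, sx, sy, score = best
    return OverlapMatch(
        pair=pair,
        z_offset=d,
        lateral_shift=(sx, sy),
        score=score,
        search_window=search_window,
    )


def match_scan_set(
    scans: ScanSet,
    nominal_frames: int,
    search_window: int = 100,
    lateral_window: int = 20,
) -> list[OverlapMatch]:
    """Register every consecutive pair of a scan set."""
    return [
        find_overlap(
            scans.scans[k],
            scans.scans[k + 1],
            nominal_frames,
            search_window,
            lateral_window,
            pair=(k, k + 1),
        )
        for k in range(len(scans.scans) - 1)
    ]


def stitch(
    scans: ScanSet | list[GreyVolume],
    matches: list[OverlapMatch],
    fill_value: float | None = None,
) -> GreyVolume:
    """Assemble matched scans into one matrix.

    Each junction contributes frames of the upper scan up to the seam (the
    centre of the matched overlap) and of the lower scan after it, with
    cumulative lateral shifts applied; voxels shifted outside any scan's
    footprint are filled with ``fill_value`` (air grey level).  Total
    z-extent is the last scan's offset plus its field of view.
    """
    if isinstance(scans, ScanSet):
        vols = scans.scans
        if fill_value is None:
            fill_value = scans.pad_value
    else:
        vols = list(scans)
    if len(matches) != len(vols) - 1:
        raise ShapeMismatchError("need exactly one match per consecutive pair")
    arrays = [np.asarray(v.data) for v in vols]
    nx, ny = arrays[0].shape[:2]
    for arr in arrays:
        if arr.shape[:2] != (nx, ny):
            raise ShapeMismatchError("scans must share their xy shape")
    if fill_value is None:
        fill_value = 0
    # cumulative placement relative to scan 0
    offsets = [0]
    shifts = [(0, 0)]
    for m in matches:
        offsets.append(offsets[-1] + m.z_offset)
        shifts.append(
            (shifts[-1][0] + m.lateral_shift[0], shifts[-1][1] + m.lateral_shift[1])
        )
    nz_out = offsets[-1] + arrays[-1].shape[2]
    # seam of junction k at the centre of the matched overlap
    seams = []
    for k, m in enumerate(matches):
        overlap = arrays[k].shape[2] - m.z_offset
        if overlap < 0:
            raise ShapeMismatchError(f"junction {k}: scans do not overlap")
        seams.append(offsets[k + 1] + overlap // 2)
    bounds = [0] + seams + [nz_out]
    if any(bounds[i] >= bounds[i + 1] for i in range(len(bounds) - 1)):
        raise ShapeMismatchError("seam frames must strictly increase along z")
    out = np.full((nx, ny, nz_out), fill_value, dtype=arrays[0].dtype)
    for k, arr in enumerate(arrays):
        a, b = bounds[k], bounds[k + 1]
        block = arr[:, :, a - offsets[k] : b - offsets[k]]
        sx, sy = shifts[k]
        ox0, ox1 = max(0, -sx), min(nx, nx - sx)
        oy0, oy1 = max(0, -sy), min(ny, ny - sy)
        if ox0 < ox1 and oy0 < oy1:
            out[ox0:ox1, oy0:oy1, a:b] = block[ox0 + sx : ox1 + sx, oy0 + sy : oy1 + sy]
    return GreyVolume(out, pitch_nm=getattr(vols[0], "pitch_nm", 25.0))


# ---------------------------------------------------------------------------
# tilt estimation / rotation

_PLANES = {0: (1, 2), 1: (2, 0), 2: (0, 1)}  # rotation planes for x, y, z
_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}


def _axis_rotation(axis: int, theta_deg: float) -> np.ndarray:
    """Coordinate transform matching ndimage.rotate(angle, axes=_PLANES[axis]).

    ndimage normalises the axis pair to ascending order, so the positive
    rotation direction is always from the lower toward the higher axis.
    """
    a, b = sorted(_PLANES[axis])
    t = math.radians(theta_deg)
    m = np.eye(3)
    m[a, a] = math.cos(t)
    m[b, b] = math.cos(t)
    m[a, b] = -math.sin(t)
    m[b, a] = math.sin(t)
    return m


def rotation_matrix(angles: tuple[float, float, float]) -> np.ndarray:
    """Net content rotation of :func:`rotate_volume` (x, then y, then z)."""
    m = np.eye(3)
    for axis in (0, 1, 2):
        m = _axis_rotation(axis, angles[axis]) @ m
    return m


def _euler_from_matrix(m: np.ndarray) -> tuple[float, float, float]:
    """Angles (x, y, z) with rotation_matrix(angles) == m, small-angle branch."""
    theta_y = math.asin(max(-1.0, min(1.0, m[2, 0])))
    theta_x = math.atan2(m[2, 1], m[2, 2])
    theta_z = math.atan2(m[1, 0], m[0, 0])
    return tuple(math.degrees(t) for t in (theta_x, theta_y, theta_z))  # type: ignore[return-value]


def estimate_tilt(vol: GreyVolume, dominance_threshold: float = 0.8):
    """Corrective angles (deg, about x/y/z) aligning the scale with the grid.

    The scale is a thin slab with its normal along x.  The dark voxels --
    those below the midpoint of the robust 1st/99th-percentile intensity
    range -- mark the material; per (y, z) column their mean x position
    gives the slab's height map, and a least-squares plane fit to it
    yields the tilts about y and z.  The in-plane angle (about x) comes
    from the second-moment tensor of the slab silhouette, whose
    elongation along z is deterministic.  Both statistics average the
    random porous texture away, unlike raw principal axes of the material
    voxels, which the texture's coherent cross-moments tilt by degrees.

    Returns the corrective angles: ``rotate_volume(vol, estimate_tilt(vol))``
    aligns the object.  A volume whose dark voxels spread along x like
    the full box (e.g. featureless noise) has no dominant slab and is
    refused; the scale should be surrounded by some air on every face.
    """
    arr = np.asarray(vol.data, dtype=np.float64)
    p1, p99 = np.percentile(arr, [1, 99])
    mask = arr < (p1 + p99) / 2.0
    if not mask.any():
        raise TiltEstimationError("no dark voxels; volume is constant")
    nx = arr.shape[0]
    x = np.arange(nx, dtype=np.float64)
    cnt = mask.sum(axis=0)
    nonzero = cnt[cnt > 0]
    silhouette = cnt >= max(1.0, 0.25 * np.median(nonzero))
    if not silhouette.any():
        raise TiltEstimationError("empty material silhouette")
    # trim the silhouette rim: partially covered edge columns carry extreme
    # heights (slab corners) that would shear the plane fit
    trimmed = ndimage.binary_erosion(silhouette, structure=np.ones((7, 7), bool))
    if trimmed.any():
        silhouette = trimmed
    sx = np.tensordot(x, mask, axes=(0, 0))
    sx2 = np.tensordot(x * x, mask, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = sx / cnt
        col_var = sx2 / cnt - centroid**2
    # robust top/bottom material surfaces (a few voxels deep, so isolated
    # dark outliers cannot claim the surface); their midsurface is set by
    # the solid cuticle faces and is immune to the porous texture, unlike
    # the material centroid, whose long-wavelength density fluctuations
    # tilt the fitted plane by a degree or more
    depth = np.maximum(1, cnt // 20)
    cum = np.cumsum(mask, axis=0)
    h_top = (cum < depth).sum(axis=0).astype(np.float64)
    cum_rev = np.cumsum(mask[::-1], axis=0)
    h_bot = (nx - 1) - (cum_rev < depth).sum(axis=0).astype(np.float64)
    height = 0.5 * (h_top + h_bot)
    pooled_sd = float(np.sqrt(np.mean(col_var[silhouette])))
    box_sd = nx / np.sqrt(12.0)
    if pooled_sd > dominance_threshold * box_sd:
        raise TiltEstimationError(
            "material spreads along x like the full box; no dominant slab"
        )
    # out-of-plane tilts: plane fit height ~ a + b_y*y + b_z*z
    yy, zz = np.nonzero(silhouette)
    design = np.stack(
        [np.ones(yy.size), yy.astype(np.float64), zz.astype(np.float64)], axis=1
    )
    coef, *_ = np.linalg.lstsq(design, height[silhouette], rcond=None)
    _, b_y, b_z = coef
    # in-plane angle from silhouette second moments (major axis vs z)
    c2 = np.cov(np.stack([yy.astype(np.float64), zz.astype(np.float64)]))
    if abs(c2[0, 0] - c2[1, 1]) < 1e-12 and abs(c2[0, 1]) < 1e-12:
        phi = 0.0
    else:
        phi = 0.5 * math.atan2(2.0 * c2[0, 1], c2[1, 1] - c2[0, 0])
    theta_x = math.degrees(phi)
    theta_y = math.degrees(math.atan(b_z))
    theta_z = math.degrees(math.atan(b_y))
    return (theta_x, theta_y, theta_z)

def rotate_volume(
    vol: GreyVolume,
    angles: tuple[float, float, float],
    order: str = "cubic",
    fill_value: float | None = None,
) -> GreyVolume:
    """Rotate about the volume centre, x then y then z, shape preserved.

    Cubic-spline interpolation by default; out-of-bounds voxels take
    ``fill_value`` (default: the volume maximum, a proxy for light air).
    """
    if order not in _ORDERS:
        raise ConfigurationError(f"interpolation order must be one of {set(_ORDERS)}")
    if not all(np.isfinite(a) for a in angles):
        raise ConfigurationError("angles must be finite")
    spline = _ORDERS[order]
    data = np.asarray(vol.data)
    if fill_value is None:
        fill_value = float(data.max())
    out = data
    for axis in (0, 1, 2):
        if angles[axis] != 0:
            out = ndimage.rotate(
                out,
                angles[axis],
                axes=_PLANES[axis],
                reshape=False,
                order=spline,
                mode="constant",
                cval=fill_value,
                prefilter=spline > 1,
            )
    return GreyVolume(out, pitch_nm=vol.pitch_nm)
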