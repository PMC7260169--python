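# Methods

This note documents the models, parameter choices and numerical decisions
behind scaletomo, and what the synthetic validation does and does not
show about real beamline data.

## Synthetic porous scale

The generator emulates the features of a whole-scale tomogram that the
processing chain must survive: a two-phase chitin/air network with one
characteristic structural length, a solid cuticle shell, greyscale
rendering with additive noise and concentric ring artefacts, and vertical
cutting into overlapping sub-scans with integer mounting jitter.

**Network model.** A Gaussian random field: seeded white noise smoothed
with an isotropic Gaussian kernel of width `correlation_length`
(default 150 nm = 6 voxels at 25 nm pitch), thresholded at the sample
quantile of the interior field that yields `target_fill` exactly. The
quantile construction pins the interior material fraction by
construction, so fill-recovery tests measure segmentation error, not
generator luck. Two fills generated from the same seed share one field,
so the denser material set strictly contains the sparser — a property the
tests exploit. The field is generated on a grid padded by the kernel's
4σ truncation radius and cropped, because smoothing a finite grid in
place inflates the variance near the faces and would bias the material
fraction of off-centre subregions by percentage points.

**Rendering.** Material voxels at `grey_material` (default 80), air at
`grey_air` (default 180) on the 0–254 8-bit convention; multiplicative
ring modulation `1 + a·sin(2πr/T)` per xy-slice about the slice centre
(rotation axis along z; defaults a = 0.05, T = 40 voxels); additive
Gaussian noise (default σ = 10 grey levels); clipping to [0, 254]. The
ring modulation is applied to the clean two-level image and noise added
afterwards, so the per-phase noise level equals the configured σ exactly.

**Scan cutting.** Scan k covers `z ∈ [k·(fov−overlap), … + fov)`; scans
after the first may receive seeded integer z and lateral jitters
(camera-position errors). Frames beyond the source are filled with an
air-level pad value. One integer seed drives field, noise and jitter
through separate spawned streams, so every object is reproducible.

**What the generator does not emulate:** beam physics, phase-retrieval
residuals, anisotropic or layered networks, partial-volume blur at the
chitin/air interface (phases render as sharp two-level signal plus
noise), intensity drift between scans, and detector defects beyond the
sinusoidal ring model. Passing tests therefore demonstrate the
correctness and internal consistency of the chain — exact registration,
halo-correct chunking, threshold arithmetic, statistics — not that the
specific threshold values are optimal for any particular beamline's
contrast. The synthetic contrast is deliberately benign; on it the chain
recovers interior fill to ~0.1 point, and the acceptance band (±2
points) mirrors the uncertainty quoted for the real scales.

## Assembly

Registration maximises normalized cross-correlation (NCC) between the
centre frame of the upper scan's overlap region — the centre avoids the
artefact-prone extreme top/bottom frames — and candidate frames of the
lower scan over ±`search_window` frames around the nominal offset and
±`lateral_window` integer shifts. NCC is invariant to affine intensity
rescaling, which tolerates per-scan normalisation differences. Ties are
broken by smallest deviation from the nominal offset, then smallest
|dx|+|dy|, then lowest offset. Registration is integer-voxel only:
frames are matched, never resampled, so stitching clean scan sets is
bit-exact. Constant (featureless) reference frames raise an error rather
than matching arbitrarily. Seams sit at the centre of the matched
overlap; the stitched z-extent is the last cumulative offset plus the
field of view.

**Tilt estimation.** The scale is a thin slab with its normal along x.
Raw principal axes of the material voxels are unusable at small volume:
the porous texture's coherent long-wavelength cross-moments tilt them by
several degrees. Instead the estimator uses the deterministic geometry:
per (y, z) column, robust top and bottom material surfaces (a few voxels
deep, so isolated outliers cannot claim a surface) give the cuticle
midsurface, whose least-squares plane fit yields the tilts about y and
z; the in-plane angle comes from the second moments of the (rim-trimmed)
material silhouette. Known 3° rotations are recovered to ~0.1° on both
clean and porous scales. The estimator assumes the scale is surrounded
by some air (true of the real matrices) and refuses volumes whose dark
voxels spread along x like the full box. Rotation uses cubic-spline
interpolation about the volume centre, applied about x, then y, then z;
scipy's rotate normalises its axis pair to ascending order, and the
package's rotation-matrix convention is anchored to that behaviour.

## Segmentation

Order of operations: saturate → normalize → chunked NLM → adaptive and
global thresholds on the same denoised volume → combine.

* **Saturation** clips at the 0.5th/99.5th linear-interpolation sample
  percentiles of the *full* volume (never per chunk, so the intensity
  scale cannot depend on the chunk grid).
* **"Normalized intensity"** is defined as the linear map of the
  saturated range onto [0, 1]; the saturation endpoints are the only
  intensity scale the pipeline establishes. The global 0.4 threshold is
  applied to the *denoised* normalized volume, matching the processing
  order of the chain.
* **Non-local means.** Weights `exp(−max(d²−2σ_n², 0)/h²)` on patch
  mean-squared differences, uniform patch weighting, 3-D patches
  (a 2-D slice-wise mode exists for comparison). The filter bandwidth h
  is not a published value; the default is 0.8 × the noise level
  estimated once per volume from the median absolute deviation of
  Laplacian residuals (the discrete 3-D Laplacian of iid noise has
  variance 42 σ², hence the √42 correction), and the derived h is
  recorded in the provenance. The implementation is built exclusively
  from elementwise operations and direct small-kernel 1-D correlations,
  so a voxel's output is a pure function of its
  (patch_distance + patch_size//2)-neighbourhood — the property that
  makes chunked processing bit-identical to monolithic, which integral-
  image NLM implementations cannot guarantee at the ulp level. Work is
  done in float32.
* **Chunking.** Chunks are extended by a halo (default 10 voxels,
  clipped at the volume boundary so reflect-padding coincides with the
  monolithic case); only chunk interiors are written back. A halo below
  the operator's declared support radius is refused outright. The chunk
  grid is planned from a target chunk voxel count (default 128³) by
  repeatedly halving the largest axis.
* **Thresholds.** Adaptive: local mean by Gaussian smoothing with
  σ = (region_size − 1)/6, kernel truncated at 4σ, reflecting
  boundaries; voxel is material iff value < mean − offset, strictly.
  Global: material iff value < 0.4, strictly. Strict inequalities are
  applied consistently in both rules. The combined mask is the product
  of the two air masks, i.e. the union of the material sets: the
  adaptive rule sees the porous interior (it keys on local contrast and
  is blind inside solid chitin), the global rule sees solid cuticle.
* **Degenerate inputs.** A constant volume saturates/normalizes to all
  zeros and thresholds to all air; region_size 1 (σ = 0) is rejected as
  degenerate; h ≤ 0 reduces NLM to the identity (zero-bandwidth limit).

## Metrics

Filling fraction is 100 × material voxels / total voxels. The
"correlation function" is the standard two-point probability S₂ along
the three lattice directions, with no wrap-around (cubes are physical
samples, not periodic cells); S₂(0) equals the fill fraction. Cube
sampling uses seeded uniform-random corners inside the volume minus an
interior margin (to exclude cuticle and edges); overlaps are allowed.
The ± on cube fill is the sample standard deviation across cubes, not a
standard error: a percent-scale spread over hundreds of cubes is a
dispersion statement about the structure, not about the mean. The
representative cube minimises the mean over directions and lags of the
squared deviation from the cube-averaged S₂ curves, ties to the lowest
index. r_max defaults to 100 voxels (2.5 µm) on deposit-scale cubes and
is configurable.

## Storage conventions

Bit-packing is MSB-first within bytes over a row-major (x, y, z)
flattening, trailing bits zero; polarity is fixed as material = 0 /
air = 1. Sizes are decimal GB (10⁹ bytes) — the published size tables
are only consistent with decimal GB — with greyscale/thresholded full
volumes at 1 byte/voxel and slabs/cubes at 8-byte floats; manifests
print three significant figures. The reader accepts any single-array
zip archive regardless of key, and warns (not errors) on grey value 255
to tolerate dialects of the 0–254 convention.

## Problem sizes in the tests

The validation suite runs the full chain at 48–112 voxels per axis
(e.g. fill recovery at 56×72×112, two target fills × three seeds;
chunked/monolithic equivalence on 64³ split 2×2×2 with production filter
parameters). These sizes are chosen so the whole suite runs in a few
minutes on one CPU while every claim — exact quantile pinning, bit-exact
chunk equivalence, exact offset recovery, sub-half-degree tilt recovery,
±2-point fill recovery — is asserted at full strictness; none of the
guarantees is size-dependent. Deposit-scale runs differ only in chunk
count and wall time.

## Known limitations

* Registration is integer-voxel and pairwise-sequential; there is no
  subvoxel refinement or global bundle adjustment over more than two
  scans (small pairwise errors could accumulate over many junctions).
* Tilt estimation presumes slab geometry with the normal near x and
  some surrounding air; it is not a general orientation estimator.
* The NLM bandwidth default is a reconstruction, not a published value;
  runs record the derived value so results remain comparable.
* No morphological post-processing is applied to masks, and no
  alternative denoisers or learned thresholds are provided.
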