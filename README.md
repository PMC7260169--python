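# scaletomo

Processing chain for whole-scale X-ray nano-holotomography of beetle
scales: assembly of overlapping tomography sub-volumes into one matrix,
saturation / denoising / dual-mode thresholding into a chitin–air binary
volume, and porous-network statistics.

## The problem

The ultra-white scales of the beetles *Cyphochilus* and *Lepidiota stigma*
owe their brilliant whiteness to a disordered porous network of chitin and
air inside a solid cuticle shell. Imaging an intact scale at 25 nm voxel
pitch exceeds any single tomography field of view (54 µm vertically), so a
scale a few hundred µm long is captured as a stack of scans overlapping by
10 µm, which must then be registered, stitched, rotation-corrected,
denoised and thresholded before the structure can be quantified. The
number of scans follows from coverage arithmetic,

```
n = 1                                   if L <= FOV
n = ceil((L - FOV) / (FOV - overlap)) + 1   otherwise
```

giving 6 scans for a 240 µm scale and 8 for a 350 µm scale at FOV 54 µm
and 10 µm overlap (400 common frames at 25 nm/voxel).

This package implements that chain as a tested, reusable library with a
ground-truthed synthetic porous-scale generator, so every stage can be
validated at desk scale without the multi-GB beamline volumes. It also
reads and writes the deposit's conventions: 0–254 greyscale volumes, and
thresholded volumes bit-packed MSB-first into uint8 bytes with polarity
material = 0 / air = 1.

## The method

* **Stitching** — the common frame between consecutive scans is found by
  maximising normalized cross-correlation between the centre frame of the
  upper scan's overlap region and candidate frames of the lower scan over
  a z search window and small integer lateral shifts; seams are placed at
  the centre of the matched overlap. Mounting tilt is estimated from the
  cuticle midsurface plane and the scale silhouette, and corrected by
  cubic-spline rotation.
* **Segmentation** — the darkest and lightest 0.5 % of grey values are
  saturated, the clipped range is rescaled to [0, 1], and the volume is
  denoised with a 3-D non-local means filter (patch size 5, patch
  distance 7), run over chunks with a 10-voxel halo that makes chunked
  output bit-identical to monolithic processing. Two thresholds are then
  combined: an adaptive Gaussian threshold (voxel is chitin when its
  value is below the Gaussian-weighted local mean minus an offset of
  0.06, with σ = (region_size − 1)/6 and region size 60) that captures
  the porous interior, and a strict global threshold (value < 0.4) that
  captures solid cuticle. The final mask is the product of the two air
  masks — the union of the material sets.
* **Statistics** — the filling fraction (percent chitin by volume), its
  spread over randomly sampled interior cubes (5 µm, i.e. 200 voxels, in
  the real data), directional two-point correlation functions
  S₂(r) = P(both voxels at lag r are material), and the representative
  cube: the sample whose S₂ curves have the least mean squared error
  against the cube-averaged curves.

On synthetic scales generated at the filling fractions observed for the
real scales (31 % and 34 %), the full chain recovers the interior fill to
well within the ±2 / ±1 percentage-point uncertainties quoted for the
real data.

## Worked example

```python
from scaletomo.pipeline import RunConfig, run_pipeline

out = run_pipeline(RunConfig(seed=11), "runs/demo")
print((out / "report.json").read_text())
```

prints (abridged):

```json
{
 "interior_fill_pct": 30.656869070870535,
 "truth_interior_fill_pct": 30.999973842075896,
 "target_fill_pct": 31.0,
 "cube_fill_mean_pct": 28.629913330078125,
 "cube_fill_sd_pct": 13.856782966376086,
 "n_cubes": 40,
 "representative_cube_index": 31,
 "stitch_junctions": [
  {"pair": [0, 1], "z_offset": 63, "lateral_shift": [2, -2], "score": 1.0},
  {"pair": [1, 2], "z_offset": 65, "lateral_shift": [-2, 1], "score": 1.0}
 ]
}
```

Reading it: a synthetic scale with a true interior fill pinned at 31 % was
cut into three overlapping scans with secret integer jitters; registration
recovered every offset exactly (scores ≈ 1), and the segmentation chain
reported an interior fill of 30.66 % — within 0.4 points of the truth.
The cube statistics show the expected large cube-to-cube spread at this
small cube size.

The same stages are available as a CLI:

```sh
scaletomo simulate --out runs/scans --seed 3 --fov 96 --overlap 32
scaletomo stitch --scans runs/scans --nominal-overlap-um 0.8 --out runs/stitched.npy
scaletomo segment --in runs/stitched.npy --out runs/mask.npz
scaletomo metrics --in runs/mask.npz --cubes 40 --edge 24 --margin 12 --out runs/stats
```

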