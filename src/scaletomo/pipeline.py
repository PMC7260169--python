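"""End-to-end orchestration: simulate -> stitch -> segment -> metrics.

One :class:`RunConfig` carries every knob of every stage plus a single
global seed; a run writes each intermediate volume, a manifest, per-stage
JSON-lines logs, the full parameter provenance and a final report.
Re-running with the same config and seed reproduces every binary output
bit-exactly, whatever the worker count.

Seed scheme: the synthetic-scale generator uses the global seed directly
(its own internal stream splitting covers field/noise/jitter); cube
sampling uses ``seed + 1``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import assembly, metrics, segmentation, synthetic, volume_io
from .errors import ScaleTomoError, StageError
from .segmentation import SegmentationConfig
from .synthetic import SyntheticScaleConfig
from .volumes import BinaryVolume, GreyVolume


@dataclass
class RunConfig:
    """Composition of every stage's parameters plus the global seed."""

    scale: SyntheticScaleConfig = field(default_factory=SyntheticScaleConfig)
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    # scan splitting (desk-scale defaults; the beamline geometry is
    # fov 2160 voxels / overlap 400 voxels at 25 nm pitch)
    fov_voxels: int = 96
    overlap_voxels: int = 32
    lateral_jitter: int = 2
    z_jitter: int = 4
    # registration
    search_window: int = 8
    lateral_window: int = 4
    # metrics (desk-scale defaults; deposit-scale: edge 200, n 275, r_max 100)
    cube_edge: int = 32
    n_cubes: int = 40
    r_max: int = 16
    # margin 0 = everything inside the cuticle shell, the region whose fill
    # the generator pins exactly; cube sampling adds its own margins
    interior_margin: int = 0
    # execution
    apply_tilt_correction: bool = False
    n_jobs: int = 1
    keep_intermediates: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale"]["shape"] = list(self.scale.shape)
        if self.seg.chunk_shape is not None:
            d["seg"]["chunk_shape"] = list(self.seg.chunk_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        scale = dict(d.pop("scale", {}))
        if "shape" in scale:
            scale["shape"] = tuple(scale["shape"])
        seg = dict(d.pop("seg", {}))
        if seg.get("chunk_shape") is not None:
            seg["chunk_shape"] = tuple(seg["chunk_shape"])
        return cls(
            scale=SyntheticScaleConfig(**scale), seg=SegmentationConfig(**seg), **d
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _log(handle, stage: str, event: str, **info) -> None:
    handle.write(json.dumps({"stage": stage, "event": event, **info}) + "\n")
    handle.flush()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute all stages in order, writing intermediates, logs and report.

    Any stage failure aborts with the stage name while preserving the
    outputs of earlier stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dataclasses.replace(
        config, scale=dataclasses.replace(config.scale, seed=config.seed)
    )
    config.to_yaml(outdir / "config.yaml")
    manifest: list[volume_io.VolumeManifest] = []
    pitch = config.scale.pitch_nm
    log = open(outdir / "log.jsonl", "w")

    def fail(stage: str, exc: Exception):
        _log(log, stage, "failed", error=str(exc))
        log.close()
        raise StageError(stage, str(exc)) from exc

    # -- simulate ----------------------------------------------------------
    try:
        _log(log, "simulate", "start", seed=config.seed)
        truth = synthetic.generate_truth(config.scale)
        grey = synthetic.render_greyscale(truth, config.scale)
        scans = synthetic.split_into_scans(
            grey,
            config.fov_voxels,
            config.overlap_voxels,
            lateral_jitter=config.lateral_jitter,
            seed=config.seed,
            z_jitter=config.z_jitter,
            pad_value=config.scale.grey_air,
        )
        if config.keep_intermediates:
            volume_io.write_packed(outdir / "truth.npz", truth)
            scans_dir = outdir / "scans"
            scans_dir.mkdir(exist_ok=True)
            for k, s in enumerate(scans.scans):
                volume_io.write_volume(scans_dir / f"scan_{k + 1:02d}.npy", s)
                manifest.append(
                    volume_io.manifest_entry(
                        f"scans/scan_{k + 1:02d}.npy",
                        s.shape,
                        s.data.dtype.itemsize,
                        "greyscale",
                        pitch,
                    )
                )
            (scans_dir / "true_offsets.json").write_text(
                json.dumps(
                    {
                        "z_offsets": scans.z_offsets,
                        "lateral_shifts": [list(s) for s in scans.lateral_shifts],
                        "fov_voxels": scans.fov_voxels,
                        "overlap_voxels": scans.overlap_voxels,
                    },
                    indent=2,
                )
            )
        _log(log, "simulate", "done", n_scans=len(scans.scans))
    except ScaleTomoError as exc:
        fail("simulate", exc)

    # -- stitch ------------------------------------------------------------
    try:
        matches = assembly.match_scan_set(
            scans,
            nominal_frames=config.overlap_voxels,
            search_window=config.search_window,
            lateral_window=config.lateral_window,
        )
        stitched = assembly.stitch(scans, matches)
        if config.apply_tilt_correction:
            angles = assembly.estimate_tilt(stitched)
            stitched = assembly.rotate_volume(stitched, angles)
            _log(log, "stitch", "tilt_corrected", angles=list(angles))
        if config.keep_intermediates:
            volume_io.write_volume(outdir / "stitched.npy", stitched)
            manifest.append(
                volume_io.manifest_entry(
                    "stitched.npy",
                    stitched.shape,
                    stitched.data.dtype.itemsize,
                    "greyscale",
                    pitch,
                )
            )
        stitch_diag = [
            {
                "pair": list(m.pair),
                "z_offset": m.z_offset,
                "lateral_shift": list(m.lateral_shift),
                "score": m.score,
            }
            for m in matches
        ]
        _log(log, "stitch", "done", junctions=stitch_diag)
    except ScaleTomoError as exc:
        fail("stitch", exc)

    # -- segment -----------------------------------------------------------
    try:
        result = segmentation.segment(
            stitched, config.seg, n_jobs=config.n_jobs, full_output=True
        )
        mask = result.mask
        volume_io.write_packed(outdir / "mask.npz", mask)
        manifest.append(
            volume_io.manifest_entry(
                "mask.npz", mask.shape, 1, "thresholded", pitch
            )
        )
        (outdir / "provenance.json").write_text(
            json.dumps(result.provenance, indent=2)
        )
        _log(log, "segment", "done", **{
            k: result.provenance[k] for k in ("derived_nlm_h", "clip_min", "clip_max")
        })
    except ScaleTomoError as exc:
        fail("segment", exc)

    # -- metrics -----------------------------------------------------------
    try:
        interior = synthetic.interior_region(
            config.scale, margin=config.interior_margin
        )
        interior_fill = metrics.fill_fraction(mask.data[interior])
        truth_fill = metrics.fill_fraction(truth.data[interior])
        margins = (
            config.scale.cuticle_thickness_voxels + config.interior_margin,
            config.interior_margin,
            config.interior_margin,
        )
        cubes = metrics.sample_cubes(
            mask,
            edge=config.cube_edge,
            n=config.n_cubes,
            seed=config.seed + 1,
            interior_margin=margins,
        )
        stats = metrics.fill_stats(cubes, seed=config.seed + 1)
        rep = metrics.representative_cube(cubes, r_max=config.r_max)
        report = {
            "interior_fill_pct": interior_fill,
            "truth_interior_fill_pct": truth_fill,
            "target_fill_pct": 100.0 * config.scale.target_fill,
            "cube_fill_mean_pct": stats.mean,
            "cube_fill_sd_pct": stats.sd,
            "n_cubes": stats.n,
            "representative_cube_index": rep,
            "representative_cube_corner": list(cubes[rep].corner),
            "stitch_junctions": stitch_diag,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        volume_io.write_manifest(outdir / "manifest.json", manifest)
        _log(log, "metrics", "done", interior_fill_pct=interior_fill)
    except ScaleTomoError as exc:
        fail("metrics", exc)

    log.close()
    return outdir
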