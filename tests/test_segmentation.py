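import numpy as np
import pytest

from scaletomo import segmentation as seg
from scaletomo import synthetic
from scaletomo.errors import ConfigurationError, HaloTooSmallError, ShapeMismatchError
from scaletomo.volumes import AIR, MATERIAL, BinaryVolume, GreyVolume


def _grey(arr):
    return GreyVolume(np.asarray(arr))


class TestSaturate:
    def test_two_point_distribution_unchanged(self):
        data = np.concatenate([np.zeros(500), np.ones(500)]).reshape(10, 10, 10)
        out, scale = seg.saturate(_grey(data))
        assert np.array_equal(out.data, data)
        assert (scale.clip_min, scale.clip_max) == (0.0, 1.0)

    def test_constant_unchanged(self):
        data = np.full((5, 5, 5), 3.0)
        out, scale = seg.saturate(_grey(data))
        assert np.array_equal(out.data, data)
        assert scale.clip_min == scale.clip_max == 3.0

    def test_ramp_matches_sort_interpolate_oracle(self):
        data = np.arange(1.0, 1001.0).reshape(10, 10, 10)
        out, scale = seg.saturate(_grey(data), 0.5, 99.5)
        # sort-and-interpolate percentile oracle
        v = np.sort(data.ravel())
        n = v.size

        def pct(q):
            pos = q / 100 * (n - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return v[lo] * (1 - frac) + v[min(lo + 1, n - 1)] * frac

        assert scale.clip_min == pytest.approx(pct(0.5))
        assert scale.clip_max == pytest.approx(pct(99.5))
        assert out.data.min() == pytest.approx(scale.clip_min)
        assert out.data.max() == pytest.approx(scale.clip_max)
        assert np.all(out.data == np.clip(data, scale.clip_min, scale.clip_max))


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        scale = seg.IntensityScale(10.0, 30.0)
        data = np.array([10.0, 20.0, 30.0] * 9)[:27].reshape(3, 3, 3)
        out = seg.normalize(_grey(data), scale)
        assert out.data.ravel()[0] == 0.0
        assert out.data.ravel()[1] == pytest.approx(0.5)
        assert out.data.ravel()[2] == 1.0

    def test_constant_maps_to_zero(self):
        out = seg.normalize(_grey(np.full((3, 3, 3), 7.0)), seg.IntensityScale(7.0, 7.0))
        assert (out.data == 0).all()

    def test_linear_map_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(50, 200, (8, 8, 8))
        scale = seg.IntensityScale(50.0, 200.0)
        out = seg.normalize(_grey(data), scale)
        assert np.allclose(out.data, (data - 50) / 150, atol=1e-6)


class TestNonLocalMeans:
    def test_constant_unchanged(self):
        out = seg.nlm_denoise(_grey(np.full((12, 12, 12), 0.4)), 3, 2, h=0.2)
        assert np.allclose(out.data, 0.4, atol=1e-6)

    def test_zero_bandwidth_limit_is_identity(self):
        rng = np.random.default_rng(1)
        data = rng.random((10, 10, 10)).astype(np.float32)
        out = seg.nlm_denoise(_grey(data), 3, 2, h=1e-8)
        assert np.allclose(out.data, data, atol=1e-5)

    def test_matches_bruteforce_oracle(self):
        """Literal per-voxel NLM (python loops) agrees with the vectorised path."""
        rng = np.random.default_rng(2)
        arr = rng.random((8, 7, 6)).astype(np.float32)
        ps, pd, h, sigma = 3, 2, 0.3, 0.1
        mine = seg._nlm_nd(arr, ps, pd, h, sigma)
        pr = ps // 2
        radius = pr + pd
        pad = np.pad(arr.astype(np.float64), radius, mode="reflect")
        oracle = np.zeros(arr.shape)
        for ix in range(arr.shape[0]):
            for iy in range(arr.shape[1]):
                for iz in range(arr.shape[2]):
                    cx, cy, cz = ix + radius, iy + radius, iz + radius
                    p0 = pad[cx - pr:cx + pr + 1, cy - pr:cy + pr + 1, cz - pr:cz + pr + 1]
                    num = den = 0.0
                    for dx in range(-pd, pd + 1):
                        for dy in range(-pd, pd + 1):
                            for dz in range(-pd, pd + 1):
                                qx, qy, qz = cx + dx, cy + dy, cz + dz
                                pq = pad[qx - pr:qx + pr + 1, qy - pr:qy + pr + 1,
                                         qz - pr:qz + pr + 1]
                                d2 = np.mean((p0 - pq) ** 2)
                                w = 1.0 if (dx, dy, dz) == (0, 0, 0) else np.exp(
                                    -max(d2 - 2 * sigma**2, 0.0) / h**2
                                )
                                num += w * pad[qx, qy, qz]
                                den += w
                    oracle[ix, iy, iz] = num / den
        assert np.abs(mine - oracle).max() < 1e-5

    def test_reduces_noise_preserves_phase_means(self):
        cfg = synthetic.SyntheticScaleConfig(
            shape=(32, 32, 48), noise_sigma=10.0, ring_amplitude=0.0,
            grey_dtype="float32", seed=4,
        )
        truth, grey = synthetic.simulate_scale(cfg)
        norm = GreyVolume(grey.data.astype(np.float32) / 254.0)
        out = seg.nlm_denoise(norm, 3, 3, h=0.05)
        for phase, level in ((MATERIAL, cfg.grey_material), (AIR, cfg.grey_air)):
            sel = truth.data == phase
            assert out.data[sel].var() < norm.data[sel].var()
            assert abs(out.data[sel].mean() - level / 254.0) < 0.01

    def test_even_patch_rejected(self):
        with pytest.raises(ConfigurationError):
            seg.NonLocalMeansFilter(patch_size=4)


class TestChunkedApply:
    def test_single_chunk_equals_monolithic(self):
        rng = np.random.default_rng(5)
        data = rng.random((20, 20, 20)).astype(np.float32)
        f = seg.NonLocalMeansFilter(3, 2, h=0.2)
        assert np.array_equal(
            seg.chunked_apply(data, f, chunk_shape=(64, 64, 64), halo=10), f(data)
        )

    def test_chunked_bit_identical_small(self):
        rng = np.random.default_rng(6)
        data = rng.random((24, 24, 24)).astype(np.float32)
        f = seg.NonLocalMeansFilter(3, 2, h=0.15)  # support radius 3
        mono = f(data)
        chunked = seg.chunked_apply(data, f, chunk_shape=(12, 12, 12), halo=5)
        assert np.array_equal(mono, chunked)

    def test_halo_below_support_refused(self):
        data = np.zeros((16, 16, 16), np.float32)
        f = seg.NonLocalMeansFilter(5, 7, h=0.1)  # support radius 9
        with pytest.raises(HaloTooSmallError):
            seg.chunked_apply(data, f, chunk_shape=(8, 8, 8), halo=5)

    def test_plan_chunk_shape(self):
        assert seg.plan_chunk_shape((64, 64, 64), 128**3) == (64, 64, 64)
        chunk = seg.plan_chunk_shape((512, 512, 512), 128**3)
        assert np.prod(chunk) <= 128**3


class TestThresholds:
    def test_gaussian_sigma_formula(self):
        assert seg.gaussian_sigma(60) == pytest.approx(59 / 6)
        assert seg.gaussian_sigma(7) == 1.0
        assert seg.gaussian_sigma(1) == 0.0  # degenerate: surface collapses

    def test_adaptive_constant_is_all_air(self):
        out = seg.adaptive_gaussian_threshold(_grey(np.full((16, 16, 16), 0.5)))
        assert (out.data == AIR).all()

    def test_adaptive_single_dark_voxel(self):
        data = np.full((41, 41, 41), 0.8)
        data[20, 20, 20] = 0.0
        out = seg.adaptive_gaussian_threshold(_grey(data), region_size=15, offset=0.06)
        assert out.data[20, 20, 20] == MATERIAL
        assert out.data[0, 0, 0] == AIR
        assert out.data[40, 40, 40] == AIR

    def test_adaptive_matches_kernel_sum_oracle(self):
        """Voxel-identical to an explicit kernel-sum local mean, reflect padding."""
        rng = np.random.default_rng(7)
        data = rng.random((32, 32, 32))
        region, offset = 15, 0.06
        out = seg.adaptive_gaussian_threshold(_grey(data), region, offset)
        sigma = seg.gaussian_sigma(region)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        padded = np.pad(data, radius, mode="symmetric")
        win = np.lib.stride_tricks.sliding_window_view(
            padded, (2 * radius + 1,) * 3
        )
        local_mean = np.einsum("abcijk,ijk->abc", win, kernel)
        expected = np.where(data < local_mean - offset, MATERIAL, AIR)
        assert np.array_equal(out.data, expected)

    def test_adaptive_degenerate_region_rejected(self):
        with pytest.raises(ConfigurationError):
            seg.adaptive_gaussian_threshold(_grey(np.zeros((4, 4, 4))), region_size=1)

    def test_global_threshold_strict_inequality(self):
        data = np.array([0.39, 0.40, 0.41] * 9)[:27].reshape(3, 3, 3)
        out = seg.global_threshold(_grey(data), 0.4)
        flat = out.data.ravel()
        assert flat[0] == MATERIAL and flat[1] == AIR and flat[2] == AIR

    def test_global_threshold_edge_cases(self):
        assert (seg.global_threshold(_grey(np.ones((3, 3, 3))), 0.4).data == AIR).all()
        assert (
            seg.global_threshold(_grey(np.full((3, 3, 3), 0.9)), 1.0).data == MATERIAL
        ).all()

    def test_monotonicity(self):
        """Raising t grows the material set; raising offset shrinks adaptive's."""
        rng = np.random.default_rng(8)
        vol = _grey(rng.random((24, 24, 24)))
        m_lo = seg.global_threshold(vol, 0.3).data == MATERIAL
        m_hi = seg.global_threshold(vol, 0.6).data == MATERIAL
        assert np.all(m_hi[m_lo])
        a_small = seg.adaptive_gaussian_threshold(vol, 15, 0.02).data == MATERIAL
        a_large = seg.adaptive_gaussian_threshold(vol, 15, 0.10).data == MATERIAL
        assert np.all(a_small[a_large])


class TestCombineMasks:
    def test_truth_table_and_idempotence(self):
        a = BinaryVolume(np.array([0, 0, 1, 1], np.uint8).reshape(1, 1, 4))
        b = BinaryVolume(np.array([0, 1, 0, 1], np.uint8).reshape(1, 1, 4))
        out = seg.combine_masks(a, b)
        assert out.data.ravel().tolist() == [0, 0, 0, 1]
        assert np.array_equal(seg.combine_masks(a, a).data, a.data)

    def test_union_of_material_sets(self):
        rng = np.random.default_rng(9)
        a = BinaryVolume(rng.integers(0, 2, (16, 16, 16)).astype(np.uint8))
        b = BinaryVolume(rng.integers(0, 2, (16, 16, 16)).astype(np.uint8))
        out = seg.combine_masks(a, b)
        fill = lambda m: np.mean(m.data == MATERIAL)
        assert fill(out) >= max(fill(a), fill(b))
        assert np.array_equal(out.data == MATERIAL, (a.data == MATERIAL) | (b.data == MATERIAL))

    def test_shape_mismatch(self):
        a = BinaryVolume(np.zeros((2, 2, 2), np.uint8))
        b = BinaryVolume(np.zeros((2, 2, 3), np.uint8))
        with pytest.raises(ShapeMismatchError):
            seg.combine_masks(a, b)


class TestSegmentChain:
    def test_output_polarity_and_packing(self, noisy_scale):
        _, _, grey = noisy_scale
        cfg = seg.SegmentationConfig(patch_size=3, patch_distance=2, halo=10)
        mask = seg.segment(GreyVolume(grey.data[:, :, :64]), cfg)
        assert set(np.unique(mask.data).tolist()) <= {0, 1}
        from scaletomo import volume_io as vio

        payload, shape = vio.pack_binary(mask)
        assert np.array_equal(vio.unpack_binary(payload, shape).data, mask.data)

    def test_noiseless_recovery_away_from_cuticle(self, noiseless_scale):
        cfg, truth, grey = noiseless_scale
        sub = GreyVolume(grey.data[:, :, :64].astype(np.uint8))
        mask = seg.segment(sub, seg.SegmentationConfig(patch_size=3, patch_distance=2))
        interior = synthetic.interior_region(cfg)
        got = mask.data[interior][:, :, :64]
        want = truth.data[interior][:, :, :64]
        assert np.array_equal(got, want)

    def test_identical_parameters_across_samples(self, noisy_scale):
        _, _, grey = noisy_scale
        cfg = seg.SegmentationConfig(patch_size=3, patch_distance=2, nlm_strength=0.05)
        r1 = seg.segment(GreyVolume(grey.data[:, :, :48]), cfg, full_output=True)
        r2 = seg.segment(GreyVolume(grey.data[:, :, 48:96]), cfg, full_output=True)
        keys = [
            "sat_low_pct", "sat_high_pct", "patch_size", "patch_distance",
            "nlm_strength", "halo", "region_size", "offset", "global_threshold",
            "derived_nlm_h", "derived_threshold_sigma",
        ]
        assert {k: r1.provenance[k] for k in keys} == {
            k: r2.provenance[k] for k in keys
        }

    def test_config_invariants(self):
        with pytest.raises(ConfigurationError):
            seg.SegmentationConfig(halo=5)  # below patch_distance
        with pytest.raises(ConfigurationError):
            seg.SegmentationConfig(sat_low_pct=99.0, sat_high_pct=1.0)
        with pytest.raises(ConfigurationError):
            seg.SegmentationConfig(global_threshold=1.5)


class TestNoiseEstimate:
    def test_recovers_known_sigma(self):
        rng = np.random.default_rng(10)
        noise = rng.normal(0.0, 0.05, (48, 48, 48))
        est = seg.estimate_noise_sigma(noise)
        assert est == pytest.approx(0.05, rel=0.1)
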