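"""Noise-map construction: subtraction identities, resampling, patches."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cacdn import (block_downsample, bicubic_upsample, extract_patches,
                   pseudo_noise_map, real_noise_map, shuffle_patches)
from cacdn.noisemaps import _keys_kernel, smooth_image
from conftest import small_image


class TestRealNoiseMap:
    def test_identical_images_zero(self):
        thin = small_image(np.full((8, 8), 50.0), thickness=1.5)
        thick = small_image(np.full((8, 8), 50.0), thickness=3.0)
        m = real_noise_map(thick, thin)
        assert np.all(m.values == 0.0)

    def test_known_delta_recovered(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 30, (16, 16)).astype(np.float32)
        delta = rng.normal(0, 5, (16, 16)).astype(np.float32)
        thick = small_image(base, thickness=3.0)
        thin = small_image(base + delta, thickness=1.0)
        m = real_noise_map(thick, thin)
        expect = (base + delta).astype(np.float64) - base.astype(np.float64)
        assert np.array_equal(m.values, expect)

    def test_subtraction_closure_bit_exact(self, cirs_pair):
        """thin - sigma_real reproduces the 3-mm image at bit level."""
        m = real_noise_map(cirs_pair.thick, cirs_pair.thin)
        recon = (cirs_pair.thin.pixels.astype(np.float64) - m.values
                 ).astype(np.float32)
        assert np.array_equal(recon, cirs_pair.thick.pixels)

    def test_map_sd_matches_monte_carlo(self, cirs_s, grid):
        """SD of the real map in a flat ROI agrees with direct simulation."""
        from cacdn import simulate_scan
        yy, xx = grid.pixel_centers()
        roi = xx ** 2 + yy ** 2 <= 10.0 ** 2
        sds = []
        for s in range(5):
            p = simulate_scan(cirs_s, grid, z=1.5, seed=500 + s)
            sds.append(real_noise_map(p.thick, p.thin).values[roi].std())
        # direct oracle: sigma_real = (1-1/n)*thin_ind - mean(other inds),
        # each realization sigma_z = sd_ref*sqrt(2), shared part cancels
        sd_ref, rho, n = 25.29, 0.10, 2
        sigma_z = sd_ref * np.sqrt(3.0 / 1.5)
        expect = sigma_z * np.sqrt((1 - rho) * (1 - 1 / n))
        assert np.mean(sds) == pytest.approx(expect, rel=0.10)

    def test_rejects_mismatch(self):
        thin = small_image(np.zeros((8, 8)), thickness=1.5)
        also_thin = small_image(np.zeros((8, 8)), thickness=1.5)
        with pytest.raises(ValueError):
            real_noise_map(also_thin, thin)


class TestBlockDownsample:
    def test_constant(self):
        assert np.all(block_downsample(np.full((6, 6), 7.5)) == 7.5)

    def test_single_block_mean(self):
        out = block_downsample(np.array([[0.0, 100.0], [50.0, 50.0]]))
        assert out.shape == (1, 1) and out[0, 0] == 50.0

    def test_checkerboard_cancels(self):
        a = 13.0
        board = np.indices((8, 8)).sum(axis=0) % 2
        img = np.where(board, a, -a)
        assert np.all(block_downsample(img) == 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(10, 12))
        out = block_downsample(img)
        for r in range(5):
            for c in range(6):
                assert out[r, c] == pytest.approx(
                    img[2 * r:2 * r + 2, 2 * c:2 * c + 2].mean(), abs=1e-12)

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(16, 16))
        assert block_downsample(img).mean() == pytest.approx(img.mean(),
                                                             abs=1e-12)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            block_downsample(np.zeros((7, 8)))


def _brute_force_upsample(img):
    """Direct Keys-kernel evaluation with edge replication."""
    n_in = img.shape[0]
    out = np.zeros((2 * n_in, 2 * img.shape[1]))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            y = (i + 0.5) / 2.0 - 0.5
            x = (j + 0.5) / 2.0 - 0.5
            acc = 0.0
            for ty in range(int(np.floor(y)) - 1, int(np.floor(y)) + 3):
                for tx in range(int(np.floor(x)) - 1, int(np.floor(x)) + 3):
                    wy = _keys_kernel(np.array([y - ty]))[0]
                    wx = _keys_kernel(np.array([x - tx]))[0]
                    cy = min(max(ty, 0), n_in - 1)
                    cx = min(max(tx, 0), img.shape[1] - 1)
                    acc += wy * wx * img[cy, cx]
            out[i, j] = acc
    return out


class TestBicubicUpsample:
    def test_constant_preserved(self):
        out = bicubic_upsample(np.full((8, 8), 3.25))
        assert np.allclose(out, 3.25, atol=1e-12)

    def test_linear_ramp_preserved(self):
        x = np.arange(16, dtype=float)
        ramp = np.add.outer(2.0 * x, 3.0 * x)
        out = bicubic_upsample(ramp)
        xo = (np.arange(32) + 0.5) / 2.0 - 0.5
        expect = np.add.outer(2.0 * xo, 3.0 * xo)
        interior = (slice(4, -4), slice(4, -4))
        assert np.allclose(out[interior], expect[interior], atol=1e-6)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(9, 7))
        assert np.allclose(bicubic_upsample(img), _brute_force_upsample(img),
                           atol=1e-10)

    def test_downsample_inverts_nearest_upsample(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(12, 12))
        nn = np.repeat(np.repeat(img, 2, axis=0), 2, axis=1)
        assert np.allclose(block_downsample(nn), img, atol=1e-12)


class TestPseudoNoiseMap:
    def test_constant_image_zero(self):
        thin = small_image(np.full((16, 16), 40.0))
        m = pseudo_noise_map(thin)
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_small_in_flat_regions(self, cirs_s, grid):
        from cacdn import rasterize
        import dataclasses
        ideal = rasterize(cirs_s, grid)
        thin = dataclasses.replace(ideal, slice_thickness=1.5)
        m = pseudo_noise_map(thin)
        center = grid.matrix // 2
        flat = m.values[center - 10:center + 10, center - 10:center + 10]
        assert np.abs(flat).max() < 1.0  # noise-free flat region ~ zero

    def test_zero_mean_on_noise(self, cirs_pair):
        m = pseudo_noise_map(cirs_pair.thin)
        assert abs(float(m.values.mean())) < 0.5


class TestPatches:
    def test_patch_count_512(self, cirs_pair):
        pm = pseudo_noise_map(cirs_pair.thin)
        rm = real_noise_map(cirs_pair.thick, cirs_pair.thin)
        ps = extract_patches(pm, rm)
        assert len(ps) == 400

    def test_single_patch(self):
        thin = small_image(np.arange(64, dtype=float).reshape(8, 8))
        pm = pseudo_noise_map(thin)
        ps = extract_patches(pm, pm, patch=8, stride=8)
        assert len(ps) == 1

    def test_provenance_roundtrip(self, cirs_pair):
        pm = pseudo_noise_map(cirs_pair.thin)
        rm = real_noise_map(cirs_pair.thick, cirs_pair.thin)
        ps = shuffle_patches(extract_patches(pm, rm), seed=9)
        for i in (0, 17, len(ps) - 1):
            _, r, c = ps.provenance[i]
            assert np.array_equal(ps.inputs[i],
                                  pm.values[r:r + 25, c:c + 25])
            assert np.array_equal(ps.labels[i],
                                  rm.values[r:r + 25, c:c + 25])

    def test_reassembly_lossless(self, cirs_pair):
        pm = pseudo_noise_map(cirs_pair.thin)
        rm = real_noise_map(cirs_pair.thick, cirs_pair.thin)
        ps = extract_patches(pm, rm)
        recon = np.zeros((500, 500))
        for patch, (_, r, c) in zip(ps.inputs, ps.provenance):
            recon[r:r + 25, c:c + 25] = patch
        assert np.array_equal(recon, pm.values[:500, :500])

    @given(seed=st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shuffle_is_permutation(self, seed):
        rng = np.random.default_rng(0)
        inputs = rng.normal(size=(30, 5, 5))
        labels = rng.normal(size=(30, 5, 5))
        from cacdn.noisemaps import PatchSet
        ps = PatchSet(inputs=inputs, labels=labels, patch_size=5, stride=5,
                      provenance=[(0, i, 0) for i in range(30)])
        sh = shuffle_patches(ps, seed)
        again = shuffle_patches(ps, seed)
        assert np.array_equal(sh.inputs, again.inputs)
        order = np.argsort([p[1] for p in sh.provenance])
        assert np.array_equal(sh.inputs[order], inputs)
        assert np.array_equal(sh.labels[order], labels)
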