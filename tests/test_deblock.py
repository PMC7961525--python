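import numpy as np
import pytest

from wce3dct.bayer import blocks_from_image, build_block3d
from wce3dct.deblock import (
    GffParams,
    deblock_blocks,
    dither_amplitude,
    gff_modify,
    gff_weights,
    mean_boundary_msds,
    msds,
    smsds,
)
from wce3dct.errors import ConfigurationError, InputShapeError, PipelineError
from wce3dct.pipeline import psnr
from wce3dct.quantize import QTable, default_qtable, dequantize, flat_qtable, quantize
from wce3dct.synthetic import SceneParams, generate_wce
from wce3dct.transform import dct3d_fast_batch, idct3d_fast_batch


def _encode_pair(tile_a, tile_b, table):
    """Dequantized spectra of two vertically adjacent tiles."""
    blocks = np.stack([build_block3d(tile_a), build_block3d(tile_b)]).astype(float)
    F = dct3d_fast_batch(blocks - 128.0)
    return dequantize(quantize(F, table), table)


class TestMsds:
    def test_flat_blocks_have_zero_msds(self):
        A = np.full((4, 4, 4), 100.0)
        assert msds(A, A, axis=0) == 0.0

    def test_pure_step_boundary(self):
        """Constant 100 against constant 110: 16 face terms of (10 - 0)^2."""
        A = np.full((4, 4, 4), 100.0)
        B = np.full((4, 4, 4), 110.0)
        assert msds(A, B, axis=0) == pytest.approx(1600.0)
        assert msds(A, B, axis=1) == pytest.approx(1600.0)

    def test_linear_ramp_is_invisible(self):
        """A ramp continuing across the boundary has step == mean slope."""
        x = np.arange(4, dtype=float)
        A = np.broadcast_to(3.0 * x[:, None, None], (4, 4, 4)).copy()
        B = A + 12.0  # continuation: slope 3 per sample, offset 4*3
        assert msds(A, B, axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_axis_validation(self):
        A = np.zeros((4, 4, 4))
        with pytest.raises(InputShapeError):
            msds(A, A, axis=2)  # z is the colour axis, never a tile boundary


class TestDitherAmplitude:
    def test_zero_coefficient_limit(self):
        assert dither_amplitude(0.0, 32.0) == pytest.approx(-16.0)

    def test_frozen_regression_value(self):
        # high-precision evaluation of -(Q/2)(coth(x) - 1/x), x = (52/F^2) Q/2
        assert dither_amplitude(10.0, 32.0) == pytest.approx(
            -14.076924975769431, abs=1e-12
        )

    def test_strong_coefficients_barely_dithered(self):
        assert abs(dither_amplitude(1000.0, 8.0)) < 1e-3

    def test_bounded_by_half_step(self, rng):
        F = rng.uniform(-500, 500, 1000)
        Q = rng.choice([1.0, 8.0, 16.0, 32.0, 64.0], 1000)
        d = dither_amplitude(F, Q)
        assert (d <= 0).all() and (np.abs(d) <= Q / 2 + 1e-12).all()

    def test_non_positive_step_rejected(self):
        with pytest.raises(ConfigurationError):
            dither_amplitude(1.0, np.array([0.0]))


class TestSmsds:
    def test_zero_base_msds_returns_zero(self):
        F = np.zeros((4, 4, 4))
        F[0, 0, 0] = 64.0  # constant blocks, no boundary step
        assert smsds(F, F, default_qtable(), axis=0) == 0.0

    def test_artifact_boundary_is_highly_sensitive(self):
        """Smooth ramp + coarse quantization: the boundary is pure artifact."""
        yy = np.mgrid[0:16, 0:8][0].astype(float)
        ramp = 100.0 + 3.0 * yy
        FA, FB = _encode_pair(ramp[:8], ramp[8:], default_qtable())
        assert smsds(FA, FB, default_qtable(), axis=0) > 0.5

    def test_real_edge_is_insensitive(self):
        """A strong step edge under fine quantization barely reacts."""
        yy = np.mgrid[0:16, 0:8][0].astype(float)
        edge = np.where(yy < 8, 80.0, 180.0)
        fine = flat_qtable(1)
        FA, FB = _encode_pair(edge[:8], edge[8:], fine)
        assert smsds(FA, FB, fine, axis=0) < 0.5

    def test_discrimination_under_equal_quantization(self):
        """Core claim: artifacts are more dither-sensitive than real edges."""
        q = default_qtable()
        yy = np.mgrid[0:16, 0:8][0].astype(float)
        ramp = 100.0 + 3.0 * yy
        edge = np.where(yy < 8, 80.0, 180.0)
        s_artifact = smsds(*_encode_pair(ramp[:8], ramp[8:], q), q, axis=0)
        s_edge = smsds(*_encode_pair(edge[:8], edge[8:], q), q, axis=0)
        assert s_artifact > s_edge


class TestGffModify:
    def test_block_at_guided_mean_is_unchanged(self, rng):
        FA = rng.normal(0, 50, (4, 4, 4))
        FB = rng.normal(0, 50, (4, 4, 4))
        FC = 0.5 * (FA + FB)
        out = gff_modify(FC, FA, FB, s=0.8, q=default_qtable())
        assert np.allclose(out, FC)
        alpha, beta = gff_weights(FC, FA, FB, 0.8, default_qtable())
        assert np.allclose(alpha, 0.0) and np.allclose(beta, 0.5)

    def test_zero_sensitivity_preserves_detail(self, rng):
        FA, FB, FC = rng.normal(0, 50, (3, 4, 4, 4))
        out = gff_modify(FC, FA, FB, s=0.0, q=default_qtable())
        assert np.array_equal(out, FC)
        alpha, _ = gff_weights(FC, FA, FB, 0.0, default_qtable())
        assert (alpha == 1.0).all()

    def test_weight_identities(self, rng):
        for _ in range(10):
            FA, FB, FC = rng.normal(0, 30, (3, 4, 4, 4))
            s = float(rng.uniform(0, 3))
            alpha, beta = gff_weights(FC, FA, FB, s, default_qtable())
            assert np.allclose(alpha + 2 * beta, 1.0)
            assert (alpha >= 0).all() and (alpha <= 1).all()
            assert (beta >= 0).all() and (beta <= 0.5).all()

    def test_more_smoothing_never_raises_alpha(self, rng):
        FA, FB, FC = rng.normal(0, 30, (3, 4, 4, 4))
        a1, _ = gff_weights(FC, FA, FB, 0.2, default_qtable())
        a2, _ = gff_weights(FC, FA, FB, 2.0, default_qtable())
        assert (a2 <= a1 + 1e-12).all()

    def test_eta_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            GffParams(eta=0.0)


def _decode_grid(mosaic, table):
    blocks = blocks_from_image(mosaic).astype(np.float64) - 128.0
    F = dct3d_fast_batch(blocks)
    spectra = dequantize(quantize(F, table), table)
    decoded = idct3d_fast_batch(spectra)
    tr, tc = mosaic.height // 8, mosaic.width // 8
    return (
        blocks,
        decoded.reshape(tr, tc, 4, 4, 4),
        spectra.reshape(tr, tc, 4, 4, 4),
    )


class TestDeblockImage:
    def test_single_tile_unchanged(self, rng):
        blocks = rng.uniform(-100, 100, (1, 1, 4, 4, 4))
        spectra = dct3d_fast_batch(blocks.reshape(-1, 4, 4, 4)).reshape(blocks.shape)
        out = deblock_blocks(blocks, spectra, default_qtable())
        assert np.array_equal(out, blocks)

    def test_reduces_boundary_msds_on_coarse_quantization(self):
        _, mosaic = generate_wce(SceneParams(height=96, width=96, seed=5))
        coarse = QTable(default_qtable().steps * 2)
        _, grid, sgrid = _decode_grid(mosaic, coarse)
        out = deblock_blocks(grid, sgrid, coarse)
        assert mean_boundary_msds(out) < mean_boundary_msds(grid)

    def test_improves_fidelity_on_coarse_quantization(self):
        _, mosaic = generate_wce(SceneParams(height=96, width=96, seed=5))
        coarse = QTable(default_qtable().steps * 2)
        ref, grid, sgrid = _decode_grid(mosaic, coarse)
        out = deblock_blocks(grid, sgrid, coarse)
        assert psnr(ref, out.reshape(-1, 4, 4, 4)) > psnr(ref, grid.reshape(-1, 4, 4, 4))

    def test_near_lossless_input_barely_changes(self):
        """Identity-level streams see only mild filtering."""
        _, mosaic = generate_wce(SceneParams(height=96, width=96, seed=5))
        fine = flat_qtable(1)
        _, grid, sgrid = _decode_grid(mosaic, fine)
        out = deblock_blocks(grid, sgrid, fine)
        assert psnr(grid.reshape(-1, 4, 4, 4) + 128, out.reshape(-1, 4, 4, 4) + 128) > 40

    def test_changes_confined_to_boundary_halves(self):
        _, mosaic = generate_wce(SceneParams(height=64, width=64, seed=3))
        q = default_qtable()
        _, grid, sgrid = _decode_grid(mosaic, q)
        out = deblock_blocks(grid, sgrid, q)
        diff = np.abs(out - grid)
        # interior tiles: their x-interior rows away from any boundary stay put
        # only block rows/cols within 2 of a tile edge may change
        assert np.array_equal(out[0, 0, :2, :2], grid[0, 0, :2, :2])

    def test_mismatched_grids_rejected(self, rng):
        blocks = rng.uniform(-1, 1, (2, 2, 4, 4, 4))
        with pytest.raises(PipelineError):
            deblock_blocks(blocks, blocks[:1], default_qtable())
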