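"""End-to-end compression/decompression orchestration and quality metrics.

Encoder: mosaic -> 8x8 tiles -> 4x4x4 blocks -> level shift (-128) ->
fast 3D DCT -> quantize -> zigzag + DPCM + run-length/Huffman -> stream.
Decoder: the inverse chain, with optional SMSDS-guided deblocking between
inverse transform and block disassembly (the filter operates on the
3D-block grid before any demosaicing).

The headline quality metric is Bayer-domain PSNR (the codec's native
domain); RGB-domain PSNR against a bilinear demosaic of both images is
reported alongside.  Compression ratio is raw mosaic bits (8 per pixel)
over stream bits.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np

from . import entropy
from .bayer import BayerImage, blocks_from_image, demosaic, image_from_blocks
from .deblock import GffParams, deblock_blocks, mean_boundary_msds
from .entropy import ScanOrder, decode_image, default_scan_order, encode_image
from .errors import InputShapeError
from .quantize import QTable, default_qtable, dequantize, quantize
from .transform import dct3d_fast_batch, idct3d_fast_batch

__all__ = [
    "CodecConfig",
    "CodecReport",
    "compress",
    "decompress",
    "roundtrip",
    "psnr",
    "compression_ratio",
]

LEVEL_SHIFT = 128.0


@dataclass(frozen=True)
class CodecConfig:
    """Codec options; ``None`` table / scan order selects the shipped defaults."""

    qtable: QTable | None = None
    scan_order: ScanOrder | None = None
    level_shift: bool = True
    deblock: bool = True
    eta: float = 0.5

    def resolved_qtable(self) -> QTable:
        return self.qtable if self.qtable is not None else default_qtable()

    def resolved_scan_order(self) -> ScanOrder:
        return self.scan_order if self.scan_order is not None else default_scan_order()


@dataclass
class CodecReport:
    """Sizes, quality and per-stage timings of one codec run."""

    raw_bits: int = 0
    compressed_bits: int = 0
    cr: float = 0.0
    psnr_bayer: float | None = None
    psnr_rgb: float | None = None
    msds_before: float | None = None
    msds_after: float | None = None
    timings: dict = field(default_factory=dict)


def compress(image: BayerImage, cfg: CodecConfig | None = None) -> tuple:
    """Encode a mosaic; returns ``(stream_bytes, CodecReport)``."""
    cfg = cfg or CodecConfig()
    q = cfg.resolved_qtable()
    order = cfg.resolved_scan_order()
    report = CodecReport(raw_bits=image.height * image.width * 8)

    t0 = time.perf_counter()
    blocks = blocks_from_image(image).astype(np.float64)
    if cfg.level_shift:
        blocks -= LEVEL_SHIFT
    t1 = time.perf_counter()
    spectra = dct3d_fast_batch(blocks)
    t2 = time.perf_counter()
    levels = quantize(spectra, q)
    t3 = time.perf_counter()
    stream = encode_image(
        levels, q, order, image.width, image.height, level_shift=cfg.level_shift
    )
    t4 = time.perf_counter()

    report.compressed_bits = 8 * len(stream)
    report.cr = compression_ratio(report.raw_bits, stream)
    report.timings = {
        "blocking": t1 - t0,
        "transform": t2 - t1,
        "quantize": t3 - t2,
        "entropy": t4 - t3,
    }
    return stream, report


def decompress(
    stream: bytes,
    cfg: CodecConfig | None = None,
    report: CodecReport | None = None,
) -> BayerImage:
    """Decode a stream back to a mosaic (optionally deblocked)."""
    cfg = cfg or CodecConfig()
    t0 = time.perf_counter()
    parsed = decode_image(stream)
    q: QTable = parsed["qtable"]
    spectra = dequantize(parsed["levels"], q)
    blocks = idct3d_fast_batch(spectra)
    t1 = time.perf_counter()

    if cfg.deblock:
        tr = parsed["height"] // 8
        tc = parsed["width"] // 8
        grid = blocks.reshape(tr, tc, 4, 4, 4)
        sgrid = spectra.reshape(tr, tc, 4, 4, 4)
        if report is not None:
            report.msds_before = mean_boundary_msds(grid)
        grid = deblock_blocks(grid, sgrid, q, GffParams(eta=cfg.eta))
        if report is not None:
            report.msds_after = mean_boundary_msds(grid)
        blocks = grid.reshape(-1, 4, 4, 4)
    t2 = time.perf_counter()

    if parsed["level_shift"]:
        blocks = blocks + LEVEL_SHIFT
    pixels = np.clip(np.round(blocks), 0, 255).astype(np.uint8)
    mosaic = BayerImage(image_from_blocks(pixels, parsed["height"], parsed["width"]))
    if report is not None:
        report.timings.update({"decode": t1 - t0, "deblock": t2 - t1})
    return mosaic


def roundtrip(image: BayerImage, cfg: CodecConfig | None = None) -> tuple:
    """Compress, decompress and fill a complete quality report.

    Returns ``(decoded_mosaic, CodecReport)``.
    """
    stream, report = compress(image, cfg)
    decoded = decompress(stream, cfg, report=report)
    report.psnr_bayer = psnr(image.pixels, decoded.pixels)
    report.psnr_rgb = psnr(demosaic(image), demosaic(decoded))
    return decoded, report


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """10 log10(255^2 / MSE); ``math.inf`` for identical images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputShapeError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / mse)


def compression_ratio(raw_bits: int, stream: bytes) -> float:
    """raw bits over stream bits."""
    nbits = 8 * len(stream)
    if nbits == 0:
        raise InputShapeError("empty stream")
    return raw_bits / nbits
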