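"""Bayer-mosaic geometry: tiling, 3D block construction, mosaicing and demosaicing.

A capsule-endoscope sensor delivers a single-channel RGGB Bayer mosaic
(even rows R,G,R,G,...; odd rows G,B,G,B,..., 0-based).  The codec never
demosaics before compressing: each 8x8 mosaic tile is regrouped into a
4x4x4 block whose four z-planes are the R, G1, G2 and B samples of the
tile (G1 = green samples on R rows, G2 = green samples on B rows).  The
2:1:1 G:R:B sample proportion of the CFA makes the four planes the same
size, and their strong mutual correlation is what the z-axis DCT removes.

Block index convention: ``values[x, y, z]`` with x the within-plane row,
y the column and z in {0:R, 1:G1, 2:G2, 3:B}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import convolve

from .errors import InputShapeError

TILE = 8  #: mosaic tile edge; one tile -> one 4x4x4 block
CFA_PHASE = "RGGB"

__all__ = [
    "BayerImage",
    "split_tiles",
    "assemble_tiles",
    "build_block3d",
    "unbuild_block3d",
    "demosaic",
    "mosaic_from_rgb",
    "read_mosaic",
    "write_mosaic",
    "write_rgb",
]


@dataclass(frozen=True)
class BayerImage:
    """A single-channel 8-bit RGGB mosaic with dimensions divisible by 8."""

    pixels: np.ndarray
    phase: str = CFA_PHASE

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputShapeError(f"mosaic must be 2D, got shape {px.shape}")
        h, w = px.shape
        if h % TILE:
            raise InputShapeError(f"height {h} is not a multiple of {TILE}")
        if w % TILE:
            raise InputShapeError(f"width {w} is not a multiple of {TILE}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputShapeError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        if self.phase != CFA_PHASE:
            raise InputShapeError(f"only the {CFA_PHASE} phase is supported")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def split_tiles(image: BayerImage | np.ndarray) -> np.ndarray:
    """Split a mosaic into 8x8 tiles in raster order, shape ``(n, 8, 8)``."""
    px = image.pixels if isinstance(image, BayerImage) else np.asarray(image)
    h, w = px.shape
    if h % TILE:
        raise InputShapeError(f"height {h} is not a multiple of {TILE}")
    if w % TILE:
        raise InputShapeError(f"width {w} is not a multiple of {TILE}")
    tiles = px.reshape(h // TILE, TILE, w // TILE, TILE).swapaxes(1, 2)
    return tiles.reshape(-1, TILE, TILE)


def assemble_tiles(tiles: np.ndarray, height: int, width: int) -> np.ndarray:
    """Inverse of :func:`split_tiles`."""
    tiles = np.asarray(tiles)
    th, tw = height // TILE, width // TILE
    if tiles.shape != (th * tw, TILE, TILE):
        raise InputShapeError(
            f"expected {(th * tw, TILE, TILE)} tiles, got {tiles.shape}"
        )
    return tiles.reshape(th, tw, TILE, TILE).swapaxes(1, 2).reshape(height, width)


def build_block3d(tile: np.ndarray) -> np.ndarray:
    """Regroup one 8x8 RGGB tile into a 4x4x4 block stacked R-G1-G2-B."""
    tile = np.asarray(tile)
    if tile.shape != (TILE, TILE):
        raise InputShapeError(f"tile must be 8x8, got {tile.shape}")
    return np.stack(
        [
            tile[0::2, 0::2],  # R
            tile[0::2, 1::2],  # G1: green on R rows
            tile[1::2, 0::2],  # G2: green on B rows
            tile[1::2, 1::2],  # B
        ],
        axis=-1,
    )


def unbuild_block3d(block: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`build_block3d`."""
    block = np.asarray(block)
    if block.shape != (4, 4, 4):
        raise InputShapeError(f"block must be 4x4x4, got {block.shape}")
    tile = np.empty((TILE, TILE), dtype=block.dtype)
    tile[0::2, 0::2] = block[..., 0]
    tile[0::2, 1::2] = block[..., 1]
    tile[1::2, 0::2] = block[..., 2]
    tile[1::2, 1::2] = block[..., 3]
    return tile


def blocks_from_image(image: BayerImage | np.ndarray) -> np.ndarray:
    """All 4x4x4 blocks of a mosaic in raster order, shape ``(n, 4, 4, 4)``."""
    tiles = split_tiles(image)
    return np.stack(
        [tiles[:, 0::2, 0::2], tiles[:, 0::2, 1::2],
         tiles[:, 1::2, 0::2], tiles[:, 1::2, 1::2]],
        axis=-1,
    )


def image_from_blocks(blocks: np.ndarray, height: int, width: int) -> np.ndarray:
    """Inverse of :func:`blocks_from_image` (returns the raw pixel array)."""
    blocks = np.asarray(blocks)
    n = (height // TILE) * (width // TILE)
    if blocks.shape != (n, 4, 4, 4):
        raise InputShapeError(f"expected {(n, 4, 4, 4)} blocks, got {blocks.shape}")
    tiles = np.empty((n, TILE, TILE), dtype=blocks.dtype)
    tiles[:, 0::2, 0::2] = blocks[..., 0]
    tiles[:, 0::2, 1::2] = blocks[..., 1]
    tiles[:, 1::2, 0::2] = blocks[..., 2]
    tiles[:, 1::2, 1::2] = blocks[..., 3]
    return assemble_tiles(tiles, height, width)


# Bilinear interpolation kernels.  At a native site the centre weight is 1,
# so demosaicing never alters a pixel's own channel sample.
_K_G = np.array([[0, 1, 0], [1, 4, 1], [0, 1, 0]], dtype=np.float64) / 4.0
_K_RB = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float64) / 4.0


def _channel_masks(h: int, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r = (rows % 2 == 0) & (cols % 2 == 0)
    b = (rows % 2 == 1) & (cols % 2 == 1)
    g = ~(r | b)
    return r, g, b


def demosaic(image: BayerImage) -> np.ndarray:
    """Bilinear demosaic to an ``(H, W, 3)`` uint8 RGB image.

    The mosaic is padded by two pixels with CFA-parity-preserving
    reflection before convolution, so border pixels are interpolated from
    correct-channel neighbours.
    """
    px = image.pixels.astype(np.float64)
    h, w = px.shape
    padded = np.pad(px, 2, mode="reflect")
    rmask, gmask, bmask = _channel_masks(h + 4, w + 4)
    out = np.empty((h, w, 3), dtype=np.float64)
    for ch, (mask, kern) in enumerate(
        [(rmask, _K_RB), (gmask, _K_G), (bmask, _K_RB)]
    ):
        plane = np.where(mask, padded, 0.0)
        interp = convolve(plane, kern, mode="constant")
        out[..., ch] = interp[2:-2, 2:-2]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def mosaic_from_rgb(rgb: np.ndarray) -> BayerImage:
    """Sample an 8-bit RGB image onto an RGGB mosaic."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise InputShapeError(f"expected (H, W, 3) RGB array, got {rgb.shape}")
    h, w = rgb.shape[:2]
    rmask, gmask, bmask = _channel_masks(h, w)
    px = np.where(rmask, rgb[..., 0], np.where(gmask, rgb[..., 1], rgb[..., 2]))
    return BayerImage(px.astype(np.uint8))


def read_mosaic(path: str | Path) -> BayerImage:
    """Read an 8-bit grayscale PGM or PNG mosaic."""
    with Image.open(path) as im:
        return BayerImage(np.asarray(im.convert("L")))


def write_mosaic(image: BayerImage, path: str | Path) -> None:
    """Write the mosaic as PGM (``.pgm``) or PNG."""
    Image.fromarray(image.pixels, mode="L").save(path)


def write_rgb(rgb: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB image as PNG or PPM."""
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)
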