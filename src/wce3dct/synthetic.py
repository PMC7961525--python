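"""Synthetic wireless-capsule-endoscopy scenes for fixtures and training.

Real WCE frames are smooth, pink-to-yellow hued, and show very strong
inter-channel correlation (pairwise Pearson rho above 0.9) with mean
intensity ordering R > G > B.  The generator reproduces exactly these
statistics — not photorealism — by mixing a shared low-pass luminance
field into all three channels and adding parametric structures that
exercise the codec and the deblocker's real-edge discrimination:

* folds    — smooth ridges (Gaussian profiles along random lines);
* vessels  — dark curvilinear strokes, attenuating G and B more than R;
* villi    — band-pass micro-texture inside elliptical patches;
* bubbles  — bright ellipse rims with a mild specular interior.

All randomness flows through one seeded generator, so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .bayer import BayerImage, mosaic_from_rgb
from .errors import ConfigurationError, InputShapeError

__all__ = [
    "SceneParams",
    "generate_wce",
    "channel_correlation",
    "RHO_UNDEFINED",
    "default_scan_corpus_params",
]

#: sentinel returned for correlations with a constant (zero-variance) channel
RHO_UNDEFINED = -2.0


@dataclass(frozen=True)
class SceneParams:
    """Generator controls; defaults emulate the documented WCE statistics."""

    height: int = 480
    width: int = 480
    base_hue: tuple = (185.0, 125.0, 92.0)  # mean (R, G, B), R > G > B
    gains: tuple = (30.0, 24.0, 19.0)       # channel amplitude of the shared field
    smoothness: float = 20.0                # Gaussian blur scale, pixels
    correlation_strength: float = 0.93      # shared-luminance mixing weight
    folds: int = 4
    vessels: int = 5
    villi: int = 3
    bubbles: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height % 8 or self.width % 8:
            raise InputShapeError("scene dimensions must be multiples of 8")
        if not 0.0 <= self.correlation_strength <= 1.0:
            raise ConfigurationError("correlation_strength must be in [0, 1]")


def _smooth_field(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian field."""
    f = gaussian_filter(rng.standard_normal((h, w)), scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _line_distance(h: int, w: int, p0, p1) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    d = np.array(p1) - np.array(p0)
    norm = np.hypot(*d) + 1e-12
    return np.abs(d[1] * (yy - p0[0]) - d[0] * (xx - p0[1])) / norm


def _bezier_mask(rng: np.random.Generator, h: int, w: int, width_px: float) -> np.ndarray:
    """Soft mask of a random quadratic Bezier stroke."""
    pts = rng.uniform([0, 0], [h, w], size=(3, 2))
    t = np.linspace(0, 1, 200)[:, None]
    curve = ((1 - t) ** 2) * pts[0] + 2 * t * (1 - t) * pts[1] + t**2 * pts[2]
    mask = np.zeros((h, w))
    ys = np.clip(curve[:, 0].round().astype(int), 0, h - 1)
    xs = np.clip(curve[:, 1].round().astype(int), 0, w - 1)
    mask[ys, xs] = 1.0
    mask = gaussian_filter(mask, width_px)
    peak = mask.max()
    return mask / peak if peak > 0 else mask


def _ellipse(rng: np.random.Generator, h: int, w: int, rmin: float, rmax: float):
    cy, cx = rng.uniform([0.15 * h, 0.15 * w], [0.85 * h, 0.85 * w])
    ry, rx = rng.uniform(rmin, rmax, size=2)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return np.hypot((yy - cy) / ry, (xx - cx) / rx)


def generate_wce(params: SceneParams) -> tuple:
    """Render one scene; returns ``(rgb_uint8, BayerImage)``."""
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)
    wgt = params.correlation_strength

    lum = _smooth_field(rng, h, w, params.smoothness)
    indep = [_smooth_field(rng, h, w, params.smoothness) for _ in range(3)]

    # shared structure field keeps channels correlated; per-channel tints below
    structure = np.zeros((h, w))
    tint = [np.zeros((h, w)) for _ in range(3)]

    for _ in range(params.folds):
        p0 = rng.uniform([0, 0], [h, w])
        p1 = rng.uniform([0, 0], [h, w])
        sigma = rng.uniform(8.0, 16.0)
        amp = rng.uniform(8.0, 16.0) * rng.choice([-1.0, 1.0])
        structure += amp * np.exp(-0.5 * (_line_distance(h, w, p0, p1) / sigma) ** 2)

    for _ in range(params.vessels):
        stroke = _bezier_mask(rng, h, w, rng.uniform(2.0, 3.5))
        depth = rng.uniform(8.0, 18.0)
        # vessels read dark red: G and B drop more than R
        tint[0] -= 0.5 * depth * stroke
        tint[1] -= depth * stroke
        tint[2] -= depth * stroke

    for _ in range(params.villi):
        patch = np.clip(1.8 - _ellipse(rng, h, w, 0.12 * min(h, w), 0.3 * min(h, w)), 0, 1)
        noise = rng.standard_normal((h, w))
        texture = gaussian_filter(noise, 1.5) - gaussian_filter(noise, 4.0)
        sd = texture.std()
        if sd > 0:
            texture /= sd
        structure += 2.0 * patch * texture

    for _ in range(params.bubbles):
        dist = _ellipse(rng, h, w, 10.0, max(12.0, 0.12 * min(h, w)))
        rim = np.exp(-0.5 * ((dist - 1.0) / 0.15) ** 2)
        interior = np.clip(1.0 - dist, 0, 1)
        structure += rng.uniform(10.0, 20.0) * rim + 5.0 * interior

    rgb = np.empty((h, w, 3))
    for c in range(3):
        shared = wgt * lum + (1.0 - wgt) * indep[c]
        gain_ratio = params.gains[c] / params.gains[0]
        rgb[..., c] = (
            params.base_hue[c]
            + params.gains[c] * shared
            + gain_ratio * structure
            + tint[c]
            + params.noise_sd * rng.standard_normal((h, w))
        )
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb, mosaic_from_rgb(rgb)


def channel_correlation(rgb: np.ndarray) -> np.ndarray:
    """3x3 Pearson correlation matrix of the R, G, B channels.

    Pairs involving a constant channel get the sentinel
    :data:`RHO_UNDEFINED` instead of NaN.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise InputShapeError(f"expected (H, W, 3), got {rgb.shape}")
    flat = rgb.reshape(-1, 3).T
    sds = flat.std(axis=1)
    out = np.eye(3)
    for a in range(3):
        for b in range(a + 1, 3):
            if sds[a] == 0 or sds[b] == 0:
                rho = RHO_UNDEFINED
            else:
                rho = float(np.corrcoef(flat[a], flat[b])[0, 1])
            out[a, b] = out[b, a] = rho
    return out


def default_scan_corpus_params(n_images: int = 8, size: int = 128) -> list:
    """Parameter list defining the corpus behind the shipped scan order."""
    return [
        replace(SceneParams(), height=size, width=size, seed=i)
        for i in range(n_images)
    ]
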