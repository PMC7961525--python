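"""Decoder-side deblocking: MSDS, SMSDS and the guided frequency-domain filter.

Block transforms quantize each 4x4x4 block independently, leaving visible
steps at block boundaries.  The mean squared difference of slopes (MSDS)
measures such a step for two blocks A, B adjacent along an in-plane axis:
over the 4x4 boundary face it accumulates

    [ (B0 - A3) - ((A3 - A2) + (B1 - B0)) / 2 ]^2

i.e. the cross-boundary step minus the mean of the two one-sided slopes —
zero for any linear ramp through the boundary.  A large MSDS alone cannot
tell a quantization artifact from real tissue structure.  The
discriminator is *sensitivity*: each transmitted coefficient is perturbed
by a model-based dither — the negated centroid shift of a uniform
quantizer under a Laplacian coefficient prior with rate xi,

    xi = 52 / F^2,   delta = -[(Q/2) * coth(xi * Q / 2) - 1 / xi]

which lies in (-Q/2, 0], tends to -Q/2 as F -> 0 and vanishes for strong
coefficients.  SMSDS = |MSDS(F+delta) - MSDS(F)| / MSDS(F).  Artifact
boundaries are comparable in size to the quantization error the dither
emulates, so their MSDS moves a lot (SMSDS near 1 or above); genuine
edges carry large coefficients whose dither is negligible (SMSDS near 0).

Smoothing acts in the frequency domain on the straddling block C (far
half of A + near half of B): with m = (F_A + F_B)/2 and the ridge
regularizer eps = SMSDS * eta * Q per coefficient,

    alpha = (F_C - m)^2 / ((F_C - m)^2 + eps),  beta = (1 - alpha) / 2,
    F_C' = alpha * F_C + beta * (F_A + F_B),       alpha + 2 beta = 1

so coefficients already equal to the guided mean, or boundaries judged to
be real edges (SMSDS = 0), pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputShapeError, PipelineError
from .quantize import QTable
from .transform import dct3d_oracle, idct3d_oracle

__all__ = [
    "GffParams",
    "msds",
    "dither_amplitude",
    "smsds",
    "gff_modify",
    "deblock_blocks",
    "mean_boundary_msds",
]

XI_CONST = 52.0


@dataclass(frozen=True)
class GffParams:
    """Guided-filter controls: eta scales the ridge penalty with the Q step."""

    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ConfigurationError("eta must be positive")


def _check_block(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.float64)
    if a.shape != (4, 4, 4):
        raise InputShapeError(f"{name} must be 4x4x4, got {a.shape}")
    return a


def msds(A: np.ndarray, B: np.ndarray, axis: int = 0) -> float:
    """Boundary discontinuity of blocks adjacent along ``axis`` (0=x, 1=y).

    A precedes B along the axis; the sum runs over the 4x4 boundary face
    including the colour dimension.
    """
    A = _check_block(A, "A")
    B = _check_block(B, "B")
    if axis not in (0, 1):
        raise InputShapeError("blocks tile only along the in-plane axes 0 and 1")
    Am = np.moveaxis(A, axis, 0)
    Bm = np.moveaxis(B, axis, 0)
    step = Bm[0] - Am[3]
    slope = 0.5 * ((Am[3] - Am[2]) + (Bm[1] - Bm[0]))
    return float(np.sum((step - slope) ** 2))


def dither_amplitude(F, Q, params: GffParams | None = None):
    """Model-based spectral dither delta(F, Q); elementwise on arrays.

    The magnitude (Q/2)*coth(xi*Q/2) - 1/xi = (Q/2)*(coth(x) - 1/x) with
    x = xi*Q/2 is the centroid shift of a mid-tread uniform quantizer
    under a Laplacian prior with rate xi; it lies in [0, Q/2) and the
    dither is its negation, pulling every coefficient toward zero.
    Limits: delta -> -Q/2 as F -> 0 (xi -> inf) and delta -> -xi*Q^2/12
    -> 0 for strong coefficients, so real edges are barely perturbed.
    """
    F = np.asarray(F, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if (Q <= 0).any():
        raise ConfigurationError("quantization steps must be positive")
    with np.errstate(divide="ignore"):
        xi = XI_CONST / np.square(F)  # F == 0 -> xi = inf
    x = xi * Q / 2.0
    # tanh saturates to 1 for large x, so the F -> 0 (xi -> inf) limit
    # evaluates to -Q/2 without special casing; for tiny x use the series
    # coth(x) - 1/x = x/3 - x^3/45 + ... to avoid inf - inf.
    with np.errstate(over="ignore", divide="ignore"):
        coth_minus_inv = np.where(
            x < 1e-4, x / 3.0, 1.0 / np.tanh(np.maximum(x, 1e-12)) - 1.0 / x
        )
    out = -(Q / 2.0) * coth_minus_inv
    return out if out.ndim else float(out)


def smsds(
    FA: np.ndarray,
    FB: np.ndarray,
    q: QTable,
    axis: int = 0,
    params: GffParams | None = None,
) -> float:
    """Sensitivity of MSDS to the spectral dither, for one boundary pair.

    ``FA``/``FB`` are the dequantized (transmitted) spectra of the two
    adjacent blocks.  Returns 0 when the undithered MSDS is 0.
    """
    FA = _check_block(FA, "FA")
    FB = _check_block(FB, "FB")
    steps = q.steps.astype(np.float64)
    A = idct3d_oracle(FA)
    B = idct3d_oracle(FB)
    base = msds(A, B, axis)
    if base == 0.0:
        return 0.0
    Ad = idct3d_oracle(FA + dither_amplitude(FA, steps))
    Bd = idct3d_oracle(FB + dither_amplitude(FB, steps))
    dithered = msds(Ad, Bd, axis)
    return abs(dithered - base) / base


def gff_modify(
    FC: np.ndarray,
    FA: np.ndarray,
    FB: np.ndarray,
    s: float,
    q: QTable,
    params: GffParams | None = None,
) -> np.ndarray:
    """Ridge-regression blend of F_C toward the neighbour mean (F_A+F_B)/2."""
    params = params or GffParams()
    FC = _check_block(FC, "FC")
    FA = _check_block(FA, "FA")
    FB = _check_block(FB, "FB")
    eps = s * params.eta * q.steps.astype(np.float64)
    m = 0.5 * (FA + FB)
    dev2 = np.square(FC - m)
    denom = dev2 + eps
    # denom == 0 only when FC == m and eps == 0; any alpha then leaves FC
    # unchanged, so take alpha = 1.
    alpha = np.where(denom > 0, np.divide(dev2, np.where(denom > 0, denom, 1.0)), 1.0)
    beta = 0.5 * (1.0 - alpha)
    return alpha * FC + beta * (FA + FB)


def gff_weights(FC, FA, FB, s: float, q: QTable, params: GffParams | None = None):
    """(alpha, beta) arrays for one boundary; alpha + 2*beta == 1 exactly."""
    params = params or GffParams()
    eps = s * params.eta * q.steps.astype(np.float64)
    m = 0.5 * (np.asarray(FA, dtype=float) + np.asarray(FB, dtype=float))
    dev2 = np.square(np.asarray(FC, dtype=float) - m)
    denom = dev2 + eps
    alpha = np.where(denom > 0, np.divide(dev2, np.where(denom > 0, denom, 1.0)), 1.0)
    return alpha, 0.5 * (1.0 - alpha)


def _pair_iter(tr: int, tc: int, axis: int):
    if axis == 0:
        for r in range(tr - 1):
            for c in range(tc):
                yield (r, c), (r + 1, c)
    else:
        for r in range(tr):
            for c in range(tc - 1):
                yield (r, c), (r, c + 1)


def deblock_blocks(
    blocks: np.ndarray,
    spectra: np.ndarray,
    q: QTable,
    params: GffParams | None = None,
) -> np.ndarray:
    """Filter a decoded tile grid in place order: all x boundaries, then y.

    ``blocks``: (tile_rows, tile_cols, 4, 4, 4) decoded spatial blocks
    (level-shifted domain).  ``spectra``: same grid of dequantized
    transmitted spectra — these stay fixed while pixels are updated
    sequentially.  Returns the filtered copy of ``blocks``.
    """
    params = params or GffParams()
    blocks = np.asarray(blocks, dtype=np.float64)
    spectra = np.asarray(spectra, dtype=np.float64)
    if blocks.ndim != 5 or blocks.shape[2:] != (4, 4, 4):
        raise InputShapeError(f"expected (tr, tc, 4, 4, 4) blocks, got {blocks.shape}")
    if spectra.shape != blocks.shape:
        raise PipelineError("spectra grid does not match the decoded block grid")
    tr, tc = blocks.shape[:2]
    out = blocks.copy()
    steps = q.steps.astype(np.float64)

    # per-tile reconstructions from the transmitted spectra (fixed) and
    # their dithered twins; both feed every SMSDS evaluation
    flat = spectra.reshape(-1, 4, 4, 4)
    recon = np.stack([idct3d_oracle(f) for f in flat]).reshape(blocks.shape)
    dithered = np.stack(
        [idct3d_oracle(f + dither_amplitude(f, steps)) for f in flat]
    ).reshape(blocks.shape)

    for axis in (0, 1):
        for (ar, ac), (br, bc) in _pair_iter(tr, tc, axis):
            base = msds(recon[ar, ac], recon[br, bc], axis)
            if base == 0.0:
                s = 0.0
            else:
                d = msds(dithered[ar, ac], dithered[br, bc], axis)
                s = abs(d - base) / base
            A = np.moveaxis(out[ar, ac], axis, 0)
            B = np.moveaxis(out[br, bc], axis, 0)
            C = np.concatenate([A[2:4], B[0:2]], axis=0)
            C = np.moveaxis(C, 0, axis)
            FC = dct3d_oracle(C)
            FCp = gff_modify(
                FC, spectra[ar, ac], spectra[br, bc], s, q, params
            )
            Cp = np.moveaxis(idct3d_oracle(FCp), axis, 0)
            A[2:4] = Cp[0:2]
            B[0:2] = Cp[2:4]
    return out


def mean_boundary_msds(blocks: np.ndarray) -> float:
    """Mean MSDS over all x and y tile boundaries of a block grid."""
    blocks = np.asarray(blocks, dtype=np.float64)
    tr, tc = blocks.shape[:2]
    vals = []
    for axis in (0, 1):
        for a, b in _pair_iter(tr, tc, axis):
            vals.append(msds(blocks[a], blocks[b], axis))
    return float(np.mean(vals)) if vals else 0.0
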