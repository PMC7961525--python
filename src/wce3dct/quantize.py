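"""Uniform quantization of 4x4x4 spectra with power-of-two step tables.

The shipped default table was selected offline by the rate-distortion
search (see :mod:`wce3dct.qtable_search`) to maximise compression ratio
subject to an average-PSNR floor; all of its 64 steps are powers of two
in {8, 16, 32, 64} and every z-slice starts with a DC step of 8.  The
table is frozen here as the versioned fixture; its four slices are
indexed by the colour-plane frequency k.

Rounding is half-away-from-zero (JPEG-like), which keeps the
quantization error symmetric: |F - dequantize(quantize(F))| <= step/2
per coefficient, always.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputShapeError

__all__ = ["QTable", "default_qtable", "flat_qtable", "quantize", "dequantize"]

# Default steps, one 4x4 slice per colour-frequency index k (row-major i, j).
_DEFAULT_SLICES = (
    ((8, 16, 16, 32), (8, 32, 32, 32), (32, 32, 32, 64), (16, 16, 32, 64)),
    ((8, 32, 32, 32), (32, 32, 32, 32), (32, 64, 32, 32), (64, 64, 32, 64)),
    ((8, 32, 32, 32), (32, 64, 32, 32), (32, 64, 32, 32), (64, 64, 64, 32)),
    ((8, 32, 32, 32), (32, 32, 32, 32), (64, 32, 32, 64), (32, 32, 64, 32)),
)


@dataclass(frozen=True)
class QTable:
    """A 4x4x4 table of positive integer quantization steps, indexed (i, j, k)."""

    steps: np.ndarray

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps)
        if steps.shape != (4, 4, 4):
            raise InputShapeError(f"steps must be 4x4x4, got {steps.shape}")
        if not np.issubdtype(steps.dtype, np.integer):
            rounded = np.rint(steps)
            if not np.array_equal(rounded, steps):
                raise ConfigurationError("steps must be integers")
            steps = rounded.astype(np.int64)
        if (steps <= 0).any():
            raise ConfigurationError("all quantization steps must be positive")
        object.__setattr__(self, "steps", steps.astype(np.int64))

    def to_bytes(self) -> bytes:
        """64 unsigned bytes in (i, j, k) row-major order."""
        if (self.steps > 255).any():
            raise ConfigurationError("steps > 255 cannot be serialized to bytes")
        return bytes(int(v) for v in self.steps.reshape(-1))

    @classmethod
    def from_bytes(cls, raw: bytes) -> "QTable":
        if len(raw) != 64:
            raise InputShapeError(f"expected 64 table bytes, got {len(raw)}")
        return cls(np.frombuffer(raw, dtype=np.uint8).reshape(4, 4, 4).astype(np.int64))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"steps": self.steps.tolist()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "QTable":
        return cls(np.array(json.loads(Path(path).read_text())["steps"]))


def default_qtable() -> QTable:
    """The shipped rate-distortion-optimised table (entries in {8, 16, 32, 64})."""
    steps = np.empty((4, 4, 4), dtype=np.int64)
    for k, rows in enumerate(_DEFAULT_SLICES):
        steps[:, :, k] = rows
    return QTable(steps)


def flat_qtable(step: int = 1) -> QTable:
    """A uniform table, useful for near-lossless encoding and as a test limit."""
    return QTable(np.full((4, 4, 4), step, dtype=np.int64))


def _broadcast_steps(values: np.ndarray, q: QTable) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-3:] != (4, 4, 4):
        raise InputShapeError(f"expected trailing 4x4x4 shape, got {values.shape}")
    return values


def quantize(spectrum: np.ndarray, q: QTable) -> np.ndarray:
    """Integer levels ``round(F / step)`` with round-half-away-from-zero.

    Accepts a single 4x4x4 spectrum or a batch ``(n, 4, 4, 4)``.
    """
    F = _broadcast_steps(spectrum, q)
    ratio = F / q.steps
    return (np.sign(ratio) * np.floor(np.abs(ratio) + 0.5)).astype(np.int64)


def dequantize(levels: np.ndarray, q: QTable) -> np.ndarray:
    """Reconstructed spectrum ``levels * step``."""
    lv = _broadcast_steps(levels, q)
    return lv * q.steps.astype(np.float64)
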