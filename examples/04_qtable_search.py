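"""Run a reduced GA+PSO rate-distortion search for a quantization table.

Optimises MSE + lambda * bits-per-pixel over a small training corpus with
a population of 16 for 30 generations.  The printed trace is the
best-so-far objective per generation — elitism makes it non-increasing.
A full offline run would use a larger corpus and ~500 generations.
"""

import numpy as np

from wce3dct import RdConfig, SceneParams, generate_wce, optimize_qtable
from wce3dct.bayer import blocks_from_image

_, mosaic = generate_wce(SceneParams(height=96, width=96, seed=8))
blocks = blocks_from_image(mosaic).astype(float) - 128.0

cfg = RdConfig(lam=20.0, population_size=16, max_generations=30, seed=4)
table, trace = optimize_qtable(blocks, cfg)

print(f"objective: initial {trace[0]:.3f} -> final {trace[-1]:.3f}")
print("best-so-far trace:", " ".join(f"{v:.2f}" for v in trace[::5]))
print("optimised steps, colour-frequency slice k=0:")
print(table.steps[:, :, 0])
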