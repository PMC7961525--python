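"""Count the arithmetic of the multiplication-free fast 3D DCT.

The 4-point butterfly uses one multiply-by-sqrt(2), realised as four
shifts and four additions, for 13 additions + 4 shifts per call.  A full
4x4x4 block needs 48 butterflies, i.e. 9.75 additions and 3 shifts per
pixel — the encoder's whole transform budget inside the capsule.
The fast path is also compared against the exact reference transform.
"""

import numpy as np

from wce3dct import OpCounter, dct3d_fast, dct3d_oracle, dct4_fast

rng = np.random.default_rng(0)

counter = OpCounter()
dct4_fast(rng.uniform(-128, 127, 4), counter)
print(f"4-point butterfly : {counter.additions} additions, {counter.shifts} shifts")

counter = OpCounter()
block = rng.uniform(-128, 127, (4, 4, 4))
fast = dct3d_fast(block, counter)
print(f"4x4x4 transform   : {counter.additions / 64} additions/pixel, "
      f"{counter.shifts / 64:.0f} shifts/pixel")

err = np.abs(fast - dct3d_oracle(block)).max()
print(f"max |fast - exact| on this block: {err:.2e}  (sqrt2 approximation)")
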