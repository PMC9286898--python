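"""Encode one compound-disease pair as a grayscale image.

Builds a small synthetic world, min-max normalizes the descriptor tables,
fuses the first compound's descriptor vector with the first disease's
symptom vector into the additive matrix M[r, c] = (b_r + a_c) / 2, and
quantizes it to 8-bit pixels.
"""

import numpy as np

from cdrscreen import SimConfig, build_matrix, simulate, to_grayscale, write_png
from cdrscreen.pipeline import normalize_world

world = simulate(SimConfig(n_compounds=20, n_diseases=8, seed=0))
compounds, diseases = normalize_world(world)

cid, did = compounds.ids[0], diseases.ids[0]
matrix = build_matrix(compounds.vector(cid), diseases.vector(did), cid, did)
image = to_grayscale(matrix)
write_png(image, f"{cid}__{did}.png")

print(f"pair:          {cid} x {did}")
print(f"matrix shape:  {matrix.shape} (compound features x disease features)")
print(f"value range:   [{matrix.values.min():.3f}, {matrix.values.max():.3f}]")
print(f"pixel range:   [{image.pixels.min()}, {image.pixels.max()}] of 0..255")
print(f"quantization:  max |pixel/255 - value| = "
      f"{np.abs(image.pixels / 255 - matrix.values).max():.5f} (bound 1/510)")
print(f"wrote {cid}__{did}.png")
# Each row of the image is one molecular descriptor, each column one symptom
# descriptor; bright cells mean both features are large for this pair.
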