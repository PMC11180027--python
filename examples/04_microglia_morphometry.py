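"""Box-counting fractal analysis of generated microglial silhouettes.

Ramified (surveillant) microglia have complex arborisations and a higher
box-counting dimension than amoeboid (reactive) cells. The generator's
branch depth controls geometric complexity; the analysis recovers the
ordering, together with circularity, hull density and lacunarity.
"""

import numpy as np

from neuroforage import MorphParams, generate_microglia_mask
from neuroforage.morphometry import analyse_cell, segment_cells, summarise_roi

rng = np.random.default_rng(5)

print(f"{'cell kind':>22} {'D':>6} {'circ':>6} {'density':>8} {'lacunarity':>10}")
for label, params in [
        ("amoeboid", MorphParams(cell_kind="amoeboid", branch_depth=0,
                                 soma_radius=18)),
        ("ramified, depth 2", MorphParams(branch_depth=2)),
        ("ramified, depth 5", MorphParams(branch_depth=5))]:
    mask, _ = generate_microglia_mask(params, rng)
    cell = segment_cells(mask)[0]
    m = analyse_cell(cell)
    print(f"{label:>22} {m.fractal_dimension:6.3f} {m.circularity:6.3f} "
          f"{m.density:8.3f} {m.lacunarity:10.3f}")

# a region-of-interest summary needs at least 20 cells to be valid
morphs = []
for _ in range(25):
    mask, _ = generate_microglia_mask(MorphParams(branch_depth=3), rng)
    morphs.append(analyse_cell(segment_cells(mask)[0]))
s = summarise_roi(morphs)
print(f"\nROI summary over {s.n_cells} cells (valid={s.valid}): "
      f"mean D = {s.means['fractal_dimension']:.3f}, "
      f"mean area = {s.means['area']:.0f} px^2")
print("Deramification (lower D, higher circularity) is the morphological "
      "signature of pro-inflammatory microglial activation.")
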