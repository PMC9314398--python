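"""Pseudocell construction for cross-species comparison inputs.

Normalizes each cell to 100,000 total counts and averages shuffled groups of
up to 50 same-cell-type cells; pseudocell profiles stay on the 100k simplex.
"""

import numpy as np

from xenatlas import AtlasConfig, filter_cells, generate_atlas, make_pseudocells, total_normalize

cfg = AtlasConfig(lineages={"epidermis": 170, "immune": 120, "neuron": 55}, seed=2)
cm, _ = generate_atlas(cfg)
cells = filter_cells(cm)

em = total_normalize(cells, target=100_000)
pc = make_pseudocells(em, cells.meta, group_size=50, min_group=10, seed=0)

print(f"{cells.n_barcodes} cells -> {len(pc.values)} pseudocells")
for pc_id, members in sorted(pc.members.items()):
    print(f"  {pc_id}: {len(members)} cells")
sums = pc.values.sum(axis=1)
print(f"row sums stay at 100,000 (max deviation {np.abs(sums - 1e5).max():.2e})")
# groups of ~50 cells of one type; remainders under 10 cells are dropped,
# so lineage sizes not divisible by 50 lose at most a handful of cells
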