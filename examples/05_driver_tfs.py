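"""Driver TFs of a cell type's transition between two stages.

Each TF gets a within-stage cell-type-specificity vector Y; the driver score
h = T(S(Y1)) * T(S(Y2)) rewards TFs specific to the matched cell type at both
stages.  A single planted epidermis-specific TF should top the list.
"""

from xenatlas import AtlasConfig, find_driver_tfs, generate_atlas, lognormalize

cfg = AtlasConfig(
    lineages={k: 400 for k in ("epidermis", "immune", "neuron", "muscle", "endothelium")},
    n_tfs=50,
    planted_tfs_per_lineage=1,
    ambient_fraction=0.0,
    n_empty_barcodes=0,
    seed=4,
)
cm, truth = generate_atlas(cfg)
em = lognormalize(cm)
meta = cm.meta
em1 = em.subset_barcodes((meta["stage"] == "NF54").to_numpy())
em2 = em.subset_barcodes((meta["stage"] == "NF59").to_numpy())

tfs = [g for g in cm.genes if g.startswith("tf")]
res = find_driver_tfs(em1, em2, meta, meta, tfs, cell_type="epidermis",
                      stage_pair=("NF54", "NF59"), k=5)

planted = next(iter(truth.planted_tf_sets["epidermis"]))
print(f"planted epidermis regulator: {planted}")
print("top 5 driver TFs (NF54 -> NF59, epidermis):")
for tf, row in res.top.iterrows():
    marker = "  <- planted" if tf == planted else ""
    print(f"  {tf}  h={row.h:.3f}{marker}")
# h multiplies the positively truncated z-scores of the two stages'
# specificity values, so only TFs above-average specific at BOTH stages
# can score; everything else is exactly 0
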