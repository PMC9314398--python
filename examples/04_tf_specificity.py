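"""Lineage-specific transcription factors via JSD specificity scores.

Scores every TF's mean-expression profile against each lineage's indicator
distribution (1 - sqrt of the base-2 Jensen-Shannon divergence), z-scores
across lineages, and calls the top-20 TFs per lineage; planted single-lineage
TFs should dominate the calls.
"""

from xenatlas import (
    AtlasConfig,
    call_specific_tfs,
    correct_background,
    estimate_background_profile,
    filter_cells,
    generate_atlas,
    group_mean_profile,
    lognormalize,
    specificity_scores,
    zscore_scores,
)

cfg = AtlasConfig(
    lineages={k: 500 for k in ("epidermis", "immune", "neuron", "muscle", "endothelium")},
    seed=1,
)
cm, truth = generate_atlas(cfg)
profile = estimate_background_profile(cm)
cells = filter_cells(cm)
corrected = correct_background(cells, profile)

em = lognormalize(corrected)
mean_profile = group_mean_profile(em, corrected.meta, "lineage")
tfs = [g for g in corrected.genes if g.startswith("tf")]
raw = specificity_scores(mean_profile, tfs)
calls = call_specific_tfs(zscore_scores(raw), raw=raw, k=20)

for lineage, planted in truth.planted_tf_sets.items():
    called = set(calls[lineage])
    recall = len(planted & called) / len(planted)
    top_score = raw.scores.loc[calls[lineage][0], lineage]
    print(f"{lineage:12s} recall of 20 planted TFs in top-20: {recall:.0%}  "
          f"(best raw score {top_score:.3f})")
# a raw score of 1 would mean perfectly exclusive expression; planted TFs
# (8-fold up in their lineage, 8-fold down elsewhere) land around 0.8
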