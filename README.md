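# xenatlas

Post-quantification analysis toolkit for droplet single-cell atlases of
amphibian metamorphosis — the thyroid-hormone-driven remodeling of a larva
(Nieuwkoop–Faber stages NF48 → NF54 → NF59 → NF66, with NF59 the metamorphic
climax) into an adult.  It implements, as a tested and reusable library, the
bespoke computations that sit between UMI quantification and biological
interpretation in such an atlas:

* **Ambient-RNA (batch gene background) correction.** Barcodes with fewer
  than 500 UMIs are treated as empty beads exposed only to cell-free RNA;
  their mean gene detection `bg` defines the soup.  For each cell *c* the
  soup is rescaled by the median fold difference
  `scale(c) = median_{g: bg(g)>0} count(c,g) / bg(g)`, rounded to the nearest
  integer, and subtracted: `corrected(c,g) = max(0, count(c,g) − round(bg(g)·scale(c)))`.
* **JSD TF specificity.** A transcription factor's cross-group expression
  distribution p_g is compared with each group's indicator e_l by the base-2
  Jensen–Shannon divergence; the specificity score is
  `score(g,l) = 1 − √JSD(p_g, e_l) ∈ [0,1]`, 1 iff the TF is exclusive to the
  group.  Z-scoring across groups ranks group-specific TFs, and ortholog maps
  intersect calls across species into conserved TFs.
* **Cross-stage driver TFs.** For a cell type matched between two stages,
  `h_g = T(S(Y₁,g)) · T(S(Y₂,g))` where Y is the within-stage specificity
  vector, S standardizes to zero mean / unit variance and T truncates
  negatives to zero; the top-5 TFs by h are candidate drivers of the
  transition.
* **Trajectory modules.** Stage-averaged, standardized gene profiles are
  softly clustered with fuzzy c-means (m = 1.25); each cell is scored for a
  cluster's genes against expression-bin-matched controls; repeated
  subsampled (150–1000 cells) Wilcoxon rank-sum tests against the first
  stage give averaged p-values; after Benjamini–Hochberg correction,
  clusters with any q < 1e-10 are classified by one-sided tests into
  module 1 (climax peak), 2 (climax trough), 3 (monotone down) or
  4 (monotone up).
* **Enrichment.** One-sided hypergeometric over-representation
  `p = P(X ≥ k)` with BH correction, on plain term → gene tables.
* **Synthetic atlas generator.** Negative-binomial per-lineage programs
  across stages, a shared ambient soup plus empty barcodes, planted
  single-lineage TFs and planted module-archetype genes — with full ground
  truth, so every stage above is verifiable by parameter recovery without
  any data download.

The normalizations used throughout are `log2(CPM/100 + 1)` (i.e. log2
counts-per-10k + 1) and total-count scaling to 100,000, plus pseudocell
averaging of ~50 same-cell-type cells for cross-species comparison inputs.

## Worked example

`examples/` holds one short script per capability.  For instance,
`python examples/04_tf_specificity.py` builds a five-lineage atlas with 20
planted TFs per lineage (8-fold up in their lineage, 8-fold down elsewhere),
corrects the background, and calls lineage-specific TFs:

```
epidermis    recall of 20 planted TFs in top-20: 100%  (best raw score 0.813)
immune       recall of 20 planted TFs in top-20: 100%  (best raw score 0.807)
neuron       recall of 20 planted TFs in top-20: 100%  (best raw score 0.837)
muscle       recall of 20 planted TFs in top-20: 100%  (best raw score 0.826)
endothelium  recall of 20 planted TFs in top-20: 100%  (best raw score 0.843)
```

Every planted TF is recovered in its lineage's top-20 call list; raw scores
near 0.8 reflect strong-but-not-perfect exclusivity (a score of 1 requires
expression in exactly one lineage).  Similarly,
`python examples/02_background_correction.py` reports

```
per-gene absolute error vs endogenous truth, median ratio after/before: 0.233
genes with error at least halved: 100.0%
```

i.e. after background subtraction the per-gene deviation from the known
endogenous counts drops to roughly a quarter of the uncorrected deviation,
and `python examples/06_trajectory_modules.py` classifies every planted
archetype cluster into its true module with q-values below 1e-80.

## Layout

```
src/xenatlas/
  io.py          # CountMatrix / ExpressionMatrix / OrthologMap, mtx+tsv I/O
  simulate.py    # synthetic atlas generator with ground truth
  background.py  # cell filtering, soup estimation, background correction
  normalize.py   # log2cp10k, cp100k, pseudocells
  specificity.py # JSD, specificity scores, z-scoring, calls, conserved TFs
  driver.py      # cross-stage driver-TF scoring
  modules.py     # DEGs, fuzzy c-means, module scores, resampled tests
  enrich.py      # hypergeometric enrichment + BH
  pipeline.py    # seeded end-to-end composition
```

Methodological details, parameter defaults and known limitations are in
`docs/methods.md`.
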