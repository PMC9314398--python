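# Methods

This note documents the models behind each analysis stage, the defaults that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the procedure was genuinely open.

## Background (ambient RNA) correction

**Model.** In bead-based droplet protocols, cell-free RNA released during
dissociation and washing is captured alongside every cell's own mRNA.
Barcodes with fewer than 500 total UMIs are assumed to be empty beads whose
counts are pure soup; for each experimental batch, the background value of
gene *g* is the arithmetic mean `bg(g)` of its counts over those barcodes.
A cell's contamination level is estimated as the median, over genes with
`bg(g) > 0`, of the fold difference `count(c,g)/bg(g)` — genes the cell does
not detect contribute a ratio of 0, which is deliberate: excluding them
would overestimate contamination, since for a typical gene the cell's
detected signal *is* mostly soup while its own program is concentrated on a
minority of genes.  The per-gene background `bg(g)·scale(c)` is rounded to
the nearest integer (half away from zero; the choice at .5 is arbitrary but
fixed and tested) and subtracted with clipping at zero, so corrected counts
stay integers in `[0, count]`.  Genes with `bg(g) = 0` are untouched.

**Order of operations.** The profile is estimated from the *unfiltered*
matrix (it needs the empty beads); correction is applied to the 500-UMI
filtered cells.  Correction never crosses batch boundaries.  An optional
`min_prevalence` knob restricts subtraction to genes detected in at least a
given fraction of empty beads — the "extensively expressed in all beads"
reading of batch genes — and is off by default.

**When it works.** The median-fold estimator is consistent when, for a
typical cell, more than half of the soup-supported genes carry little of
that cell's endogenous program.  If the soup profile were proportional to a
broadly shared expression program, the median fold would absorb endogenous
signal and overcorrect; this is a property of the method, not of the
implementation, and the generator's soup model (below) reflects the regime
the method assumes.

## TF specificity

For gene *g* with cross-group mean-expression distribution p_g (means taken
on the linear normalized scale, groups being lineages or cell types), the
specificity score against group *l* is `1 − √JSD(p_g, e_l)` with e_l the
group's indicator distribution and JSD the base-2 Jensen–Shannon
divergence.  Two choices deserve emphasis:

* **Reference distribution.** The score form only lands in [0, 1] when the
  comparison is against a one-hot indicator and logs are base 2 — with
  natural logs √JSD can exceed 1 and the score would go negative.  The
  indicator reference makes the score 1 exactly when the gene is exclusive
  to the group.
* **Z-scoring direction.** Scores are standardized *within a TF across
  groups* (sample sd, n−1; rows constant up to float residue become zeros).
  Ranking a group's TFs by that z asks "which groups does this TF prefer",
  which is what calling lineage-specific TFs requires.  The alternative
  (within-group across TFs) would rank TFs by absolute score and is not
  used.

Calls are the top-k (default 20) TFs per group, ties broken by raw score
then gene identifier so the ranking is fully deterministic.  Cross-species
conservation takes an anchor species' calls and keeps a TF iff every other
species has at least one ortholog (one-to-one or one-to-many) among its own
calls for the same group.

## Driver TFs across stages

For a cell type matched between two stages (matching is by identical
annotation label, with an optional user-supplied pairing table — no manifold
alignment is re-implemented), the within-stage specificity vectors Y₁, Y₂
over the TFs expressed at both stages are standardized (S, sample sd),
truncated at zero (T) and multiplied elementwise:
`h = T(S(Y₁)) ∘ T(S(Y₂))`.  Truncation means a TF below average specificity
at either stage scores exactly 0, so h > 0 only for TFs above-average
specific at both stages.  TFs with zero expression at a stage are dropped
from the stage's TF set rather than scored 0.  The top-5 by h (ties by
Y₁+Y₂ then identifier) are reported; zero-score TFs pad the list only when
fewer than five are positive, and are flagged.

## Trajectory modules

1. **Stage DEGs** between a stage pair follow the conventional filters:
   detection in ≥ 10% of cells in at least one stage, |log fold change|
   ≥ 0.1 on the natural-log de-logged-mean convention
   `ln(mean(2^x − 1) + 1)` over log2cp10k input, and a two-sided Wilcoxon
   rank-sum BH-adjusted p < 0.05 (the BH family being the genes passing the
   first two filters).
2. **Stage averaging** de-logs, averages per stage, re-logs as
   `log2(mean + 1)`, then standardizes each gene's row (constant rows are
   excluded with a warning — they carry no trajectory).
3. **Fuzzy c-means** with fuzzifier m = 1.25, Euclidean distance, tolerance
   1e-6 on the center shift, centers initialized from c distinct data rows
   (seeded).  m = 1.25 keeps memberships informative but close to hard;
   the cluster count c is a user choice (15–30 at atlas scale, smaller for
   small inputs).  Membership rows summing to 1 and a non-increasing
   objective Σ u^m d² are asserted on every run.  Exact-zero distances give
   full membership to the touching cluster.
4. **Module scores** per cell: genes are binned into 24 equal-frequency bins
   by mean expression over all cells; each set gene contributes up to 100
   control genes from its bin, and the score is mean(set) − mean(pooled
   controls).  When a bin holds no more candidates than requested the whole
   bin is used — this keeps the degenerate case "control pool equals the
   gene set" exactly zero, which replacement sampling would not.
5. **Significance**: for each cluster and each stage, n =
   clamp(min stage size, 150, 1000) cells are drawn without replacement
   from the first stage and the comparison stage; the two-sided Wilcoxon
   rank-sum p-values of repeated draws (1000 at atlas scale; smaller values
   are a parameter) are averaged; BH correction runs over all
   (cluster, stage) pairs, and clusters need some q < 1e-10 to proceed.
   Both stages are resampled, without replacement.
6. **Classification** uses the same resampling machinery with one-sided
   alternatives at α = 0.05 on the averaged p, checked in order:
   module 1 (climax stage, default the penultimate one, above every other
   stage), module 2 (below every other stage), module 3 (each successive
   stage below its predecessor), module 4 (each above).  Modules 1 and 2
   are mutually exclusive by construction; clusters passing nothing stay
   unassigned.  Genes inherit the module of their maximal-membership
   cluster (hard argmax).

## Enrichment

Upper-tail hypergeometric `P(X ≥ k)` for overlap k between a query of size
n and a term of size K in a universe of size N, BH-corrected across terms.
Annotation input is a flat term → gene table; no ontology graph or term
propagation.  The significance flag applies to adjusted values by default
(configurable to raw).  Ortholog translation of queries, where needed, is
the caller's responsibility via `OrthologMap`.

## Synthetic atlas generator

The generator emulates exactly the structures the analyses assume, with
ground truth for recovery testing:

* **Programs.** Each lineage is one cell type with a per-gene mean =
  shared log-normal base abundance (σ = 1.5 for generic genes, σ = 0.5 for
  TFs and module genes so planted structure is well detected) × a lineage
  gate.  Generic genes are "on" in a lineage with probability 0.25 (soft
  log-normal variation when on, hard zero otherwise): sparse, largely
  disjoint programs, the regime the median-fold background estimator
  assumes.  TFs are broadly expressed with mild lineage variation.
* **Counts.** Negative binomial via gamma–Poisson with dispersion θ = 2
  shared across genes and expected totals of 2,000 UMIs per cell — shallow
  bead-based sequencing scale.
* **Planted TFs** are exactly fold f up in their lineage and fold f down
  elsewhere (default f = 8, i.e. a 64-fold separation, lineage share
  f²/(f²+L−1) ≈ 0.94 for L = 5).  Multiplying only the target lineage by
  f = 8 would cap the expected lineage share at 8/12 and the specificity
  score near 0.56 — not a "single-lineage" TF in the sense the score is
  meant to flag; the symmetric up/down planting is what the generator means
  by planting a single-lineage marker.
* **Module genes** are expressed in every lineage and follow multiplicative
  natural-log bumps of amplitude 1.0 (≈ e-fold, about one SD of the
  per-cell log-expression noise) along four archetypes: climax peak,
  climax trough, monotone down, monotone up, with the penultimate stage as
  climax.  An optional adult stage reuses each archetype's endpoint.
* **Soup.** The ambient profile covers the `n_ambient_genes = 40` most
  abundant unplanted genes of the library-size-weighted program mixture,
  with relative abundances from a symmetric Dirichlet (concentration 40,
  so comparable magnitudes).  Real lysis supernatant is dominated by a
  modest set of highly abundant transcripts; modeling it as fully
  proportional to the mixture would leave expected ambient counts below one
  on most genes, where integer-rounded subtraction cannot act at all and
  recovery is undefined rather than hard.  Planted genes are excluded from
  the soup so each recovery test isolates one mechanism.  Every cell
  receives a multinomial ambient draw of `round(f/(1−f) ×
  endogenous total)` counts (f = 0.10 by default, so ambient is 10% of the
  observed total in expectation); empty barcodes are pure soup with totals
  uniform in [50, 400].  Observed = endogenous + ambient holds exactly,
  per barcode per gene.
* **Determinism.** A single `numpy` Generator seeded from the config drives
  all draws; identical config and seed give bit-identical output.

**What it does not emulate** — and hence what passing recovery tests do not
show about real data: doublets, per-gene dispersion variation, batch effects
beyond one soup per batch, sequencing error, correlated gene programs,
ambiguous or hierarchical cell-type labels, and soup profiles that overlap
strongly with individual cell programs.  On real atlases the background
correction and module significance will degrade in ways the synthetic tests
cannot reveal.

## Problem sizes in the verification suite

The recovery tests and `scripts/acceptance.py` run at desk scale, chosen to
keep each property measurable with comfortable margins: background recovery
on 2,000 cells × 1,000 genes with 5,000 empty barcodes; TF recovery on
5 lineages × 500 cells over 10 seeds; driver recovery over 20 seeds; module
recovery on 4 stages × 500 cells with 4 × 50 planted + 200 null genes in the
clustering (embedded in a 2,200-gene matrix so module-score control bins are
dominated by neutral genes, as in a real transcriptome) over 10 seeds with
200 resampling tests per comparison.

## Known limitations

* The background scale estimator assumes soup-supported genes are mostly
  "off" in any given cell; tissues with a dominant shared program violate
  this and will be overcorrected.
* Driver-TF analysis matches cell types across stages by label; if
  annotations drift between stages a pairing table must be supplied, and
  no graph-based cross-stage mapping is provided.
* The resampled Wilcoxon averaged-p is not a calibrated p-value (averaging
  is conservative near 0 and anticonservative near 1); it is used as the
  original procedure uses it, as a ranking statistic against a very strict
  threshold.
* Fuzzy c-means converges to local optima; runs are seeded, and atlas-scale
  users should compare several seeds/cluster counts.
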