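"""Convenience composition of the full synthetic-atlas analysis.

Chains generation, background correction, normalization, TF specificity and
trajectory-module classification with a single seed, mainly for determinism
checks and the worked examples.  Each step is the public function from its
own module; nothing here adds behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .background import correct_background, estimate_background_profile, filter_cells
from .modules import classify_modules, fuzzy_cmeans, module_score, stage_average
from .normalize import lognormalize
from .simulate import AtlasConfig, generate_atlas
from .specificity import call_specific_tfs, group_mean_profile, specificity_scores, zscore_scores


def run_synthetic_analysis(cfg: AtlasConfig, seed: int, n_clusters: int = 8, n_tests: int = 100):
    """Generate an atlas and run every analysis stage on it.

    Returns a dict of the principal result tables; identical config and seed
    give bit-identical results.
    """
    cm, truth = generate_atlas(cfg, seed=seed)
    profile = estimate_background_profile(cm, umi_threshold=500)
    cells = filter_cells(cm, min_transcripts=500)
    corrected = correct_background(cells, profile)
    em = lognormalize(corrected)

    prof = group_mean_profile(em, corrected.meta, "lineage")
    tfs = [g for g in corrected.genes if g.startswith("tf")]
    raw = specificity_scores(prof, tfs)
    z = zscore_scores(raw)
    calls = call_specific_tfs(z, raw=raw, k=20)

    stages = list(cfg.all_stages)
    avg, _dropped = stage_average(em, corrected.meta, stages)
    fc = fuzzy_cmeans(avg, c=n_clusters, seed=seed)
    hard = fc.hard_assignment()
    scores_by_cluster = {
        cl: module_score(em, hard.index[hard == cl], seed=seed + 31 + i)
        for i, cl in enumerate(sorted(hard.unique()))
    }
    assignment = classify_modules(
        fc, scores_by_cluster, corrected.meta, stages,
        n_tests=n_tests, seed=seed + 97,
    )

    return {
        "observed": cm,
        "corrected": corrected,
        "background_mean": profile.bg_mean,
        "tf_scores_raw": raw.scores,
        "tf_scores_z": z.scores,
        "tf_calls": calls,
        "stage_profiles": avg,
        "membership": fc.membership,
        "cluster_module": assignment.cluster_module,
        "gene_module": assignment.gene_module,
        "truth": truth,
    }
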