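"""Canonical synthetic study conditions for end-to-end evaluation.

The benchmark cohort mirrors the statistical shape of a serum
microbial-EV case/control study at desk scale: 200 genus features
(8 phyla x 5 families x 5 genera), 100 samples per group, background
zero fraction 0.5, and 10 genera enriched 8-fold in the disease
group, spread across the four dominant phyla. Analysis drivers, the
test suite and the acceptance script all evaluate against these same
conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coding import code_table
from .models import CVResult, LabeledDataset, METHODS, ModelSpec, cross_validate
from .synthetic import SyntheticConfig, build_taxonomy, simulate_counts


def planted_cohort(
    seed: int,
    n_per_group: int = 100,
    n_effect: int = 10,
    fold_change: float = 8.0,
    zero_fraction: float = 0.5,
) -> tuple[LabeledDataset, list[int]]:
    """Coded two-group cohort with planted genus-level effects.

    Returns the labeled coded dataset and the row indices of the
    planted genera (every 10th leaf, so effects spread across phyla
    and families).
    """
    cfg = SyntheticConfig(
        n_samples_per_group=n_per_group, zero_fraction=zero_fraction, seed=seed
    )
    tree = build_taxonomy(cfg)
    planted = list(range(0, n_effect * 10, 10))
    cfg.effect_taxa = [
        (tree.leaves[i].name_at("genus"), 1, fold_change) for i in planted
    ]
    table, labels = simulate_counts(tree, cfg)
    coded = code_table(table, tree)
    return LabeledDataset.from_coded(coded, labels), planted


def evaluate_suite(
    data: LabeledDataset,
    n_iter: int = 10,
    base_seed: int = 0,
    desk_scale: bool = True,
) -> dict[str, CVResult]:
    """Repeated 7:3 cross-validation of all five methods on one dataset."""
    results = {}
    for method in METHODS:
        spec = ModelSpec(method=method)
        if desk_scale:
            spec = spec.desk_scale()
        results[method] = cross_validate(data, spec, n_iter=n_iter, base_seed=base_seed)
    return results


def permute_labels(data: LabeledDataset, seed: int) -> LabeledDataset:
    """Label-shuffled copy of a dataset (the null benchmark)."""
    rng = np.random.default_rng(seed)
    shuffled = data.labels.to_numpy().copy()
    rng.shuffle(shuffled)
    return LabeledDataset(data.features, pd.Series(shuffled, index=data.labels.index))
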