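"""Permutation feature importance on held-out data.

Importance of a feature is the drop in held-out AUC when that
feature's column is shuffled, averaged over repeats. Each (repeat,
feature) pair draws its permutation from an independent seeded
stream, so results do not depend on feature order and a constant
column scores exactly zero. Importances are reported in absolute AUC
units and are not normalized — they need not sum to anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import LabeledDataset, TrainedModel, predict, roc_auc


@dataclass
class ImportanceTable:
    """Per-feature mean AUC drop, SD across repeats, and rank (1 = largest)."""

    table: pd.DataFrame  # index = feature, columns = mean_importance, sd, rank
    model_label: str

    def to_tsv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path, sep="\t", float_format="%.6g")


def permutation_importance(
    model: TrainedModel,
    test: LabeledDataset,
    n_iter: int = 30,
    seed: int = 0,
    model_label: str | None = None,
) -> ImportanceTable:
    """Mean held-out AUC drop per feature over ``n_iter`` shuffles."""
    test.require_both_classes()
    y = test.labels.to_numpy()
    baseline, _ = roc_auc(predict(model, test.features), y)
    n = len(test.features)
    features = list(test.features.columns)
    drops = np.zeros((n_iter, len(features)))
    X = test.features
    for r in range(n_iter):
        for j, name in enumerate(features):
            rng = np.random.default_rng([seed, r, j])
            perm = rng.permutation(n)
            col = X.iloc[:, j].to_numpy()
            if np.all(col == col[0]):
                continue  # permutation of a constant is the identity
            Xp = X.copy()
            Xp.iloc[:, j] = col[perm]
            auc, _ = roc_auc(predict(model, Xp), y)
            drops[r, j] = baseline - auc
    mean = drops.mean(axis=0)
    sd = drops.std(axis=0)
    rank = stats.rankdata(-mean, method="ordinal").astype(int)
    table = pd.DataFrame(
        {"mean_importance": mean, "sd": sd, "rank": rank}, index=pd.Index(features)
    )
    return ImportanceTable(table=table, model_label=model_label or model.method)


def compare_importance(a: ImportanceTable, b: ImportanceTable) -> pd.DataFrame:
    """Join two importance tables on their shared feature universe.

    Returns (feature, importance_a, importance_b) sorted by the larger
    of the two importances, descending — ready for scatter export.
    """
    missing_in_b = set(a.table.index) - set(b.table.index)
    missing_in_a = set(b.table.index) - set(a.table.index)
    if missing_in_b or missing_in_a:
        missing = sorted(missing_in_b | missing_in_a)
        raise ValueError(f"feature universes differ; unmatched: {missing[:5]}")
    joined = pd.DataFrame(
        {
            "importance_a": a.table["mean_importance"],
            "importance_b": b.table["mean_importance"].reindex(a.table.index),
        }
    )
    order = joined.max(axis=1).sort_values(ascending=False).index
    return joined.loc[order]
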