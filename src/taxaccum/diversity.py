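"""Per-sample alpha diversity: observed richness, Chao1, ACE, Shannon, Simpson.

Estimator conventions follow the common ecology-package defaults:
bias-corrected Chao1 ``S_obs + F1*(F1-1) / (2*(F2+1))`` (defined even
without doubletons), ACE with the conventional rare-abundance cutoff
of 10, Shannon in natural-log units, and Simpson reported as the
diversity ``1 - sum(p^2)`` so larger is more diverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import ace, chao1, shannon, simpson

from .io_qc import TaxaCountTable


@dataclass
class DiversityReport:
    """One row per sample: observed, chao1, ace, shannon, simpson."""

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.6g")


def alpha_diversity(sample_counts) -> dict[str, float]:
    """All five alpha-diversity statistics for one sample's count vector."""
    counts = np.asarray(sample_counts)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    counts = counts[counts > 0].astype(np.int64)
    if counts.size == 0:
        raise ValueError("all-zero count vector has no diversity")
    chao1_value = float(chao1(counts, bias_corrected=True))
    try:
        ace_value = float(ace(counts, rare_threshold=10))
    except ValueError:
        # ACE is undefined when every rare taxon is a singleton; the
        # EstimateS convention substitutes bias-corrected Chao1
        ace_value = chao1_value
    return {
        "observed": float(counts.size),
        "chao1": chao1_value,
        "ace": ace_value,
        "shannon": float(shannon(counts, base=np.e)),
        "simpson": float(simpson(counts)),
    }  # simpson here is the diversity 1 - sum(p^2)


def diversity_report(table: TaxaCountTable) -> DiversityReport:
    rows = {s: alpha_diversity(table.counts[s].to_numpy()) for s in table.sample_ids}
    return DiversityReport(pd.DataFrame.from_dict(rows, orient="index"))
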