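"""Taxonomic hierarchical accumulation coding.

Genus-level counts are log2-scaled (with a +1 pseudocount so zeros
stay zero), normalized so each sample's transformed abundances sum to
one (the relative abundance V_G), and then each genus feature is
augmented with geometrically down-weighted abundance sums of its
ancestor ranks:

    V_ACC = V_G + k1*V_F + k2*V_O + k3*V_C + k4*V_P + k5*V_K

where V_F/V_O/V_C/V_P/V_K are the per-sample sums of V_G over all
genus features under the genus's family, order, class, phylum and
kingdom, and k_i = 10^-(1+i) (0.01, 0.001, 1e-4, 1e-5, 1e-6). A genus
absent from a sample (V_G = 0) still receives contributions from its
relatives, which is what mitigates the heavy zero-inflation of
genus-level microbiome tables; an imprecisely assigned placeholder
pseudo-genus contributes to every verified ancestor rank it has, and
stands in for itself at the ranks it lacks.

Because every rank sum lies in [0, 1], the coded value is bounded:
V_G <= V_ACC <= V_G + sum(k_i) = V_G + 0.011111.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import TaxaCountTable
from .taxonomy import RANKS, TaxLineage, TaxonomyTree

#: ranks accumulated above genus, nearest first, paired with their weight index
_ACCUM_RANKS = ("family", "order", "class", "phylum", "kingdom")


def rank_weight(i: int) -> float:
    """Weight k_i = 10^-(1+i) for rank index i (1=family … 5=kingdom)."""
    if i not in (1, 2, 3, 4, 5):
        raise ValueError(f"rank index must be in 1..5, got {i}")
    return 10.0 ** -(1 + i)


#: k_1..k_5 in rank order family→kingdom
DEFAULT_WEIGHTS: tuple[float, ...] = tuple(rank_weight(i) for i in range(1, 6))


@dataclass
class AbundanceMatrix:
    """Per-sample relative abundances V_G (columns sum to one)."""

    values: pd.DataFrame  # genus features (rows) × samples (columns)
    lineages: list[TaxLineage]

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if (v < 0).any():
            raise ValueError("negative abundance")
        sums = v.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.values.columns[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"sample {bad!r} abundances sum to {sums.max():.12f}, not 1")


@dataclass
class CodedFeatureMatrix:
    """Accumulation-coded genus features V_ACC with the rank weights used."""

    values: pd.DataFrame  # genus features (rows) × samples (columns)
    lineages: list[TaxLineage]
    weights: tuple[float, ...] = DEFAULT_WEIGHTS


def normalize_abundance(genus_table: TaxaCountTable) -> AbundanceMatrix:
    """log2(count + 1), then scale each sample's values to sum to one.

    Zeros remain exactly zero. A sample with no nonzero counts has no
    defined composition and is rejected.
    """
    counts = genus_table.counts.to_numpy(dtype=float)
    transformed = np.log2(counts + 1.0)
    sums = transformed.sum(axis=0)
    zero_samples = np.flatnonzero(sums == 0)
    if zero_samples.size:
        bad = genus_table.counts.columns[zero_samples[0]]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    values = pd.DataFrame(
        transformed / sums,
        index=genus_table.counts.index,
        columns=genus_table.counts.columns,
    )
    return AbundanceMatrix(values=values, lineages=list(genus_table.lineages))


def accumulate(
    abundance: AbundanceMatrix,
    tree: TaxonomyTree | None = None,
    weights: tuple[float, ...] = DEFAULT_WEIGHTS,
) -> CodedFeatureMatrix:
    """Apply the accumulation formula to every (sample, genus) cell.

    Rank sums are grouped by the full ancestor path (names from
    kingdom down to that rank), so same-named nodes on different
    branches never pool. When ``tree`` is given, every feature must
    resolve to one of its leaves.
    """
    if len(weights) != 5:
        raise ValueError("need five rank weights (family→kingdom)")
    lineages = abundance.lineages
    if tree is not None:
        known = {lin.to_string() for lin in tree.leaves}
        for lin in lineages:
            if lin.to_string() not in known:
                raise KeyError(f"genus {lin.to_string()!r} not in taxonomy tree")

    v = abundance.values
    coded = v.copy()
    # prefix depth: family=5, order=4, class=3, phylum=2, kingdom=1
    for k_i, depth in zip(weights, range(5, 0, -1)):
        keys = pd.Index([lin.prefix_key(depth) for lin in lineages])
        rank_sum = v.groupby(keys, sort=False).transform("sum")
        coded = coded + k_i * rank_sum.to_numpy()
    return CodedFeatureMatrix(values=coded, lineages=list(lineages), weights=tuple(weights))


def code_table(
    genus_table: TaxaCountTable,
    tree: TaxonomyTree | None = None,
    weights: tuple[float, ...] = DEFAULT_WEIGHTS,
) -> CodedFeatureMatrix:
    """Convenience: normalize then accumulate a genus-level count table."""
    return accumulate(normalize_abundance(genus_table), tree=tree, weights=weights)


def write_coded(coded: CodedFeatureMatrix, path) -> None:
    out = coded.values.copy()
    out.index.name = "lineage"
    out.to_csv(path, sep="\t", float_format="%.12g")
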