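"""Synthetic serum microbial-EV metagenome generator.

Emulates the statistical shape of genus-level serum EV taxa tables:
zero-inflated log-normal counts, per-sample read totals spanning four
to five orders of magnitude, dominance of a few phyla (the first four
phyla are named Firmicutes, Proteobacteria, Actinobacteria and
Bacteroidetes and carry geometrically decaying base-abundance
factors), and optional group-specific planted effects at any taxonomic
rank. An effect planted on an internal node multiplies the expected
counts of every descendant genus, so hierarchy-level signals propagate
the way a real phylum-level shift would.

Zero-inflation is an independent Bernoulli mask per (sample, taxon)
applied after the effect fold-change scales the log-normal draw.
Detection is abundance-coupled: a taxon's zero probability is
``zero_fraction`` divided by its fold-change in that sample's group
(capped at 1), reflecting that sequencing dropouts are sampling zeros
— more template means proportionally fewer dropouts. An enriched
taxon is therefore both more abundant and more consistently detected
in the affected group, while with ``zero_fraction = 1`` every
non-effect count is zero. One master seed drives everything; each
sample uses a stream seeded ``seed + sample_index``, so a table is
reproducible under sample subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import TaxaCountTable
from .taxonomy import RANKS, TaxLineage, TaxonomyTree

_NAMED_PHYLA = ("Firmicutes", "Proteobacteria", "Actinobacteria", "Bacteroidetes")


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic cohort.

    ``effect_taxa`` entries are ``(node_name, group, fold_change)``:
    every genus below ``node_name`` has its expected count multiplied
    by ``fold_change`` in samples of ``group`` (0 = control,
    1 = disease).
    """

    n_samples_per_group: int = 100
    n_phyla: int = 8
    families_per_phylum: int = 5
    genera_per_family: int = 5
    zero_fraction: float = 0.5
    mean_log: float = 3.0
    sd_log: float = 1.2
    effect_taxa: list[tuple[str, int, float]] = field(default_factory=list)
    read_count_range: tuple[float, float] = (1e4, 1e5)
    phylum_dominance_decay: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name, value in (
            ("n_samples_per_group", self.n_samples_per_group),
            ("n_phyla", self.n_phyla),
            ("families_per_phylum", self.families_per_phylum),
            ("genera_per_family", self.genera_per_family),
        ):
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise ValueError(f"zero_fraction must be in [0, 1], got {self.zero_fraction}")
        lo, hi = self.read_count_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid read_count_range {self.read_count_range}")
        for node, group, fold in self.effect_taxa:
            if fold <= 0:
                raise ValueError(f"fold-change for {node!r} must be > 0, got {fold}")
            if group not in (0, 1):
                raise ValueError(f"group for {node!r} must be 0 or 1, got {group}")


def build_taxonomy(config: SyntheticConfig) -> TaxonomyTree:
    """Deterministic taxonomy with ``n_phyla * families_per_phylum *
    genera_per_family`` genus leaves.

    Names are index-derived and seed-independent; each phylum owns one
    class and one order, so every leaf has a full six-rank chain.
    """
    config.validate()
    lineages = []
    for p in range(config.n_phyla):
        phylum = _NAMED_PHYLA[p] if p < len(_NAMED_PHYLA) else f"Phylum{p + 1:02d}"
        cls_name = f"{phylum}_c"
        order = f"{phylum}_o"
        for f in range(config.families_per_phylum):
            family = f"{phylum}_f{f + 1:02d}"
            for g in range(config.genera_per_family):
                genus = f"{family}_g{g + 1:02d}"
                lineages.append(
                    TaxLineage(("Bacteria", phylum, cls_name, order, family, genus))
                )
    tree = TaxonomyTree.from_lineages(lineages)
    tree.validate()
    return tree


def _phylum_factors(tree: TaxonomyTree, decay: float) -> np.ndarray:
    """Per-leaf base-abundance multipliers giving early phyla dominance."""
    phyla = []
    seen: dict[str, int] = {}
    for lin in tree.leaves:
        ph = lin.name_at("phylum")
        if ph not in seen:
            seen[ph] = len(seen)
        phyla.append(seen[ph])
    idx = np.asarray(phyla)
    return decay ** idx.astype(float)


def simulate_counts(
    tree: TaxonomyTree, config: SyntheticConfig
) -> tuple[TaxaCountTable, pd.Series]:
    """Zero-inflated two-group genus count table with planted effects.

    Returns the count table and a balanced 0/1 label series (group 1 =
    disease). Identical config (including seed) yields a bit-identical
    table.
    """
    config.validate()
    leaves = tree.leaves
    n_taxa = len(leaves)
    if n_taxa < 1:
        raise ValueError("taxonomy has no genus leaves")

    # per-leaf multiplicative effect per group
    fold = np.ones((2, n_taxa))
    for node, group, fc in config.effect_taxa:
        idx = tree.descendant_genus_indices(node)
        if not idx:
            raise ValueError(f"effect node {node!r} not found in taxonomy")
        fold[group, idx] *= fc

    # abundance-coupled detection: zero probability scales inversely
    # with the fold-change in the affected group, capped at 1
    p_zero = np.minimum(config.zero_fraction / fold, 1.0)
    base = _phylum_factors(tree, config.phylum_dominance_decay)
    lo, hi = config.read_count_range

    n = config.n_samples_per_group
    sample_ids = [f"ctrl_{i + 1:04d}" for i in range(n)] + [
        f"case_{i + 1:04d}" for i in range(n)
    ]
    groups = np.repeat([0, 1], n)

    counts = np.zeros((n_taxa, 2 * n), dtype=np.int64)
    for s, group in enumerate(groups):
        rng = np.random.default_rng(config.seed + s)
        raw = rng.lognormal(mean=config.mean_log, sigma=config.sd_log, size=n_taxa)
        raw *= base * fold[group]
        mask = rng.random(n_taxa) >= p_zero[group]
        raw = raw * mask
        total = raw.sum()
        if total > 0:
            # log-uniform read total: frequencies span the 4-5 log decade
            target = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
            scaled = raw * (target / total)
            col = np.rint(scaled).astype(np.int64)
            col[mask & (col < 1)] = 1  # keep masked-in taxa present
            counts[:, s] = col

    df = pd.DataFrame(counts, index=[lin.to_string() for lin in leaves], columns=sample_ids)
    labels = pd.Series(groups, index=sample_ids, name="label")
    table = TaxaCountTable(counts=df, lineages=list(leaves))
    return table, labels


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read summary: length (bp) and mean Phred quality."""

    length: int
    mean_quality: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("read length must be >= 0")
        if self.mean_quality < 0:
            raise ValueError("mean quality must be >= 0")


def simulate_reads(
    n: int,
    length_range: tuple[int, int] = (300, 600),
    quality_range: tuple[float, float] = (10.0, 40.0),
    seed: int = 0,
) -> list[ReadRecord]:
    """``n`` reads with lengths and mean qualities uniform over the ranges."""
    if n < 0:
        raise ValueError("n must be >= 0")
    l_lo, l_hi = length_range
    q_lo, q_hi = quality_range
    if l_lo > l_hi or q_lo > q_hi:
        raise ValueError("empty range")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(l_lo, l_hi + 1, size=n)
    quals = rng.uniform(q_lo, q_hi, size=n)
    return [ReadRecord(int(l), float(q)) for l, q in zip(lengths, quals)]
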