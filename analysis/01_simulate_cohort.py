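#!/usr/bin/env python
"""Generate the synthetic serum microbial-EV case/control cohort.

Produces a 200-genus (8 phyla x 5 families x 5 genera), 100-per-group
count table with 10 genera enriched 8-fold in the disease group, plus
the balanced 0/1 labels and a 10,000-read QC fixture summary. Writes
counts.tsv / labels.tsv under results/cohort/.
"""

import sys
from pathlib import Path

from taxaccum import (
    QCConfig,
    SyntheticConfig,
    build_taxonomy,
    filter_reads,
    simulate_counts,
    simulate_reads,
    write_labels,
    write_taxa_table,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path("results/cohort")


def main() -> None:
    cfg = SyntheticConfig(n_samples_per_group=100, zero_fraction=0.5, seed=SEED)
    tree = build_taxonomy(cfg)
    planted = [tree.leaves[i] for i in range(0, 100, 10)]
    cfg.effect_taxa = [(lin.name_at("genus"), 1, 8.0) for lin in planted]
    table, labels = simulate_counts(tree, cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    write_taxa_table(table, OUT / "counts.tsv")
    write_labels(labels, OUT / "labels.tsv")
    (OUT / "planted_genera.txt").write_text(
        "\n".join(lin.to_string() for lin in planted) + "\n"
    )

    reads = simulate_reads(10_000, length_range=(300, 600), quality_range=(10, 40), seed=SEED)
    kept = filter_reads(reads, QCConfig())
    zero_prop = (table.counts.to_numpy() == 0).mean()
    print(f"cohort: {table.n_taxa} genera x {table.n_samples} samples, seed {SEED}")
    print(f"zero fraction (empirical): {zero_prop:.3f}")
    print(f"read totals span {table.counts.sum(axis=0).min()}-{table.counts.sum(axis=0).max()}")
    print(f"read QC fixture: {len(kept)}/{len(reads)} reads pass 350-550 bp / Phred>=20")
    print(f"planted: {len(planted)} genera enriched 8-fold in cases -> {OUT}/planted_genera.txt")


if __name__ == "__main__":
    main()
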