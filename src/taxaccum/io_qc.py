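"""Taxa-table IO and quality-control filters.

The pipeline starts from taxa count tables with QIIME-style lineage
row keys and from per-read (length, mean Phred) records; raw-read
processing upstream of taxonomic assignment (trimming, merging, OTU
clustering, database assignment) is out of scope. Three filters are
applied before coding:

* reads outside 350–550 bp or with mean Phred below 20 are discarded
  (boundaries retained — only strict violations are dropped);
* samples with fewer than 1000 OTUs are removed;
* species-level rows are summed into their genus-level lineages, with
  placeholder pseudo-genera kept as their own features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import LineageError, TaxLineage


class TaxaTableFormatError(ValueError):
    """Malformed taxa-table input; message carries offending line numbers."""


class EmptyResultError(ValueError):
    """A filter removed every sample."""


@dataclass
class QCConfig:
    """Read-, sample- and quality-filter thresholds."""

    min_read_length: int = 350
    max_read_length: int = 550
    min_phred: float = 20.0
    min_sample_otus: int = 1000

    def __post_init__(self) -> None:
        if self.min_read_length > self.max_read_length:
            raise ValueError("min_read_length > max_read_length")
        if min(self.min_read_length, self.min_phred, self.min_sample_otus) < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class TaxaCountTable:
    """Raw counts for taxa (rows) across samples (columns).

    ``counts`` is indexed by the canonical lineage string of each
    taxon; ``lineages`` holds the parsed identities in row order.
    ``otu_counts``, when present, records the pre-summarization OTU
    count per sample; otherwise the number of nonzero features stands
    in for it.
    """

    counts: pd.DataFrame
    lineages: list[TaxLineage]
    otu_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.lineages) != self.counts.shape[0]:
            raise ValueError("lineages/counts row mismatch")
        if self.counts.columns.duplicated().any():
            raise TaxaTableFormatError("duplicate sample IDs")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TaxaTableFormatError(f"duplicate lineage {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise TaxaTableFormatError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    def effective_otu_counts(self) -> pd.Series:
        """Metadata OTU counts when available, else nonzero features per sample."""
        if self.otu_counts is not None:
            return self.otu_counts.reindex(self.counts.columns)
        return (self.counts > 0).sum(axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "TaxaCountTable":
        otus = None if self.otu_counts is None else self.otu_counts.loc[sample_ids]
        return TaxaCountTable(self.counts[sample_ids], list(self.lineages), otus)


def write_taxa_table(table: TaxaCountTable, path: str | Path) -> None:
    """Canonical lineage-TSV: first column ``lineage``, one column per sample."""
    out = table.counts.copy()
    out.index = [lin.to_string() for lin in table.lineages]
    out.index.name = "lineage"
    out.to_csv(path, sep="\t")


def read_taxa_table(path: str | Path, lineage_map: str | Path | None = None) -> TaxaCountTable:
    """Parse a lineage-TSV (or matrix + lineage-map) into a count table.

    ``lineage_map``, when given, maps the matrix's short row keys to
    full lineage strings (two-column TSV: key, lineage). Malformed rows
    are reported with their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if lineage_map is not None:
        mapping = pd.read_csv(
            lineage_map, sep="\t", index_col=0, dtype=str
        ).iloc[:, 0]
        missing = [k for k in df.index if k not in mapping.index]
        if missing:
            raise TaxaTableFormatError(f"rows without lineage mapping: {missing[:5]}")
        df.index = [mapping[k] for k in df.index]

    errors: list[str] = []
    lineages: list[TaxLineage] = []
    values = np.zeros(df.shape, dtype=np.int64)
    seen: dict[str, int] = {}
    for i, (key, row) in enumerate(df.iterrows()):
        line_no = i + 2  # header is line 1
        try:
            lin = TaxLineage.from_string(str(key))
        except LineageError as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        canon = lin.to_string()
        if canon in seen:
            errors.append(f"line {line_no}: duplicate lineage {canon!r} (first at line {seen[canon]})")
            continue
        seen[canon] = line_no
        lineages.append(lin)
        for j, raw in enumerate(row):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                errors.append(f"line {line_no}: non-integer count {raw!r} in column {df.columns[j]!r}")
                v = 0
            if v < 0:
                errors.append(f"line {line_no}: negative count {v} in column {df.columns[j]!r}")
                v = 0
            values[i, j] = v
    if errors:
        raise TaxaTableFormatError("; ".join(errors))
    counts = pd.DataFrame(values, index=[lin.to_string() for lin in lineages], columns=df.columns)
    return TaxaCountTable(counts=counts, lineages=lineages)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("label").rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    s = pd.read_csv(path, sep="\t", index_col=0)["label"]
    if not set(s.unique()) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return s


def filter_reads(reads: list, qc: QCConfig | None = None) -> list:
    """Keep reads with length in [min, max] and mean quality >= min_phred.

    Order-preserving; idempotent.
    """
    qc = qc or QCConfig()
    return [
        r
        for r in reads
        if qc.min_read_length <= r.length <= qc.max_read_length
        and r.mean_quality >= qc.min_phred
    ]


@dataclass
class QCReport:
    """Counts removed per filtering rule, serializable to JSON."""

    samples_in: int = 0
    samples_removed_low_otus: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)
    taxa_dropped_all_zero: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def filter_samples(
    table: TaxaCountTable,
    qc: QCConfig | None = None,
    drop_empty_taxa: bool = False,
    report: QCReport | None = None,
) -> TaxaCountTable:
    """Remove samples whose OTU count falls below ``min_sample_otus``.

    All-zero taxon rows left behind are kept by default (the feature
    universe is fixed across samples) and dropped only on request.
    """
    qc = qc or QCConfig()
    otus = table.effective_otu_counts()
    keep = [s for s in table.sample_ids if otus[s] >= qc.min_sample_otus]
    if report is not None:
        report.samples_in = table.n_samples
        report.samples_removed_low_otus = table.n_samples - len(keep)
        report.removed_sample_ids = [s for s in table.sample_ids if s not in set(keep)]
    if not keep:
        raise EmptyResultError(
            f"all {table.n_samples} samples fall below {qc.min_sample_otus} OTUs"
        )
    out = table.subset_samples(keep)
    if drop_empty_taxa:
        nz = (out.counts > 0).any(axis=1).to_numpy()
        if report is not None:
            report.taxa_dropped_all_zero = int((~nz).sum())
        out = TaxaCountTable(
            out.counts.loc[nz],
            [lin for lin, k in zip(out.lineages, nz) if k],
            out.otu_counts,
        )
    return out


def summarize_to_genus(table: TaxaCountTable) -> TaxaCountTable:
    """Sum rows sharing the same genus-level lineage.

    Species-level rows collapse onto their genus; placeholder
    pseudo-genera (parenthesized or bracketed genus slots) remain
    distinct features and are never merged with verified genera of the
    same family. Per-sample totals are conserved.
    """
    genus_lineages = [lin.genus_lineage for lin in table.lineages]
    keys = [lin.to_string() for lin in genus_lineages]
    summed = table.counts.groupby(pd.Index(keys, name="lineage"), sort=False).sum()
    uniq: dict[str, TaxLineage] = {}
    for key, lin in zip(keys, genus_lineages):
        uniq.setdefault(key, lin)
    lineages = [uniq[k] for k in summed.index]
    return TaxaCountTable(counts=summed, lineages=lineages, otu_counts=table.otu_counts)
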