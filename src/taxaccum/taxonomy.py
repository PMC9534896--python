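"""Six-rank bacterial taxonomy: lineages and the taxonomy tree.

Features in serum microbial-EV taxa tables are identified by a
kingdom→phylum→class→order→family→genus lineage. Taxa that could not be
assigned at genus level carry a placeholder in the genus slot: a
parenthesized name means the taxon was assigned at the next verified
higher rank (e.g. ``g__(Fimbriimonadaceae)`` for a family-level
assignment), while a bracketed name marks an unverified suggested
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")
_SPECIES_PREFIX = "s__"


class LineageError(ValueError):
    """Raised for malformed lineage strings."""


def _decoration(name: str) -> str:
    if name.startswith("(") and name.endswith(")"):
        return "parenthesized"
    if name.startswith("[") and name.endswith("]"):
        return "bracketed"
    return "none"


@dataclass(frozen=True)
class TaxLineage:
    """A six-rank taxon identity, optionally carrying a species name.

    ``names`` holds the kingdom…genus names in order; placeholder slots
    keep their decoration (parentheses/brackets). ``assignment_rank`` is
    the deepest rank whose name is verified (undecorated);
    ``placeholder_style`` reflects the genus-slot decoration.
    """

    names: tuple[str, str, str, str, str, str]
    species: str | None = None

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise LineageError(f"expected {len(RANKS)} rank names, got {len(self.names)}")
        if any(n == "" for n in self.names):
            raise LineageError("empty rank name; placeholders must be filled")

    @property
    def placeholder_style(self) -> str:
        return _decoration(self.names[-1])

    @property
    def assignment_rank(self) -> str:
        for rank, name in zip(reversed(RANKS), reversed(self.names)):
            if _decoration(name) == "none":
                return rank
        # fully decorated lineage: treat the kingdom as the anchor
        return "kingdom"

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def prefix_key(self, depth: int) -> str:
        """Ancestor identity down to ``depth`` ranks (1 = kingdom … 6 = genus)."""
        return ";".join(self.names[:depth])

    @property
    def genus_lineage(self) -> "TaxLineage":
        """This lineage with any species stripped — the genus-level feature key."""
        if self.species is None:
            return self
        return TaxLineage(self.names)

    def to_string(self, with_species: bool = True) -> str:
        parts = [p + n for p, n in zip(RANK_PREFIXES, self.names)]
        if with_species and self.species is not None:
            parts.append(_SPECIES_PREFIX + self.species)
        return ";".join(parts)

    @classmethod
    def from_string(cls, lineage: str) -> "TaxLineage":
        """Parse a QIIME-style lineage string.

        Accepts 6 fields (kingdom…genus) or 7 (…species), with or
        without ``k__``-style prefixes (unprefixed fields are assigned
        by position). Empty trailing ranks are filled with a
        parenthesized placeholder derived from the deepest named
        ancestor, so every lineage is complete.
        """
        fields = [f.strip() for f in lineage.strip().split(";")]
        if len(fields) < len(RANKS) or len(fields) > len(RANKS) + 1:
            raise LineageError(
                f"expected {len(RANKS)} or {len(RANKS) + 1} ';'-separated ranks, "
                f"got {len(fields)}: {lineage!r}"
            )
        names: list[str] = []
        species: str | None = None
        for i, raw in enumerate(fields):
            prefix = RANK_PREFIXES[i] if i < len(RANKS) else _SPECIES_PREFIX
            name = raw[len(prefix):] if raw.startswith(prefix) else raw
            # tolerate any recognized prefix in the wrong slot only if it matches position
            if i < len(RANKS):
                names.append(name)
            else:
                species = name or None
        if names[0] == "":
            raise LineageError(f"kingdom name missing: {lineage!r}")
        # fill empty ranks from the deepest named ancestor
        for i in range(1, len(names)):
            if names[i] == "":
                anc = names[i - 1]
                names[i] = anc if _decoration(anc) != "none" else f"({anc})"
        return cls(tuple(names), species=species)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass
class TaxonomyTree:
    """Rank-decreasing tree over (rank, name) nodes with genus leaves.

    ``parent`` maps every non-kingdom node to its node at the next
    higher rank; ``leaves`` are the genus-level feature lineages.
    """

    nodes: set[tuple[str, str]] = field(default_factory=set)
    parent: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    leaves: list[TaxLineage] = field(default_factory=list)

    @classmethod
    def from_lineages(cls, lineages: list[TaxLineage]) -> "TaxonomyTree":
        tree = cls()
        for lin in lineages:
            tree.add_lineage(lin)
        return tree

    def add_lineage(self, lin: TaxLineage) -> None:
        prev: tuple[str, str] | None = None
        for rank, name in zip(RANKS, lin.names):
            node = (rank, name)
            self.nodes.add(node)
            if prev is not None:
                existing = self.parent.get(node)
                if existing is not None and existing != prev:
                    raise LineageError(
                        f"{rank} {name!r} has conflicting parents {existing} and {prev}"
                    )
                self.parent[node] = prev
            prev = node
        self.leaves.append(lin.genus_lineage)

    def ancestors(self, lin: TaxLineage) -> list[tuple[str, str]]:
        """Ancestor chain of a genus leaf, kingdom first, genus last."""
        return [(rank, name) for rank, name in zip(RANKS, lin.names)]

    def descendant_genus_indices(self, node_name: str) -> list[int]:
        """Indices of leaves having a node named ``node_name`` at any rank."""
        return [i for i, lin in enumerate(self.leaves) if node_name in lin.names]

    def validate(self) -> None:
        rank_order = {r: i for i, r in enumerate(RANKS)}
        for child, par in self.parent.items():
            if rank_order[child[0]] - rank_order[par[0]] != 1:
                raise LineageError(f"edge {par} -> {child} is not rank-decreasing by one")
        for lin in self.leaves:
            chain = self.ancestors(lin)
            if len(chain) != len(RANKS):
                raise LineageError(f"leaf {lin} lacks a full ancestor chain")
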