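"""Core domain objects: gene symbols, regulatory networks, pathway sets.

Gene symbols are plain uppercase strings; all containers normalize and
deduplicate on construction, so equality of two containers means equality
of their scientific content regardless of input file casing or row order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

VALID_MODES = ("activation", "repression", "unknown")

# canonical HGNC-style token: letters/digits plus the few separators that
# occur in real symbols (e.g. HLA-A, NKX2-1)
_CLEAN_SYMBOL = re.compile(r"^[A-Z0-9][A-Z0-9_.\-@]*$")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_symbol(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    """Return the canonical form of a gene symbol.

    Canonical form is uppercase with surrounding whitespace stripped.
    ``aliases`` maps non-standard spellings (already uppercased) to their
    official symbol, e.g. ``{"BCL-2": "BCL2"}``; normalization is applied
    before the lookup so alias resolution is case-insensitive.  Symbols
    absent from the alias table pass through verbatim; a warning is issued
    when such a symbol does not look like a clean token (it may be an
    unrecognized alias).
    """
    if symbol is None:
        raise ValueError("gene symbol must not be None")
    out = symbol.strip().upper()
    if not out:
        raise ValueError("gene symbol must not be empty")
    if any(ch.isspace() for ch in out):
        raise ValueError(f"gene symbol contains internal whitespace: {symbol!r}")
    if aliases:
        resolved = aliases.get(out)
        if resolved is not None:
            return resolved.strip().upper()
        if not _CLEAN_SYMBOL.match(out):
            warnings.warn(
                f"symbol {out!r} is not in the alias table and is not a "
                "clean token; passing through verbatim",
                stacklevel=2,
            )
    return out


@dataclass(frozen=True)
class TFInteraction:
    """One directed transcription-factor -> target-gene interaction."""

    tf: str
    target: str
    mode: str = "unknown"
    evidence: str = ""

    def __post_init__(self) -> None:
        if not self.tf or not self.target:
            raise ValueError("tf and target must be non-empty")
        if self.mode not in VALID_MODES:
            raise ValueError(
                f"mode must be one of {VALID_MODES}, got {self.mode!r}"
            )


class RegulatoryNetwork:
    """Directed TF -> target interaction store.

    Duplicate (tf, target) pairs are collapsed to the first occurrence;
    regulation mode never affects membership queries, only provenance.
    """

    def __init__(self, interactions: Iterable[TFInteraction] = ()) -> None:
        self._by_pair: dict[tuple[str, str], TFInteraction] = {}
        self._targets_of: dict[str, set[str]] = {}
        self._regulators_of: dict[str, set[str]] = {}
        for ia in interactions:
            self.add(ia)

    def add(self, interaction: TFInteraction) -> None:
        key = (interaction.tf, interaction.target)
        if key in self._by_pair:
            return
        self._by_pair[key] = interaction
        self._targets_of.setdefault(interaction.tf, set()).add(interaction.target)
        self._regulators_of.setdefault(interaction.target, set()).add(interaction.tf)

    def __len__(self) -> int:
        return len(self._by_pair)

    def __iter__(self) -> Iterator[TFInteraction]:
        return iter(sorted(self._by_pair.values(), key=lambda i: (i.tf, i.target)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._by_pair

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._by_pair == other._by_pair

    def __repr__(self) -> str:
        return f"RegulatoryNetwork({len(self)} interactions)"

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(self._targets_of)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._targets_of) | frozenset(self._regulators_of)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(self._targets_of.get(tf, ()))

    def regulators_of(self, gene: str) -> frozenset[str]:
        return frozenset(self._regulators_of.get(gene, ()))

    def interaction(self, tf: str, target: str) -> TFInteraction:
        return self._by_pair[(tf, target)]


@dataclass(frozen=True)
class PathwayRecord:
    """A named gene set (one pathway / functional annotation)."""

    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be non-empty")
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id!r} has no members")

    @property
    def size(self) -> int:
        return len(self.members)


class PathwayDB:
    """Collection of pathways keyed by identifier.

    Duplicate identifiers keep the last occurrence (with a warning) so a
    later snapshot line supersedes an earlier one.
    """

    def __init__(self, records: Iterable[PathwayRecord] = ()) -> None:
        self._records: dict[str, PathwayRecord] = {}
        for rec in records:
            if rec.pathway_id in self._records:
                warnings.warn(
                    f"duplicate pathway id {rec.pathway_id!r}: keeping the "
                    "last occurrence",
                    stacklevel=2,
                )
            self._records[rec.pathway_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[PathwayRecord]:
        return iter(sorted(self._records.values(), key=lambda r: r.pathway_id))

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._records

    def __getitem__(self, pathway_id: str) -> PathwayRecord:
        return self._records[pathway_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayDB):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"PathwayDB({len(self)} pathways)"

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self._records)


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected weighted co-expression edge between two genes.

    The endpoint order is canonicalized (lexicographic) so that
    ``CoexpressionEdge(a, b) == CoexpressionEdge(b, a)``.
    """

    gene_a: str
    gene_b: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("edge endpoints must be non-empty")
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a!r} is not allowed")
        if not (self.weight >= 0):
            raise ValueError(f"edge weight must be non-negative, got {self.weight}")
        if self.gene_a > self.gene_b:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def touches(self, gene: str) -> bool:
        return gene in (self.gene_a, self.gene_b)

    def other(self, gene: str) -> str:
        if gene == self.gene_a:
            return self.gene_b
        if gene == self.gene_b:
            return self.gene_a
        raise KeyError(f"{gene!r} is not an endpoint of {self.pair}")


def dedupe_edges(edges: Iterable[CoexpressionEdge]) -> list[CoexpressionEdge]:
    """Collapse duplicate undirected pairs, keeping the first occurrence."""
    seen: dict[tuple[str, str], CoexpressionEdge] = {}
    for e in edges:
        seen.setdefault(e.pair, e)
    return sorted(seen.values(), key=lambda e: e.pair)


TISSUES = ("cancer", "mucosa")
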