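"""Seed-set expansion through the TF track and the pathway track.

TF track: find every transcription factor upstream of any seed, then take
the union of all targets of those TFs.  Pathway track: find every pathway
containing a seed, drop oversized or explicitly excluded pathways, then
take the union of the kept pathways' members.  Both tracks deliberately
use pure membership — no enrichment statistics — so a gene enters a track
as soon as a single shared regulator or pathway links it to a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from markermine.model import PathwayDB, RegulatoryNetwork, normalize_symbol


@dataclass(frozen=True)
class SeedSet:
    """A labelled set of validated disease marker genes."""

    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"seed set {self.label!r} is empty")

    @classmethod
    def from_iterable(
        cls,
        label: str,
        genes: Iterable[str],
        aliases: Mapping[str, str] | None = None,
    ) -> "SeedSet":
        return cls(label, frozenset(normalize_symbol(g, aliases) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(sorted(self.genes))


@dataclass(frozen=True)
class PathwayFilterConfig:
    """Pathway relevance filter.

    ``max_size`` drops top-level catch-all pathways: a pathway is kept
    only when it has at most ``max_size`` member genes (default 80, i.e.
    "more than 80 genes" is excluded, a size-80 pathway is kept).
    ``excluded_ids`` and ``excluded_name_patterns`` (case-insensitive
    substrings) encode the manual curation of disease-unrelated pathways;
    both default to empty.
    """

    max_size: int = 80
    excluded_ids: frozenset[str] = frozenset()
    excluded_name_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")
        object.__setattr__(self, "excluded_ids", frozenset(self.excluded_ids))
        object.__setattr__(
            self, "excluded_name_patterns", tuple(self.excluded_name_patterns)
        )

    def keeps(self, pathway_id: str, name: str, size: int) -> bool:
        if size > self.max_size:
            return False
        if pathway_id in self.excluded_ids:
            return False
        lowered = name.lower()
        return not any(p.lower() in lowered for p in self.excluded_name_patterns)


@dataclass(frozen=True)
class TrackResult:
    """Outcome of one expansion track.

    ``support`` holds the intermediate entities (TFs for the TF track,
    kept pathway ids for the pathway track); ``provenance`` maps each
    expanded gene to the supports that contributed it.
    """

    track: str
    support: frozenset[str]
    genes: frozenset[str]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)


def find_upstream_tfs(seeds: SeedSet, network: RegulatoryNetwork) -> frozenset[str]:
    """All TFs with at least one seed among their targets, deduplicated."""
    tfs: set[str] = set()
    for seed in seeds.genes:
        tfs |= network.regulators_of(seed)
    return frozenset(tfs)


def collect_tf_targets(
    tfs: Iterable[str], network: RegulatoryNetwork
) -> frozenset[str]:
    """Union of all target genes of the given TFs; regulation mode ignored."""
    genes: set[str] = set()
    for tf in tfs:
        genes |= network.targets_of(tf)
    return frozenset(genes)


def tf_track(seeds: SeedSet, network: RegulatoryNetwork) -> TrackResult:
    """Run the full TF track: seeds -> upstream TFs -> all their targets."""
    tfs = find_upstream_tfs(seeds, network)
    provenance: dict[str, set[str]] = {}
    for tf in tfs:
        for gene in network.targets_of(tf):
            provenance.setdefault(gene, set()).add(tf)
    genes = frozenset(provenance)
    return TrackResult(
        track="tf",
        support=tfs,
        genes=genes,
        provenance={g: frozenset(s) for g, s in provenance.items()},
    )


def find_pathways(seeds: SeedSet, db: PathwayDB) -> frozenset[str]:
    """Ids of all pathways containing at least one seed gene."""
    return frozenset(
        rec.pathway_id for rec in db if rec.members & seeds.genes
    )


def filter_pathways(
    ids: Iterable[str], db: PathwayDB, cfg: PathwayFilterConfig
) -> frozenset[str]:
    """Apply the size / id / name-pattern relevance filter to pathway ids."""
    kept = set()
    for pid in ids:
        if pid not in db:
            raise KeyError(f"pathway id {pid!r} not present in the database")
        rec = db[pid]
        if cfg.keeps(rec.pathway_id, rec.name, rec.size):
            kept.add(pid)
    return frozenset(kept)


def collect_pathway_genes(ids: Iterable[str], db: PathwayDB) -> frozenset[str]:
    """Union of member genes over the given pathways, deduplicated."""
    genes: set[str] = set()
    for pid in ids:
        genes |= db[pid].members
    return frozenset(genes)


def pathway_track(
    seeds: SeedSet, db: PathwayDB, cfg: PathwayFilterConfig | None = None
) -> TrackResult:
    """Run the full pathway track: seeds -> pathways -> filter -> members."""
    cfg = cfg or PathwayFilterConfig()
    kept = filter_pathways(find_pathways(seeds, db), db, cfg)
    provenance: dict[str, set[str]] = {}
    for pid in kept:
        for gene in db[pid].members:
            provenance.setdefault(gene, set()).add(pid)
    return TrackResult(
        track="pathway",
        support=kept,
        genes=frozenset(provenance),
        provenance={g: frozenset(s) for g, s in provenance.items()},
    )
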