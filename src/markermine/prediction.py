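"""Marker prediction: track intersection, cross-validation, ranking.

A gene is predicted when it appears in *both* expansion tracks — the two
knowledge bases act as independent, individually noisy predictors, and
their intersection suppresses the single-track false positives.  Two
predictions built from disjoint seed sets are then cross-validated by set
overlap, and the surviving candidates are prioritized (never selected or
de-selected) by co-expression with the seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from markermine.expansion import (
    PathwayFilterConfig,
    SeedSet,
    TrackResult,
    pathway_track,
    tf_track,
)
from markermine.model import CoexpressionEdge, PathwayDB, RegulatoryNetwork


@dataclass(frozen=True)
class PredictionResult:
    """Both tracks plus their intersection for one seed set."""

    seed_label: str
    seeds: frozenset[str]
    tf_track: TrackResult
    pathway_track: TrackResult
    predicted: frozenset[str]

    @property
    def novel(self) -> frozenset[str]:
        """Predicted genes excluding the seeds themselves."""
        return self.predicted - self.seeds

    @property
    def counts(self) -> dict[str, int]:
        return {
            "n_seeds": len(self.seeds),
            "n_tfs": len(self.tf_track.support),
            "n_tf_targets": len(self.tf_track.genes),
            "n_pathways_kept": len(self.pathway_track.support),
            "n_pathway_genes": len(self.pathway_track.genes),
            "n_predicted": len(self.predicted),
            "n_predicted_novel": len(self.novel),
        }


@dataclass(frozen=True)
class CrossValidationResult:
    """Set algebra between two independent predictions."""

    overlap: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]

    @property
    def union(self) -> frozenset[str]:
        return self.overlap | self.only_a | self.only_b

    @property
    def jaccard(self) -> float:
        union = self.union
        return len(self.overlap) / len(union) if union else 1.0


@dataclass(frozen=True)
class RankedMarkers:
    """Predicted genes ordered by co-expression support from the seeds.

    ``entries`` is the full ranking as (gene, n_seed_neighbors,
    total_edge_weight); ``retained`` holds the genes co-expressed with at
    least one seed.  Ordering: seed-neighbor count desc, total weight
    desc, then symbol asc, so reports are reproducible.
    """

    entries: tuple[tuple[str, int, float], ...]
    retained: frozenset[str]


def predict_markers(
    seeds: SeedSet,
    network: RegulatoryNetwork,
    db: PathwayDB,
    cfg: PathwayFilterConfig | None = None,
) -> PredictionResult:
    """Expand seeds through both tracks and intersect the results."""
    tf = tf_track(seeds, network)
    pw = pathway_track(seeds, db, cfg)
    predicted = tf.genes & pw.genes
    if not predicted:
        warnings.warn(
            f"seed set {seeds.label!r}: TF and pathway tracks are disjoint; "
            "no markers predicted",
            stacklevel=2,
        )
    return PredictionResult(
        seed_label=seeds.label,
        seeds=seeds.genes,
        tf_track=tf,
        pathway_track=pw,
        predicted=frozenset(predicted),
    )


def cross_validate(
    a: PredictionResult | frozenset[str] | set[str],
    b: PredictionResult | frozenset[str] | set[str],
) -> CrossValidationResult:
    """Overlap two predictions built from independent seed sets."""
    if isinstance(a, PredictionResult) and isinstance(b, PredictionResult):
        if a.seeds & b.seeds:
            warnings.warn(
                "seed sets overlap; cross-validation is not independent",
                stacklevel=2,
            )
    set_a = frozenset(a.predicted if isinstance(a, PredictionResult) else a)
    set_b = frozenset(b.predicted if isinstance(b, PredictionResult) else b)
    return CrossValidationResult(
        overlap=set_a & set_b,
        only_a=set_a - set_b,
        only_b=set_b - set_a,
    )


def rank_by_coexpression(
    predicted: Iterable[str],
    seeds_all: Iterable[str],
    edges: Sequence[CoexpressionEdge],
) -> RankedMarkers:
    """Prioritize predicted genes by their co-expression with the seeds.

    For each predicted gene, counts distinct seed neighbors and sums the
    weights of its incident seed edges.  ``retained`` is the subset with
    at least one seed neighbor; genes without seed edges still appear in
    ``entries`` (rank tail) because co-expression only prioritizes.
    """
    predicted = frozenset(predicted)
    seed_set = frozenset(seeds_all)
    neighbors: dict[str, set[str]] = {g: set() for g in predicted}
    weights: dict[str, float] = {g: 0.0 for g in predicted}
    for edge in edges:
        for gene in edge.pair:
            if gene in predicted and edge.other(gene) in seed_set:
                neighbors[gene].add(edge.other(gene))
                weights[gene] += edge.weight
    entries = sorted(
        ((g, len(neighbors[g]), weights[g]) for g in predicted),
        key=lambda t: (-t[1], -t[2], t[0]),
    )
    retained = frozenset(g for g, n, _ in entries if n >= 1)
    return RankedMarkers(entries=tuple(entries), retained=retained)
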