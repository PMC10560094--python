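"""Per-isoform interaction networks and binding-region impact flags.

Curated interaction records name the mediating isoform; records without a
known isoform accession are assigned to the canonical isoform (and flagged
as assumed). Edges are filtered by interaction-confidence (MI) score and
interaction type, optionally capped per alternative isoform, partitioned
by mediating isoform, and flagged when their annotated binding region
overlaps a splicing-variable region of that isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .model import (
    INTERACTION_TYPES,
    InteractionRecord,
    IsoformNetwork,
    NetworkEdge,
    ValidationError,
)


@dataclass
class NetworkFilters:
    min_mi_score: float = 0.45
    allowed_types: frozenset[str] = field(
        default_factory=lambda: frozenset(INTERACTION_TYPES)
    )
    max_isoform_specific: Optional[int] = None  # None = unlimited

    def __post_init__(self) -> None:
        self.allowed_types = frozenset(self.allowed_types)
        if not self.allowed_types:
            raise ValidationError("allowed_types must be non-empty")
        unknown = self.allowed_types - set(INTERACTION_TYPES)
        if unknown:
            raise ValidationError(f"unknown interaction types: {sorted(unknown)}")
        if self.max_isoform_specific is not None and self.max_isoform_specific < 1:
            raise ValidationError("max_isoform_specific must be >= 1 or unlimited")


def resolve_accession(
    record: InteractionRecord, canonical_accession: str, known_accessions: frozenset[str]
) -> tuple[str, bool]:
    """Mediating isoform for a record; unknown accessions fall back to the
    canonical isoform. Returns (accession, assumed_canonical)."""
    if record.isoform_accession in known_accessions:
        return record.isoform_accession, False
    return canonical_accession, True


def filter_edges(
    interactions: list[InteractionRecord],
    filters: NetworkFilters | None = None,
    canonical_accession: str | None = None,
    known_accessions: frozenset[str] | None = None,
) -> list[InteractionRecord]:
    """Apply MI-score / type filters, then the per-isoform specificity cap.

    The cap keeps, per non-canonical isoform, at most max_isoform_specific
    records whose partner is absent from the canonical isoform's
    (post-filter) partner set, ranked by descending MI score with ties by
    ascending partner id; non-specific records are unaffected.
    """
    filters = filters or NetworkFilters()
    kept = [
        r
        for r in interactions
        if r.mi_score >= filters.min_mi_score and r.interaction_type in filters.allowed_types
    ]
    if filters.max_isoform_specific is None or canonical_accession is None:
        return kept

    known = known_accessions or frozenset()
    resolved = [resolve_accession(r, canonical_accession, known)[0] for r in kept]
    canonical_partners = {
        r.partner_id for r, acc in zip(kept, resolved) if acc == canonical_accession
    }
    by_isoform: dict[str, list[tuple[InteractionRecord, int]]] = {}
    for idx, (rec, acc) in enumerate(zip(kept, resolved)):
        if acc != canonical_accession and rec.partner_id not in canonical_partners:
            by_isoform.setdefault(acc, []).append((rec, idx))

    drop: set[int] = set()
    for acc, group in by_isoform.items():
        ranked = sorted(group, key=lambda t: (-t[0].mi_score, t[0].partner_id))
        for _, idx in ranked[filters.max_isoform_specific:]:
            drop.add(idx)
    return [r for i, r in enumerate(kept) if i not in drop]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def flag_affected_bindings(
    interactions: list[InteractionRecord],
    variable_regions: dict[str, list[tuple[int, int]]],
    canonical_accession: str,
    known_accessions: frozenset[str] | None = None,
) -> list[NetworkEdge]:
    """Turn filtered records into edges, flagging binding regions that
    overlap any splicing-variable region of the mediating isoform.

    variable_regions maps isoform accession -> disjoint canonical
    intervals (from the splice-event union); the canonical isoform has no
    variable regions by definition.
    """
    known = known_accessions or frozenset()
    edges = []
    for rec in interactions:
        acc, assumed = resolve_accession(rec, canonical_accession, known)
        affected = bool(
            rec.binding_region is not None
            and any(_overlaps(rec.binding_region, vr) for vr in variable_regions.get(acc, []))
        )
        edges.append(
            NetworkEdge(
                isoform_accession=acc,
                partner_id=rec.partner_id,
                interaction_type=rec.interaction_type,
                mi_score=rec.mi_score,
                binding_region=rec.binding_region,
                binding_affected=affected,
                assumed_canonical=assumed,
            )
        )
    return edges


def partition_network(edges: list[NetworkEdge], canonical_accession: str) -> IsoformNetwork:
    """Group edges by mediating isoform and mark isoform-specific partners.

    A partner is isoform-specific when it does not appear in the canonical
    isoform's partition. The whole network is the union of all partitions,
    deduplicated by (partner, interaction type); an edge wins over its
    duplicates by higher MI score, then by mediating-accession order.
    """
    canonical_partners = {
        e.partner_id for e in edges if e.isoform_accession == canonical_accession
    }
    partitions: dict[str, list[NetworkEdge]] = {}
    for e in edges:
        specific = (
            e.isoform_accession != canonical_accession
            and e.partner_id not in canonical_partners
        )
        partitions.setdefault(e.isoform_accession, []).append(
            replace(e, isoform_specific=specific)
        )
    for group in partitions.values():
        group.sort(key=lambda e: (e.partner_id, e.interaction_type, -e.mi_score))

    best: dict[tuple[str, str], NetworkEdge] = {}
    for group in partitions.values():
        for e in group:
            key = (e.partner_id, e.interaction_type)
            cur = best.get(key)
            if cur is None or (e.mi_score, cur.isoform_accession) > (cur.mi_score, e.isoform_accession):
                best[key] = e
    whole = [best[k] for k in sorted(best)]
    return IsoformNetwork(canonical_accession, partitions, whole)
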