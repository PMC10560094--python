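"""Domain model: loci, isoforms, annotations, events, network edges, enrichment.

All protein coordinates are 1-based and intervals are closed on both ends
(the UniProt convention). The amino-acid alphabet is the 20 standard
residues plus ``X`` for an unknown residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_ALPHABET_SET = frozenset(ALPHABET)

INTERACTION_TYPES = ("direct", "physical", "association")
EVENT_TYPES = ("insertion", "deletion", "divergent")
PTM_STATUSES = ("lost", "altered_context", "retained")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (coordinates, enums, ranges)."""


class DomainError(ValueError):
    """An operation was called with arguments outside its domain."""


def check_sequence(sequence: str, *, context: str = "sequence") -> str:
    """Validate and upper-case an amino-acid sequence.

    Raises FormatError naming the first illegal character and its 1-based
    offset; empty sequences are rejected.
    """
    if not sequence:
        raise FormatError(f"{context}: empty sequence")
    seq = sequence.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET_SET:
            raise FormatError(
                f"{context}: illegal residue {ch!r} at position {i} "
                f"(alphabet is the 20 amino acids plus X)"
            )
    return seq


@dataclass
class IsoformRecord:
    isoform_id: str
    sequence: str
    is_canonical: bool = False


@dataclass
class Locus:
    """All protein isoforms transcribed from one genetic locus."""

    gene_symbol: str
    isoforms: list[IsoformRecord]
    cluster_assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValidationError("gene_symbol must be non-empty")
        seen: set[str] = set()
        for rec in self.isoforms:
            if rec.isoform_id in seen:
                raise FormatError(f"duplicate isoform id {rec.isoform_id!r}")
            seen.add(rec.isoform_id)
            rec.sequence = check_sequence(rec.sequence, context=f"isoform {rec.isoform_id!r}")

    def get(self, isoform_id: str) -> IsoformRecord:
        for rec in self.isoforms:
            if rec.isoform_id == isoform_id:
                return rec
        raise KeyError(isoform_id)

    @property
    def isoform_ids(self) -> list[str]:
        return [r.isoform_id for r in self.isoforms]


@dataclass(frozen=True)
class DomainAnnotation:
    """A domain interval on the canonical sequence (closed, 1-based)."""

    domain_name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PTMSite:
    position: int
    modification_type: str


@dataclass(frozen=True)
class InteractionRecord:
    partner_id: str
    isoform_accession: str
    interaction_type: str
    mi_score: float
    binding_region: Optional[tuple[int, int]] = None


@dataclass(frozen=True)
class DERecord:
    transcript_id: str
    gene_symbol: str
    tissue: str
    log2fc: float
    ppde: float


@dataclass
class GeneSetCollection:
    """Named gene sets keyed by term id, as read from a GMT file."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term_id!r} is empty")

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return frozenset(out)


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    member_ids: tuple[str, ...]
    canonical_id: str


@dataclass(frozen=True)
class SpliceEvent:
    """A protein-level splice event of an isoform relative to its canonical.

    For deletions the isoform coordinates are absent. For insertions
    canonical_start == canonical_end == the anchor position: the canonical
    position after which the insertion occurs (0 for an N-terminal
    insertion).
    """

    isoform_id: str
    event_type: str
    canonical_start: int
    canonical_end: int
    isoform_start: Optional[int]
    isoform_end: Optional[int]
    length: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.length < 1:
            raise ValidationError("event length must be >= 1")
        if self.event_type == "deletion" and self.isoform_start is not None:
            raise ValidationError("deletion events carry no isoform coordinates")
        if self.event_type == "insertion" and self.canonical_start != self.canonical_end:
            raise ValidationError("insertion events are anchored at a single canonical position")

    @property
    def canonical_anchor(self) -> int:
        """Anchor of an insertion (position after which it occurs)."""
        return self.canonical_start


@dataclass(frozen=True)
class DomainImpact:
    isoform_id: str
    domain_name: str
    event_type: str
    overlap_start: int
    overlap_end: int
    overlap_length: int
    domain_fraction_affected: float
    insertion_inside: bool = False


@dataclass(frozen=True)
class PTMImpact:
    isoform_id: str
    position: int
    modification_type: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in PTM_STATUSES:
            raise ValidationError(f"unknown PTM status {self.status!r}")


@dataclass(frozen=True)
class NetworkEdge:
    isoform_accession: str
    partner_id: str
    interaction_type: str
    mi_score: float
    binding_region: Optional[tuple[int, int]]
    binding_affected: bool = False
    isoform_specific: bool = False
    assumed_canonical: bool = False

    def __post_init__(self) -> None:
        if self.binding_affected and self.binding_region is None:
            raise ValidationError("binding_affected requires a binding_region")


@dataclass
class IsoformNetwork:
    """Per-isoform interaction partitions plus their deduplicated union."""

    canonical_accession: str
    partitions: dict[str, list[NetworkEdge]]
    whole_network: list[NetworkEdge]

    def partners(self, accession: str) -> frozenset[str]:
        return frozenset(e.partner_id for e in self.partitions.get(accession, []))


@dataclass(frozen=True)
class EnrichmentResult:
    network_label: str
    term_id: str
    term_name: str
    overlap_k: int
    query_n: int
    term_K: int
    background_N: int
    p_value: float
    fdr: float
    overlap_genes: tuple[str, ...]
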