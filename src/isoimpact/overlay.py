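"""Differential-expression filtering and per-gene report assembly.

Differential expression is consumed from an upstream transcript-level
table carrying a log2 fold change and a posterior probability of being
differentially expressed (PPDE) per transcript and tissue; transcripts
with PPDE strictly greater than 0.95 are considered significant by
default. The assembled per-gene report joins clusters, splice events,
annotation impacts, the isoform interaction network, enrichment results
and DE status into one JSON document.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .model import (
    DERecord,
    Cluster,
    DomainImpact,
    EnrichmentResult,
    IsoformNetwork,
    Locus,
    PTMImpact,
    SpliceEvent,
    ValidationError,
)


@dataclass
class DEFilterParams:
    ppde_threshold: float = 0.95
    strict: bool = True  # keep only ppde strictly greater than threshold

    def __post_init__(self) -> None:
        if not (0 <= self.ppde_threshold <= 1):
            raise ValidationError("ppde_threshold must be in [0, 1]")


def significant_de(records: list[DERecord], params: DEFilterParams | None = None) -> list[DERecord]:
    """DE records passing the PPDE significance rule (strictly greater by default)."""
    params = params or DEFilterParams()
    if params.strict:
        return [r for r in records if r.ppde > params.ppde_threshold]
    return [r for r in records if r.ppde >= params.ppde_threshold]


def strip_version(transcript_id: str) -> str:
    """Drop a trailing ".N" version suffix from a transcript id."""
    base, _, suffix = transcript_id.rpartition(".")
    if base and suffix.isdigit():
        return base
    return transcript_id


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _direction(log2fc: float) -> str:
    if log2fc > 0:
        return "up"
    if log2fc < 0:
        return "down"
    return "none"


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _event_span(ev: SpliceEvent) -> Optional[tuple[int, int]]:
    if ev.event_type == "insertion":
        if ev.canonical_anchor < 1:
            return None
        return (ev.canonical_anchor, ev.canonical_anchor)
    return (ev.canonical_start, ev.canonical_end)


def assemble_report(
    locus: Locus,
    clusters: list[Cluster],
    events_by_isoform: dict[str, list[SpliceEvent]],
    domain_impacts: list[DomainImpact],
    ptm_impacts: list[PTMImpact],
    network: Optional[IsoformNetwork],
    enrichments: Optional[list[EnrichmentResult]],
    de_records: Optional[list[DERecord]],
    de_params: DEFilterParams | None = None,
    parameters: Optional[dict] = None,
    input_digests: Optional[dict] = None,
) -> dict:
    """Join all per-locus results into the JSON report structure."""
    de_params = de_params or DEFilterParams()
    warnings: list[str] = []

    cluster_of = {m: c.cluster_id for c in clusters for m in c.member_ids}
    for iso in locus.isoform_ids:
        if iso not in cluster_of:
            raise ValidationError(f"isoform {iso!r} is not assigned to any cluster")

    de_by_transcript: dict[str, list[DERecord]] = {}
    if de_records is not None:
        locus_ids = {strip_version(i) for i in locus.isoform_ids}
        for rec in de_records:
            tid = strip_version(rec.transcript_id)
            if tid not in locus_ids:
                warnings.append(
                    f"DE transcript {rec.transcript_id!r} not found among locus isoforms"
                )
                continue
            de_by_transcript.setdefault(tid, []).append(rec)

    n_de_significant = 0
    isoform_blocks = []
    for rec in locus.isoforms:
        events = events_by_isoform.get(rec.isoform_id, [])
        ev_json = [
            {
                "event_type": e.event_type,
                "canonical_start": e.canonical_start,
                "canonical_end": e.canonical_end,
                "isoform_start": e.isoform_start,
                "isoform_end": e.isoform_end,
                "length": e.length,
            }
            for e in events
        ]
        dom_json = [
            {
                "domain_name": d.domain_name,
                "event_type": d.event_type,
                "overlap_start": d.overlap_start,
                "overlap_end": d.overlap_end,
                "overlap_length": d.overlap_length,
                "domain_fraction_affected": d.domain_fraction_affected,
                "insertion_inside": d.insertion_inside,
            }
            for d in domain_impacts
            if d.isoform_id == rec.isoform_id
        ]
        ptm_json = [
            {
                "position": p.position,
                "modification_type": p.modification_type,
                "status": p.status,
            }
            for p in ptm_impacts
            if p.isoform_id == rec.isoform_id
        ]
        block = {
            "isoform_id": rec.isoform_id,
            "cluster_id": cluster_of[rec.isoform_id],
            "is_canonical": rec.is_canonical,
            "length": len(rec.sequence),
            "events": ev_json,
            "domain_impacts": dom_json,
            "ptm_impacts": ptm_json,
        }
        if de_records is None:
            block["de"] = None
        else:
            matches = de_by_transcript.get(strip_version(rec.isoform_id), [])
            if not matches:
                block["de"] = []
                block["no_de_data"] = True
            else:
                entries = []
                significant_any = False
                for m in sorted(matches, key=lambda r: r.tissue):
                    sig = bool(significant_de([m], de_params))
                    significant_any = significant_any or sig
                    entries.append(
                        {
                            "tissue": m.tissue,
                            "log2fc": m.log2fc,
                            "ppde": m.ppde,
                            "significant": sig,
                            "direction": _direction(m.log2fc),
                        }
                    )
                block["de"] = entries
                if significant_any:
                    n_de_significant += 1
        isoform_blocks.append(block)

    edges_json = []
    n_affected = 0
    if network is not None:
        for acc in sorted(network.partitions):
            for e in network.partitions[acc]:
                affected_idx: list[int] = []
                if e.binding_affected and e.binding_region is not None:
                    for i, ev in enumerate(events_by_isoform.get(acc, [])):
                        span = _event_span(ev)
                        if span is not None and _overlaps(span, e.binding_region):
                            affected_idx.append(i)
                if e.binding_affected:
                    n_affected += 1
                edges_json.append(
                    {
                        "isoform_accession": e.isoform_accession,
                        "partner_id": e.partner_id,
                        "interaction_type": e.interaction_type,
                        "mi_score": e.mi_score,
                        "binding_start": e.binding_region[0] if e.binding_region else None,
                        "binding_end": e.binding_region[1] if e.binding_region else None,
                        "binding_affected": e.binding_affected,
                        "isoform_specific": e.isoform_specific,
                        "assumed_canonical": e.assumed_canonical,
                        "affected_event_indices": affected_idx,
                    }
                )

    enrichment_json = []
    if enrichments is not None:
        for r in enrichments:
            enrichment_json.append(
                {
                    "network_label": r.network_label,
                    "term_id": r.term_id,
                    "term_name": r.term_name,
                    "k": r.overlap_k,
                    "n": r.query_n,
                    "K": r.term_K,
                    "N": r.background_N,
                    "p_value": r.p_value,
                    "fdr": r.fdr,
                    "overlap_genes": list(r.overlap_genes),
                }
            )

    report = {
        "gene_symbol": locus.gene_symbol,
        "summary": {
            "n_isoforms": len(locus.isoforms),
            "n_clusters": len(clusters),
            "n_events": sum(len(b["events"]) for b in isoform_blocks),
            "n_de_significant": n_de_significant,
            "n_affected_edges": n_affected,
            "n_enriched_terms": len(enrichment_json),
        },
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "canonical_id": c.canonical_id,
                "member_ids": list(c.member_ids),
            }
            for c in clusters
        ],
        "isoforms": isoform_blocks,
        "network": {
            "disabled": network is None,
            "canonical_accession": network.canonical_accession if network else None,
            "edges": edges_json,
        },
        "enrichment": {
            "disabled": enrichments is None,
            "results": enrichment_json,
        },
        "provenance": {
            "tool_version": __version__,
            "parameters": parameters or {},
            "input_digests": input_digests or {},
            "warnings": warnings,
        },
    }
    return report
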