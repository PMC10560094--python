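"""End-to-end per-locus orchestration: cluster -> MSA -> events -> impacts
-> network -> ORA -> DE overlay -> report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import AlignParams, MSA, progressive_msa
from .clustering import ClusterParams, cluster_isoforms
from .events import EventParams, detect_events, variable_region_union
from .impact import classify_ptms, intersect_domains
from .model import (
    Cluster,
    DERecord,
    DomainAnnotation,
    DomainImpact,
    EnrichmentResult,
    GeneSetCollection,
    InteractionRecord,
    IsoformNetwork,
    Locus,
    PTMImpact,
    PTMSite,
    SpliceEvent,
)
from .network import NetworkFilters, filter_edges, flag_affected_bindings, partition_network
from .ora import OraParams, run_ora
from .overlay import DEFilterParams, assemble_report


@dataclass
class PipelineResult:
    locus: Locus
    clusters: list[Cluster]
    msas: dict[str, MSA]  # keyed by cluster_id
    events_by_isoform: dict[str, list[SpliceEvent]]
    variable_regions: dict[str, list[tuple[int, int]]]
    domain_impacts: list[DomainImpact] = field(default_factory=list)
    ptm_impacts: list[PTMImpact] = field(default_factory=list)
    network: Optional[IsoformNetwork] = None
    enrichments: Optional[list[EnrichmentResult]] = None
    report: dict = field(default_factory=dict)


def primary_cluster(clusters: list[Cluster], locus: Locus) -> Cluster:
    """The cluster holding the longest canonical; annotations are mapped to
    its canonical coordinate system."""
    return min(
        clusters,
        key=lambda c: (-len(locus.get(c.canonical_id).sequence), c.canonical_id),
    )


def run_pipeline(
    locus: Locus,
    domains: Optional[list[DomainAnnotation]] = None,
    ptms: Optional[list[PTMSite]] = None,
    interactions: Optional[list[InteractionRecord]] = None,
    gene_sets: Optional[GeneSetCollection] = None,
    de_records: Optional[list[DERecord]] = None,
    cluster_params: ClusterParams | None = None,
    align_params: AlignParams | None = None,
    event_params: EventParams | None = None,
    network_filters: NetworkFilters | None = None,
    ora_params: OraParams | None = None,
    de_params: DEFilterParams | None = None,
    canonical_override: str | None = None,
    parameters: Optional[dict] = None,
    input_digests: Optional[dict] = None,
) -> PipelineResult:
    """Run every enabled analysis stage on one locus and assemble the report.

    Annotation, network and enrichment stages are skipped (reported as
    disabled) when their inputs are absent.
    """
    cluster_params = cluster_params or ClusterParams()
    align_params = align_params or AlignParams()
    event_params = event_params or EventParams()
    de_params = de_params or DEFilterParams()

    clusters = cluster_isoforms(
        locus, cluster_params, align_params, canonical_override=canonical_override
    )

    msas: dict[str, MSA] = {}
    events_by_isoform: dict[str, list[SpliceEvent]] = {}
    variable_regions: dict[str, list[tuple[int, int]]] = {}
    for cluster in clusters:
        seqs = [(m, locus.get(m).sequence) for m in cluster.member_ids]
        msa = progressive_msa(seqs, cluster.canonical_id, align_params)
        msas[cluster.cluster_id] = msa
        for member in cluster.member_ids:
            if member == cluster.canonical_id:
                continue
            events = detect_events(msa, member, event_params)
            events_by_isoform[member] = events
            variable_regions[member] = variable_region_union(events)

    primary = primary_cluster(clusters, locus)

    domain_impacts: list[DomainImpact] = []
    ptm_impacts: list[PTMImpact] = []
    for member in primary.member_ids:
        if member == primary.canonical_id:
            continue
        events = events_by_isoform[member]
        if domains:
            domain_impacts.extend(intersect_domains(events, domains))
        if ptms:
            ptm_impacts.extend(classify_ptms(events, ptms, isoform_id=member))

    network: Optional[IsoformNetwork] = None
    if interactions is not None:
        filters = network_filters or NetworkFilters()
        known = frozenset(primary.member_ids)
        kept = filter_edges(
            interactions, filters,
            canonical_accession=primary.canonical_id, known_accessions=known,
        )
        edges = flag_affected_bindings(
            kept, variable_regions, primary.canonical_id, known_accessions=known
        )
        network = partition_network(edges, primary.canonical_id)

    enrichments: Optional[list[EnrichmentResult]] = None
    if network is not None and gene_sets is not None:
        ora_params = ora_params or OraParams()
        enrichments = run_ora(network, gene_sets, ora_params.background, mode="whole")
        enrichments += run_ora(network, gene_sets, ora_params.background, mode="per_isoform")

    report = assemble_report(
        locus, clusters, events_by_isoform, domain_impacts, ptm_impacts,
        network, enrichments, de_records, de_params,
        parameters=parameters, input_digests=input_digests,
    )
    return PipelineResult(
        locus, clusters, msas, events_by_isoform, variable_regions,
        domain_impacts, ptm_impacts, network, enrichments, report,
    )
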