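"""Intersection of splice events with domain intervals and PTM sites.

Both annotations live on the canonical coordinate system; intersections
use closed-interval arithmetic. Insertions have no canonical span, so they
impact a domain only informationally, when their anchor falls strictly
inside the domain. A PTM is *lost* when its position falls inside a
deletion, has *altered context* inside a divergent region, and is
*retained* otherwise; lost dominates altered context when spans were
merged.
"""

from __future__ import annotations

from .model import DomainAnnotation, DomainImpact, PTMImpact, PTMSite, SpliceEvent


def intersect_domains(
    events: list[SpliceEvent], domains: list[DomainAnnotation]
) -> list[DomainImpact]:
    """One impact record per (event, domain) pair with >= 1 residue overlap.

    Insertion anchors strictly inside a domain yield an informational
    record with zero overlap length and fraction 0.
    """
    impacts = []
    for ev in events:
        for dom in domains:
            if ev.event_type == "insertion":
                anchor = ev.canonical_anchor
                if dom.start < anchor < dom.end:
                    impacts.append(
                        DomainImpact(
                            ev.isoform_id, dom.domain_name, "insertion",
                            anchor, anchor, 0, 0.0, insertion_inside=True,
                        )
                    )
                continue
            start = max(ev.canonical_start, dom.start)
            end = min(ev.canonical_end, dom.end)
            if start > end:
                continue
            overlap = end - start + 1
            impacts.append(
                DomainImpact(
                    ev.isoform_id, dom.domain_name, ev.event_type,
                    start, end, overlap, overlap / dom.length,
                )
            )
    return impacts


def classify_ptms(
    events: list[SpliceEvent], ptms: list[PTMSite], isoform_id: str | None = None
) -> list[PTMImpact]:
    """Classify every PTM site for one isoform; exactly one record per site.

    The isoform id defaults to the (single) isoform the events belong to;
    it must be given explicitly when the event list is empty.
    """
    if isoform_id is None:
        ids = {ev.isoform_id for ev in events}
        if len(ids) != 1:
            raise ValueError("isoform_id is required unless events identify exactly one isoform")
        isoform_id = ids.pop()
    deletions = [
        (e.canonical_start, e.canonical_end) for e in events if e.event_type == "deletion"
    ]
    divergents = [
        (e.canonical_start, e.canonical_end) for e in events if e.event_type == "divergent"
    ]
    out = []
    for ptm in ptms:
        if any(s <= ptm.position <= e for s, e in deletions):
            status = "lost"
        elif any(s <= ptm.position <= e for s, e in divergents):
            status = "altered_context"
        else:
            status = "retained"
        out.append(PTMImpact(isoform_id, ptm.position, ptm.modification_type, status))
    return out
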