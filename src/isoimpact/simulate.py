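"""Synthetic loci with planted splice events and matching annotations.

Generates everything the pipeline consumes — isoform FASTA, domain and PTM
tables, an interaction table, gene sets, and a DE table — together with the
exact ground truth each stage is expected to recover. Sequences are random
over the 20-residue alphabet; events are planted with two guarantees that
make recovery well-posed:

* spacing: planted events are separated by more than merge_gap +
  min_divergent_run matching positions — across the whole locus, not just
  per isoform, because the progressive MSA couples isoforms through shared
  columns — so events can neither merge nor distort each other's gap
  placement;
* boundary uniqueness: the residues flanking a planted indel differ from
  the residues a gap shift would pair them with, so the optimal affine-gap
  alignment places every planted gap run at exactly one set of columns.

Divergent blocks replace each canonical residue with its highest-scoring
non-identical substitution: every planted divergent column is a guaranteed
mismatch, yet the block scores well enough ungapped that the optimal
alignment never fragments it into indels (a fully random replacement block
would score so poorly that gapped alignments win, making the planted
"divergent" label unrecoverable by any sensible aligner).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio.Align import substitution_matrices

from .model import (
    AMINO_ACIDS,
    DERecord,
    DomainAnnotation,
    DomainImpact,
    GeneSetCollection,
    InteractionRecord,
    IsoformRecord,
    Locus,
    PTMImpact,
    PTMSite,
    SpliceEvent,
    ValidationError,
)


def _similar_residue_table() -> dict[str, str]:
    """Most similar non-identical residue per residue (BLOSUM62, ties alphabetical)."""
    matrix = substitution_matrices.load("BLOSUM62")
    return {
        a: min((b for b in AMINO_ACIDS if b != a), key=lambda b: (-matrix[a, b], b))
        for a in AMINO_ACIDS
    }


_SIMILAR = _similar_residue_table()


class GenerationError(ValidationError):
    """A fixture spec violates the planting invariants (never silently adjusted)."""


@dataclass(frozen=True)
class PlannedEvent:
    """A planted event in canonical coordinates.

    position: first deleted/diverged canonical position, or for insertions
    the anchor (canonical position after which the block is inserted; 0 for
    an N-terminal insertion).
    """

    event_type: str
    position: int
    length: int


@dataclass
class FixtureSpec:
    seed: int = 1
    canonical_length: int = 300
    n_isoforms: int = 4
    # one planned-event list per alternative isoform (n_isoforms - 1 lists);
    # None = draw a random plan
    events_per_isoform: Optional[list[list[PlannedEvent]]] = None
    n_domains: int = 3
    n_ptms: int = 6
    n_interactions: int = 10
    n_genesets: int = 5
    fraction_binding_overlapping: float = 0.5
    de_tissues: tuple[str, ...] = ("Breast", "Lung")
    gene_symbol: str = "GENE1"
    min_divergent_run: int = 5
    merge_gap: int = 0


@dataclass
class GroundTruth:
    """Exact expected pipeline output for a generated fixture."""

    events: dict[str, list[SpliceEvent]]
    variable_regions: dict[str, list[tuple[int, int]]]
    domain_impacts: list[DomainImpact]
    ptm_impacts: list[PTMImpact]
    binding_affected: list[bool]  # per interaction record, file order
    ora_whole_overlap: dict[str, int]  # term id -> expected k in whole network
    de_significant: frozenset[str]  # isoform ids with any PPDE > 0.95

    def to_json(self) -> dict:
        return {
            "events": {
                iso: [
                    {
                        "event_type": e.event_type,
                        "canonical_start": e.canonical_start,
                        "canonical_end": e.canonical_end,
                        "isoform_start": e.isoform_start,
                        "isoform_end": e.isoform_end,
                        "length": e.length,
                    }
                    for e in evs
                ]
                for iso, evs in sorted(self.events.items())
            },
            "variable_regions": {
                iso: [list(r) for r in regions]
                for iso, regions in sorted(self.variable_regions.items())
            },
            "binding_affected": self.binding_affected,
            "ora_whole_overlap": dict(sorted(self.ora_whole_overlap.items())),
            "de_significant": sorted(self.de_significant),
        }


@dataclass
class FixtureBundle:
    spec_seed: int
    gene_symbol: str
    locus: Locus
    truth: GroundTruth
    domains: list[DomainAnnotation]
    ptms: list[PTMSite]
    interactions: list[InteractionRecord]
    gene_sets: GeneSetCollection
    de_records: list[DERecord]
    de_tissues: tuple[str, ...] = ()
    canonical_id: str = ""

    def write(self, outdir) -> dict[str, Path]:
        """Write the full fixture as 7 text files; byte-stable for a fixed seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "isoforms.fasta",
            "domains": outdir / "domains.tsv",
            "ptms": outdir / "ptms.tsv",
            "interactions": outdir / "interactions.tsv",
            "genesets": outdir / "genesets.gmt",
            "de": outdir / "de.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["fasta"], "w") as fh:
            for rec in self.locus.isoforms:
                fh.write(f">{rec.isoform_id}\n{rec.sequence}\n")
        with open(paths["domains"], "w") as fh:
            fh.write("domain_name\tstart\tend\n")
            for d in self.domains:
                fh.write(f"{d.domain_name}\t{d.start}\t{d.end}\n")
        with open(paths["ptms"], "w") as fh:
            fh.write("position\tmodification_type\n")
            for p in self.ptms:
                fh.write(f"{p.position}\t{p.modification_type}\n")
        with open(paths["interactions"], "w") as fh:
            fh.write("partner_id\tisoform_accession\tinteraction_type\tmi_score\tbinding_start\tbinding_end\n")
            for r in self.interactions:
                bs = str(r.binding_region[0]) if r.binding_region else ""
                be = str(r.binding_region[1]) if r.binding_region else ""
                fh.write(f"{r.partner_id}\t{r.isoform_accession}\t{r.interaction_type}\t{r.mi_score:.2f}\t{bs}\t{be}\n")
        with open(paths["genesets"], "w") as fh:
            for term_id in sorted(self.gene_sets.sets):
                name, members = self.gene_sets.sets[term_id]
                fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")
        with open(paths["de"], "w") as fh:
            fh.write("transcript_id\tgene_symbol\ttissue\tlog2fc\tppde\n")
            for r in self.de_records:
                fh.write(f"{r.transcript_id}\t{r.gene_symbol}\t{r.tissue}\t{r.log2fc:.2f}\t{r.ppde:.3f}\n")
        paths["truth"].write_text(json.dumps(self.truth.to_json(), indent=2) + "\n")
        return paths


# --- planning and validation --------------------------------------------------

def _event_canonical_span(ev: PlannedEvent) -> tuple[int, int]:
    if ev.event_type == "insertion":
        # an anchor sits between position and position + 1
        return (max(ev.position, 1), min(ev.position + 1, 10 ** 9))
    return (ev.position, ev.position + ev.length - 1)


def validate_plan(plan: list[PlannedEvent], spec: FixtureSpec) -> None:
    """Check the planting invariants; violations raise, never auto-fix."""
    min_sep = spec.merge_gap + spec.min_divergent_run
    for ev in plan:
        if ev.event_type not in ("insertion", "deletion", "divergent"):
            raise GenerationError(f"unknown planted event type {ev.event_type!r}")
        if ev.length < 1:
            raise GenerationError("planted events need length >= 1")
        if ev.event_type == "divergent" and ev.length < spec.min_divergent_run:
            raise GenerationError(
                f"divergent length {ev.length} below min_divergent_run {spec.min_divergent_run}"
            )
        if ev.event_type == "insertion":
            if not (0 <= ev.position <= spec.canonical_length):
                raise GenerationError(f"insertion anchor {ev.position} outside canonical")
        else:
            if not (1 <= ev.position and ev.position + ev.length - 1 <= spec.canonical_length):
                raise GenerationError(
                    f"{ev.event_type} [{ev.position},{ev.position + ev.length - 1}] outside canonical"
                )
    ordered = sorted(plan, key=lambda e: _event_canonical_span(e)[0])
    for prev, nxt in zip(ordered, ordered[1:]):
        gap = _event_canonical_span(nxt)[0] - _event_canonical_span(prev)[1] - 1
        if gap <= min_sep:
            raise GenerationError(
                f"planted events separated by {gap} positions; need > {min_sep}"
            )
    net = sum(
        e.length if e.event_type == "insertion" else (-e.length if e.event_type == "deletion" else 0)
        for e in plan
    )
    if net > 0:
        raise GenerationError(
            "planted plan must not make the alternative isoform longer than the canonical "
            "(canonical selection would pick the wrong representative)"
        )


def check_global_spacing(plans: dict[str, list[PlannedEvent]], spec: FixtureSpec) -> None:
    """Cross-isoform spacing: all planted events on the locus must be separated."""
    min_sep = spec.merge_gap + spec.min_divergent_run
    spans = sorted(
        (_event_canonical_span(ev), iso)
        for iso, plan in plans.items()
        for ev in plan
    )
    for ((_, prev_end), prev_iso), ((next_start, _), next_iso) in zip(spans, spans[1:]):
        if next_start - prev_end - 1 <= min_sep:
            raise GenerationError(
                f"planted events of {prev_iso!r} and {next_iso!r} separated by "
                f"{next_start - prev_end - 1} positions; need > {min_sep} across the locus"
            )


def _random_plan(
    rng: random.Random, spec: FixtureSpec, occupied: dict[str, list[PlannedEvent]]
) -> list[PlannedEvent]:
    """Draw one isoform's plan; rejection-sampled against the locus-wide spacing."""
    for _ in range(500):
        n_events = rng.randint(1, 2)
        plan: list[PlannedEvent] = []
        for _ in range(n_events):
            etype = rng.choice(("deletion", "insertion", "divergent"))
            if etype == "deletion":
                length = rng.randint(8, 25)
                pos = rng.randint(1, max(1, spec.canonical_length - length + 1))
            elif etype == "insertion":
                length = rng.randint(5, 12)
                pos = rng.randint(0, spec.canonical_length)
            else:
                length = rng.randint(spec.min_divergent_run, 15)
                pos = rng.randint(1, max(1, spec.canonical_length - length + 1))
            plan.append(PlannedEvent(etype, pos, length))
        # keep the isoform no longer than the canonical
        inserted = sum(e.length for e in plan if e.event_type == "insertion")
        deleted = sum(e.length for e in plan if e.event_type == "deletion")
        if inserted > deleted:
            length = rng.randint(inserted - deleted, inserted - deleted + 15)
            pos = rng.randint(1, max(1, spec.canonical_length - length + 1))
            plan.append(PlannedEvent("deletion", pos, length))
        try:
            validate_plan(plan, spec)
            check_global_spacing({**occupied, "_candidate": plan}, spec)
        except GenerationError:
            continue
        return sorted(plan, key=lambda e: _event_canonical_span(e)[0])
    raise GenerationError("could not draw a valid random event plan; spec too constrained")


def _fix_boundaries(
    canonical: list[str], plans: dict[str, list[PlannedEvent]], rng: random.Random
) -> None:
    """Resample canonical residues so every planted gap placement is unique.

    For a deletion of [s, e], a left shift of the gap run pairs position
    s-1 with e and a right shift pairs s with e+1; forcing those residue
    pairs to differ makes every shifted placement strictly worse (the
    substitution matrix's diagonal dominates its rows).
    """
    constraints: list[tuple[int, int]] = []  # (a, b) 1-based: canonical[a] != canonical[b]
    length = len(canonical)
    for plan in plans.values():
        for ev in plan:
            if ev.event_type != "deletion":
                continue
            s, e = ev.position, ev.position + ev.length - 1
            if s >= 2:
                constraints.append((s - 1, e))
            if e < length:
                constraints.append((e + 1, s))
    partners: dict[int, set[int]] = {}
    for a, b in constraints:
        partners.setdefault(b, set()).add(a)
        partners.setdefault(a, set()).add(b)
    for _ in range(100):
        dirty = False
        for a, b in constraints:
            if canonical[a - 1] == canonical[b - 1]:
                forbidden = {canonical[p - 1] for p in partners[b]}
                choices = [c for c in AMINO_ACIDS if c not in forbidden]
                canonical[b - 1] = rng.choice(choices)
                dirty = True
        if not dirty:
            return
    raise GenerationError("could not satisfy indel boundary-uniqueness constraints")


def _apply_plan(
    canonical: str, plan: list[PlannedEvent], rng: random.Random, isoform_id: str
) -> tuple[str, list[SpliceEvent]]:
    """Build the isoform sequence and its expected event list."""
    length = len(canonical)
    pieces: list[str] = []
    events: list[SpliceEvent] = []
    consumed = 0  # canonical prefix (0-based length) already emitted/skipped
    offset = 0  # isoform position - canonical position, left of the cursor
    for ev in plan:
        if ev.event_type == "deletion":
            s, e = ev.position, ev.position + ev.length - 1
            pieces.append(canonical[consumed:s - 1])
            consumed = e
            events.append(SpliceEvent(isoform_id, "deletion", s, e, None, None, ev.length))
            offset -= ev.length
        elif ev.event_type == "insertion":
            p = ev.position
            pieces.append(canonical[consumed:p])
            left = canonical[p - 1] if p >= 1 else None
            right = canonical[p] if p < length else None
            block = [rng.choice(AMINO_ACIDS) for _ in range(ev.length)]
            # boundary uniqueness: the block must not slide into the flanks
            if right is not None:
                while block[0] == right or (ev.length == 1 and left is not None and block[0] == left):
                    block[0] = rng.choice(AMINO_ACIDS)
            if left is not None and ev.length > 1:
                while block[-1] == left:
                    block[-1] = rng.choice(AMINO_ACIDS)
            if ev.length == 1 and right is None and left is not None:
                while block[0] == left:
                    block[0] = rng.choice(AMINO_ACIDS)
            pieces.append("".join(block))
            iso_start = p + offset + 1
            events.append(
                SpliceEvent(isoform_id, "insertion", p, p, iso_start,
                            iso_start + ev.length - 1, ev.length)
            )
            consumed = p
            offset += ev.length
        else:  # divergent: conservative, guaranteed-mismatch substitutions
            s, e = ev.position, ev.position + ev.length - 1
            pieces.append(canonical[consumed:s - 1])
            block = [_SIMILAR[canonical[pos]] for pos in range(s - 1, e)]
            pieces.append("".join(block))
            events.append(
                SpliceEvent(isoform_id, "divergent", s, e, s + offset, e + offset, ev.length)
            )
            consumed = e
    pieces.append(canonical[consumed:])
    return "".join(pieces), events


def _union(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _truth_variable_regions(events: list[SpliceEvent]) -> list[tuple[int, int]]:
    spans = []
    for ev in events:
        if ev.event_type == "insertion":
            if ev.canonical_anchor >= 1:
                spans.append((ev.canonical_anchor, ev.canonical_anchor))
        else:
            spans.append((ev.canonical_start, ev.canonical_end))
    return _union(spans)


def _truth_impacts(
    events_by_iso: dict[str, list[SpliceEvent]],
    domains: list[DomainAnnotation],
    ptms: list[PTMSite],
) -> tuple[list[DomainImpact], list[PTMImpact]]:
    dom_impacts: list[DomainImpact] = []
    ptm_impacts: list[PTMImpact] = []
    for iso, events in sorted(events_by_iso.items()):
        for ev in events:
            for dom in domains:
                if ev.event_type == "insertion":
                    if dom.start < ev.canonical_anchor < dom.end:
                        dom_impacts.append(
                            DomainImpact(iso, dom.domain_name, "insertion",
                                         ev.canonical_anchor, ev.canonical_anchor,
                                         0, 0.0, insertion_inside=True)
                        )
                    continue
                s = max(ev.canonical_start, dom.start)
                e = min(ev.canonical_end, dom.end)
                if s <= e:
                    dom_impacts.append(
                        DomainImpact(iso, dom.domain_name, ev.event_type,
                                     s, e, e - s + 1, (e - s + 1) / dom.length)
                    )
        for ptm in ptms:
            if any(
                ev.event_type == "deletion"
                and ev.canonical_start <= ptm.position <= ev.canonical_end
                for ev in events
            ):
                status = "lost"
            elif any(
                ev.event_type == "divergent"
                and ev.canonical_start <= ptm.position <= ev.canonical_end
                for ev in events
            ):
                status = "altered_context"
            else:
                status = "retained"
            ptm_impacts.append(PTMImpact(iso, ptm.position, ptm.modification_type, status))
    return dom_impacts, ptm_impacts


def _nonoverlapping_interval(
    rng: random.Random, length: int, regions: list[tuple[int, int]], width: int
) -> Optional[tuple[int, int]]:
    candidates = [
        s
        for s in range(1, length - width + 2)
        if all(s + width - 1 < rs or re_ < s for rs, re_ in regions)
    ]
    if not candidates:
        return None
    start = rng.choice(candidates)
    return (start, start + width - 1)


def generate_locus(spec: FixtureSpec) -> FixtureBundle:
    """Generate a locus with planted ground truth from a fixture spec.

    Deterministic for a fixed seed: the same spec produces byte-identical
    files from FixtureBundle.write.
    """
    rng = random.Random(spec.seed)
    if spec.n_isoforms < 1:
        raise GenerationError("need at least one isoform")
    L = spec.canonical_length
    gene = spec.gene_symbol
    ids = [f"{gene}-{i + 1:02d}" for i in range(spec.n_isoforms)]
    canonical_id = ids[0]

    if spec.events_per_isoform is not None:
        if len(spec.events_per_isoform) != spec.n_isoforms - 1:
            raise GenerationError(
                "events_per_isoform must hold one plan per alternative isoform"
            )
        plans = {
            ids[i + 1]: sorted(plan, key=lambda e: _event_canonical_span(e)[0])
            for i, plan in enumerate(spec.events_per_isoform)
        }
        for plan in plans.values():
            validate_plan(plan, spec)
        check_global_spacing(plans, spec)
    else:
        plans = {}
        for i in range(spec.n_isoforms - 1):
            plans[ids[i + 1]] = _random_plan(rng, spec, plans)

    canonical = [rng.choice(AMINO_ACIDS) for _ in range(L)]
    _fix_boundaries(canonical, plans, rng)
    canonical_seq = "".join(canonical)

    isoforms = [IsoformRecord(canonical_id, canonical_seq)]
    events_by_iso: dict[str, list[SpliceEvent]] = {}
    for iso in ids[1:]:
        seq, events = _apply_plan(canonical_seq, plans[iso], rng, iso)
        isoforms.append(IsoformRecord(iso, seq))
        events_by_iso[iso] = events
    locus = Locus(gene, isoforms)

    variable_regions = {
        iso: _truth_variable_regions(evs) for iso, evs in events_by_iso.items()
    }

    # annotations on the canonical coordinate system
    domains = []
    for d in range(spec.n_domains):
        width = rng.randint(20, min(60, L))
        start = rng.randint(1, L - width + 1)
        domains.append(DomainAnnotation(f"DOM{d + 1:02d}", start, start + width - 1))
    ptms = []
    mods = ("phosphorylation", "ubiquitination", "acetylation", "methylation")
    positions = sorted(rng.sample(range(1, L + 1), min(spec.n_ptms, L)))
    for i, pos in enumerate(positions):
        ptms.append(PTMSite(pos, mods[i % len(mods)]))

    dom_impacts, ptm_impacts = _truth_impacts(events_by_iso, domains, ptms)

    # interactions, planting the target fraction of affected binding regions
    partners = [f"PART{i + 1:02d}" for i in range(spec.n_interactions + 4)]
    interactions: list[InteractionRecord] = []
    affected_flags: list[bool] = []
    itypes = ("direct", "physical", "association")
    for i in range(spec.n_interactions):
        partner = partners[i]
        acc = rng.choice(ids)
        itype = itypes[i % 3]
        mi = round(rng.uniform(0.50, 0.99), 2)
        regions = variable_regions.get(acc, [])
        region = None
        affected = False
        if rng.random() < 0.7:  # most records carry a binding region
            if regions and rng.random() < spec.fraction_binding_overlapping:
                vs, ve = regions[rng.randrange(len(regions))]
                start = max(1, vs - 2)
                region = (start, min(L, start + 6))
                affected = True
            else:
                region = _nonoverlapping_interval(rng, L, regions, 7)
                affected = False
        interactions.append(InteractionRecord(partner, acc, itype, mi, region))
        affected_flags.append(affected)

    # gene sets: cover every partner so the default background is a superset
    all_partner_genes = sorted({r.partner_id for r in interactions})
    fillers = [f"BG{i + 1:03d}" for i in range(20)]
    sets: dict[str, tuple[str, frozenset[str]]] = {
        "TERM00": ("background universe", frozenset(all_partner_genes + fillers)),
    }
    for t in range(spec.n_genesets):
        size = rng.randint(3, 8)
        members = rng.sample(all_partner_genes + fillers, min(size, len(all_partner_genes + fillers)))
        if not members:
            continue
        sets[f"TERM{t + 1:02d}"] = (f"synthetic term {t + 1}", frozenset(members))
    gene_sets = GeneSetCollection(sets)
    whole_partners = set(all_partner_genes)
    ora_overlap = {
        tid: len(members & whole_partners)
        for tid, (_, members) in sets.items()
        if members & whole_partners
    }

    # DE table: a planted subset of isoforms is significant
    de_records: list[DERecord] = []
    significant: set[str] = set()
    for iso in ids:
        for tissue in spec.de_tissues:
            if rng.random() < 0.5:
                continue
            sig = rng.random() < 0.5
            ppde = round(rng.uniform(0.96, 0.999), 3) if sig else round(rng.uniform(0.2, 0.9), 3)
            log2fc = round(rng.uniform(-3, 3), 2)
            de_records.append(DERecord(iso, gene, tissue, log2fc, ppde))
            if ppde > 0.95:
                significant.add(iso)

    truth = GroundTruth(
        events=events_by_iso,
        variable_regions=variable_regions,
        domain_impacts=dom_impacts,
        ptm_impacts=ptm_impacts,
        binding_affected=affected_flags,
        ora_whole_overlap=ora_overlap,
        de_significant=frozenset(significant),
    )
    return FixtureBundle(
        spec.seed, gene, locus, truth, domains, ptms, interactions, gene_sets,
        de_records, spec.de_tissues, canonical_id,
    )


def prkacb_template_fixture(seed: int = 2023) -> FixtureBundle:
    """A synthetic locus shaped like a kinase-family case study.

    Sixteen isoforms of one gene: nine carry significant DE calls; five
    have C-terminal deletions overlapping a planted kinase-like domain;
    three of those deletions cover a binding region [210, 218] carrying a
    ubiquitination site at 214, producing exactly three affected
    interaction edges and three isoforms that lose the site. Sequences are
    synthetic; only the combinatorial structure mirrors the case study.
    """
    rng = random.Random(seed)
    gene = "PRKACB"
    L = 350
    ids = [f"{gene}-{i + 1:02d}" for i in range(16)]
    spec = FixtureSpec(seed=seed, canonical_length=L, n_isoforms=16, gene_symbol=gene)

    # five nested C-terminal deletions (the case-study structure; empirically
    # recoverable because the gap runs share the C-terminus) plus mutually
    # disjoint interior events; four isoforms are identical to the canonical
    plans: dict[str, list[PlannedEvent]] = {
        ids[1]: [PlannedEvent("deletion", 200, 151)],   # covers 214 and [210,218]
        ids[2]: [PlannedEvent("deletion", 205, 146)],   # covers 214 and [210,218]
        ids[3]: [PlannedEvent("deletion", 210, 141)],   # covers 214 and [210,218]
        ids[4]: [PlannedEvent("deletion", 230, 121)],   # C-terminal, misses 214
        ids[5]: [PlannedEvent("deletion", 240, 111)],   # C-terminal, misses 214
        ids[6]: [PlannedEvent("insertion", 10, 6), PlannedEvent("deletion", 20, 14)],
        ids[7]: [PlannedEvent("divergent", 41, 20)],
        ids[8]: [PlannedEvent("deletion", 68, 20)],
        ids[9]: [PlannedEvent("deletion", 95, 16)],
        ids[10]: [PlannedEvent("deletion", 118, 18)],
        ids[11]: [PlannedEvent("divergent", 143, 8), PlannedEvent("deletion", 158, 13)],
        ids[12]: [PlannedEvent("deletion", 178, 15)],
        ids[13]: [],
        ids[14]: [],
        ids[15]: [],
    }
    for plan in plans.values():
        validate_plan(plan, spec)
    check_global_spacing({k: v for k, v in plans.items() if k not in ids[1:6]}, spec)

    canonical = [rng.choice(AMINO_ACIDS) for _ in range(L)]
    _fix_boundaries(canonical, plans, rng)
    canonical_seq = "".join(canonical)
    isoforms = [IsoformRecord(ids[0], canonical_seq)]
    events_by_iso: dict[str, list[SpliceEvent]] = {}
    for iso in ids[1:]:
        seq, events = _apply_plan(canonical_seq, plans[iso], rng, iso)
        isoforms.append(IsoformRecord(iso, seq))
        events_by_iso[iso] = events
    locus = Locus(gene, isoforms)
    variable_regions = {
        iso: _truth_variable_regions(evs) for iso, evs in events_by_iso.items()
    }

    domains = [
        DomainAnnotation("regulatory-like", 10, 50),
        DomainAnnotation("kinase-like", 60, 300),
    ]
    ptms = [
        PTMSite(100, "phosphorylation"),
        PTMSite(214, "ubiquitination"),
        PTMSite(310, "phosphorylation"),
    ]
    dom_impacts, ptm_impacts = _truth_impacts(events_by_iso, domains, ptms)

    # three binding-region edges over [210,218], mediated by the isoforms
    # whose deletions cover it; the rest of the network is unaffected
    interactions = [
        InteractionRecord("PITX2", ids[1], "direct", 0.72, (210, 218)),
        InteractionRecord("PITX2", ids[2], "direct", 0.70, (210, 218)),
        InteractionRecord("PITX2", ids[3], "physical", 0.68, (210, 218)),
        InteractionRecord("AKAP11", ids[0], "physical", 0.81, (100, 110)),
        InteractionRecord("PRKAR1A", ids[0], "direct", 0.92, None),
        InteractionRecord("PRKAR2B", ids[0], "direct", 0.88, None),
        InteractionRecord("GSK3B", ids[0], "association", 0.61, None),
        InteractionRecord("CFTR", ids[11], "physical", 0.66, None),
        InteractionRecord("SMAD3", ids[11], "association", 0.58, None),
        InteractionRecord("PRKAR1A", ids[11], "direct", 0.77, None),
    ]
    affected_flags = [True, True, True, False, False, False, False, False, False, False]

    partners = sorted({r.partner_id for r in interactions})
    fillers = [f"BG{i + 1:03d}" for i in range(30)]
    sets = {
        "TERM00": ("background universe", frozenset(partners + fillers)),
        "TERM01": ("kinase regulatory complex", frozenset(["PRKAR1A", "PRKAR2B", "AKAP11", "BG001", "BG002"])),
        "TERM02": ("developmental transcription", frozenset(["PITX2", "SMAD3", "BG003", "BG004", "BG005"])),
        "TERM03": ("ion transport", frozenset(["CFTR", "BG006", "BG007", "BG008"])),
        "TERM04": ("signaling scaffold", frozenset(["AKAP11", "GSK3B", "SMAD3", "BG009", "BG010", "BG011"])),
    }
    gene_sets = GeneSetCollection(sets)
    whole = set(partners)
    ora_overlap = {
        tid: len(members & whole) for tid, (_, members) in sets.items() if members & whole
    }

    # nine DE-significant isoforms: six exclusively up, two up and down in
    # different tissues, one exclusively down; the rest below threshold
    de_records = [
        DERecord(ids[1], gene, "Breast", 2.10, 0.990),
        DERecord(ids[2], gene, "Lung", 1.80, 0.985),
        DERecord(ids[3], gene, "Colon", 1.40, 0.978),
        DERecord(ids[4], gene, "Breast", 2.60, 0.991),
        DERecord(ids[5], gene, "Prostate", 1.10, 0.972),
        DERecord(ids[6], gene, "Thyroid", 0.90, 0.969),
        DERecord(ids[7], gene, "Breast", 1.30, 0.982),
        DERecord(ids[7], gene, "Lung", -1.50, 0.975),
        DERecord(ids[8], gene, "Colon", 0.80, 0.968),
        DERecord(ids[8], gene, "Prostate", -0.70, 0.961),
        DERecord(ids[9], gene, "Stomach", -1.90, 0.988),
        DERecord(ids[10], gene, "Breast", 0.50, 0.700),
        DERecord(ids[11], gene, "Lung", -0.20, 0.420),
        DERecord(ids[12], gene, "Breast", 0.30, 0.880),
        DERecord(ids[0], gene, "Lung", 0.10, 0.300),
    ]
    significant = frozenset(r.transcript_id for r in de_records if r.ppde > 0.95)

    truth = GroundTruth(
        events=events_by_iso,
        variable_regions=variable_regions,
        domain_impacts=dom_impacts,
        ptm_impacts=ptm_impacts,
        binding_affected=affected_flags,
        ora_whole_overlap=ora_overlap,
        de_significant=significant,
    )
    return FixtureBundle(
        seed, gene, locus, truth, domains, ptms, interactions, gene_sets,
        de_records, ("Breast", "Lung", "Colon", "Prostate", "Thyroid", "Stomach"),
        ids[0],
    )
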