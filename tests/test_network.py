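import pytest

from isoimpact.model import InteractionRecord, ValidationError
from isoimpact.network import (
    NetworkFilters,
    filter_edges,
    flag_affected_bindings,
    partition_network,
    resolve_accession,
)

CANON = "G-01"
ALT = "G-02"
KNOWN = frozenset({CANON, ALT})


def rec(partner, acc, itype="direct", mi=0.9, region=None):
    return InteractionRecord(partner, acc, itype, mi, region)


class TestFilters:
    def test_mi_threshold_inclusive(self):
        records = [rec("A", CANON, mi=0.45), rec("B", CANON, mi=0.449)]
        kept = filter_edges(records, NetworkFilters(min_mi_score=0.45))
        assert [r.partner_id for r in kept] == ["A"]

    def test_type_filter(self):
        records = [rec("A", CANON, itype="direct"), rec("B", CANON, itype="association")]
        kept = filter_edges(records, NetworkFilters(allowed_types=frozenset({"direct"})))
        assert [r.partner_id for r in kept] == ["A"]

    def test_specificity_cap_ranks_by_mi_then_partner(self):
        records = [
            rec("P1", ALT, mi=0.7),
            rec("P2", ALT, mi=0.9),
            rec("P3", ALT, mi=0.7),
            rec("SHARED", CANON, mi=0.8),
            rec("SHARED", ALT, mi=0.6),  # not specific: canonical has SHARED
        ]
        kept = filter_edges(
            records,
            NetworkFilters(max_isoform_specific=2),
            canonical_accession=CANON,
            known_accessions=KNOWN,
        )
        partners = [(r.partner_id, r.isoform_accession) for r in kept]
        # keeps P2 (0.9) and P1 (0.7, tie with P3 broken by partner id);
        # the shared edge is never capped
        assert ("P2", ALT) in partners and ("P1", ALT) in partners
        assert ("P3", ALT) not in partners
        assert ("SHARED", ALT) in partners

    def test_unlimited_cap_keeps_everything(self):
        records = [rec(f"P{i}", ALT, mi=0.9) for i in range(5)]
        kept = filter_edges(records, NetworkFilters(), canonical_accession=CANON, known_accessions=KNOWN)
        assert len(kept) == 5

    def test_invalid_filters(self):
        with pytest.raises(ValidationError):
            NetworkFilters(allowed_types=frozenset())
        with pytest.raises(ValidationError):
            NetworkFilters(allowed_types=frozenset({"telepathic"}))
        with pytest.raises(ValidationError):
            NetworkFilters(max_isoform_specific=0)


class TestResolveAccession:
    def test_known_accession_kept(self):
        assert resolve_accession(rec("A", ALT), CANON, KNOWN) == (ALT, False)

    def test_unknown_falls_back_to_canonical(self):
        assert resolve_accession(rec("A", "Q99999"), CANON, KNOWN) == (CANON, True)


class TestFlagAffected:
    REGIONS = {ALT: [(100, 150)]}

    def test_overlapping_region_flagged(self):
        (edge,) = flag_affected_bindings([rec("A", ALT, region=(140, 160))], self.REGIONS, CANON, KNOWN)
        assert edge.binding_affected

    def test_disjoint_region_not_flagged(self):
        (edge,) = flag_affected_bindings([rec("A", ALT, region=(151, 160))], self.REGIONS, CANON, KNOWN)
        assert not edge.binding_affected

    def test_touching_endpoint_counts(self):
        (edge,) = flag_affected_bindings([rec("A", ALT, region=(150, 160))], self.REGIONS, CANON, KNOWN)
        assert edge.binding_affected

    def test_no_region_never_affected(self):
        (edge,) = flag_affected_bindings([rec("A", ALT)], self.REGIONS, CANON, KNOWN)
        assert not edge.binding_affected

    def test_unknown_accession_marked_assumed(self):
        (edge,) = flag_affected_bindings([rec("A", "Q9")], self.REGIONS, CANON, KNOWN)
        assert edge.assumed_canonical and edge.isoform_accession == CANON


class TestPartition:
    def test_isoform_specific_flagging(self):
        edges = flag_affected_bindings(
            [rec("SHARED", CANON), rec("SHARED", ALT), rec("ONLY", ALT)], {}, CANON, KNOWN
        )
        net = partition_network(edges, CANON)
        flags = {(e.isoform_accession, e.partner_id): e.isoform_specific for e in net.partitions[ALT]}
        assert flags[(ALT, "ONLY")] is True
        assert flags[(ALT, "SHARED")] is False

    def test_whole_network_dedup_prefers_higher_mi(self):
        edges = flag_affected_bindings(
            [rec("P", CANON, mi=0.6), rec("P", ALT, mi=0.9)], {}, CANON, KNOWN
        )
        net = partition_network(edges, CANON)
        assert len(net.whole_network) == 1
        assert net.whole_network[0].mi_score == 0.9

    def test_partners_helper(self):
        edges = flag_affected_bindings([rec("A", CANON), rec("B", ALT)], {}, CANON, KNOWN)
        net = partition_network(edges, CANON)
        assert net.partners(CANON) == frozenset({"A"})
        assert net.partners("missing") == frozenset()
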