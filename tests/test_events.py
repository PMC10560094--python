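import pytest

from isoimpact.align import MSA
from isoimpact.events import (
    EventParams,
    build_coordinate_map,
    classify_columns,
    detect_events,
    variable_region_union,
)
from isoimpact.model import DomainError, SpliceEvent, ValidationError


def msa_of(canon: str, iso: str) -> MSA:
    return MSA(["c", "i"], [canon, iso], "c")


class TestCoordinateMap:
    def test_maps_columns_to_positions(self):
        assert build_coordinate_map("A-CD-") == [1, None, 2, 3, None]

    def test_empty_row(self):
        assert build_coordinate_map("") == []


class TestClassifyColumns:
    def test_all_classes(self):
        # a third row keeps column 3 from being all-gap while the pair
        # under classification sees it as both_gap
        msa = MSA(["c", "i", "z"], ["AC-DW", "AW-D-", "AAEDW"], "c")
        assert classify_columns(msa, "i") == ["match", "mismatch", "both_gap", "match", "isoform_gap"]

    def test_canonical_gap(self):
        msa = msa_of("A-D", "AED")
        assert classify_columns(msa, "i") == ["match", "canonical_gap", "match"]

    def test_x_vs_x_is_match(self):
        # classification uses literal equality, unlike identity scoring
        msa = msa_of("AX", "AX")
        assert classify_columns(msa, "i") == ["match", "match"]

    def test_self_comparison_rejected(self):
        msa = msa_of("AC", "AC")
        with pytest.raises(DomainError):
            classify_columns(msa, "c")


class TestDetectEvents:
    def test_deletion(self):
        msa = msa_of("MKVLAGPT", "MKV---PT")
        (ev,) = detect_events(msa, "i")
        assert (ev.event_type, ev.canonical_start, ev.canonical_end, ev.length) == ("deletion", 4, 6, 3)
        assert ev.isoform_start is None and ev.isoform_end is None

    def test_insertion_anchor(self):
        msa = msa_of("MKV---PT", "MKVLAGPT")
        (ev,) = detect_events(msa, "i")
        assert ev.event_type == "insertion"
        assert ev.canonical_anchor == 3  # after canonical position 3
        assert (ev.isoform_start, ev.isoform_end, ev.length) == (4, 6, 3)

    def test_n_terminal_insertion_anchor_zero(self):
        msa = msa_of("---MKVPT", "LAGMKVPT")
        (ev,) = detect_events(msa, "i")
        assert ev.canonical_anchor == 0
        assert ev.isoform_start == 1

    def test_divergent_needs_min_run(self):
        msa = msa_of("MKVLAGPTW", "MKWITPPTW")  # mismatch run of 4 (cols 3-6)
        assert detect_events(msa, "i", EventParams(min_divergent_run=5)) == []
        (ev,) = detect_events(msa, "i", EventParams(min_divergent_run=4))
        assert (ev.event_type, ev.canonical_start, ev.canonical_end) == ("divergent", 3, 6)

    def test_merge_gap_joins_same_type_runs(self):
        msa = msa_of("MKVLAGPTW", "MK--A--TW")
        params = EventParams(merge_gap=0)
        evs = detect_events(msa, "i", params)
        assert [(e.event_type, e.canonical_start, e.canonical_end) for e in evs] == [
            ("deletion", 3, 4),
            ("deletion", 6, 7),
        ]
        (merged,) = detect_events(msa, "i", EventParams(merge_gap=1))
        assert (merged.event_type, merged.canonical_start, merged.canonical_end, merged.length) == (
            "deletion", 3, 7, 4,
        )

    def test_merge_does_not_join_across_other_events(self):
        # two deletion runs separated by a mismatch column never merge
        msa = msa_of("MKVLAGPTW", "MK--W--TW")
        evs = detect_events(msa, "i", EventParams(merge_gap=5))
        assert [e.event_type for e in evs] == ["deletion", "deletion"]

    def test_both_gap_columns_transparent(self):
        msa = MSA(
            ["c", "i", "z"],
            ["MK--VLAG", "MK--V-AG", "MKEEVLAG"],
            "c",
        )
        (ev,) = detect_events(msa, "i")
        assert (ev.event_type, ev.canonical_start, ev.canonical_end) == ("deletion", 4, 4)

    def test_sorted_by_canonical_coordinate(self):
        msa = msa_of("MKVLAGPTWY", "M--LAGP--Y")
        evs = detect_events(msa, "i")
        starts = [e.canonical_start for e in evs]
        assert starts == sorted(starts)

    def test_params_validated(self):
        with pytest.raises(ValidationError):
            EventParams(min_divergent_run=0)
        with pytest.raises(ValidationError):
            EventParams(merge_gap=-1)


class TestVariableRegionUnion:
    def test_merges_touching_intervals(self):
        events = [
            SpliceEvent("i", "deletion", 5, 9, None, None, 5),
            SpliceEvent("i", "divergent", 10, 14, 5, 9, 5),
        ]
        assert variable_region_union(events) == [(5, 14)]

    def test_insertion_contributes_anchor_point(self):
        events = [SpliceEvent("i", "insertion", 7, 7, 8, 10, 3)]
        assert variable_region_union(events) == [(7, 7)]

    def test_n_terminal_insertion_contributes_nothing(self):
        events = [SpliceEvent("i", "insertion", 0, 0, 1, 3, 3)]
        assert variable_region_union(events) == []

    def test_disjoint_kept_separate(self):
        events = [
            SpliceEvent("i", "deletion", 5, 9, None, None, 5),
            SpliceEvent("i", "deletion", 20, 24, None, None, 5),
        ]
        assert variable_region_union(events) == [(5, 9), (20, 24)]
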