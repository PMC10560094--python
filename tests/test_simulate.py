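import hashlib

import pytest

from isoimpact.simulate import (
    FixtureSpec,
    GenerationError,
    PlannedEvent,
    check_global_spacing,
    generate_locus,
    prkacb_template_fixture,
    validate_plan,
)

SPEC = FixtureSpec(seed=3, canonical_length=200, n_isoforms=3)


class TestValidatePlan:
    def test_valid_plan_passes(self):
        validate_plan([PlannedEvent("deletion", 20, 10), PlannedEvent("divergent", 60, 8)], SPEC)

    def test_short_divergent_rejected(self):
        with pytest.raises(GenerationError, match="min_divergent_run"):
            validate_plan([PlannedEvent("divergent", 20, 3)], SPEC)

    def test_out_of_range_rejected(self):
        with pytest.raises(GenerationError, match="outside"):
            validate_plan([PlannedEvent("deletion", 195, 10)], SPEC)

    def test_too_close_events_rejected(self):
        with pytest.raises(GenerationError, match="separated"):
            validate_plan(
                [PlannedEvent("deletion", 20, 10), PlannedEvent("deletion", 32, 5)], SPEC
            )

    def test_net_growth_rejected(self):
        with pytest.raises(GenerationError, match="longer"):
            validate_plan([PlannedEvent("insertion", 50, 6)], SPEC)

    def test_unknown_type_rejected(self):
        with pytest.raises(GenerationError, match="unknown"):
            validate_plan([PlannedEvent("duplication", 20, 5)], SPEC)


def test_global_spacing_across_isoforms():
    plans = {
        "a": [PlannedEvent("deletion", 20, 10)],
        "b": [PlannedEvent("deletion", 33, 10)],  # 3 positions away from a's event
    }
    with pytest.raises(GenerationError, match="across the locus"):
        check_global_spacing(plans, SPEC)


class TestGenerateLocus:
    def test_deterministic_bundles(self, tmp_path):
        digests = []
        for d in ("one", "two"):
            paths = generate_locus(FixtureSpec(seed=42)).write(tmp_path / d)
            digests.append(
                {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}
            )
        assert digests[0] == digests[1]

    def test_different_seeds_differ(self):
        a = generate_locus(FixtureSpec(seed=1))
        b = generate_locus(FixtureSpec(seed=2))
        assert a.locus.get(a.canonical_id).sequence != b.locus.get(b.canonical_id).sequence

    def test_canonical_is_longest(self):
        bundle = generate_locus(FixtureSpec(seed=5, n_isoforms=5))
        canon_len = len(bundle.locus.get(bundle.canonical_id).sequence)
        assert all(len(r.sequence) <= canon_len for r in bundle.locus.isoforms)

    def test_truth_lengths_consistent(self):
        bundle = generate_locus(FixtureSpec(seed=9, n_isoforms=4))
        canonical = bundle.locus.get(bundle.canonical_id).sequence
        for iso, events in bundle.truth.events.items():
            net = sum(
                e.length if e.event_type == "insertion"
                else (-e.length if e.event_type == "deletion" else 0)
                for e in events
            )
            assert len(bundle.locus.get(iso).sequence) == len(canonical) + net

    def test_explicit_plans_are_honoured(self):
        spec = FixtureSpec(
            seed=4,
            canonical_length=100,
            n_isoforms=2,
            events_per_isoform=[[PlannedEvent("deletion", 30, 12)]],
        )
        bundle = generate_locus(spec)
        (ev,) = bundle.truth.events["GENE1-02"]
        assert (ev.event_type, ev.canonical_start, ev.canonical_end) == ("deletion", 30, 41)

    def test_plan_count_must_match_isoforms(self):
        with pytest.raises(GenerationError, match="one plan per alternative"):
            generate_locus(FixtureSpec(seed=1, n_isoforms=3, events_per_isoform=[[]]))

    def test_files_written(self, tmp_path):
        paths = generate_locus(FixtureSpec(seed=8)).write(tmp_path)
        assert sorted(p.name for p in paths.values()) == sorted(
            ["isoforms.fasta", "domains.tsv", "ptms.tsv", "interactions.tsv",
             "genesets.gmt", "de.tsv", "truth.json"]
        )
        for p in paths.values():
            assert p.stat().st_size > 0


class TestTemplateFixture:
    def test_shape(self, template_bundle):
        b = template_bundle
        assert len(b.locus.isoforms) == 16
        assert len(b.truth.de_significant) == 9
        assert sum(b.truth.binding_affected) == 3

    def test_template_deterministic(self, template_bundle):
        again = prkacb_template_fixture()
        assert [r.sequence for r in again.locus.isoforms] == [
            r.sequence for r in template_bundle.locus.isoforms
        ]
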