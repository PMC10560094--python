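import random

import pytest

from isoimpact.clustering import (
    ClusterParams,
    cluster_isoforms,
    pairwise_identity,
    select_canonical,
)
from isoimpact.model import AMINO_ACIDS, Cluster, DomainError, IsoformRecord, Locus, ValidationError


def make_locus(seqs: dict[str, str], gene="G") -> Locus:
    return Locus(gene, [IsoformRecord(k, v) for k, v in seqs.items()])


class TestPairwiseIdentity:
    def test_identical(self, align_params):
        assert pairwise_identity("MKVLA", "MKVLA", align_params) == 1.0

    def test_symmetric(self, align_params):
        rng = random.Random(3)
        for _ in range(20):
            a = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 15)))
            b = "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(1, 15)))
            assert pairwise_identity(a, b, align_params) == pytest.approx(
                pairwise_identity(b, a, align_params)
            )

    def test_subsequence_full_identity(self, align_params):
        # the denominator is the shorter sequence, matching identity-clustering tools
        assert pairwise_identity("MKVLITAGPT", "MKVLAGPT", align_params) == 1.0

    def test_empty_rejected(self, align_params):
        with pytest.raises(DomainError):
            pairwise_identity("", "A", align_params)


class TestClusterIsoforms:
    def test_partition_property(self, align_params):
        locus = make_locus({"a": "MKVLITAGPT", "b": "MKVLAGPT", "c": "WWYFHHWWYF"})
        clusters = cluster_isoforms(locus, ClusterParams(), align_params)
        assigned = [m for c in clusters for m in c.member_ids]
        assert sorted(assigned) == sorted(locus.isoform_ids)
        assert len(assigned) == len(set(assigned))

    def test_dissimilar_sequences_split(self, align_params):
        locus = make_locus({"a": "MKVLITAGPT", "b": "WWYFHHWWYF"})
        clusters = cluster_isoforms(locus, ClusterParams(), align_params)
        assert len(clusters) == 2

    def test_threshold_monotone(self, align_params):
        locus_seqs = {"a": "MKVLITAGPTREPLDS", "b": "MKVLITAGPT", "c": "MKVAITAGPT"}
        n_by_threshold = []
        for t in (0.3, 0.6, 0.95, 1.0):
            locus = make_locus(dict(locus_seqs))
            clusters = cluster_isoforms(locus, ClusterParams(identity_threshold=t), align_params)
            n_by_threshold.append(len(clusters))
        assert n_by_threshold == sorted(n_by_threshold)

    def test_canonical_is_longest_tie_by_id(self, align_params):
        locus = make_locus({"b": "MKVLA", "a": "MKVLA"})
        clusters = cluster_isoforms(locus, ClusterParams(), align_params)
        assert len(clusters) == 1
        assert clusters[0].canonical_id == "a"
        assert clusters[0].cluster_id == "G(a)"

    def test_fills_assignments_and_flags(self, align_params):
        locus = make_locus({"a": "MKVLITAGPT", "b": "MKVLAGPT"})
        clusters = cluster_isoforms(locus, ClusterParams(), align_params)
        assert locus.cluster_assignments == {"a": clusters[0].cluster_id, "b": clusters[0].cluster_id}
        assert locus.get("a").is_canonical and not locus.get("b").is_canonical

    def test_empty_locus_rejected(self, align_params):
        with pytest.raises(DomainError):
            cluster_isoforms(Locus("G", []), ClusterParams(), align_params)

    def test_threshold_range_enforced(self):
        with pytest.raises(ValidationError):
            ClusterParams(identity_threshold=0.0)
        with pytest.raises(ValidationError):
            ClusterParams(identity_threshold=1.5)


class TestSelectCanonical:
    def test_override_wins_when_member(self):
        locus = make_locus({"a": "MKVLITAGPT", "b": "MKVLAGPT"})
        cluster = Cluster("G(a)", ("a", "b"), "a")
        assert select_canonical(cluster, locus, override="b") == "b"

    def test_override_ignored_when_not_member(self):
        locus = make_locus({"a": "MKVLITAGPT", "b": "MKVLAGPT"})
        cluster = Cluster("G(a)", ("a", "b"), "a")
        assert select_canonical(cluster, locus, override="z") == "a"
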