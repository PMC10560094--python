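"""Identity-based grouping of a locus's isoforms and canonical selection.

One genetic locus can encode substantially different proteins (overlapping
reading frames, locus-specific products), and aligning those together would
report divergence that has nothing to do with splicing. Isoforms are
therefore grouped greedily by global-alignment identity before any MSA is
built, mirroring the longest-first single-representative strategy of
identity-clustering tools: the identity denominator is the shorter
sequence's length, and each cluster is represented by its founding (longest)
member.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import AlignParams, global_align, identity_fraction
from .model import Cluster, DomainError, Locus, ValidationError


@dataclass
class ClusterParams:
    identity_threshold: float = 0.6

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValidationError("identity_threshold must be in (0, 1]")


def pairwise_identity(seq_a: str, seq_b: str, align_params: AlignParams | None = None) -> float:
    """Fraction of identical aligned residue pairs over the shorter length.

    Symmetric in its arguments; ``X`` never counts as an identity.
    """
    if not seq_a or not seq_b:
        raise DomainError("pairwise_identity requires non-empty sequences")
    aligned_a, aligned_b, _ = global_align(seq_a, seq_b, align_params)
    return identity_fraction(aligned_a, aligned_b, seq_a, seq_b)


def cluster_isoforms(
    locus: Locus,
    params: ClusterParams | None = None,
    align_params: AlignParams | None = None,
    canonical_override: str | None = None,
) -> list[Cluster]:
    """Greedy longest-first clustering of a locus's isoforms.

    Isoforms are visited by descending length (ties by ascending id); each
    joins the first existing cluster whose representative reaches the
    identity threshold, else founds a new cluster. Cluster ids are
    "GENE(canonical_id)" with the canonical chosen by select_canonical.
    Fills locus.cluster_assignments and sets is_canonical flags.
    """
    params = params or ClusterParams()
    if not locus.isoforms:
        raise DomainError("locus has no isoforms")
    order = sorted(locus.isoforms, key=lambda r: (-len(r.sequence), r.isoform_id))
    reps: list[str] = []  # representative (founder) sequence per cluster
    members: list[list[str]] = []
    for rec in order:
        for ci, rep in enumerate(reps):
            if pairwise_identity(rec.sequence, rep, align_params) >= params.identity_threshold:
                members[ci].append(rec.isoform_id)
                break
        else:
            reps.append(rec.sequence)
            members.append([rec.isoform_id])

    clusters = []
    for mem in members:
        provisional = Cluster("", tuple(mem), mem[0])
        canonical = select_canonical(provisional, locus, override=canonical_override)
        cluster_id = f"{locus.gene_symbol}({canonical})"
        clusters.append(Cluster(cluster_id, tuple(mem), canonical))

    locus.cluster_assignments = {
        m: c.cluster_id for c in clusters for m in c.member_ids
    }
    for rec in locus.isoforms:
        rec.is_canonical = any(rec.isoform_id == c.canonical_id for c in clusters)
    return clusters


def select_canonical(cluster: Cluster, locus: Locus, override: str | None = None) -> str:
    """The cluster's canonical member: longest sequence, ties by smallest id.

    An override id pins the canonical if it is a member of this cluster.
    """
    if not cluster.member_ids:
        raise DomainError("cluster has no members")
    if override is not None and override in cluster.member_ids:
        return override
    return min(
        cluster.member_ids,
        key=lambda mid: (-len(locus.get(mid).sequence), mid),
    )
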