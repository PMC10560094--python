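"""Pairwise global alignment and progressive multiple sequence alignment.

A self-contained replacement for an external MSA tool at the per-cluster
scale this pipeline works at: Needleman–Wunsch/Gotoh affine-gap pairwise
alignment (BLOSUM62, gap open 10, gap extend 1 by default), and a
progressive MSA built over a UPGMA guide tree on pairwise-identity
distances with average-of-pairs profile–profile merging ("once a gap, always a
gap"). An ingest path validates alignments produced by any external
aligner against the cluster's input sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._gotoh import DIAG, LEFT, UP, gotoh_align
from .model import ALPHABET, DomainError, FormatError, ValidationError

GAP = "-"

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def _load_matrix(name: str) -> np.ndarray:
    """Return the named substitution matrix restricted to the package alphabet."""
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ValidationError(f"unknown substitution matrix {name!r}") from exc
    sub = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            sub[i, j] = mat[a, b]
    if not np.array_equal(sub, sub.T):
        raise ValidationError(f"substitution matrix {name!r} is not symmetric")
    return sub


@dataclass
class AlignParams:
    """Scoring parameters for pairwise and progressive alignment.

    gap cost for a run of length L = gap_open + L * gap_extend, charged
    once per gap run.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValidationError("require gap_open >= gap_extend >= 0")
        self._matrix = _load_matrix(self.matrix_name)

    @property
    def matrix(self) -> np.ndarray:
        return self._matrix


@dataclass
class MSA:
    """A gapped multiple alignment of one cluster's isoforms."""

    row_ids: list[str]
    rows: list[str]
    canonical_row_id: str

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValidationError("row_ids and rows differ in length")
        if self.canonical_row_id not in self.row_ids:
            raise ValidationError(f"canonical row {self.canonical_row_id!r} not in MSA")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValidationError("MSA rows have unequal lengths")
        if self.rows and len(self.rows[0]) > 0:
            for col in range(len(self.rows[0])):
                if all(r[col] == GAP for r in self.rows):
                    raise ValidationError(f"all-gap column at {col + 1}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.row_ids.index(row_id)]
        except ValueError:
            raise KeyError(row_id) from None

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")


def _encode(seq: str, context: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise DomainError(f"{context}: residue {exc.args[0]!r} absent from the substitution matrix") from None


def global_align(a: str, b: str, params: AlignParams | None = None) -> tuple[str, str, int]:
    """Optimal global alignment of two sequences under affine gap costs.

    Returns (aligned_a, aligned_b, score). Traceback ties are resolved
    deterministically (diagonal, then gap-in-b, then gap-in-a).
    """
    params = params or AlignParams()
    if not a and not b:
        return "", "", 0
    ia = _encode(a, "sequence a")
    ib = _encode(b, "sequence b")
    scores = params.matrix[np.ix_(ia, ib)] if (len(a) and len(b)) else np.zeros((len(a), len(b)))
    score, moves = gotoh_align(scores, params.gap_open, params.gap_extend)
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for mv in moves:
        if mv == DIAG:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif mv == UP:
            out_a.append(a[i])
            out_b.append(GAP)
            i += 1
        else:
            out_a.append(GAP)
            out_b.append(b[j])
            j += 1
    return "".join(out_a), "".join(out_b), int(round(score))


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Residue counts per column, gaps excluded; shape (width, |alphabet|)."""
    width = len(rows[0])
    counts = np.zeros((width, len(ALPHABET)))
    for row in rows:
        for col, ch in enumerate(row):
            if ch != GAP:
                counts[col, _AA_INDEX[ch]] += 1
    return counts


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], params: AlignParams
) -> tuple[list[str], list[str]]:
    """Align two profiles by average-of-pairs column scores.

    Residue-gap pairs score 0 and are excluded from the average; averaging
    (rather than summing) keeps column scores on the same scale as the gap
    penalties regardless of profile depth, so deep profiles cannot buy
    spurious gaps with accumulated match bonuses.
    """
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    scores = (ca @ params.matrix) @ cb.T
    pairs = np.outer(ca.sum(axis=1), cb.sum(axis=1))
    scores = np.divide(scores, pairs, out=np.zeros_like(scores), where=pairs > 0)
    _, moves = gotoh_align(scores, params.gap_open, params.gap_extend)
    na, nb = len(rows_a), len(rows_b)
    out_a: list[list[str]] = [[] for _ in range(na)]
    out_b: list[list[str]] = [[] for _ in range(nb)]
    i = j = 0
    for mv in moves:
        if mv == DIAG:
            for k in range(na):
                out_a[k].append(rows_a[k][i])
            for k in range(nb):
                out_b[k].append(rows_b[k][j])
            i += 1
            j += 1
        elif mv == UP:
            for k in range(na):
                out_a[k].append(rows_a[k][i])
            for k in range(nb):
                out_b[k].append(GAP)
            i += 1
        else:
            for k in range(na):
                out_a[k].append(GAP)
            for k in range(nb):
                out_b[k].append(rows_b[k][j])
            j += 1
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _drop_all_gap_columns(ids: list[str], rows: list[str]) -> list[str]:
    if not rows:
        return rows
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    return ["".join(r[c] for c in keep) for r in rows]


def identity_fraction(aligned_a: str, aligned_b: str, a: str, b: str) -> float:
    """Identity under the shorter-sequence denominator; X never counts as identical."""
    ident = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x != GAP and x != "X"
    )
    return ident / min(len(a), len(b))


def progressive_msa(
    sequences: list[tuple[str, str]],
    canonical_id: str,
    params: AlignParams | None = None,
) -> MSA:
    """Progressive multiple alignment over a UPGMA guide tree.

    The guide tree is built on 1 - pairwise identity; profiles are merged
    bottom-up with average-of-pairs scoring. The result is invariant to the
    order sequences are supplied in, up to row ordering.
    """
    params = params or AlignParams()
    if not sequences:
        raise DomainError("progressive_msa requires at least one sequence")
    ids = [sid for sid, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids")
    if canonical_id not in ids:
        raise DomainError(f"canonical id {canonical_id!r} not among input sequences")
    for sid, seq in sequences:
        if not seq:
            raise DomainError(f"empty sequence for {sid!r}")

    if len(sequences) == 1:
        return MSA([ids[0]], [sequences[0][1]], canonical_id)

    # canonical processing order so the guide tree (and hence the columns)
    # does not depend on input order
    order = sorted(range(len(sequences)), key=lambda k: ids[k])
    sorted_ids = [ids[k] for k in order]
    sorted_seqs = [sequences[k][1] for k in order]

    n = len(sorted_seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aa, bb, _ = global_align(sorted_seqs[i], sorted_seqs[j], params)
            d = 1.0 - identity_fraction(aa, bb, sorted_seqs[i], sorted_seqs[j])
            dist[i, j] = dist[j, i] = d

    tree = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, tuple[list[str], list[str]]] = {
        i: ([sorted_ids[i]], [sorted_seqs[i]]) for i in range(n)
    }
    for k, (left, right, _, _) in enumerate(tree):
        a, b = int(left), int(right)
        if a > b:
            a, b = b, a
        ids_a, rows_a = profiles.pop(a)
        ids_b, rows_b = profiles.pop(b)
        merged_a, merged_b = _merge_profiles(rows_a, rows_b, params)
        profiles[n + k] = (ids_a + ids_b, merged_a + merged_b)

    (final_ids, final_rows), = profiles.values()
    final_rows = _drop_all_gap_columns(final_ids, final_rows)
    by_id = dict(zip(final_ids, final_rows))
    out_rows = [by_id[i] for i in ids]  # restore input row order
    msa = MSA(list(ids), out_rows, canonical_id)
    for sid, seq in sequences:
        if msa.degapped(sid) != seq:
            raise ValidationError(f"alignment does not preserve sequence {sid!r}")
    return msa


def write_aligned_fasta(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{sid}\n{row}\n")


def external_aligner_ingest(path, expected: list[tuple[str, str]], canonical_id: str) -> MSA:
    """Validate an externally produced aligned FASTA against the cluster inputs.

    Any mismatch with the input sequences is an error, not a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    got = {r.id: str(r.seq).upper() for r in records}
    if len(got) != len(records):
        raise FormatError("duplicate ids in aligned FASTA")
    expected_map = dict(expected)
    missing = sorted(set(expected_map) - set(got))
    if missing:
        raise ValidationError(f"aligned file is missing isoform(s): {', '.join(missing)}")
    extra = sorted(set(got) - set(expected_map))
    if extra:
        raise ValidationError(f"aligned file has unexpected isoform(s): {', '.join(extra)}")
    widths = {len(s) for s in got.values()}
    if len(widths) > 1:
        raise ValidationError("aligned rows have unequal lengths")
    for sid, seq in expected_map.items():
        degapped = got[sid].replace(GAP, "")
        if degapped != seq:
            offset = next(
                (i + 1 for i, (x, y) in enumerate(zip(degapped, seq)) if x != y),
                min(len(degapped), len(seq)) + 1,
            )
            raise ValidationError(
                f"row {sid!r}: degapped sequence differs from input at position {offset}"
            )
    ids = [sid for sid, _ in expected]
    rows = _drop_all_gap_columns(ids, [got[i] for i in ids])
    return MSA(ids, rows, canonical_id)
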