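"""Splice-event detection: classify MSA columns against the canonical row
and merge them into insertion / deletion / divergent events.

An alternative isoform's row is compared column-by-column with the
canonical row. Maximal runs of isoform gaps become deletions, maximal runs
of canonical gaps become insertions (anchored after the last preceding
canonical position), and maximal runs of mismatching residues of at least
``min_divergent_run`` columns become divergent events; shorter mismatch
runs are treated as point substitutions, outside the splice-event model.
Columns gapped in both rows carry no information for the pair and are
transparent: they neither break runs nor contribute length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .align import GAP, MSA
from .model import DomainError, SpliceEvent, ValidationError

COLUMN_CLASSES = ("match", "mismatch", "canonical_gap", "isoform_gap", "both_gap")

_EVENT_ORDER = {"insertion": 0, "deletion": 1, "divergent": 2}


@dataclass
class EventParams:
    min_divergent_run: int = 5
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.min_divergent_run < 1:
            raise ValidationError("min_divergent_run must be >= 1")
        if self.merge_gap < 0:
            raise ValidationError("merge_gap must be >= 0")


def build_coordinate_map(row: str) -> list[Optional[int]]:
    """Map each alignment column (0-based index) to the 1-based sequence
    position it holds, or None for gap columns."""
    out: list[Optional[int]] = []
    pos = 0
    for ch in row:
        if ch == GAP:
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def classify_columns(msa: MSA, isoform_id: str) -> list[str]:
    """Per-column class of an isoform row relative to the canonical row."""
    if isoform_id == msa.canonical_row_id:
        raise DomainError("cannot classify the canonical row against itself")
    canon = msa.row(msa.canonical_row_id)
    iso = msa.row(isoform_id)
    classes = []
    for c, i in zip(canon, iso):
        if c == GAP and i == GAP:
            classes.append("both_gap")
        elif c == GAP:
            classes.append("canonical_gap")
        elif i == GAP:
            classes.append("isoform_gap")
        elif c == i:
            classes.append("match")
        else:
            classes.append("mismatch")
    return classes


def _runs(classes: list[str]) -> list[tuple[str, list[int]]]:
    """Maximal runs of equal class over non-both_gap columns.

    Returns (class, column indices); both_gap columns are transparent and
    never appear in any run.
    """
    runs: list[tuple[str, list[int]]] = []
    for col, cls in enumerate(classes):
        if cls == "both_gap":
            continue
        if runs and runs[-1][0] == cls:
            runs[-1][1].append(col)
        else:
            runs.append((cls, [col]))
    return runs


def detect_events(msa: MSA, isoform_id: str, params: EventParams | None = None) -> list[SpliceEvent]:
    """Merged splice events of one isoform relative to the canonical row."""
    params = params or EventParams()
    classes = classify_columns(msa, isoform_id)
    canon_map = build_coordinate_map(msa.row(msa.canonical_row_id))
    iso_map = build_coordinate_map(msa.row(isoform_id))

    runs = _runs(classes)
    # keep only event-forming runs, tagged with their type
    tagged: list[tuple[str, list[int]]] = []
    for cls, cols in runs:
        if cls == "isoform_gap":
            tagged.append(("deletion", cols))
        elif cls == "canonical_gap":
            tagged.append(("insertion", cols))
        elif cls == "mismatch" and len(cols) >= params.min_divergent_run:
            tagged.append(("divergent", cols))

    # merge same-type runs separated by <= merge_gap match columns
    merged: list[tuple[str, list[int]]] = []
    for etype, cols in tagged:
        if merged and merged[-1][0] == etype:
            prev_cols = merged[-1][1]
            between = [
                classes[c]
                for c in range(prev_cols[-1] + 1, cols[0])
                if classes[c] != "both_gap"
            ]
            if all(b == "match" for b in between) and len(between) <= params.merge_gap:
                prev_cols.extend(cols)
                continue
        merged.append((etype, cols))

    events = []
    for etype, cols in merged:
        length = len(cols)
        if etype == "deletion":
            cstart = canon_map[cols[0]]
            cend = canon_map[cols[-1]]
            events.append(
                SpliceEvent(isoform_id, "deletion", cstart, cend, None, None, length)
            )
        elif etype == "insertion":
            # anchor: last canonical position before the run (0 at N-terminus)
            anchor = 0
            for c in range(cols[0] - 1, -1, -1):
                if canon_map[c] is not None:
                    anchor = canon_map[c]
                    break
            events.append(
                SpliceEvent(
                    isoform_id, "insertion", anchor, anchor,
                    iso_map[cols[0]], iso_map[cols[-1]], length,
                )
            )
        else:
            events.append(
                SpliceEvent(
                    isoform_id, "divergent",
                    canon_map[cols[0]], canon_map[cols[-1]],
                    iso_map[cols[0]], iso_map[cols[-1]], length,
                )
            )
    events.sort(key=lambda e: (e.canonical_start, _EVENT_ORDER[e.event_type]))
    return events


def variable_region_union(events: list[SpliceEvent]) -> list[tuple[int, int]]:
    """Disjoint, sorted canonical intervals covered by splicing variation.

    Deletion and divergent events contribute their canonical spans;
    insertions contribute their single-point anchors (an N-terminal anchor
    of 0 is not a canonical position and contributes nothing). Touching or
    overlapping intervals are merged.
    """
    spans = []
    for ev in events:
        if ev.event_type == "insertion":
            if ev.canonical_anchor >= 1:
                spans.append((ev.canonical_anchor, ev.canonical_anchor))
        else:
            spans.append((ev.canonical_start, ev.canonical_end))
    spans.sort()
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]
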