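"""Readers and writers for all external formats.

Inputs: protein FASTA (one record per transcript isoform), domain and PTM
TSVs in canonical coordinates, a MITAB-lite interaction TSV, a GMT gene-set
file, and a transcript differential-expression TSV. TSVs must carry a
header row; column order is free, column names are fixed. Outputs: one
JSON report per locus (validated against the schema shipped with the
package) and flat TSV exports.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
from Bio import SeqIO

from .model import (
    INTERACTION_TYPES,
    DERecord,
    DomainAnnotation,
    FormatError,
    GeneSetCollection,
    InteractionRecord,
    IsoformRecord,
    Locus,
    PTMSite,
    ValidationError,
    check_sequence,
)


def read_locus_fasta(path, gene_symbol: str) -> Locus:
    """Read one locus's isoforms from FASTA; ids are the first header token."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not a FASTA file")
    seen: set[str] = set()
    isoforms = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate isoform id {rec.id!r}")
        seen.add(rec.id)
        seq = check_sequence(str(rec.seq), context=f"{path}: record {rec.id!r}")
        isoforms.append(IsoformRecord(rec.id, seq))
    return Locus(gene_symbol, isoforms)


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file (a header row is required)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _as_int(value: str, path, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{path}: row {row}: {column} {value!r} is not an integer") from None


def _as_float(value: str, path, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(f"{path}: row {row}: {column} {value!r} is not a number") from None


def read_annotations(
    domains_path, ptms_path, canonical_length: int
) -> tuple[list[DomainAnnotation], list[PTMSite]]:
    """Read domain intervals and PTM sites, validated against the canonical length."""
    if canonical_length < 1:
        raise ValidationError("canonical_length must be positive")
    domains = []
    df = _read_tsv(domains_path, ["domain_name", "start", "end"])
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        start = _as_int(rec.start, domains_path, row, "start")
        end = _as_int(rec.end, domains_path, row, "end")
        if start > end:
            raise ValidationError(f"{domains_path}: row {row}: start {start} > end {end}")
        if not (1 <= start and end <= canonical_length):
            raise ValidationError(
                f"{domains_path}: row {row}: interval [{start},{end}] outside "
                f"canonical length {canonical_length}"
            )
        domains.append(DomainAnnotation(rec.domain_name, start, end))

    ptms = []
    df = _read_tsv(ptms_path, ["position", "modification_type"])
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        pos = _as_int(rec.position, ptms_path, row, "position")
        if not (1 <= pos <= canonical_length):
            raise ValidationError(
                f"{ptms_path}: row {row}: position {pos} outside canonical length {canonical_length}"
            )
        ptms.append(PTMSite(pos, rec.modification_type))
    return domains, ptms


def read_interactions(path) -> list[InteractionRecord]:
    """Read the MITAB-lite interaction TSV."""
    df = _read_tsv(
        path,
        ["partner_id", "isoform_accession", "interaction_type", "mi_score",
         "binding_start", "binding_end"],
    )
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.interaction_type not in INTERACTION_TYPES:
            raise ValidationError(
                f"{path}: row {row}: interaction_type {rec.interaction_type!r} not one of "
                f"{', '.join(INTERACTION_TYPES)}"
            )
        mi = _as_float(rec.mi_score, path, row, "mi_score")
        if not (0 <= mi <= 1):
            raise ValidationError(f"{path}: row {row}: mi_score {mi} outside [0, 1]")
        bs, be = rec.binding_start.strip(), rec.binding_end.strip()
        if bool(bs) != bool(be):
            raise ValidationError(
                f"{path}: row {row}: binding_start and binding_end must both be set or both blank"
            )
        region = None
        if bs:
            start = _as_int(bs, path, row, "binding_start")
            end = _as_int(be, path, row, "binding_end")
            if not (1 <= start <= end):
                raise ValidationError(
                    f"{path}: row {row}: invalid binding region [{start},{end}]"
                )
            region = (start, end)
        out.append(
            InteractionRecord(rec.partner_id, rec.isoform_accession,
                              rec.interaction_type, mi, region)
        )
    return out


def read_de_table(path) -> list[DERecord]:
    """Read the transcript differential-expression table (log2FC + PPDE)."""
    df = _read_tsv(path, ["transcript_id", "gene_symbol", "tissue", "log2fc", "ppde"])
    seen: set[tuple[str, str]] = set()
    out = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        key = (rec.transcript_id, rec.tissue)
        if key in seen:
            raise ValidationError(
                f"{path}: row {row}: duplicate (transcript_id, tissue) pair "
                f"({rec.transcript_id!r}, {rec.tissue!r})"
            )
        seen.add(key)
        log2fc = _as_float(rec.log2fc, path, row, "log2fc")
        ppde = _as_float(rec.ppde, path, row, "ppde")
        if not (0 <= ppde <= 1):
            raise ValidationError(f"{path}: row {row}: ppde {ppde} outside [0, 1]")
        out.append(DERecord(rec.transcript_id, rec.gene_symbol, rec.tissue, log2fc, ppde))
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (term, description, members...)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need term, description and >=1 member"
                )
            term_id, name = parts[0], parts[1]
            if term_id in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate term id {term_id!r}")
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ValidationError(f"{path}: line {lineno}: gene set {term_id!r} is empty")
            sets[term_id] = (name, members)
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


# --- report output -----------------------------------------------------------

def load_report_schema() -> dict:
    text = resources.files("isoimpact").joinpath("report_schema.json").read_text()
    return json.loads(text)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "integer": int,
    "null": type(None),
}


def _check_schema(obj: Any, schema: dict, where: str) -> None:
    """Minimal structural validator (types, required keys, enums, items)."""
    types = schema.get("type")
    if types is not None:
        allowed = types if isinstance(types, list) else [types]
        ok = False
        for t in allowed:
            if t == "number":
                ok = ok or (isinstance(obj, (int, float)) and not isinstance(obj, bool))
            elif t == "integer":
                ok = ok or (isinstance(obj, int) and not isinstance(obj, bool))
            else:
                ok = ok or isinstance(obj, _TYPE_MAP[t])
        if not ok:
            raise ValidationError(f"report schema: {where}: expected {allowed}, got {type(obj).__name__}")
    if "enum" in schema and obj not in schema["enum"]:
        raise ValidationError(f"report schema: {where}: {obj!r} not in {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise ValidationError(f"report schema: {where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check_schema(obj[key], sub, f"{where}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _check_schema(item, schema["items"], f"{where}[{i}]")


def validate_report(report: dict) -> None:
    _check_schema(report, load_report_schema(), "$")


def write_gene_report(report: dict, path) -> None:
    """Write the per-locus JSON report; validated against the shipped schema."""
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")


def read_gene_report(path) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report


# --- flat TSV exports --------------------------------------------------------

def write_events_tsv(events, path) -> None:
    pd.DataFrame(
        [
            {
                "isoform_id": e.isoform_id,
                "event_type": e.event_type,
                "canonical_start": e.canonical_start,
                "canonical_end": e.canonical_end,
                "isoform_start": e.isoform_start if e.isoform_start is not None else "",
                "isoform_end": e.isoform_end if e.isoform_end is not None else "",
                "length": e.length,
            }
            for e in events
        ],
        columns=["isoform_id", "event_type", "canonical_start", "canonical_end",
                 "isoform_start", "isoform_end", "length"],
    ).to_csv(path, sep="\t", index=False)


def write_domain_impacts_tsv(impacts, path) -> None:
    pd.DataFrame(
        [
            {
                "isoform_id": d.isoform_id,
                "domain_name": d.domain_name,
                "event_type": d.event_type,
                "overlap_start": d.overlap_start,
                "overlap_end": d.overlap_end,
                "overlap_length": d.overlap_length,
                "domain_fraction_affected": d.domain_fraction_affected,
                "insertion_inside": d.insertion_inside,
            }
            for d in impacts
        ],
        columns=["isoform_id", "domain_name", "event_type", "overlap_start",
                 "overlap_end", "overlap_length", "domain_fraction_affected",
                 "insertion_inside"],
    ).to_csv(path, sep="\t", index=False)


def write_ptm_impacts_tsv(impacts, path) -> None:
    pd.DataFrame(
        [
            {
                "isoform_id": p.isoform_id,
                "position": p.position,
                "modification_type": p.modification_type,
                "status": p.status,
            }
            for p in impacts
        ],
        columns=["isoform_id", "position", "modification_type", "status"],
    ).to_csv(path, sep="\t", index=False)


def write_edges_tsv(edges, path) -> None:
    pd.DataFrame(
        [
            {
                "isoform_accession": e.isoform_accession,
                "partner_id": e.partner_id,
                "interaction_type": e.interaction_type,
                "mi_score": e.mi_score,
                "binding_start": e.binding_region[0] if e.binding_region else "",
                "binding_end": e.binding_region[1] if e.binding_region else "",
                "binding_affected": e.binding_affected,
                "isoform_specific": e.isoform_specific,
            }
            for e in edges
        ],
        columns=["isoform_accession", "partner_id", "interaction_type", "mi_score",
                 "binding_start", "binding_end", "binding_affected", "isoform_specific"],
    ).to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(results, path) -> None:
    pd.DataFrame(
        [
            {
                "network_label": r.network_label,
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.overlap_k,
                "n": r.query_n,
                "K": r.term_K,
                "N": r.background_N,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in results
        ],
        columns=["network_label", "term_id", "term_name", "k", "n", "K", "N",
                 "p_value", "fdr", "overlap_genes"],
    ).to_csv(path, sep="\t", index=False)
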