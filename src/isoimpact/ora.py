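"""Hypergeometric over-representation analysis of interactor gene sets.

For the whole interaction network, or per isoform partition, the query is
the deduplicated set of partner gene symbols; each gene-set term is tested
with the one-sided hypergeometric (Fisher exact upper tail) against a
configurable background universe, and p-values are Benjamini–Hochberg
adjusted within each network label. Alternative isoforms whose partners
are all shared with the canonical isoform are excluded from per-isoform
analysis — they carry no isoform-specific signal; the canonical partition
itself is always eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import DomainError, EnrichmentResult, GeneSetCollection, IsoformNetwork


@dataclass
class OraParams:
    alpha: float = 0.05
    background: Optional[frozenset[str]] = None  # None = gene-set universe


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = background size, K = term size, n = query size, k = overlap.
    """
    if not (0 <= k <= min(n, K)) or n > N or K > N or min(n, K, N) < 0:
        raise DomainError(
            f"hypergeometric bounds violated: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    if not p_values:
        return []
    for p in p_values:
        if not (0 < p <= 1):
            raise DomainError(f"p-value {p} outside (0, 1]")
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adjusted]


def _enrich_one(
    label: str,
    query: frozenset[str],
    gene_sets: GeneSetCollection,
    background: frozenset[str],
) -> list[EnrichmentResult]:
    query_bg = query & background
    n = len(query_bg)
    N = len(background)
    rows = []
    for term_id in sorted(gene_sets.sets):
        term_name, members = gene_sets.sets[term_id]
        members_bg = members & background
        overlap = sorted(query_bg & members_bg)
        k = len(overlap)
        if k == 0:
            continue
        K = len(members_bg)
        p = hypergeom_upper_tail(k, n, K, N)
        rows.append((term_id, term_name, k, n, K, N, p, tuple(overlap)))
    fdrs = bh_adjust([r[6] for r in rows])
    results = [
        EnrichmentResult(label, tid, tname, k, n, K, N, p, fdr, genes)
        for (tid, tname, k, n, K, N, p, genes), fdr in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def run_ora(
    network: IsoformNetwork,
    gene_sets: GeneSetCollection,
    background: Optional[Iterable[str]] = None,
    mode: str = "whole",
) -> list[EnrichmentResult]:
    """ORA of interactor genes for the whole network or per isoform partition.

    Only terms with at least one query member are reported. In per-isoform
    mode, alternative isoforms lacking a partner absent from the canonical
    partition are skipped.
    """
    if mode not in ("whole", "per_isoform"):
        raise DomainError(f"unknown ORA mode {mode!r}")
    bg = frozenset(background) if background is not None else gene_sets.universe()
    if not bg:
        raise DomainError("empty background universe")

    if mode == "whole":
        query = frozenset(e.partner_id for e in network.whole_network)
        return _enrich_one("whole", query, gene_sets, bg) if query else []

    canonical_partners = network.partners(network.canonical_accession)
    results: list[EnrichmentResult] = []
    for acc in sorted(network.partitions):
        partners = network.partners(acc)
        if not partners:
            continue
        if acc != network.canonical_accession and partners <= canonical_partners:
            continue  # no distinct interactors: excluded
        results.extend(_enrich_one(acc, partners, gene_sets, bg))
    return results
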