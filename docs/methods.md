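# Methods

This note documents the model implemented by `isoimpact`, the defaults and
why they were chosen, what the synthetic-fixture generator does and does not
emulate, and the numerical and design decisions a reader would otherwise
have to reverse-engineer from the code.

## Coordinate conventions

All protein coordinates are 1-based and intervals are closed on both ends
(the UniProt convention). The alphabet is the 20 standard amino acids plus
`X` for an unknown residue. Alignment gaps are `-` and are never part of a
sequence.

## Isoform clustering

One genetic locus can encode substantially different proteins; aligning
them together would report "events" that have nothing to do with splicing.
Isoforms are therefore grouped before alignment:

- **Identity.** `pairwise_identity(a, b)` = identical aligned residue
  pairs / min(len(a), len(b)), computed from the optimal global alignment.
  The shorter-sequence denominator is the convention of greedy identity
  clustering tools: a truncated isoform that matches a prefix of the
  canonical scores identity 1.0, which is the desired behavior for splice
  variants. `X` never counts as an identity (it denotes an unknown
  residue, so an `X`/`X` pair carries no evidence of sameness).
- **Algorithm.** Greedy longest-first: visit isoforms by descending length
  (ties by ascending id); each joins the first existing cluster whose
  *founder* reaches the threshold, else founds a new cluster.
- **Threshold.** `identity_threshold = 0.6`: low enough to keep splice
  variants with large deletions together, high enough to separate
  unrelated products.
- **Canonical.** Longest member, ties broken by smallest id; overridable
  per run.

## Alignment

- **Pairwise.** Needleman–Wunsch with Gotoh's three-state affine-gap
  recurrence. A gap run of length L costs `gap_open + L * gap_extend`,
  charged once per run. Defaults: BLOSUM62, `gap_open = 10`,
  `gap_extend = 1` — the standard protein-alignment parameterization, and
  strongly affine (opening ≫ extending) so that splice-sized indels stay
  contiguous instead of fragmenting. Traceback ties are broken
  deterministically (diagonal, then gap-in-second, then gap-in-first), so
  identical inputs always give identical alignments. The inner dynamic
  program is JIT-compiled with numba.
- **Progressive MSA.** Guide tree: UPGMA (scipy average linkage) on
  1 − identity distances. Profiles are merged bottom-up under "once a gap,
  always a gap". Input order does not affect the result: sequences are
  sorted by id before the tree is built and restored afterwards.
- **Profile scoring.** Column–column scores are **average-of-pairs**: the
  sum of substitution scores over all residue pairs in the two columns,
  divided by the number of such pairs (gap entries excluded; an all-gap
  column pair scores 0). Averaging, rather than summing, is load-bearing:
  summed scores grow with profile depth while the affine gap penalties do
  not, so in a deep profile a moderately negative mismatch column can lose
  to a spurious deletion+insertion column pair — observed as a planted
  20-column divergent run splitting into two divergent runs separated by a
  1-column deletion and insertion in a 16-row profile. Averaging keeps
  column scores on the same scale as the gap penalties at every depth, and
  reduces exactly to pairwise alignment for two single-sequence profiles.
- **External alignments.** An aligned FASTA produced by any other MSA tool
  can be ingested; rows are validated against the input sequences
  (degapping must reproduce every input exactly — a mismatch is an error,
  not a warning).

## Splice-event detection

Each non-canonical MSA row is classified column-by-column against the
canonical row: `match`, `mismatch`, `canonical_gap`, `isoform_gap`, or
`both_gap`. Columns gapped in both rows carry no information for this pair
and are transparent: they neither break runs nor add length.

- **Deletions** = maximal runs of `isoform_gap`; reported with canonical
  coordinates only.
- **Insertions** = maximal runs of `canonical_gap`; anchored after the
  last preceding canonical position (anchor 0 for an N-terminal
  insertion), with isoform coordinates for the inserted block.
- **Divergent regions** = maximal `mismatch` runs of at least
  `min_divergent_run = 5` columns. Shorter mismatch runs are treated as
  point substitutions — SNPs or conservative edits, not splicing — and are
  deliberately not reported as events.
- `merge_gap = 0` by default: same-type events separated by at most this
  many match columns are merged. Zero keeps reported events literal; raise
  it to absorb small islands of chance identity inside a larger change.
- `X` versus `X` classifies as `match` (literal equality), even though it
  scores as a non-identity during clustering: classification answers "did
  the residue change?", identity answers "is this evidence of sameness?",
  and an unknown residue aligned to an unknown residue is not evidence of
  change.

The **variable-region union** of an isoform is the merged set of canonical
intervals covered by its deletions and divergent regions plus the
single-point anchors of its insertions (an N-terminal anchor of 0 is not a
canonical position and contributes nothing).

## Annotation impact

- **Domains.** One record per (event, domain) pair with ≥ 1 residue of
  closed-interval overlap, carrying the overlap span and the fraction of
  the domain affected. Insertions have no canonical span; an insertion
  anchored *strictly inside* a domain yields an informational record with
  overlap 0 (the domain's sequence is interrupted but none of it is
  removed).
- **PTMs.** Exactly one record per site per isoform: *lost* if the
  position falls in any deletion, else *altered context* if in any
  divergent region, else *retained*. Lost dominates because a residue that
  is physically absent cannot be modified regardless of surrounding
  context.
- Annotations live on one canonical coordinate system, so in multi-cluster
  loci they are applied to the primary cluster (the one holding the
  longest isoform); other clusters still get events but no annotation
  impacts.

## Interaction network

Curated interaction records name the mediating isoform accession; records
with an unrecognized accession are assigned to the canonical isoform and
flagged `assumed_canonical` (curation usually refers to the reference
protein when it does not specify an isoform). Filters: minimum MI
(confidence) score 0.45 — the conventional "medium confidence" cut for
curated interaction scores — and an interaction-type whitelist (`direct`,
`physical`, `association`). An optional per-isoform cap keeps only the
top-scoring isoform-specific edges (ties by partner id). An edge is
`binding_affected` when its annotated binding region overlaps the
mediating isoform's variable-region union. A partner is
`isoform_specific` when absent from the canonical partition. The whole
network is the union of partitions deduplicated by (partner, type), the
higher MI score winning.

## Over-representation analysis

Hypergeometric upper tail P(X ≥ k) for overlap k between a query (the
deduplicated partner genes of a network or partition) and each gene-set
term, against a background that defaults to the gene-set universe;
Benjamini–Hochberg adjustment within each network label. Only terms with
k ≥ 1 are reported. In per-isoform mode, alternative isoforms whose
partners are all shared with the canonical are skipped — their enrichment
would duplicate the canonical's signal — while the canonical partition is
always eligible.

## Differential-expression overlay

Transcript-level DE calls (log2 fold change + posterior probability of
differential expression, PPDE) are joined to isoforms by id after
stripping a trailing numeric version suffix. A record is significant when
PPDE is **strictly greater than 0.95** (the conventional empirical-Bayes
posterior cut; strictness is configurable). Unmatched transcripts produce
report warnings, never silent drops.

## Synthetic fixtures

The generator plants events with known coordinates and emits all six input
files plus the ground truth. Three constraints make exact recovery
*well-posed* rather than hopeful:

1. **Boundary uniqueness.** For a deletion [s, e], a left shift of the gap
   run pairs position s−1 with e and a right shift pairs s with e+1; the
   generator resamples canonical residues so those pairs differ (and
   analogously for insertion-block boundaries), making every shifted gap
   placement strictly worse. Without this, co-optimal placements would make
   "exact recovery" depend on tie-breaking, not correctness.
2. **Cross-isoform spacing.** All planted events on the locus — not merely
   within one isoform — are separated by more than
   `merge_gap + min_divergent_run` matching positions, because the
   progressive MSA couples isoforms through shared columns.
3. **Recoverable divergence.** Divergent blocks replace each canonical
   residue with its highest-scoring *non-identical* BLOSUM62 substitution
   (ties alphabetical): every column is a guaranteed mismatch, yet the
   ungapped alignment remains optimal. Uniform-random replacement blocks
   score so negatively that the optimal alignment fragments them into
   indels, which would make the planted "divergent" label unrecoverable by
   any correct aligner.

Plans keep each alternative isoform no longer than the canonical (net
length change ≤ 0), so canonical selection is never ambiguous; violations
of any constraint raise an error rather than being silently adjusted.

What the generator emulates: the *combinatorial* structure of a locus —
event types, sizes and positions, annotations riding on canonical
coordinates, interaction records with and without binding regions, planted
DE significance. What it does not emulate: real amino-acid composition
(sequences are uniform-random), exon-boundary statistics of real splice
events, correlated evolution between isoforms, database-scale gene-set
structure, or real expression distributions. The structured 16-isoform
template locus mirrors a kinase-family case study's shape (nested
C-terminal deletions, a binding region covered by three of them, a PTM
inside it, 9 DE-significant isoforms) with entirely synthetic sequences.

## Numerical choices

- Alignment scores are integers (BLOSUM62 and the gap penalties are
  integral); the dynamic program runs in float64 and the pairwise score is
  rounded on return, so no floating-point comparison ambiguity can affect
  tracebacks at the pairwise level. Profile merging divides by pair counts
  and is genuinely float-valued; its ties are resolved by the same fixed
  move preference.
- Hypergeometric tails use `scipy.stats.hypergeom.sf(k − 1, N, K, n)` with
  an exact 1.0 at k = 0; BH uses `statsmodels.multipletests(method="fdr_bh")`.
  Both are validated in the tests against brute-force enumeration oracles.
- All simulation randomness flows through one `random.Random(seed)`;
  reports contain no timestamps, so identical runs are byte-identical.

## Limitations

- Event detection sees proteins only; it cannot distinguish which genomic
  mechanism (exon skipping, alternative donor/acceptor, intron retention)
  produced an event, and N-terminal insertions anchor at position 0 with
  no canonical span.
- Divergent regions below `min_divergent_run` are invisible by design;
  a cluster of 4 substitutions is never reported.
- Greedy clustering is order-dependent by specification (longest first);
  it is deterministic but not globally optimal.
- Domain "fraction affected" treats all residues as equally important;
  it is a coverage measure, not a function prediction.
- ORA assumes the background universe is well-chosen; with the default
  (gene-set universe) background, query genes outside every gene set are
  silently outside the analysis.
- The progressive MSA is exact for the pairwise case but heuristic for
  ≥ 3 sequences, as all progressive aligners are; the planted-recovery
  acceptance tests bound its behavior only on generator-shaped inputs.
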