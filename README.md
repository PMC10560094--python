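# isoimpact

Detect protein-level alternative-splicing events from a set of isoform
sequences and annotate their functional consequences.

## The problem

Most human genes produce several protein isoforms through alternative
splicing. At the protein level, an alternative isoform differs from the
reference ("canonical") isoform by **insertions**, **deletions**, and
**divergent regions** — contiguous stretches where both proteins have
residues but they disagree. These differences matter when they remove a
domain, delete a modified residue, or disrupt the part of the sequence that
mediates a protein–protein interaction.

`isoimpact` takes the isoform sequences of one gene plus optional
annotations and answers, per isoform:

1. Which splice events distinguish it from the canonical isoform, in
   canonical coordinates?
2. Which protein domains and PTM sites do those events remove or alter?
3. Which of its curated protein interactions have binding regions inside
   the changed sequence?
4. Are its isoform-specific interactors enriched for any annotated gene
   sets (hypergeometric ORA with Benjamini–Hochberg correction)?
5. Is the corresponding transcript differentially expressed (PPDE filter
   on an upstream transcript-level DE table)?

Everything is joined into one JSON report per gene, plus flat TSV exports.

## Method in brief

- **Clustering.** Isoforms are grouped greedily (longest-first) by global
  pairwise identity, with the shorter sequence as denominator, at a default
  threshold of 0.6; each cluster's longest member is its canonical isoform.
  This keeps genuinely unrelated proteins from the same locus out of one
  alignment.
- **Alignment.** Pairwise and profile alignment use Needleman–Wunsch with
  Gotoh affine gaps (BLOSUM62, gap open 10, gap extend 1). The MSA is
  progressive over a UPGMA guide tree on identity distances, merging
  profiles with average-of-pairs column scores.
- **Event calling.** Each non-canonical row is compared column-wise with
  the canonical row: runs of isoform gaps are deletions, runs of canonical
  gaps are insertions (anchored after the preceding canonical position),
  and mismatch runs of ≥ 5 columns are divergent regions. Coordinates are
  1-based, closed intervals.
- **Impact rules.** A PTM is *lost* inside a deletion, has
  *altered context* inside a divergent region, and is *retained* otherwise.
  Domains record their overlapped span and affected fraction. An
  interaction edge is *binding-affected* when its annotated binding region
  overlaps any variable region of the mediating isoform.

See `docs/methods.md` for the full model, parameter rationale, and
limitations.

## Worked example

The package ships a generator that plants known splice events and writes a
complete input bundle plus the ground truth:

```bash
isoimpact simulate --seed 7 --outdir example/
isoimpact run \
  --fasta example/isoforms.fasta --gene GENE1 --outdir results/ \
  --domains example/domains.tsv --ptms example/ptms.tsv \
  --interactions example/interactions.tsv \
  --genesets example/genesets.gmt --de example/de.tsv
```

`results/events.tsv` — the detected events (this exact output, seed 7):

```
isoform_id  event_type  canonical_start  canonical_end  isoform_start  isoform_end  length
GENE1-02    deletion    45               53                                         9
GENE1-02    divergent   260              264              251            255        5
GENE1-03    insertion   123              123              124            129        6
GENE1-03    deletion    218              242                                        25
GENE1-04    deletion    286              294                                        9
```

The report summary (`results/report.json`):

```json
{
  "n_isoforms": 4,
  "n_clusters": 1,
  "n_events": 5,
  "n_de_significant": 2,
  "n_affected_edges": 3,
  "n_enriched_terms": 16
}
```

GENE1-04's 9-residue deletion removes the planted ubiquitination site at
position 287 (`results/ptm_impacts.tsv`):

```
GENE1-04  287  ubiquitination  lost
```

and three interaction edges have binding regions inside deleted or
divergent sequence (`results/edges.tsv`, `binding_affected` column):

```
GENE1-02  PART07  direct    0.91  258  264  True  True
GENE1-02  PART10  direct    0.62  43   49   True  True
GENE1-03  PART08  physical  0.54  216  222  True  True
```

Every planted event, impact, and flag matches `example/truth.json`.

### Library use

```python
from isoimpact.io import read_locus_fasta
from isoimpact.pipeline import run_pipeline

locus = read_locus_fasta("example/isoforms.fasta", "GENE1")
result = run_pipeline(locus)
print(result.report["summary"])
# {'n_isoforms': 4, 'n_clusters': 1, 'n_events': 5, ...}
```

## Command-line interface

| command              | scope                                            |
| -------------------- | ------------------------------------------------ |
| `isoimpact run`      | full pipeline (all inputs optional except FASTA) |
| `isoimpact events`   | clustering, MSA and event calling only           |
| `isoimpact network`  | events plus the filtered interaction network     |
| `isoimpact ora`      | events, network and enrichment                   |
| `isoimpact simulate` | generate a synthetic fixture with ground truth   |

Parameters come from documented defaults, an optional YAML config
(`--config`), and command-line flags, in increasing precedence; the fully
resolved set is embedded in every report under `provenance.parameters`.
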