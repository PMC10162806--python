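# Methods

## Pipeline model

`tfcat` treats TF cataloguing as domain-architecture classification: a
protein is a putative transcription factor exactly when it carries at least
one detectable DNA-binding domain (DBD) from a curated registry of profile
HMMs, and its structural family is the family of its best-scoring DBD. This
deliberately over-calls relative to experimentally validated TF lists —
proteins with a DBD but no proven sequence-specific regulatory activity
(e.g. some HMG-box or chromatin proteins) are included — which is the
appropriate behaviour for building candidate repertoires in poorly
annotated genomes.

Annotation is nearest-relative symbol transfer on user-supplied gene trees:
the query leaf adopts the gene symbol of the leaf with the smallest
patristic distance among leaves that have metadata. The quality of the
transfer is bounded by the quality of the trees; the package computes
distances exactly and surfaces ties, but performs no tree inference,
rooting, or reconciliation.

## Proteome pre-processing

Proteomes usually contain several isoforms per gene; the catalog unit is
the gene, so one **primary isoform** is selected per gene before scanning.
The default rule is *longest isoform, ties broken by lexicographically
smaller sequence id*: it is deterministic and needs no external annotation.
A `tagged_primary` strategy honours explicit primary flags in headers
(falling back to the longest rule), and `first_seen` preserves input order.
Sequences from alternative genome mappings (haplotype or patch scaffolds)
are removed by user-supplied header predicates; the shipped default
substrings are `PATCH`, `HSCHR` and `alt` against an Ensembl-style region
field. Every filter appends a `(step, n_in, n_out)` row to the proteome's
provenance log.

Gene identity is recovered from FASTA headers by a configurable scheme:
`key_value` accepts both `gene=X` and Ensembl-style `gene:X` tokens;
`pipe` takes a positional field of a `|`-delimited id; `opaque` leaves
gene ids unset (records then pass filters untouched, with a warning).

## Domain search and hit filtering

Scanning is delegated to `pyhmmer`'s in-process `hmmscan`; the package never
reimplements the Forward/Viterbi machinery. Equivalently, precomputed
HMMER3 per-domain tabular output or a custom TSV hit table can be ingested;
all three routes produce the same `DomainHit` records and share the
downstream path (a property the test suite asserts).

Default hit filters: per-domain independent E-value ≤ **1e-3** and model
coverage (matched match-states / model length) ≥ **0.30**, both
overridable; a gathering-threshold mode is available for curated models
that carry GA cutoffs. E-values scale with the number of models searched,
so the registry size is logged with every scan and thresholds should not be
ported between registries blindly. Greedy overlap resolution (descending
bit score; ties by lower E-value, lower start, accession) is available for
multi-domain architectures; both raw and resolved hit sets can be kept,
since family assignment aggregates per family and does not require
overlap-free input.

Family ranking within a protein: best (lowest) per-domain independent
E-value, ties by higher bit score, then alphabetical family label. The
first-ranked family is the primary family; `family_distribution` counts
each TF once under its primary family by default (counts then sum to the
catalog size), with an `all_families` membership count available.

## Patristic distances

The all-pairs matrix is computed in a single post-order traversal: at each
internal node, for every pair of leaves drawn from two distinct child
subtrees, the distance is the sum of the two leaf depths relative to that
node. Each leaf pair's path crosses exactly one such node, so every entry
is set exactly once; the result is contractually identical to per-pair path
summation (the test suite keeps a naive LCA path-sum oracle and checks
agreement to 1e-9 relative tolerance on hundreds of random trees, plus
metric axioms, the four-point condition, agreement with dendropy, and
invariance under rerooting).

Numerical choices: branch lengths are summed as IEEE doubles in tree order;
comparisons between candidate distances use exact ordering (no epsilon) —
ties in real gene trees arise from exactly duplicated path sums, and an
epsilon would hide them. Missing branch lengths are an **error** by
default; an explicit `fill=1.0` opt-in turns patristic distance into
node-path length. Negative lengths are rejected at parse time. Root edge
lengths are ignored (no leaf-leaf path uses them), which is also why
distances are invariant to root placement and unrooted input needs no
special handling.

The Newick parser is implemented in-repo (quoted labels with `''` escapes,
literal underscores, internal support labels, scientific-notation lengths,
position-carrying errors); `dendropy` appears only in tests as an
independent oracle.

## Annotation semantics

Candidate donors for a query are leaves ≠ query that appear in the metadata
and whose source tag is not excluded (the exclusion hook exists chiefly to
forbid same-species self-annotation). The donor is the candidate at minimum
patristic distance; exact ties are broken by case-insensitive
lexicographic gene symbol (then leaf label) and the number of minimal
candidates is reported as `n_ties`, so downstream users can review
ambiguous transfers. No distance ceiling is applied by default: a transfer
over a long branch is reported with its distance rather than suppressed,
leaving the confidence judgement to the user.

## Benchmark arithmetic

Identifiers are normalized by case-folding and stripping trailing `.N`
version suffixes, with an optional user alias table applied afterwards.
Recall percentages are rounded half away from zero to one decimal, the
convention of published benchmark figures. Family vocabularies between a
catalog and a reference are harmonized through a user-editable two-column
map (a small default covers common synonym pairs such as "C2H2 ZF" /
"zf-C2H2"); labels that do not harmonize count as distinct families, which
makes parity conservative.

## Synthetic fixtures: what they do and do not show

The generators produce, deterministically from (parameters, seed):

- **Toy proteomes** — uniform-random background residues over the 20
  canonical amino acids, with fixed 20-residue family motifs planted in the
  primary isoform of a chosen fraction of genes (`round(n_genes ·
  tf_fraction)` TF genes, 1–2 motif copies each), plus a mock hit table
  listing exactly the planted records.
- **Toy profile HMMs** — built with pyhmmer from 8-row alignments where
  each variant row differs from the motif in ≤ 20% of columns and
  per-column substitutions are capped so the consensus equals the motif.
- **Annotation cases** — random binary background trees with branch lengths
  0.5 + Exp(1), onto which a shallow (query, donor) clade with ~0.01
  pendant edges is grafted, making the donor strictly nearest by a wide
  margin; tie cases plant two donors at exactly equal distance.

Passing planted-truth tests therefore demonstrates the correctness of the
bookkeeping (parsing, filtering, assignment, export, distance math, tie
handling) — not detection power on real proteomes. Real DBDs are variable,
repetitive (tandem zinc fingers), and embedded in compositionally biased
sequence; real gene trees have no engineered margin. Published-scale counts
additionally depend on the exact model registry, its thresholds, and
reference-catalog curation, which is why the benchmark module reproduces
the published *arithmetic* from printed set sizes rather than the
biological counts themselves.

Problem sizes used by the shipped checks (chosen to keep the default suite
fast while covering the size range): 200 random trees of 4–64 leaves for
the distance oracle, 100 planted annotation queries plus 20 tie queries,
and catalogue-path fixtures of 10, 100 and 500 genes.

## Known limitations

- No gene-tree inference or rooting; trees and their branch lengths are
  trusted inputs.
- The registry is user-supplied; no curated DBD model set is bundled beyond
  the 4-model toy registry for tests.
- Family-label harmonization is by exact mapped string; fuzzy vocabulary
  reconciliation is out of scope.
- Gene Ontology analysis and interactive visualization are out of scope;
  plots are a thin optional layer over the tested tables.
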