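# Methods

This note documents the models and procedures implemented in `mirkit`,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real data.

## Reference snapshots

All retrievals query a *snapshot*: a directory of UTF-8, tab-separated
tables (one header row, literal `NA` as the missing token) enumerated by
`manifest.tsv`. The snapshot replaces live database connections with a
frozen, versioned local copy — the same trade the original client–server
tools made when public APIs became unreliable — and makes every analysis
offline-reproducible and diffable. A relational database would buy
nothing here: tables are read once, indexed in memory, and never
mutated.

Loading validates headers strictly (a wrong column set is fatal, naming
the file) but treats referential problems as warnings: a target row
whose miRNA is missing from the metadata table is reported, not fatal,
because partial snapshots are a normal state of reference data.
Retrievals are capped at 500,000 rows by default (configurable);
truncation always warns and marks the result, never silently.

## Identifier mapping

Six namespaces are supported: gene symbol, Entrez, Ensembl gene,
Ensembl transcript, GenBank, UniProt. Gene symbols are matched
case-insensitively — zebrafish symbols are conventionally lower-case
where human symbols are upper-case, and cross-species symbol joins must
not care — while every other namespace is exact. One-to-many mappings
expand to one row per value; downstream merges need atomic keys, and
collapsing values into delimited cells would make joins lossy.

Ortholog pairs are stored directionally with percent identity for both
the source and destination gene, and materialized in both directions at
query time so no pair is missed for being recorded the other way round.
The percent-identity fields are carried opaquely (the upstream
convention does not state whether identity is nucleotide or amino-acid
level), so they are reported, never thresholded internally.

## Consensus target prediction

Single prediction databases carry substantial false-positive rates;
requiring agreement between ≥2 of 3 independent sources is the standard
mitigation. For query miRNAs M, sources S, and threshold k:

- **pair level**: a (miRNA, gene) pair is reported with one membership
  flag per source and agreement count equal to the number of true
  flags; rows below k are dropped.
- **gene level**: a gene's flag for source s is true when *any* queried
  miRNA targets it in s; gene rows are unique. This is the mode that
  corresponds to counting "targets with unique gene symbols", and is
  deliberately distinct from pair-level agreement: a gene can reach
  two-source agreement through two different miRNAs without any single
  pair being multi-source. Both modes are first-class because published
  target counts rarely state which was used.

Output is sorted by (agreement desc, key asc) for determinism. The
agreement computation is a set operation over the raw tables and is
property-tested against a brute-force recount at every threshold.

## Cross-species homology filtering

When a species lacks target predictions (zebrafish is covered by a
single source), its miRNAs can be bridged to a better-covered species
through mature-sequence homology. Two normalized sequences (uppercase
RNA, T→U) are compared aligned at the 5′ end:

    n_mismatch = Hamming(overlap) + |len(a) − len(b)|
    seed_identical = (a[2..8] == b[2..8], 1-based)
    pass = n_mismatch ≤ max_mismatch AND seed_identical

Choices worth stating:

- *Seed = positions 2–8.* The seed is the primary determinant of target
  recognition; 2–8 is the standard convention.
- *Identity, not hybridization.* The filter compares two candidate
  homologs of the same miRNA, not a miRNA:mRNA duplex, so
  "complementarity" is implemented as sequence identity.
- *5′ anchoring.* Mature 3′ ends are heterogeneous across species and
  miRBase versions; the 5′ end defines the seed, so unequal lengths are
  compared over the 5′ overlap with the length difference charged in
  full to the mismatch count. A seed-region edit fails the pair even
  when the total budget would allow it.

The workflow maps a miRNA to bridge-species candidates by mature-name
suffix (`dre-miR-21` → `hsa-miR-21`); all passing candidates are kept
and multiplicity is logged, since choosing one silently would bias
downstream target sets.

## Multi-level merging

A merge plan is an *ordered* list of key relations. Left rows are
offered to relation 1; those matched are excluded from relation 2, and
so on — so the per-level counts `matched_i` partition the left table:
Σ matched_i + left_unmatched = |left|. A relation may translate the
left key through the cross-reference tables first (e.g. Entrez →
symbol), which is how tables with no shared identifier still join.
`NA` keys never match. Key comparison follows the namespace case rules
above (declared per relation).

Duplicate keys expand cartesianly — every matching right row produces
an output row — because first-match semantics silently drop data;
`dedupe_rows` is the explicit alternative. The report therefore carries
both `matched_total` (left rows) and `matched_pairs` (output rows); in
union mode the output size is exactly
`matched_pairs + left_unmatched + right_unmatched`, a conservation law
that is property-tested on random tables.

The default workflow plan is: gene symbol (case-folded), then Entrez,
then Entrez translated to gene symbol — direct relations first, the
translated relation as a catch-all for rows whose symbols were missing.

## Enrichment

Over-representation of a gene set of size K in a query of size n drawn
against a universe of size N with overlap k is scored by the exact
hypergeometric upper tail P(X ≥ k) (`scipy.stats.hypergeom.sf`), with
Benjamini–Hochberg adjustment (statsmodels) across all tested sets. The
universe is always explicit — by default every gene symbol the snapshot
knows for the species, i.e. the array platform — because enrichment
against an unstated background is not interpretable. Two significance
flags are reported: on raw p (the conventional report) and on q
(recommended). The modified one-tail scores and annotation-clustering
heuristics of dedicated enrichment servers are deliberately not
replicated; this is a plain, exactly-testable hypergeometric test.

## Clustering

Agglomerative clustering with Euclidean distance and centroid linkage
(UPGMC): at each step the two clusters with nearest centroids merge,
and the new centroid is the exact size-weighted mean of the members —
no Lance–Williams recurrence — so the merge sequence can be compared
verbatim against a naive recompute-everything oracle, which the test
suite does on 50 random matrices. Ties break on the lexicographically
smallest node-id pair, making results deterministic. Centroid linkage
can produce height inversions; they are flagged and exported as-is
(negative internal branch lengths in the Newick output) rather than
clamped. The O(n³) cost is irrelevant at the tens-to-hundreds of
profiles this pipeline clusters.

## Synthetic fixtures

The generator emits a full snapshot and experiment from a seed, as a
pure function of its spec; identical specs produce byte-identical
directories. Planted structure:

- `n_conserved_pairs` (miRNA, gene) pairs present in all three sources,
  each on a distinct gene, assigned to miRNAs that are both significant
  and homology-passing so the planted structure is reachable end to
  end; mirrored into the source species' single available tool.
- Background predictions at `background_rate` per source that are
  always single-source, so any pair reaching two-source agreement is
  planted by construction.
- A mismatch profile over {identical, one non-seed edit, one seed edit,
  two non-seed edits} controlling exactly how many miRNAs survive the
  homology filter. The default (20/13/5/4 over 42 miRNAs, 33 passing)
  mirrors the shape of a developmental neurotoxicant exposure study in
  zebrafish bridged to human.
- One GO term attached to every conserved target gene (the planted
  enriched process), plus Poisson(`mean_terms_per_gene`) background
  terms per gene.
- An experiment with `n_sig_mirnas` miRNA rows and `n_sig_genes` mRNA
  rows (three log-fold-change timepoints, p < 0.05 by construction), of
  which exactly `round(target_enrichment × n_sig_genes)` are planted
  conserved-target genes and the rest are genes with no prediction at
  all.

Every planted fact is written to plain-TSV ledgers, so tests recount
the pipeline's output against the ledger rather than against the code
that produced it. Default problem sizes (hundreds of genes, dozens of
miRNAs) were chosen as the smallest scale at which every planted
structure is distinguishable from background; the machinery is
unchanged at larger sizes.

What the fixtures do *not* emulate: real sequence composition and
miRNA family structure, realistic target-count distributions (real
databases predict hundreds of targets per miRNA), correlated
multi-source errors, annotation bias, many-to-many orthology, or the
version drift of real reference databases. Passing tests demonstrate
the *bookkeeping* is exact — set agreement, merge accounting, p-value
arithmetic, filter logic — not that any particular prediction database
is accurate. Headline counts from published studies depend on specific
database snapshots and are intentionally not reproduction targets.

## Numerical and degenerate-input conventions

- Sequences: DNA input and mixed case are normalized silently (T→U,
  uppercase); non-ACGU characters after normalization are fatal, naming
  the record; mature lengths outside 18–26 warn but proceed.
- Empty query lists yield empty tables, never errors; unknown ids
  always surface as `NA` rows with a matched flag, never disappear.
- Clustering refuses single-row input, missing values and non-numeric
  cells (fatal, naming the row).
- Workflow artifacts carry a provenance header (config hash computed
  over the analysis parameters, snapshot version tag, timestamp);
  re-running an identical config reproduces every artifact byte-for-byte
  except the timestamp line.
- Anti-correlated merging (up-miRNAs × down-mRNAs and vice versa,
  split on the sign of the mean log-fold-change) is available but off
  by default: repression is the primary miRNA mechanism, but the
  unfiltered merge is the conventional first analysis.
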