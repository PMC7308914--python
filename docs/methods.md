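# Methods

## Coordinates and the reference catalog

All intervals are 0-based half-open (BED convention) and unstranded;
sequences are always taken from the forward strand, since accessible-chromatin
regions carry no strand. Region identifiers are `chrom:start-end` of the
original coordinates; merged regions take their merged coordinates, so every
id is self-describing and joinable across files.

Merging unites intervals transitively whenever they overlap or their gap
(`next.start − prev.end`) is **≤ d**; a gap of exactly *d* merges, matching
`bedtools merge -d`. The default *d* = 500 bp reflects the observation that
very close catalog entries behave as one accessibility unit at
quantification time. Identical duplicate intervals in an input catalog are
collapsed on reading: they denote the same region and share its id. Merging
is implemented as a single sweep over the sorted catalog; the test suite
checks it against an O(n²) pairwise-union oracle (connected components of
the proximity graph), along with idempotence and monotonicity in *d*.

## Pseudoalignment

The index maps each canonical k-mer (lexicographic minimum of the k-mer and
its reverse complement; k odd so no k-mer is its own reverse complement) to
the equivalence class of exactly the regions containing it. Default k = 31.
Windows containing non-ACGT characters are skipped on both the index and
query side; regions shorter than k contribute nothing and are logged.

A read is assigned the intersection of the region sets of its indexed
k-mers, taken over every ACGT window of the read — deliberately simpler
than a de Bruijn-graph pseudoaligner: no contig skipping and no union
fallback. On an error-free or low-error read this intersection equals what
graph-based intersection semantics produce; under heavy error the read
tends to UNMAPPED rather than to a wrong region, which is the conservative
failure mode. Reads shorter than k, reads with no indexed k-mer, and reads
whose hits intersect to ∅ are unmapped (logged, not an error). The
implementation short-circuits as soon as the running intersection is empty
and skips repeated equivalence classes, so typical single-region reads cost
one set copy.

## PseudoUMI construction and barcode selection

The three restructuring strategies are:

- **random** — *n* random nucleotides (default n = 10) from a seeded
  generator; the forward read R1 is aligned. This is the control in which
  deduplication is uninformative.
- **n_fwd** — pseudoUMI = first *n* nt of R3; R1 aligned.
- **n_rev** — pseudoUMI = first *n* nt of R1; R3 aligned (the default
  operating point, n = 10).

The cell barcode is always the raw first 16 nt of R2; no error correction
against a barcode whitelist is performed, keeping the method self-contained.
Records whose UMI-slot read is shorter than *n* are skipped with a warning.
FASTQ qualities are read and ignored (pseudoalignment does not use them).

Cell selection uses a deterministic knee rule: rank barcodes by descending
read count, take the count *m* at rank `expected_cells` (default 10,000; the
minimum count if fewer barcodes exist), and keep every barcode with count ≥
m/10. Ties are broken lexicographically so the whitelist is reproducible.

## Deduplication and counting

Sorted records are grouped by (barcode, pseudoUMI); a group is one candidate
molecule. Each record's equivalence class is mapped through the feature
projection (identity, merge mapping, or region→gene mapping) to a target
set; the group's target set is the **intersection** across its records. A
singleton target receives one molecule; empty and multi-target groups are
discarded. Consequences, verified by tests:

- total molecules ≤ distinct (barcode, pseudoUMI) pairs;
- singleton-EC records are never discarded under a total mapping;
- many-to-one projection can only rescue molecules, never lose them, so
  counting a full catalog and projecting onto merged intervals yields ≥ the
  molecules of identity counting — the mechanism that separates
  quantify-then-project from quantify-on-merged.

The discard rule (rather than fractional assignment) keeps counts integral
and mirrors the dominant gene-count semantics of BUS-based pipelines; the
choice is declared, not inferred from any external tool's internals.

Note an inherent property of prefix pseudoUMIs: two distinct fragments from
the same cell that share a 5′ start position are indistinguishable — they
produce the same pseudoUMI and the same equivalence class and collapse to
one molecule. At typical depth (a few thousand fragments per cell over
hundreds of regions) this affects well under 1% of molecules; at 10⁴
molecules per cell it costs ~20% even for n = 10. With n = 5 the 4⁵ = 1,024
possible pseudoUMIs make collisions across regions near-certain and the
ambiguity discard removes almost all molecules — the collision mechanism
that makes very short pseudoUMIs unusable.

## Gene Activity Scores

Gene windows extend the gene body 2 kb beyond the TSS (start for + strand,
end for − strand; extension clamped at 0). A region maps to every window it
overlaps by ≥ 1 bp (half-open; no fractional-overlap weighting — the
simplest defensible rule). Two summarization routes are exposed on purpose:

- **matrix level**: each gene column is the sum of its mapped region
  columns; a multi-gene region contributes fully to each gene, so totals are
  conserved weighted by overlap multiplicity.
- **molecule level**: the counting step is re-run with the region→gene
  mapping, so molecules ambiguous between genes are discarded.

The two differ exactly on multi-gene regions; which is appropriate depends
on whether downstream analysis tolerates double counting or prefers
conservative integral counts.

## Clustering and concordance metrics

`cluster_cells` filters cells with < 200 detected regions and regions in
< 10 cells, normalizes each cell to the median total count, applies
log(1+x), keeps the top 15,000 variable regions (dispersion-based; skipped
when fewer exist), reduces to 50 principal components (capped by matrix
rank), builds a 15-nearest-neighbor graph and partitions it with Leiden at
resolution 0.2. All steps are delegated to scanpy with a fixed random
state; the leidenalg backend is pinned so the partition semantics do not
drift with library defaults. Every parameter is exposed.

Mutual information uses natural logarithms. AMI subtracts the expected MI
under the permutation (hypergeometric) model and normalizes by the
arithmetic mean of the two entropies; a zero denominator (e.g. a
single-cluster partition) returns 0 by convention. The expected-MI sum is
computed with log-gamma arithmetic for stability; tests require agreement
with an independent reference implementation to 1e-10 and with an
exhaustive label-permutation oracle at n = 6.

Cluster matching is greedy maximum overlap on the contingency table with
lexicographic tie-breaks. Marker regions use a one-vs-rest Wilcoxon
rank-sum z statistic (normal approximation with tie correction) on
normalized log counts, Benjamini–Hochberg adjustment within each cluster,
adjusted p < 0.05, ranked by statistic, truncated to the top 1,000.
Adjusted p-values and statistic ranking are deliberate choices where the
convention is ambiguous. Marker distance concordance uses gap distances
(0 when overlapping) and bins at 0 / ≤ 20 kb / farther.

The AMI-vs-cutoff curve keeps the N regions detected in the most cells
(ties by region id), re-clusters, and reports AMI against a reference
labeling. Cutoffs must exceed the per-cell region filter, otherwise every
cell is removed and the point is undefined.

## The synthetic-data generator

The generator emulates what the quantification method actually consumes:

- a random ACGT genome with non-overlapping regions ≥ 1 kb apart (so
  distinct regions share no 31-mers in practice and ground truth is
  unambiguous);
- clusters of near-equal size; the first 30% of the catalog is split into
  per-cluster blocks up-weighted 8× within their own cluster, giving each
  cluster a distinctive accessibility profile over ~50 regions at defaults;
- fragments with uniform starts and truncated-normal insert sizes
  (mean 200, sd 30, clamped into [read length, region length]); R1 is the
  fragment's forward 5′ read, R3 the reverse-complemented 3′ read, R2 the
  16 nt barcode; constant 'I' qualities;
- PCR duplicates: a `duplicate_rate` fraction of fragments (default 0.1) is
  emitted twice verbatim. Substitution errors (default 0.002/base) are
  injected once per molecule so duplicate copies stay identical and
  prefix-pseudoUMI deduplication can be validated exactly; an
  `errors_per_copy` option instead draws errors independently per copy to
  probe how sequencing errors break duplicate detection;
- read names encode (cell, fragment, region, copy), and a truth TSV is
  written alongside.

Defaults — 200 cells, 3 clusters, 500 regions of 400 bp, 2,000 fragments
per cell — are the standard study condition used by the test battery and
the acceptance script; they are large enough for the clustering defaults
(200-region cell filter) to be meaningful while keeping a full simulate +
quantify + cluster cycle around a minute on one CPU.

What the generator does **not** model: Tn5 insertion sequence bias, GC bias,
the nucleosome-ladder fragment-size mixture, barcode sequencing errors,
doublets, and open chromatin outside the catalog. Passing tests therefore
demonstrate the correctness of the quantification mechanics and the
collision behavior of pseudoUMIs, not robustness to every artifact of real
libraries.

## Numerical and degenerate-input conventions

- Merging an empty catalog returns an empty catalog; empty FASTQ streams
  yield empty record lists and counting them yields an empty matrix.
- `count` requires sorted input and fails loudly on unsorted records or on
  mappings missing a source id.
- Matrix I/O is MatrixMarket integer coordinate (features × cells on disk,
  10x convention) with `barcodes.tsv` / `features.tsv` sidecars;
  read(write(x)) round-trips exactly.
- All randomness (simulation, random pseudoUMIs, PCA/Leiden) flows from
  explicit integer seeds; reruns are bit-identical.

## Known limitations

- The intersection pseudoaligner holds the whole k-mer map in memory
  (~40 bytes/k-mer in CPython): suitable for catalogs up to a few hundred
  Mb of sequence, not for whole mammalian genomes.
- Prefix pseudoUMIs under-count at extreme per-cell depth (see above); the
  random-UMI strategy avoids start-position collapse but cannot remove PCR
  duplicates at all.
- No barcode error correction: sequencing errors in R2 fragment cells.
- Marker p-values use the normal approximation to the rank-sum statistic,
  inaccurate for clusters of only a few cells (clusters of one cell are
  skipped with a warning).
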