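# Methods

This note records the model behind `longstr`, the tunables that matter,
the numerical choices made where the design was genuinely open, what
the synthetic data does and does not emulate, and known limitations.

## Genotyping model

A tandem repeat allele is modelled as the contiguous read sequence
replacing the catalogued repeat interval. The central device is the
*excised artificial reference*: deleting `[start, end)` from the locus
reference leaves two flanks joined at a single junction, so a spanning
read realigned to it must place its entire repeat — however long, and
regardless of how the original aligner represented it — between the two
flanks. This converts repeat genotyping into junction-insertion
extraction and avoids any assumption about which motifs the allele
contains.

### Junction extraction

Each flank's junction-proximal anchor (`span_margin` bases, default
100) is located in the read independently by unit-cost infix edit
alignment (edlib); the allele is the read segment between the left
anchor's end and the right anchor's start. We deliberately do not read
the insertion operations off a single joined alignment: when flank
boundary bases coincide with repeat bases (a `CAG` repeat following a
flank ending in `...CA`, say), an optimal aligner is free to slide the
insertion across the junction, and the reported allele becomes a
rotation of the true one. Anchoring each flank as a whole is
unambiguous on non-periodic flanks because a shifted full-anchor match
would have to mismatch along its entire length. With this scheme,
noiseless reads recover simulated alleles of 0–2000 bp exactly
(property-tested).

An anchor diverging by more than 30 % of its length marks the read
unusable (it stops before the junction, or is not the locus). Anchor
overlaps up to `merge_window_bp` (default 25) — boundary indel wobble —
clamp to a 0 bp allele; larger overlaps mark the read unusable.

### Allele grouping

With prephased `HP` tags (mode `auto`, requiring at least two tagged
reads per haplotype, or `force`), grouping is the phasing. Otherwise
reads are clustered by average-linkage agglomerative clustering on raw
pairwise Levenshtein distances of their insertions. Average linkage
keeps merge heights on the same scale as edit distances, which is the
scale on which the two cleaning rules below are defined; raw
(unnormalised) distance is used because a fixed dissimilarity cutoff in
base-pair units is what separates sequencing junk from genuine allele
structure at catalogued locus sizes.

Two cleaning rules apply:

* **Subtree exclusion.** While a child of the dendrogram root holds
  fewer than `exclusion_fraction` (default 0.10) of the reads and the
  root's merge height exceeds `exclusion_dissimilarity` (default 5),
  that child's reads are excluded and the root descends. This removes
  low-quality or non-repetitive reads hanging off the top of the tree
  without disturbing the surviving consensus (tested as an invariant).
* **Length outliers.** The larger allele is the group with the greater
  median insertion length. Any read at least twice that median is
  reported as an outlier and (by default) excluded from consensus;
  `keep_outliers_in_consensus` retains them. For a candidate inside the
  larger group the median is computed over its peers (leave-one-out),
  since otherwise a single aberrant read inflates the very median that
  should catch it; a zero median flags nothing.

The surviving tree is cut into two groups, and the call is heterozygous
only if both groups reach `min_support` (default 2 reads) and the final
merge height exceeds `max(hom_het_threshold, hom_het_rel ×
longer-median-length)` = `max(5, 0.05 × L)`. The relative term exists
because read-to-read edit distance grows linearly with allele length
under a fixed error rate, so a fixed threshold alone would split long
homozygous alleles. A locus with one supported and one unsupported
group degrades to a homozygous call on the supported group with a
warning. Haploid chromosomes (`haploid_chroms`) are never split;
genotypes are hemizygous. All failure modes collapse to a `missing`
genotype with a machine-readable reason.

### Consensus

Per-allele consensus is a partial-order alignment: the first read seeds
a linear base graph; each further read is aligned to the DAG by global
dynamic programming (match +2, mismatch −1, linear gap −2; indel pairs
cost more than a substitution) and fused, matched bases reusing nodes
and mismatches joining the node's aligned column. Edge weights count
traversing reads; the consensus is the heaviest-bundle source→sink
path, choosing each node's incoming edge by weight, then accumulated
score, then the lexicographically smaller predecessor base, making the
result deterministic for a given read order. Virtual source/sink nodes
let empty insertions (0 bp alleles) weight a direct source→sink edge,
so a group dominated by 0 bp reads yields an empty consensus. The DP is
vectorised row-wise (numpy prefix-max for the linear-gap insertion
recursion), which keeps 20 reads × 600 bp groups in the tens of
milliseconds.

## Composition engine

Alleles are cut into consecutive, non-overlapping k-length chunks from
position 0, with k the catalogued motif length — deliberately unbiased
to which motifs occur. Each chunk maps to the catalogued unit when it
is a rotation of it, else to its lexicographically smallest rotation; a
trailing remainder (< k) is the sentinel `OTHER` and is excluded from
fraction denominators, so row fractions sum to 1 over complete chunks.

* **Run-length encoding** renders maximal runs of one canonical label
  as `(CHUNK)n` (n ≥ 2) and single chunks bare, e.g. `(GGC)15`,
  `CCA(GCA)11`; decoding reproduces a sequence with the identical
  decomposition (property-tested).
* **Raw filter**: keep a motif iff it reaches ≥ 1 % of the sequence in
  ≥ 2 % of alleles, or any allele reaches 10 %. **Collapsed filter**:
  keep iff ≥ 5 % in ≥ 10 % of alleles, or at least five alleles reach
  10 %. Filtering drops columns only; retained fractions are never
  rescaled. The prevalence denominators are alleles (not individuals),
  consistent with the five-allele exception. Both filters are verified
  against exhaustive predicate evaluation on random matrices.
* **Collapsed grouping** bins retained fractions to the nearest
  `bin_width` (default 0.05 — "similar profile" is otherwise
  undefined); identical binned profiles form a group, groups below
  `min_group` (default 5) merge into a residual `other` row.
* **Sequence view**: the `top_n` (default 10) motifs by total chunk
  count get palette slots, count ties broken lexicographically;
  everything else (including `OTHER`) is gray. Alleles are ordered by
  length descending.
* **z-score**: `(x − mean)/sd` with the sample (n−1) standard deviation
  over the pooled allele lengths of the cohort at the locus; undefined
  (an error) for cohorts smaller than two or with zero spread.

## Synthetic data

The simulator emulates exactly the study conditions the pipeline
expects: a contig of seeded random flanks around a repeat locus, one or
two structured alleles (interruptions as `(motif, copies)` segments),
and per-allele `depth` spanning reads with uniform start jitter and
i.i.d. per-base errors applied in the order substitutions →
insertions → deletions, each read independently seeded so oracles can
replay it. Alignment records are constructed analytically from the
known provenance (matched flanks, one insertion/deletion at the
repeat, error perturbations), so no external aligner runs and output
BAMs are bit-reproducible. Default conditions used throughout the
tests: 400 bp contig flanks, ≥ 150 bp read anchors, 1200–1600 bp reads,
depth 10–20×, error rates 2 %/1 %/1 % — the depth and error regime of
current nanopore long-read data at the catalogued locus sizes, with
flanks sized to the simulated reads rather than the 5 kb default used
on real genomes.

What it does **not** emulate: homopolymer-biased nanopore error
profiles, strand-specific errors, coverage dips, somatic length
mosaicism, mapping errors in repetitive flanks, or alleles longer than
the read length (non-spanning reads are absent by construction; on real
data such reads are dropped, imposing a read-length ceiling on callable
expansions). Passing tests therefore demonstrate algorithmic
correctness under the stated noise model, not end-to-end accuracy on
real nanopore data.

Recovery under these conditions, recomputed by `scripts/acceptance.py`
at every run (problem sizes: 50 heterozygous loci with 0–600 bp alleles
at ≥ 3-motif separation for the noisy sweep; 200 random matrices for
the filter oracle): clean reads recover allele lengths exactly; noisy
sweeps recover both lengths within one motif in ≥ 90 % of loci with
≥ 95 % correct zygosity. The z-score fixture standardises a 100-sample
cohort to mean 300 bp, sd 10 bp and scores a 395 bp expanded allele.

## Catalog conventions

Catalog coordinates are BED-style 0-based half-open; VCF output is
1-based, using the indel anchor-base convention whenever an allele is
empty. Pathogenic cutoffs are stored in motif units and converted to bp
for reporting; since published cutoffs are sometimes quoted in bp, an
optional per-locus `cutoff_unit` column (`units`/`bp`) records the
convention, defaulting to `units`. The packaged example catalog is a
small illustrative set and not a substitute for a current disease
catalog.

## Known limitations

* Unit-cost edit alignment treats all errors equally; an aligner with
  affine gaps might anchor marginally better at very high indel rates.
* The fixed dissimilarity thresholds (exclusion 5, hom/het 5 + 5 % of
  length) can misbehave for alleles in the many-hundreds of bp when the
  two alleles differ by only a few motifs — length separation below the
  read-noise scale is not resolvable by clustering on edit distance.
* POA consensus is driven by the heaviest bundle; with exactly two
  reads, ties fall to the first read's bases, so two-read alleles carry
  that read's errors with probability ~1/2 per discrepant column.
* Remote (https/ftp/s3) alignment access follows whatever htslib
  supports; it is not exercised by the hermetic test suite.
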