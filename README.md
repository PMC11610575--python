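# longstr

Tandem repeat genotyping from spanning long reads, plus a
motif-composition engine for comparing repeat alleles across a cohort.

Short tandem repeats (STRs) — head-to-tail repetitions of a short DNA
motif — are among the most mutable loci in the human genome, and
expansions of dozens of them cause disease (Huntington disease,
myotonic dystrophy, fragile X syndrome, ...). Long sequencing reads
(e.g. Oxford Nanopore) can span an entire expanded allele, but standard
reference alignment fragments the repeat into a mixture of matches,
insertions and soft-clips that is painful to interpret. `longstr` is
aimed at researchers genotyping catalogued disease repeats from
long-read BAM/CRAM files and comparing patient alleles against a
control cohort.

## Method

For each catalogued locus `[start, end)` with motif `m` (length
`k = |m|`):

1. **Read collection.** Primary alignments that fully span
   `[start − f, end + f]` (margin `f`, default 100 bp, MAPQ ≥ 5) are
   collected; `HP` tags from upstream phasing are honoured.
2. **Excised-reference realignment.** An artificial reference
   `R = ref[start − F .. start) ⧺ ref[end .. end + F)` is built with the
   repeat deleted (flank `F`, default 5000 bp). Each read is realigned
   to `R`, so its entire repeat allele surfaces as the sequence between
   the two flanks at the excision junction; that junction insertion is
   taken to be the complete repeat allele of the read.
3. **Allele grouping.** Without usable phasing, reads are clustered by
   average-linkage hierarchical clustering on pairwise Levenshtein
   distances of their insertions. Subtrees at the top of the dendrogram
   holding < 10 % of reads at merge dissimilarity > 5 are excluded as
   low-quality/non-repetitive reads. Reads at least twice the median
   length of the larger allele are reported as length outliers. Haploid
   chromosomes are never split into two alleles.
4. **Consensus.** Each allele with ≥ 2 supporting reads is polished by
   partial-order alignment (POA): reads are fused into a weighted DAG
   and the heaviest-bundle path is the consensus.
5. **Output.** VCF 4.2 with full ALT sequences (`GT:AL:SUP:OL`), plus a
   lengths TSV (total bp and difference with the reference).

The composition engine decomposes an allele into consecutive k-mers,
canonicalised under rotation (a chunk equal to a rotation of the known
unit is labelled with that unit, otherwise with its lexicographically
smallest rotation). On top of the per-allele motif tracks it provides
run-length encodings such as `(GGC)15` or `CCA(GCA)11`, cohort
composition matrices with the `raw` (< 1 % of the sequence in < 2 % of
alleles discarded, unless some allele reaches 10 %) and `collapsed`
(< 5 % in < 10 % of alleles, unless five alleles reach 10 %) noise
filters, a profile-grouped `collapsed` view, a positional `sequence`
view colouring the ten most frequent motifs, and cohort z-scores
`z = (x − x̄)/s` for flagging expansion outliers.

A seeded simulator (`longstr.simulate`) generates the matching inputs —
reference contig, catalog, noisy spanning reads as a sorted indexed BAM
and a ground-truth JSON — so the whole pipeline is testable hermetically.

## Worked example

Simulate a heterozygous locus — a reference-like `(CAG)17` allele and an
interrupted expansion `(CGG)9 AGG (CGG)32` — at 12× per-allele depth
with 2 %/1 %/1 % substitution/insertion/deletion errors, then genotype
and inspect it:

```sh
cat > spec.json <<'JSON'
{"seed": 42,
 "allele_structures": [[["CAG", 17]], [["CGG", 9], ["AGG", 1], ["CGG", 32]]],
 "reference_structure": [["CAG", 17]],
 "depth": 12,
 "error_rates": [0.02, 0.01, 0.01]}
JSON
longstr simulate --spec spec.json --outdir sim
longstr genotype --bam sim/reads.bam --ref sim/reference.fa \
    --catalog sim/catalog.tsv --sample demo \
    --out-vcf demo.vcf --out-tsv demo.tsv
longstr compose --vcf demo.vcf --catalog sim/catalog.tsv --view rle --out comp
```

The genotype step logs
`locus SIMLOC: n_reads=24 n_excluded=0 zygosity=het` and the VCF record
carries `GT:AL:SUP:OL` = `0/1:51,126:12,12:0,0`: a heterozygous call
with a 51 bp allele identical to the reference repeat and a 126 bp
expanded allele, each supported by 12 reads, no outliers. The lengths
TSV shows the expansion as `+75` bp over the reference, and the
run-length encodings recover the simulated structures exactly despite
the read noise:

```
allele_id       rle
demo:SIMLOC:0   (CAG)17
demo:SIMLOC:1   (CGG)9AGG(CGG)32
```

`longstr zscore --vcf demo.vcf --cohort-tsv cohort.tsv --locus SIMLOC`
compares each allele length against a cohort lengths table.

A small STRchive-style example catalog ships with the package
(`longstr.catalog.example_catalog_path()`).

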