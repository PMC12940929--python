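# amplistr

Amplicon-based short tandem repeat (STR) profiling from noisy long reads.

`amplistr` builds a sequence-based STR allele catalog from GenBank-style
records, assigns genome-aligned reads to candidate alleles by semi-global
edit distance, calls autosomal genotypes and Y haplotypes from read counts
normalized to the top allele, and reports profiles in both sequence-based
(bracketed repeat motif) and CE-compatible length-based nomenclature. A
concordance benchmarker (TP/FP/FN, precision/recall/F1 at the allele level)
and a seeded amplicon-read simulator make the whole pipeline testable
offline without any downloads.

## Layout

| module | role |
| --- | --- |
| `amplistr.nomenclature` | bracketed motif parsing/serialization, length-based allele designations (incl. microvariants like `15.1`) |
| `amplistr.catalog` | GenBank record parsing, redundancy collapse, reference flank assembly, catalog FASTA/TSV/BED I/O |
| `amplistr.intake` | SAM/BAM loading, primary-alignment filtering, binning reads to the STR locus they fully span, mapping statistics |
| `amplistr.matcher` | Myers bit-parallel semi-global edit distance, per-read allele assignment, per-locus count tables |
| `amplistr.caller` | top-allele normalization, heterozygote threshold calling (default 0.4, strict), Y haplotypes, DYS385a/b read merging |
| `amplistr.report` | profile TSV writer/reader, ground-truth TSV, TP/FP/FN tallies (paper-concordant and conventional dialects), precision/recall/F1 |
| `amplistr.simulate` | deterministic toy catalogs (GenBank + mini reference) and nanopore-like amplicon reads with substitution/indel error and PCR stutter models |
| `amplistr.pipeline` | glue: alignments (or FASTQ via an external aligner) → profile |

## CLI

```sh
# 1. build an allele catalog from GenBank records + a reference genome
amplistr build-db --genbank alleles.gb --reference hg38.fasta --flank 500 --out db/

# 2. profile a sample from genome-aligned reads (or FASTQ with --reference)
amplistr profile --input sample.bam --db db/ --threshold 0.4 --out results/

# 3. benchmark a predicted profile against ground truth
amplistr benchmark --predicted results/sample.profile.tsv \
    --truth truth.tsv --level length --out benchmark.tsv

# generate a fully synthetic dataset (catalog + reads + truth) to try it out
amplistr simulate --out sim/ --depth 200 --sub 0.05 --ins 0.02 --del 0.03 \
    --stutter 0.1 --seed 7
```

Notes:

* Catalogs auto-built from records anchor each locus at its recorded
  genomic interval. For duplicated loci typed as one marker (DYS385a/b),
  supply a BED naming both target sites via `--bed` (the `simulate` command
  emits one under `sim/db/loci.bed`); reads from both sites are pooled and
  the top two alleles over the threshold are reported.
* Homozygous autosomal calls are reported once but count as two allele
  calls during benchmarking.
* The benchmark's default `paper` tally dialect books a substituted allele
  as a false positive only; `--mode conventional` also counts the displaced
  truth allele as a false negative.

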