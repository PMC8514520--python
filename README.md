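# pirnasig

Read-level statistical signatures of ribosome-guided piRNA biogenesis on mRNA
3′UTRs, packaged as a tested, reusable library with a CLI and a seeded
synthetic-data generator, so every analysis stage is testable without
external downloads.

## What it computes

- **5′-end overlap distance spectra** between two read sets (e.g. ribosome
  footprints vs piRNAs), with a Z score at the exact-coincidence offset
  against the −50..−1 / 2..50 background, and one-sided normal p-values.
- **Ping-pong statistics**: opposite-strand 5′–5′ overlap pair counts with
  the standardized excess at overlap 10 (z10).
- **Phasing periodograms**: the classical (Schuster) periodogram of a read
  set's self distance spectrum, for detecting 3-nt footprint periodicity.
- **Nucleotide-bias logos** (1U bias) at read 5′ ends and 1 nt upstream,
  with Shannon information content in bits, plus first-nucleotide-matched
  simulated control reads (sliding-window 28-mer pool, exact
  largest-remainder stratified sampling).
- **Region-aware quantification**: ppm/rpkm per 5′UTR/ORF/3′UTR (reads
  assigned by their 5′ end; rpkm pseudocount 0.001), exon/intron enrichment,
  exon–exon junction read assignment, length-rescaled 10%-trimmed-mean
  metagene profiles, per-transcript region ratios, and sense/antisense TE
  content of transcripts.
- **Coupling statistics and calling**: partial correlation of piRNA vs RPF
  abundance conditional on RNA abundance (residual method, verified against
  the closed form), a Yates-corrected 2×2 chi-square helper, and 3′UTR
  precursor (uppl) calling with >100 ppm / ≥90% 3′UTR fraction / ≥1 ppm ORF
  RPF thresholds.
- **Synthetic data**: seeded generators for transcript models (BED12/FASTA),
  piRNA/RPF read libraries with configurable 1U bias, frame fidelity, 5′
  coincidence rate, and ping-pong fraction, TE inserts, and coupled or
  decoupled (rna, rpf, pirna) abundance triplets. All generator parameters
  are recoverable from the generated data (tested to ±0.02).

## CLI

One entry point, `piRNA-sig`, with subcommands:

```
piRNA-sig simulate --preset uppl --n 30 --seed 1 --out-dir sim/
piRNA-sig spectrum --a sim/rpf_reads.tsv --b sim/pirna_reads.tsv --out spec.tsv
piRNA-sig pingpong --plus sim/pingpong_plus.tsv --minus sim/pingpong_minus.tsv
piRNA-sig periodogram --reads sim/rpf_reads.tsv
piRNA-sig bias --reads sim/pirna_reads.tsv --precursors sim/transcripts.fa
piRNA-sig simulate-controls --precursors sim/transcripts.fa --reads sim/pirna_reads.tsv \
    --n 10000 --seed 1 --out-prefix controls
piRNA-sig quantify --reads sim/pirna_reads.tsv --transcripts sim/transcripts.bed --out ab.tsv
piRNA-sig metagene --reads sim/rpf_reads.tsv --transcripts sim/transcripts.bed --out meta.tsv
piRNA-sig te-content --transcripts sim/transcripts.bed --te-bed sim/te.bed --out te.tsv
piRNA-sig region-ratio --num a.tsv --den b.tsv --transcripts sim/transcripts.bed --out ratio.tsv
piRNA-sig junctions --reads unmapped.tsv --transcripts t.bed --genome genome.fa --out j.tsv
piRNA-sig partialcorr --table sim/abundance_triplets.tsv
piRNA-sig chi2 207 4 326 3
piRNA-sig call-uppl --pirna-abundance pa.tsv --rpf-abundance ra.tsv \
    --transcripts sim/transcripts.bed --out calls.tsv
piRNA-sig run --preset uppl --seed 1 --out-dir run1/   # end-to-end + JSON report
```

Annotations are read from BED12 or GTF (Ensembl dialect; coordinates
converted to 0-based half-open on read, ORF includes the stop codon).
Reads come from tab-delimited tables (`ref_id  strand  five_prime  length
[count  sequence  chemistry]`) or BED6. All outputs are TSV with a header
line, plus a JSON report for `run`.

## Conventions

- No offset 0 in distance spectra: offset 1 is exact 5′-end coincidence,
  negative offsets are upstream. The Z-score background is the sample
  (n−1) standard deviation over the 99 non-focal offsets.
- Minus-strand read `five_prime` is the plus-strand coordinate of the
  5′-most template base.
- All statistics weight collapsed reads by their `count` multiplicity;
  ppm = count / norm_denominator × 10⁶.

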