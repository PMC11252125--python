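# protoy

Structural characterization of young male-determining (**M**) loci on proto-Y
chromosomes.

Many insects carry recently evolved proto-Y chromosomes: one homolog of an
otherwise ordinary chromosome pair has acquired a dominant male-determining
locus and is therefore hemizygous in males, while the rest of the chromosome
has not yet degenerated. Characterizing such a locus from sequencing data
means answering a small set of recurring questions: *how many copies of the
male-determining gene does the locus carry, what is its internal architecture
(palindrome? tandem array?), where exactly was it inserted, does the insertion
carry transposition signatures, and how diverged are the intact gene copies
from one another?* `protoy` implements each of these analyses as a tested,
reusable library with a thin CLI, and ships a synthetic-genome generator so
every analysis can be exercised end-to-end against machine-readable ground
truth.

## What it computes

**Hemizygous copy number from read depth.** Reads are placed on the target
gene *g* and three single-copy autosomal reference genes *r₁, r₂, r₃* by exact
k-mer seeding plus substitution-only verification; multi-placed reads get
weight 1/n over their n equally best placements. With per-base mean coverages
C(·),

    copy number = 2 · (1/3) Σᵢ C(g) / C(rᵢ)

— the factor 2 corrects for the target being hemizygous while autosomal
references have two alleles. Female coverage over the target is reported as an
off-target (paralog) background check.

**Male-specific regions by female subtraction.** Positions of a contig with
female depth ≥ 1 are masked; unmasked positions with male depth ≥ 5 (the
default minimum coverage) are merged into BED intervals. Interval sets from
several male datasets can be overlaid into presence-pattern sections (which
parts of the locus are private to one strain, shared by some, or by all).

**Architecture by self-alignment.** A dotplot engine chains shared k-mers on
diagonals (forward) and anti-diagonals (reverse complement) into match
segments, then calls: palindromes (mirror-placed reverse segments merged into
arm pairs, re-aligned for percent identity, spacer = gap between arms), tandem
duplication clusters (single-linkage over forward segments, with an estimated
period), and gene copies (gene-vs-contig matches merged when collinear,
classified intact iff they cover ≥ 99 % of the gene and the contig sequence is
a complete ORF).

**Insertion borders and transposition signatures.** Aligning the M-contig to
its non-M homolog brackets the interval present only on the M-contig between
two high-identity flank matches. The insertion's end windows are locally
aligned to each other (one reverse-complemented) to detect terminal inverted
repeats (TIRs), and the flanking sequence is scanned for a target-site
duplication (TSD): a short direct repeat flanking the insertion that occurs as
a single copy at the homologous junction of the non-M contig. TIR + verified
TSD ⇒ "transposon-like".

**Consensus divergence.** Intact ORF copies are voted into a majority
consensus; each copy's mismatching positions are listed and classified
synonymous/nonsynonymous under the standard genetic code.

## Worked example

The `mv` demo generates a compact palindromic locus — two intact, inverted
copies of a 2199 bp male-determining gene 4.7 kb apart around a 3046 bp
spacer, flanked by tandem-repeat blocks and TIRs, 31 kb in total — inserts it
into a host chromosome with a 9 bp target-site duplication (`TTTTAGGTT`),
simulates 100 bp reads at 15× per haplotype for a male and a female, and runs
every analysis against the recorded truth:

```
protoy demo --preset mv --seed 42 --out demo_mv
```

Key numbers from `demo_mv/report.json` (seed 42):

* `copy_number.estimate.copy_number` = **2.020** (truth 2): target mean
  coverage 29.51 against reference means 27.68 / 30.62 / 29.51, relative
  coverages 1.066 / 0.964 / 1.000, averaged and doubled. Female background
  over the target is 0.0 (negligible).
* `palindrome` = arm length 13 977 bp at 99.99 % arm-to-arm identity around a
  spacer of **3046 bp** (exactly the generated spacer; the single arm-to-arm
  difference is the one synonymous substitution the generator plants between
  the two gene copies).
* `insertion` = interval of **31 009 bp** (31 kb rounded; locus 31 000 bp plus
  one copy of the 9 bp TSD), TSD motif `TTTTAGGTT` length 9 verified as a
  single copy on the non-M contig, terminal inverted match present ⇒
  signature **"transposon-like"**.
* `copies` = 2 copies, both intact, **4700 bp** apart (4.7 kb).
* `divergence.counts` = 0 and 1: the second copy differs from the two-copy
  consensus at exactly the planted synonymous site.

The `miii` demo instead generates a ~180 kb tandem array of 88 gene copies
(exactly one intact) and reports, for seed 42: copy-number estimate 41.9
against a depth-equivalent truth of 43.8 (−4.2 %), 88 copies called with 1
intact, truncated copies covering 40.0 % of the contig (truth 40.0 %),
male-specific intervals recovering 99.998 % of locus positions with male depth
≥ 5, and presence-pattern sections across three simulated male strains with
nested sub-loci.

Other subcommands operate on standard files instead of presets: `protoy
simulate` (FASTA/FASTQ/truth JSON out), `copynum` (reads → copy-number JSON),
`mspec` (samtools-dialect depth TSVs → BED), `structure` (contig FASTA →
segments TSV, copies BED, palindrome/cluster JSON), `borders` (two contig
FASTAs → insertion JSON/BED), `diverge` (ORF multi-FASTA → consensus FASTA +
per-copy TSV).

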