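# Methods

This note documents the models, assumptions, parameter choices and numerical
conventions behind `protoy`. Coordinates are 0-based half-open everywhere;
every stochastic operation takes an explicit seed and there is no hidden
global RNG state.

## The biological setting being modelled

A dominant male-determining locus that recently landed on an ordinary
chromosome is hemizygous: males carry it on one homolog, females not at all.
Against that background the package models two locus architectures observed in
young M-loci:

* a **palindromic locus** — two intact, inverted copies of the
  male-determining gene separated by a non-palindromic spacer, with
  tandem-repeat blocks at the distal ends of the arms, terminal inverted
  repeats (TIRs) at the locus boundaries, and a short target-site duplication
  (TSD) flanking the whole insertion; and
* a **tandem-array locus** — many head-to-tail copies of the gene, almost all
  truncated, interleaved with non-gene repeats.

## Synthetic genomes (synthio)

Background sequence is i.i.d. random with configurable base frequencies
(default uniform); genomic context beyond the planted features is irrelevant
to the computations under test, so no attempt is made to model real base
composition, repeats outside the locus, or chromosome-scale structure.

**Palindromic locus.** Layout per arm: `TIR + distal repeats + pad + gene +
fill`, mirrored exactly (arm 2 = reverse complement of arm 1) around a spacer
carrying a direct terminal repeat at each end. `intercopy_gap` (distance
between the two gene copies) = fill + spacer + fill, so `intercopy_gap −
spacer_len` must be even and non-negative. `total_len_target` is met by sizing
the pad; a target of the wrong parity yields a locus one base short, because
the pad must stay arm-symmetric to keep the palindrome exact. Defaults follow
the modelled locus: spacer 3046 bp, inter-copy gap 4700 bp, 9 bp TSD motif
`TTTTAGGTT`, 28 bp TIR, 12 × 171 bp distal repeats per arm, 31 kb total.
By default one synonymous substitution is injected into the second gene copy
(`arm_substitutions=1`), mirroring the near-identity of palindrome arms under
concerted evolution; the substitution site is chosen at a codon position that
is synonymous under the standard code, so both copies remain intact ORFs.

**Tandem array.** `n_copies` head-to-tail copies, `n_intact` of them complete
(the 88-copy preset fixes the intact copy at index 35); each truncated copy
retains a seeded random gene subinterval whose length is a fraction in
[`truncation_min_frac`, `truncation_max_frac`] of the gene and at least
`min_copy_len` = 300 bp (shorter fragments would fall below the enumeration
caller's `min_len` and make "copy count" ill-defined). Intervening gaps are
unique random filler (≥ 100 bp when the budget allows, so adjacent copies are
never chained together), occasionally salted with repeat units; their total
length is set by `intervening_frac` (default 0.45 of the locus).

**Construction guarantees (truth hygiene).** The truth record must equal the
maximal homology actually present, so the generator patches single background
bases where a chance coincidence would extend a planted feature: the host
bases immediately flanking an insertion are forced to differ from the insert's
edge bases (otherwise ~25 % of seeds per edge carry a TSD one base longer than
the planted motif), and gap bases adjacent to each tandem-array copy are
forced to differ from the next gene base (otherwise copy intervals extend 1–3
bp beyond the planted truncation). These patches are decided at construction
time from the generator's own parameters.

**Reads.** Single-end reads of fixed length are drawn uniformly per haplotype
at `depth` fold-coverage per haploid copy, so diploid regions see twice the
per-haplotype rate and the hemizygous locus sees it once. Substitution errors
are applied per base at `error_rate` (default 10⁻³); there are no indel
errors, no quality model, no paired ends and no read-length distribution —
the estimators under test are placement- and depth-based only. Read names
encode haplotype, chromosome, start and strand for debugging.

**Problem sizes.** The demo scenarios use a 60 kb host chromosome plus two
25 kb reference-gene chromosomes, a 2199 bp gene, 100 bp reads at 15× per
haplotype (30× diploid). These are desk-scale stand-ins chosen so a full demo
runs in seconds while every per-gene coverage still has thousands of reads;
all structural constants of the loci are kept at their full values.

## Read placement and copy number (covmap)

Placement is exact k-mer seeding (default seed length 31, taken at
`max_mismatches + 1` evenly spaced offsets) followed by full-length
substitution-only verification with ≤ `max_mismatches` (default 2)
mismatches. When the seeds are disjoint (read length ≥ (m+1)·s) the pigeonhole
principle makes the search exhaustive for qualifying placements. A read's
equally best placements share weight 1/n — deterministic and unbiased for
coverage sums, in contrast to aligners that assign a random primary placement.
Reads shorter than the seed are skipped and counted.

"Average coverage" of a gene is the mean over **every** base of the gene
sequence, including zero-depth positions. Copy number = 2 × the mean of the
three target/reference coverage ratios; a zero-mean reference raises
immediately (a broken reference choice should not silently produce infinite
ratios). For truncated-copy arrays the estimator's ground truth is defined as
(total gene-homologous bases in the locus) / (gene length): depth cannot
distinguish 88 partial copies from the equivalent number of full copies.
A small negative bias (≈ 4 % at the defaults) is expected for arrays of short
copies, because reads spanning a copy boundary fail to place on the gene
reference while the same edge effect is weaker for the full-length reference
genes; this is well inside the ±15 % recovery tolerance used in the tests.

Masking uses threshold ≥ 1 (any female coverage masks a position) by default.
Male-specific intervals are maximal runs of unmasked positions with male depth
≥ `min_cov` (default 5); merging across gaps ≤ `merge_gap` (default 0) never
bridges a masked position, so no interval can overlap the mask. Raising
`min_cov` can only shrink intervals; raising the mask threshold can only grow
them. Depth tracks serialize in the samtools-depth dialect (TAB-separated
name / 1-based position / depth, zero rows optionally omitted, fractional
depths at fixed precision 4).

## Self-alignment engine (selfalign)

Seeds are exact shared k-mers; forward seeds chain on equal diagonals
(t − q), reverse-complement seeds on equal anti-diagonals (q + t), with
unmatched stretches ≤ `max_gap` (default 50 bp) along the diagonal. Because
the generator introduces substitutions only, drift across diagonals (indels)
is deliberately not chained; the engine is a dotplot, not a gapped aligner.
Segment identity is recomputed by global edit-distance re-alignment (edlib) of
the called intervals — seed density under-estimates identity. The identity
diagonal is excluded and each symmetric pair is reported once (query start ≤
target start).

Word sizes follow the task: k = 15 for palindrome-scale analysis, k = 10 for
fragmented copy arrays, k = 50 for cross-contig flank anchoring on synthetic
contigs (all configurable).

**Palindromes.** Reverse segments in mirror order are grouped by
anti-diagonal (single linkage, tolerance 100 bp = 2 × max_gap); each group's
query side is arm 1, target side arm 2, re-aligned as arm1 vs revcomp(arm2)
for identity. A spacer-less palindrome produces one segment that overlaps
itself by up to k − 1 around the hairpin centre; such arm pairs are split at
the midpoint. Calls are sorted longest-arm first.

**Tandem clusters.** Forward segments cluster by single linkage on their
spans. The period is the median of member offsets after discarding offsets
> 1.5 × the minimum: in a head-to-tail array the offset multiset contains all
multiples of the unit spacing, and a plain median would report a multiple for
short arrays. For arrays of irregular truncated copies the "period" is a
rough typical spacing, not a precise unit length.

**Copy enumeration.** Gene-vs-contig segments merge into one copy when
continuous on both sequences (collinear within `max_gap`, same strand); ties
resolve leftmost-start then longest. A copy is intact iff its matched gene
subinterval covers ≥ `intact_min_frac` (default 0.99) of the gene **and** its
oriented contig sequence is a complete ORF (ATG start, terminal stop, no
internal stop, length ≡ 0 mod 3). The ORF rule is strict — zero frameshifts:
a near-complete copy with indels classifies as truncated. `min_len` = 200 bp
and `min_identity` = 85 % operationalize where "truncated copy" ends and
incidental similarity begins. The truncated fraction of a contig is the
length of the union (not the sum) of non-intact copy intervals divided by the
contig length.

## Borders and transposition signatures (borders)

Flanks are anchored with the cross-contig chaining engine; the left flank is
the forward segment starting leftmost, the right flank the one ending
rightmost, both required to reach `min_flank` (default 500 bp). Absence of a
flank on either side raises "borders undeterminable" — the expected outcome
when the homolog of the locus region is simply not in the assembly. When the
two flank images on the non-M contig overlap (the TSD situation, or an
insertion inside a host tandem repeat) the insertion interval is extended
rightwards by the overlap and the overlap width is reported as the placement
ambiguity. **Dialect:** the insertion interval contains exactly one of the two
TSD motif copies (the right one), which makes plain deletion of the interval
reconstruct the non-M contig exactly — a directly testable invariant.

TSD detection scans motif lengths from the top of `len_range` (default 2–20)
downwards, testing exact equality (0 mismatches, gap 0) of the L-mer
immediately left of the insertion and the L-mer ending at the insertion's
right edge, then verifying the motif occurs as a single copy at the homologous
junction of the non-M contig. The longest verified length wins. TIR detection
is the best local alignment (match 2, mismatch −3, linear gap −4) between the
insertion's first window and the reverse complement of its last window
(default window 300 bp, reported at length ≥ 10 and identity ≥ 80 %). On a
palindromic locus the terminal inverted match legitimately extends beyond the
annotated TIR into the distal repeats — the detector reports maximal inverted
terminal homology, not an annotation. Signature labels: TIR + verified TSD ⇒
"transposon-like"; otherwise "TSD-only" / "TIR-only" / "none".

## Consensus divergence (diverge)

Inputs must be ≥ 2 complete ORFs of high pairwise identity (≥ 95 % enforced).
Unequal lengths are projected onto the longest input by global alignment
before per-column majority voting; ties break toward the first input's base
(deterministic — the choice of tie-break is arbitrary and documented rather
than hidden); gap-majority columns are dropped and reported. Divergent sites
are mismatching nucleotide columns only (indels are not counted as
divergence), reported 0-based on the consensus (external TSVs add a 1-based
column). Classification translates the consensus codon with and without the
observed base under the standard genetic code; a substitution creating an
internal stop is flagged, not an error.

## What passing tests do and do not show

The generator reproduces the *structural* statistics the detectors consume:
hemizygous dosage, exact repeat geometry, uniform coverage, substitution-only
divergence. It does not emulate sequencing indels, coverage biases (GC,
mappability), assembly errors, or repeat families beyond those planted.
Consequently, green tests demonstrate that the estimators and callers are
correct under their stated models and recover planted parameters at realistic
sizes — not that they are robust to real-data artefacts such as collapsed
assemblies or indel-rich copies (the strict ORF rule, in particular, will
under-count "intact" copies in noisy assemblies).

## Numerical conventions and degenerate inputs

Fractional depths from weight-split reads are clamped for the ~10⁻¹⁶ negative
residue cumulative summation can leave. `k` < 8 is rejected; a sequence
shorter than k self-aligns to an empty segment list (not an error). Identical
M and non-M contigs return an empty insertion flagged "identical" at the
trivial breakpoint. An empty insert, an out-of-bounds placement, a reference
gene on the M chromosome, more intact than total copies, and a zero-mean
reference track all raise with named messages. Demo outputs (config snapshot,
truth JSON, report JSON, log) are byte-identical across reruns with the same
seed; the log deliberately omits wall-clock times for that reason.

## Known limitations

* Placement is substitution-only; indel-containing reads are unplaced (and at
  the default error model none are generated).
* The dotplot engine chains exact diagonals, so indel-containing repeats
  fragment into multiple segments; copy merging tolerates this only within
  `max_gap` per junction.
* The tandem-cluster period is a coarse spacing estimate (see above).
* `find_insertion` assumes one insertion between two anchorable flanks; nested
  or multiple insertions between the same flanks would be reported as one
  interval.
* Consensus voting assumes mutations are rare and mostly private to copies;
  sites mutated in ≥ half the copies will flip the consensus (by design of
  majority voting).
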