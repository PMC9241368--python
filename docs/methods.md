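# Methods

This note records the models, rules and numerical choices behind tipscan, and
what the synthetic validation does and does not demonstrate.

## TE classification

A structural-variant sequence is accepted as a copy of a TE library element
when its best local alignment reaches both **identity ≥ 80%** and **query
coverage ≥ 80%** (both thresholds are parameters). Scoring is affine-gap
Smith–Waterman: match +1, mismatch −2, first gap base −5, each further gap
base −2 (delegated to Biopython's `PairwiseAligner`; tests verify score
equality against an independent O(nm) dynamic-programming oracle).

*Identity* is matching columns over all aligned columns (gap columns count
against identity). *Coverage* is aligned query bases over query length,
summed over non-overlapping local hits to the same subject: after the best
hit, the remaining query prefix/suffix is re-aligned and secondary hits
scoring ≥ 25 contribute (fragmented old elements align as several
high-scoring pairs; the score floor stops short spurious hits between
unrelated sequences from inflating coverage). Coverage is query-side by
default — the question asked is "is this SV a TE copy", not "is the element
fully present" — with a reciprocal-coverage flag available. Under this
scoring a uniformly diverged full-length copy stays fully aligned up to
roughly one-third divergence (expected per-column score 1−3p > 0), so the
identity threshold, not alignment truncation, decides the 80–80 boundary:
15% divergence → identity ≈ 85 (classified), 25% → ≈ 75 (rejected).

Tie-breaks among passing library hits: higher identity, then longer
alignment, then lexicographic element id. Sequences under 50 bp are never
classified. Classification is monotone in both thresholds by construction.
Externally computed 12-column tabular hits can be ingested in place of the
internal aligner; coverage then sums overlap-trimmed hit intervals per
(query, subject) and identity is the alignment-length-weighted mean.

Genic context assigns one of CDS / intron / upstream2kb / downstream2kb /
intergenic with precedence CDS > intron > upstream > downstream; flanks are
strand-aware and 2 kb by default; among equal-precedence genes the nearest
gene start wins. Positions inside non-coding exon sequence (UTRs) take the
intron slot, as the four-class scheme has no separate UTR class.

## Collation of pairwise SV calls

All calls are projected onto one anchor genome; a deletion in the anchor at
interval start *s* is re-expressed as an insertion at *s* carried by the
other genome, so the presence allele (CC) always means "TE present". Calls
within 100 bp on the same contig whose sequences reach 80% identity *and*
80% query coverage in a local alignment merge into one locus (identity alone
is insufficient: any two random sequences share a short perfect local hit).
The longest sequence represents the locus; every contributing genome pair is
recorded as support, so support counts conserve the input count, and the
procedure is idempotent and input-order-invariant (records are processed in
sorted order with deterministic tie-breaks). Both merge parameters are
exposed; no published redundancy-collapse rule exists for this step, so
these defaults are this package's own.

The aligned/unaligned region partition is a point-in-interval query against
merged, sorted half-open BED intervals; contigs absent from the map are
unaligned.

## Genotyping model

Per locus, two mapping targets: the **presence construct**
`left_flank(≤1 kb) + TE + right_flank(≤1 kb)` (flanks truncated at contig
ends, never padded) and the **absence construct** `left_flank + right_flank`.

The built-in mapper seeds with exact 21-mers (stride 13, plus the final
position) in both orientations against an index of all construct sequences,
evaluates each candidate diagonal by ungapped comparison, and — when a read
only partially belongs to a diagonal — trims to the best-scoring contiguous
segment under the same +1/−2 scoring (the ungapped analogue of local
alignment). A gapped banded rescue against the seeded window exists behind a
flag for indel-containing input; the bundled simulator introduces
substitutions only, and external indel-aware alignments can be ingested from
SAM instead (matched bases computed from CIGAR/NM, same > 20 bp filter).
Alignments with ≤ 20 matched bases are dropped. Per construct sequence the
placement maximizing matched bases is kept, ties broken by position, so the
genotyper sees each read's best placement on *both* alleles of a locus. On
error-free reads, placements equal exact substring search (tested).

Evidence, deduplicated by alignment coordinates (PCR duplicates count once):

* **presence** — a read covering junction L or R with ≥ 20 bases on each
  side *and* aligning better to the presence than the absence allele; or a
  pair with one mate wholly in a flank and the other wholly inside the TE.
* **absence** — a read covering the flank–flank junction of the absence
  construct with ≥ 20 bases on each side and a better absence-side
  alignment; or a pair with mates wholly in opposite flanks whose absence
  span is ≤ mean insert + 3·sd (2 kb fallback cap when no genome-wide
  insert estimate is available).

Decision with `min_presence = min_absence = 1` (exposed; 1 is permissive and
noise-sensitive at realistic error rates): presence only → CC; absence only
→ GG; both classes at threshold → CG if the minority class holds ≥ 20% of
the evidence, else the majority homozygote; neither → NN. NN therefore
means "insufficient evidence", never "conflicting evidence"; a locus with
50 presence reads and 1 stray absence read is CC, not NN. The heterozygote
rule (both classes, minority fraction ≥ 0.2) is this package's definition —
mapping-pattern genotyping of this kind has no published CG criterion — and
is validated on simulated 50:50 haplotype read mixtures.

The requirement of ≥ 20 bases on *each* side of a junction (rather than a
global ≥ 20 bp alignment) is deliberate: symmetric anchoring prevents
soft-clip-style false junction support.

Insert-size validation: a fragment sequenced from a TE-lacking haplotype but
placed on TE-containing coordinates is stretched by exactly the TE length,
so flank-bracketing spans near `mean_insert + te_length` (± 3 sd) confirm an
insertion of that length; spans near `mean_insert` are consistent with no
insertion. Insert statistics require ≥ 20 genome-wide pairs.

## Population statistics

* **MAF**: presence-allele count over 2 × (non-NN calls); CG contributes one
  allele of each kind. Loci with MAF ≤ 0.05 are removed before
  tree/PCA/scan. Filtering is monotone in the threshold.
* **Distance**: mismatch fraction of allele dosage over loci called in both
  accessions (CC↔GG = 1, het↔hom = 0.5). All-NN accessions and pairs with
  no shared called locus are errors, not silent zeros.
* **NJ**: Saitou–Nei with the standard Q criterion; ties break on the
  smallest index pair; a negative branch length is clamped to zero and the
  deficit moved to the sister edge, preserving the joined pair's path
  length. Exact recovery on additive matrices is tested against an
  independent random-tree generator and cross-checked against scikit-bio.
* **PCA**: dosage GG/CG/CC = 0/1/2, per-locus centering and 1/√(2p(1−p))
  scaling, NN imputed to the locus mean, eigendecomposition of the
  accession covariance; monomorphic loci contribute zero; each PC's
  largest-magnitude loading is made positive for a deterministic sign.
* **Fisher scan**: carriers (CC+CG) vs non-carriers (GG), NN excluded, per
  locus; two-sided Fisher's exact p (scipy; equals exhaustive hypergeometric
  enumeration to < 1e−7 relative error, tested); −log10(p) is z-scored
  across all loci of one scan (population sd). Bonferroni and BH columns are
  emitted for convenience but never used in ranking.
* **Core-variant comparison**: per gene, the smallest TIP p and smallest
  nonsynonymous-SNP p; paired two-sided t-test on raw p differences
  (−log10 variant behind a flag); genes lacking SNPs are reported but
  excluded from the pairing; zero-variance differences are flagged
  degenerate rather than reported as a spurious t.
* **SNP effects**: standard nuclear codon table, strand-aware; an unchanged
  amino acid (stop included) is synonymous. The nonsynonymous/synonymous
  ratio of random SNPs is validated against exhaustive enumeration of all
  nine single-base changes per codon.

## Synthetic data: what it emulates, what it does not

The generator emulates the target study design: a pan-genome of donor
assemblies differing from a base genome by planted TE copies at known loci;
150 bp paired-end resequencing (insert 500 ± 50 bp, 20× coverage) of every
accession; and a two-group population (329 vs 195 accessions) in which five
of 500 loci are enriched at 0.80 vs 0.02 carrier frequency. Defaults:
uniform-random base genomes and TE elements (3–6 kb), one TE copy per locus
shared by all carriers (one historical insertion event), optional uniform
point divergence of the planted copy, per-base substitution errors
(default 1e−3; the validation presets use 0), homozygous accessions with
heterozygotes simulated as 50:50 read mixtures. Loci are spaced ≥ 2.6 kb so
neighbouring 1 kb flanks stay disjoint. Everything is deterministic under
the configured seed, byte for byte.

Deliberately not modelled: TE nesting and LTR structure (target-site
duplications, paired LTRs), indel sequencing errors, recombination and
demography, reference bias from a real repeat landscape. Passing the
synthetic validation therefore demonstrates the *decision logic* — junction
detection, pattern classification, threshold behaviour, scan power — under
clean mappability, not performance on real repeat-rich genomes, where
multi-mapping and diverged flanks will raise NN rates and genotype error.

## Problem sizes and presets

`tiny` (3 loci × 6 accessions) is a smoke-test fixture; `demo` (50 loci ×
60 accessions, error-free 20× reads, ~1M read pairs) is the genotyping
validation scale; `scan_only` (500 loci × 524 accessions) is the selection
design. These sizes keep full validation runs in the minutes range on one
core while preserving the study's group sizes and effect sizes; genome-wide
counts from the original 20-assembly, 524-accession dataset are not
reproducible from simulation and are out of scope.

## Known limitations

* The built-in mapper is exact-seeded: a read whose every 21-mer is hit by
  a substitution error cannot seed (negligible below ~1% error).
* Fisher p-values below ~1e−290 underflow to 0 in double precision;
  −log10(p) is then infinite and such loci rank first, which is the
  intended ordering.
* `collate_insertions` keeps the first (smallest) anchor position of a
  merged cluster; a long chain of calls each within the merge window can
  drift the representative position.
* All stages are single-threaded; per-locus and per-accession work is
  independent, so results would not change under parallel execution.
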