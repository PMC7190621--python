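# Methods

This note documents the models and procedures implemented in `haplopipe`,
their assumptions, the parameters that matter, and the design decisions taken
where the published descriptions of these procedures leave room.

## Trio binning (`trio_binning`)

**Model.** An F1 individual's long reads are classified by parent of origin
using k-mers unique to each parent's short-read data.  A k-mer is a marker of
parent *i* when its count there reaches `min_count` and it is absent from the
other parent; the two marker sets are disjoint by construction.  A read's
score per parent is its number of marker-hit positions (each k-mer position
counts, so a marker occurring twice counts twice — positional counting
preserves dosage).  The read goes to the strictly higher score; ties,
including the 0/0 case of reads without parent-specific k-mers, are
unassigned, mirroring the exclusion of marker-free reads in trio-binning
practice.

**Parameters.** `k = 21` (the standard trio-binning k-mer size: long enough
to be mostly unique in a mammalian genome, short enough that a read error
corrupts only 21 k-mers). `min_count = 5` for read-derived count tables — a
noise floor against sequencing-error k-mers; when marker sets are built from
assembled parental sequences (as the CLI does from FASTA), the floor is 1,
since every genomic k-mer appears once in an assembly. `normalize` (default
off) divides each count by its marker-set size before comparison; it is
offered because parents of unequal heterozygosity contribute unequal marker
counts, biasing raw-count comparisons.  Whether the original tools normalized
or thresholded marker hits is not published, so both behaviours are exposed
rather than asserted.

**Canonicalization.** All k-mers are reduced to the lexicographic minimum of
the k-mer and its reverse complement, making classification strand-independent.
k-mers containing non-ACGT characters are skipped.

## Hi-C haplotype scoring (`hic_binning`)

Each pair is aligned to both haplotype assemblies; the score per haplotype is
the sum over the pair's two ends of `identity x match_length`, with unmapped
ends contributing 0.  The pair is assigned to the strictly higher-scoring
haplotype; tied pairs come from homozygous loci and are given to both
haplotypes, so neither scaffolding input loses contact information.

Identity is defined as `(aligned_len − edit_distance)/aligned_len` (an
NM-style edit distance over aligned bases) and stored as a fraction, not a
percentage — the constant factor cancels in every comparison.  Scores within
`1e-9` of each other are ties, so float noise cannot manufacture a spurious
assignment.  When reading alignments (the optional SAM converter), only the
primary alignment per end is scored; whether the original procedure used
primary-only or best-of-all alignments is not published.

## Recombination-map validation (`assembly_qc.validate_scaffold_order`)

**Rule.** Probe coordinates on a scaffold should be monotone in map rank, in
whichever orientation (increasing or decreasing) fits better — scaffold
orientation is arbitrary before map anchoring.  Isolated disagreements are
expected from probe-mapping ambiguity, so one mismatched probe in any window
of three consecutive map-ordered probes is tolerated; clustered mismatches
count.

**Operationalization.** The error count is the minimum, over deletion sets
that leave the remaining coordinates strictly monotone, of the number of
deleted probes that have another deleted probe within two map positions
(equivalently: a deletion is free exactly when no window of three consecutive
probes contains a second deletion).  This is computed exactly with an
O(n²) dynamic program over (last kept probe, deletion-run flags); the test
suite verifies it against a brute-force subset-enumeration oracle on every
permutation of up to eight probes and on random larger cases.  The quadratic
cost is comfortable at recombination-map densities of up to a few thousand
probes per scaffold.  Only the published window of 3 with tolerance 1 is
supported; other combinations raise rather than silently approximating.

A scaffold carrying probes of more than one map chromosome is an
inter-chromosomal fusion; every chromosome switch along the scaffold counts
as one error located at the junction, and each chromosome's own probes are
additionally checked for monotonicity.  This junction rule is what makes
fusion detection independent of whether the fused blocks are concatenated or
interleaved.

**Breakpoint refinement.** Imprecise breakpoints (e.g. from optical maps) are
moved to the position of minimum short-read coverage within
`approx_pos ± search_radius`; ties break toward the original position, then
leftward, so the refinement is deterministic.

## Sequence-level QC (`assembly_qc`)

- **Gaps**: maximal runs of N of length >= `min_run`, 1-based closed; the
  reported gap lengths plus non-N bases always reconstruct the sequence
  length.
- **Telomeres**: at least `min_consecutive = 2` exact tandem copies of
  TTAGGG (either strand) whose run boundary nearest a sequence end lies
  within `end_window = 1 Mb` of that end.  Anchoring on the near boundary
  (rather than always the run start) is the package's choice: it is the only
  reading under which reverse-complementing a sequence exactly swaps the
  left/right flags.
- **Satellite blocks**: consecutive same-family repeat units separated by at
  most `merge_gap = 100 bp` are scored as one block; an array of units counts
  once.  The merge gap is a package default — "a sequence of repeat units"
  implies near-adjacency but no published number.
- **Centromere proximity**: a block overlapping the terminal 100 kb of a
  sequence flags that end.
- **Repeat filtering**: matches at identity <= 60% are dropped; per-family
  length gates (LINE > 2.5 kb, satellite/centromeric > 10 kb by default,
  longest-prefix family matching) remove fragments below the scale of
  interest.

Coordinates in this module are 1-based closed (map and RepeatMasker
convention); BED conversion happens only in `haplopipe.io` and is tested in
both directions.

## CNV differentiation (`cnv_vst`)

Windowed depth levels are normalized so the diploid state sits at 1.0;
copy number is `2 x level`.  A gene's copy number per individual is the
overlap-length-weighted mean over the windows it intersects — robust to
window boundaries cutting through genes.  Differentiation between two
populations uses

    Vst = (Vt − Vs)/Vt,  Vs = (n1·V1 + n2·V2)/(n1 + n2),

with population variances (ddof = 0) and population-size weighting, following
the convention of the CNV-differentiation literature this statistic comes
from; `ddof` is exposed for sensitivity analysis since the exact variant used
by any given study's unpublished script cannot be asserted.  Vt = 0 is
defined as Vst = 0: without any variance there is no differentiation.
Vst <= 1 always, and the statistic is invariant to shifting all values or
scaling them by a positive constant.

Genes are **called** at Vst > 0.3 and an absolute mean copy-number difference
> 3; a **plot set** at a difference >= 1.5 is reported alongside, as is the
empirical top-1% Vst quantile — a fixed 0.3 cut-off coincides with the top 1%
only on data where that happens to hold, so both are reported.  Whether the
mean difference is signed is unstated in the source procedures; the absolute
value is used.

**SV depth-support filter.** Paired-end SV calls longer than 1 Mb are likely
false positives unless the copy number across their span deviates from 2 by
at least 0.5 copies (a flag) in at least one individual; shorter calls pass
untouched.  **CNVR intersection** partitions each named region set, at
base-pair resolution, into bp unique to it and bp shared with any other set;
unique + shared equals the set's total by construction.

## Isoform phasing and allelic imbalance (`isophase`)

Transcript alignments are first gated at coverage >= 99% and identity >= 95%
(both inclusive).  FLNC reads of all isoforms of a gene are piled up over the
gene's candidate positions; a position with two or more observed bases is
tested by a one-sided Fisher exact test of the minor-base count m out of
coverage N against an expected-error pseudo-sample:

    [[m, N−m], [round(p_err·N), N−round(p_err·N)]],  p_err = 0.005.

Bonferroni correction runs over the positions tested in the gene;
significance requires adjusted p < 0.01.  Only the top two bases per position
are considered (substitution SNPs only; indels are ignored).  The published
description of this test is one line; the table construction above is this
package's declared interpretation, with `p_err` exposed as a flag.

**Phasing** is exact complete-string voting: reads' allele strings over the
significant positions are counted, the two most frequent complete strings
(ties broken lexicographically) define hap1 (more frequent) and hap2, and
every read joins the unique compatible haplotype — compatibility meaning
agreement at all covered positions — or stays ambiguous.  At FLNC error rates
(~0.5%/base over a handful of SNPs) this is as accurate as an EM assignment
and fully deterministic.  Ambiguous reads are excluded from abundance, not
fractionally split (conservative and reported); counts are conserved at every
stage (hap1 + hap2 + ambiguous = total).

**Normalization.** TPM = count / per-tissue total x 1e6.  Per tissue the TPM
values sum to 1e6 — exactly in rational arithmetic; the float64 column
carries about one ulp of rounding, so numeric checks use an absolute
tolerance of 1e-6 on 1e6.  The maternal-allele proportion is m/(m+p), NaN
when both alleles are silent; swapping the labels maps p to 1−p exactly.
Because proportions are ratios within a gene, using TPM or per-tissue-scaled
counts gives identical values whenever the totals are shared.

**Imbalance screen.** Per tissue, the distribution of per-gene proportions is
screened with a Shapiro–Wilk test (flag at p < 0.01): balanced tissues
concentrate symmetrically near 0.5, while strong allele-specific expression
piles mass toward 0 and 1.  This is a tissue-level screen, not a per-gene
call, and the normality null is a proxy — the flag should be read as
"distribution of allelic ratios is distorted", nothing more.  **Concordance**
between long-read, WGS and RNA-seq SNP sets is computed after restricting all
three to positions covered by at least 40 FLNC reads, reporting the seven
Venn regions and the fraction of retained long-read SNPs confirmed by both
short-read callers.

## Synthetic data (`synthetic_data`)

The generators emulate the study conditions each stage is tested under:

- diploid genome pairs diverging by planted substitution SNPs at 0.5–1%
  (the taurine/indicine range used throughout the tests);
- long reads drawn uniformly from the two haplotypes, normal length around
  the mean (sd 10%), substitution errors only;
- Hi-C pairs with uniform, independent end loci; per end and candidate
  haplotype the emitted (mapped, identity, match length) triple comes from
  exact comparison at the end's true locus;
- depth matrices with background level 1.0 plus Gaussian noise (default
  window 1 kb — segmentation tools do not publish a canonical window size,
  so it is a parameter) and planted per-gene copy numbers at cn/2;
- FLNC reads carrying their haplotype's alleles with per-base errors and
  optional missing positions, per gene, isoform and tissue, at planted
  maternal fractions;
- probe-placement cases: perfect, single transposition (forgivable),
  block reversal, inter-chromosomal fusion, and k isolated violations.

Every record id gets exactly one truth entry; all generators are
deterministic given (parameters, seed), with one seeded NumPy generator per
call.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: realistic long-read error profiles (no indels, no
homopolymer effects), Hi-C contact-distance decay and restriction-site
structure, GC- and mappability-driven depth waves (noise is i.i.d. Gaussian),
isoform-level expression structure, and reference/alignment artifacts.  The
tests demonstrate that each statistic and decision rule is implemented
correctly and recovers planted truth under its stated noise model, not that
the rules are optimal for any particular dataset.

## Numerical choices

- Fisher tails via the exact hypergeometric survival function; the test
  suite's independent oracle enumerates tails with exact integer binomials
  and requires agreement within 1e-12 on every 2x2 table with margins <= 30.
- Hi-C tie tolerance 1e-9 (absolute, on scores of order 1e2).
- Vst of a zero-variance vector is 0 by definition, not NaN.
- Breakpoint and phasing tie-breaks are deterministic (toward the prior
  position then leftward; lexicographic for equally frequent haplotypes).
- Problem sizes in the test suite and acceptance script (100 kb genomes,
  150–2000 reads/pairs, 20-seed CNV batches, 120 phasing runs, permutations
  up to n = 8 for the validator oracle) are chosen so the statistical
  assertions have comfortable margins while the whole suite runs in about a
  minute; all sizes are parameters and scale up freely.

## Known limitations

- The map validator's dynamic program is exact but quadratic; for maps with
  tens of thousands of probes per scaffold a windowed or divide-and-conquer
  variant would be needed.
- `count_kmers` is an in-memory counter for assemblies and test-scale read
  sets; building 21-mer tables from deep short-read data belongs to a
  dedicated k-mer counter upstream.
- The phasing model assumes exactly two haplotypes per gene (a diploid F1);
  collapsed paralogs violating that assumption will surface as excess
  ambiguous reads rather than being detected explicitly.
- Without a parental-allele table the inferred haplotypes are labelled
  hap1/hap2 by frequency; anchoring to maternal/paternal requires known
  parental alleles at the gene's SNPs.
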