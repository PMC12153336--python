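# Methods

## The problem being modelled

Antibody-secreting cells (ASCs) obey a one-cell-one-antibody rule: class
switch recombination physically deletes the unused heavy-chain constant
regions, so each ASC transcribes exactly one isotype gene (IGHM, IGHD,
IGHG1-4, IGHA1-2, IGHE).  3' tag scRNA-seq reads from these transcripts pile
up on the most 3' constant-region exon of the secreted isoform (the CH3-CHS
exon).  Because the isotype genes are recent paralogs, whether such a read
can be attributed to one gene depends on a handful of diagnostic bases — and
those bases differ between *alleles*.  A genome reference whose isotype
alleles do not match the donor's haplotype can therefore (a) assign a read
to the wrong paralog (fewer mismatches against the wrong gene's reference
allele) or (b) discard it as a multi-mapper (the reference's paralogs are
identical over the read's window even though the donor's are not).  At the
cell level, systematic misassignment manifests as double-positive (DP)
cells that violate the one-cell-one-antibody rule.

This package implements that inference chain end to end on synthetic data:
allele panels with exactly-placed variants, cells and 3'-biased reads, a
mismatch-based assignment model, the cell-level QC/calling/DP pipeline, and
the exon-splitting rescue annotation that recovers shared-segment reads.

## Allele panels

A panel stores, per reference, each gene's CH3-CHS exon in transcript
orientation (300 nt by default, genes on the minus strand as in the real
IGH locus; FASTA output is genomic orientation).  Panels are built from
explicit placement specs: every within-reference paralog difference and
every cross-reference allele difference is declared as (position, base)
substitutions over a random family background, and the builder guarantees
that declared substitutions are present *and no others* (backgrounds are
re-drawn at declared columns so a declared base never coincides with the
background).  Variant inventories downstream are therefore exact by
construction.

The default panel pair ("hg38_like" / "t2t_like") realises the divergence
pattern that drives the analysis:

* IGHG family: 28 variant columns among the four genes in the hg38-like
  reference, 34 in the T2T-like one (counting its two IGHG4 copies);
  cross-reference allele differences of 5 coding + 8 UTR columns for IGHG1,
  1 + 3 for IGHG2, a single UTR column near the exon end for IGHG3, and a
  duplicated IGHG4 (copy 1: two coding variants; copy 2: one coding + six
  UTR variants).  A designated 3' window of IGHG2 is arranged so that a
  donor read carrying the T2T-like IGHG2 allele has mismatch counts
  (2, 1, 0, 7) against IGHG2-hg38like / IGHG1-hg38like / IGHG2-t2tlike /
  IGHG1-t2tlike — the worked example of a read whose assignment flips with
  the reference.  No real sequencing read is bundled; the worked example is
  a synthetic stand-in constructed to that mismatch pattern, and all counts
  are computed by the aligner at run time.
* IGHA pair: nine hg38-only pair variants spread over the 3' block
  (identical there in the T2T-like reference), one T2T-only interior
  variant, and three constant 5' variants.  Under a 90-mer window this
  yields the three-region decomposition: a 3' "blue" region (ambiguous in
  the T2T-like reference only), an interior "orange" region (ambiguous in
  the hg38-like reference only) and "red" elsewhere (distinguishable in
  both).
* IGHM, IGHD, IGHE: singleton genes on independent backgrounds, always
  unambiguous.

Each gene family uses its own random background, so cross-family
misalignment is impossible at the mismatch cap; this matches the real
situation (isotype subclasses are ~95% identical within a family, unrelated
at exon scale across families).

## Synthetic cells and reads

`simulate_cells` draws per-cell truth: isotype (categorical), doublet status
(Bernoulli; a doublet mixes two distinct isotypes and its library size is
the sum of two independent draws, hence roughly twice a singlet's), and
per-cell library size, mitochondrial fraction and background-gene fraction.

Parameter defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| library size | log-normal, log-mean 7.3, log-sd 0.5 (median ≈ 1500 isotype molecules) | plasma cells are isotype-dominated; with background added this puts median cell totals near 2.5–3k reads, compatible with the 1500-read QC floor |
| doublet rate | 0.02 | typical droplet doublet rate at moderate loading |
| mito fraction | Beta(2, 38), mean 0.05 | most cells below the 10% QC cap, a tail above it |
| background fraction | Beta(60, 50), mean ≈ 0.55 | isotype genes ≈ 40% of ASC counts |
| read length | 90 nt | 10x 3' cDNA read scale |
| position bias | geometric from the 3'-most start, p = 0.02 (mean ≈ 50 nt) | tag reads concentrate at the 3' end |
| sequencing error | 0 (configurable) | the artifact is allele-driven, not error-driven; error runs are exercised in tests |
| PCR duplication | 1 + Poisson(mean − 1) copies per molecule, mean 1.0 by default | observed per-gene duplication rates are not available; exposed in config |

Reads are drawn only from the terminal exon, in transcript orientation;
barcodes are unique random 16-mers, UMIs random 12-mers without collision
checking (collision probability is negligible at these depths and the UMI
deduplication handles the residue).  The read container is columnar
(numpy arrays; sequences materialised on demand from gene, offset and a
sparse error list), which keeps multi-million-read simulations in memory
comfortably.

What the generator does **not** emulate: ambient RNA, empty droplets,
barcode sequencing errors, splicing/intronic reads, chimeric molecules,
gene-length or GC biases, and transcriptome-wide expression structure
(background genes are an exchangeable multinomial).  Passing tests
demonstrate the mechanics of reference-allele-driven misassignment and its
remedies under these idealised conditions; they do not certify performance
on real droplet data.

## Divergence analysis

`align_pair` is a global alignment with match 0 / mismatch 1 / gap 1 and
deterministic tie-breaking (diagonal, then vertical, then horizontal); its
cost is oracle-checked against an independent edit-distance implementation.
Equal-length sequences take a gapless fast path.  `enumerate_variants`
reports one row per mismatch column (1-based positions; indel columns
inventoried separately) and attributes coding/UTR compartments from the
annotated stop-codon boundary, never by translation.  `decompose_regions`
classifies every read-start offset by whether the two paralogs' windows are
identical per reference; it is exhaustively checked against a direct window
comparison.  Family variant columns are counted as the union of alignment
columns at which the family's sequences (gene copies included) are not all
identical — one of several possible conventions; it is the one that
reproduces the intended inventory and is used consistently.

## Read assignment model

Reads are placed ungapped at every offset of every candidate region;
placements with more than `max_mismatch` mismatches (default 6 for 90-mers,
a ~93% identity floor) are dropped and the rest scored
`1·(R − mm) − 2·mm`, an integer alignment-score analogue monotone in the
mismatch count.  The decision is unique-best-gene: a single best gene id is
assigned; a best-score tie across gene ids is discarded as a multi-mapper;
a tie confined to one gene id (several offsets or regions) is kept when
gene-level rescue is on (the default, matching the aligner behaviour the
rescue annotation exploits).  Score ties are strict integer equality.  UMI
deduplication keeps the lowest-mismatch, first-seen read per (barcode, UMI,
gene) and marks the rest PCR duplicates; the four read classes are
exhaustive and mutually exclusive and always sum to the read count.

The bulk path deduplicates error-free reads by their (gene, offset) source
and aligns unique sequences in vectorised chunks; it is oracle-equivalent
to the per-read reference implementation (tested on random reads with
errors).

Limitations by design: no gapped read alignment (indel alleles out of
scope), no quality-aware scoring, no barcode error correction, no splice
awareness.

## Cell-level pipeline

QC applies four steps in order — mito-fraction cap (10%), ribosomal-gene
removal, minimum gene prevalence (0.5% of cells), minimum reads (1500) and
detected genes (450) — and reports counts removed per step; the order is
part of the contract.  ASCs are cells with >10% immunoglobulin counts,
intersected across the two references when both are analysed.  The isotype
call assigns the gene holding >85% of the cell's isotype counts, else
`unassigned`.  DP detection and QC thresholds operate on raw
percent-of-total counts; the log1p(y/L·10⁴) transform (and reads-per-hundred)
is provided for display/export only.  Whether percent thresholds should be
of total or of isotype counts is ambiguous in the field; percent-of-total
is adopted (consistent with reads-per-hundred axes) and isolated in one
function.  Default DP thresholds: 0.5%/0.5% for IGHG1/IGHG2 and
IGHG1/IGHG3, 0.8%/0.3% for IGHA1/IGHA2.

The doublet diagnostic is a two-sided rank-sum test of DP vs non-DP library
sizes, implemented in-repo (midranks, tie-corrected variance, continuity
correction) with an exact permutation test used automatically when the
smaller group has ≤20 cells; the permutation test doubles as the oracle for
the approximation (agreement within 0.02 on small continuous samples; the
approximation is coarser on heavily tied tiny samples, where the exact test
is used anyway).

## Rescue annotation

The shared terminal segment of a paralog pair is the longest common suffix
(exact identity — rescue is only safe where multi-mapping is caused by
identical sequence, so no near-identity padding is applied).  The
annotation splits each terminal exon at that boundary: distinguishable
segments keep their gene ids, shared segments carry a merged gene id, and
the split records tile the original exon exactly (low-coordinate side for
minus-strand genes).  In the assignment model the exon sequence stays whole
and only gene attribution is segmented; a placement is attributed to the
gene of the segment containing its start, so boundary-spanning reads keep
their original gene and any read uniquely assigned under the plain
annotation is unchanged under rescue.  At error rate zero, the merged
gene's assigned reads equal exactly the plain-annotation multi-mapper
discards whose windows lie wholly in the shared segment; after UMI
deduplication the effective count can fall short of that identity only by
UMI collisions, so the exact check is made pre-deduplication.

## Analytic DP expectation

At error rate zero the fate of a donor read is a deterministic function of
its (true gene, start offset).  The per-offset assignment profile combined
with the read-position distribution gives, per true gene, the probability
that a read is assigned to each reference gene.  For a cell with known
molecule counts per truth component, each pair gene's count is a sum of
independent binomial thinnings, and the probability of exceeding both DP
thresholds is computed by convolving the binomial mass up to the (small)
threshold counts, using the cell's realised total for the percent
denominators.  Summing over ASC cells yields the expected DP count the
simulation is compared against (within 10%); the simulation runs every read
through the real assignment machinery, the expectation never touches the
simulated reads.

## Orchestration and determinism

`run_experiment` seeds every stage separately (panel, cells, reads,
background); re-running a config reproduces byte-identical summary JSON
(schema-versioned).  Problem sizes used by the shipped experiments: 5000
cells for the matched/swapped study, 600 IgA-weighted cells for the rescue
study, 10³ reads for the brute-force assignment oracle and 100 datasets for
the rank-sum oracle — sizes chosen so every statistical check has
comfortable resolution on a single CPU.
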