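# Methods

This note documents the models, conventions and numerical choices behind
each module, what the simulator does and does not emulate, and the known
limitations. Coordinates are 0-based, half-open everywhere; minus-strand
genes are stored as plus-strand exon intervals with a strand flag.

## Synthetic data

The simulator emulates a poly(A)-selected, non-stranded, paired-end
short-read library over a multi-isoform spliced transcriptome:

* **Genes.** Each gene is a mature transcript (5′ UTR + ATG···stop ORF +
  3′ UTR for coding genes; plain random sequence for non-coding) split into
  3–8 exons of ≥ 40 nt, separated by introns of 60–400 nt (always ≥ 30 nt)
  that start GT and end AG. ORFs are 120–400 codons drawn from sense codons
  only, and UTR ATGs are ablated so the planted ORF is the gene's best.
  Strand is random; the chromosome is the concatenation of genes and random
  intergenic spacers.
* **Isoforms.** Isoform counts are geometric with mean 3.7 (a field-typical
  multiplicity for deeply sequenced coding loci; the true distribution of
  any given library is unknown, so this is a modelling choice). Variants
  skip one internal exon or shorten the 3′-terminal exon; a single-exon
  gene asked for a skip variant falls back to an identical isoform with a
  warning.
* **Abundance.** Coding loci draw log₁₀ TPM from the two-component mixture
  0.5·N(0.3, 0.4) + 0.5·N(1.5, 0.5); non-coding loci from N(0.0, 0.4).
  This reproduces the qualitative bimodality seen in deep transcriptomes —
  a low-abundance population plus a robustly expressed one — and is
  configuration, not a claim about any particular dataset. Locus abundance
  is split across isoforms by a flat Dirichlet, then all isoform TPMs are
  renormalised to sum to 10⁶.
* **Reads.** Fragment counts per isoform are multinomial with probability
  ∝ TPM × max(ℓ − μ + 1, 1) (μ = 275 nt mean insert, σ = 25); fragment
  lengths are truncated normal on [read_len/2, ℓ]; 150 nt mates read inward
  from the fragment ends; fragments shorter than the read run into the
  adapter (a 33-nt standard adapter prefix, then random filler); fragment
  orientation flips with probability ½. Qualities decay linearly from mean
  Phred 38 (cycle 0) to 30 (cycle 149) with Gaussian jitter σ = 3, floored
  at 2 — enough dynamic range to exercise Q28 trimming. Substitutions are
  injected at the per-base rate implied by each quality value.

Not emulated: indel errors, PCR duplicates beyond what start-site counting
needs, stranded chemistry, sequence-composition bias, assembly artifacts
(chimeras, fragmented contigs). Tests passing on this generator therefore
show algorithmic correctness on clean spliced data, not robustness to the
full error structure of real libraries.

## Read QC

One merged rule set replaces the usual chain of two external trimmers, with
a fixed operation order for reproducibility: adapter clip (best
read-suffix/adapter-prefix overlap, ≥ 5 nt, ≥ 90 % identity; ties broken by
match count then identity then leftmost position) → up to 2 trailing Ns →
quality-trim both ends below Phred 28 → reject mates shorter than 20 nt or
with mean quality < 28. Q20 is reported per base (the convention matching
the familiar ~98 % scale); a per-read variant is computed alongside because
the phrase "percentage of sequences" is genuinely ambiguous. GC excludes Ns
from numerator and denominator.

Digital normalization uses canonical k-mers (lexicographic minimum of
k-mer and reverse complement; the library is non-stranded) with k = 25 and
a 30× ceiling. A pair is kept iff the median multiplicity of at least one
mate's k-mers — measured against the table built from previously kept
pairs — is ≤ 30; kept pairs then add each of their distinct k-mers once
(a fragment contributes one unit of coverage). The pass is single and
order-dependent by design, and idempotent on its own output.

## Assembly metrics

N50 is the largest length L such that transcripts of length ≥ L contain at
least half the assembled bases; ties resolve to that maximality, and the
result is always an element of the input.

ORF calling is a six-frame scanner, a deliberately simple stand-in for
Markov-model ORF extractors: candidates are ATG-to-stop, transcript-edge-
to-stop (5′-partial) and ATG-to-edge (3′-partial). Complete ORFs are
preferred over partial ones; within a class the longest wins
(`min_codons`, default 100, counts amino acids); remaining ties go to the
plus strand, lowest frame, smallest start. The complete-over-partial
preference is this package's convention: a short complete ORF is better
evidence of coding potential than a marginally longer open-ended frame.
An exhaustive brute-force scanner validates the implementation in tests.

Unigenes are recovered from identifier structure (`<locus>_seq<k>`), not by
re-clustering sequences — this mirrors how assemblers encode loci, and
sequence-level clustering is out of scope. Clusters are coding loci with
≥ 2 coding isoforms; singletons have exactly one; non-coding loci count in
neither, so clusters + singletons = coding loci always.

## Abundance and complexity

The mapper is a 31-mer-seeded exact/near-exact matcher (ungapped extension,
≤ 2 mismatches, both orientations, all equally-best placements reported);
concordant means both mates on one transcript, inward, fragment ≤ 800 nt.
It exists to validate abundance arithmetic on simulated data, not to
replace a production aligner.

The estimator implements the TPM/FPKM formulas with effective length
max(ℓ − μ + 1, 1) and three multi-mapper policies: drop (`unique`), split
1/n (`uniform`), or EM (`em`): fragment weights ∝ θ_t/ℓ̃_t over the
fragment's placements, θ updated as normalised summed weights, until
max |Δθ| < 1e-8 or 1 000 iterations. The EM is a minimal resolver with no
fragment-length or quality likelihood — the update is a true EM step for a
uniform-within-transcript generative model, so the data log-likelihood is
non-decreasing (asserted in tests). On simulated data with distinct
(single-isoform) transcripts it recovers abundance ranks at Spearman
ρ ≈ 0.99 with 100 000 pairs; heavily overlapping isoform variants lower
rank recovery for rare isoforms, as expected for any equivalence-class
method without additional modelling.

Library complexity samples concordant pairs (multi-mapped pairs excluded by
default, matching unique-hits mapping practice; a switch keeps one best
placement instead): unpaired complexity = distinct (transcript,
orientation, mate 5′ start) keys over both mates ÷ 2·pairs; paired
complexity = distinct (transcript, fragment start, fragment end) keys ÷
pairs. Neither bound implies the other, so no ordering is asserted.

## Completeness and cross-species identity

Pairwise alignment is textbook affine-gap dynamic programming written for
explicit tie control — global (Needleman–Wunsch) for identity and
full-length checks, local (Smith–Waterman) for search — scored with
BLOSUM62, gap open 11, extend 1 (a gap of length L costs 11 + L). Traceback
prefers a match column, then a gap in the second sequence. Scores are
verified against an independent exact aligner in tests. Identity is
identical columns over alignment length including gap columns; the
alternative denominator (shorter sequence length) is a configuration
switch because published identity percentages rarely state their tool's
convention.

Search is seeded (4-mer pre-filter) local alignment with **no
low-complexity masking** — short degenerate peptides such as
arginine/lysine-rich ribosomal tails must still find their verbatim
matches, a case where default masking in standard search tools is known to
hide true hits.

Completeness replaces profile-HMM e-value machinery with raw score +
coverage: complete when the best hit covers ≥ 70 % of the reference
(the classification rule is kept verbatim; the engine is not the content),
partial when any hit reaches the score threshold (default 50) without the
coverage, absent otherwise. The call is monotone in coverage.

The most-abundant-full-length procedure walks a locus's isoforms by
decreasing TPM and accepts the first whose protein is full-length against
the reference: length ratio within [0.85, 1.20] (bounds chosen to bracket
the ratios observed across typical cross-species ortholog tables;
configurable) and a global alignment reaching within 15 residues of both
reference termini.

## Annotation summaries

The report format is tab-separated with backtick-delimited multi-hits,
caret-delimited subfields and `.` for missing values; write-then-parse is
the identity on generated tables. "Annotated" means ≥ 1 GO biological-
process term (other aspects are counted separately); GO terms are used as
given, with no ancestor propagation. Quartiles use linear interpolation
(the common statistics default; the convention matters and is fixed here);
whiskers sit on the most extreme data points within 1.5 IQR of the
quartiles, and points beyond are outliers.

## Exon inference

Candidate blocks are maximal exact matches ≥ 20 nt (seeded per diagonal);
a dynamic program selects the collinear chain maximising union transcript
coverage, allowing small overlaps between neighbouring maximal blocks
(the familiar splice-junction ambiguity, where exon ends resemble intron
ends) which are resolved by trimming the later block. When a junction is
ambiguous, the cut is slid to the position whose intron starts GT and ends
AG if one exists; motifs are annotated but never required, and chains are
never rejected for lacking them. Ties in coverage break toward fewer
blocks, then leftmost placement. Both orientations of the mRNA are tried
and the better-covering chain returned. The chain is exact-match only —
appropriate for same-species or very-close-relative comparisons; a
mismatch-tolerant spliced aligner is out of scope.

Exon ordinals in the comparison matrix are connected components of genomic
intervals overlapping ≥ 1 nt across isoforms, numbered along the genome;
cells hold block lengths or absence, and ordinals whose lengths differ (or
that any isoform lacks) are flagged variant.

## siRNA design

Candidates are every 19-mer of the canonical isoform's ORF occurring
verbatim (sense strand) in all isoforms of the target locus. The three
built-in scorers are documented rule-based stand-ins for external design
services (whose exact models are proprietary or unpublished): a GC-content
window (30–52 % preferred), a duplex-end asymmetry score (nearest-neighbour
stability difference between the two duplex ends; an unstable 3′ sense end
favours correct guide-strand loading), and a composition score penalising
mononucleotide runs ≥ 4 and self-complementary stretches. The interface —
each scorer returns a ranked top-n list — is the contract; scorers are
pluggable.

The consensus rule (keep candidates on ≥ 2 of the 3 lists) and the
off-target discard rules are exact: discard if an off-target window matches
in ≥ 18 of 19 positions (Hamming, no indels — matching the aligned-window
semantics of seed-based read search) or shares a contiguous exact stretch
of ≥ 16 nt. Both the candidate and its reverse complement are screened
(either duplex strand can silence); sense-only is a switch. Hits to the
target locus's own isoforms never count. The Hamming search uses pigeonhole
seeding (m + 1 seeds for m allowed mismatches), the stretch rule an exact
16-mer table; both are verified against an exhaustive window-scan oracle.
Screening is monotone: adding transcripts can only create discards.

## Pipeline

One flat YAML config with a single seed drives all stages; per-stage random
streams are derived from (stage id, seed), so runs are bit-reproducible and
a config hash is recorded in the report. Stages run in dependency order;
disabling a stage removes its report block, and stages whose prerequisites
are disabled refuse with a configuration error. Every partition identity is
re-asserted from the emitted report at the end of each run.

## Problem sizes and tolerances

The default test suite and the acceptance script use desk-scale problems
chosen to exercise every code path while completing in about a minute:
10–60 genes, 800–100 000 read pairs, reference sets of ~12 proteins, 100
decoy transcriptomes of ~6 × 0.4–1.6 kb for screening equivalence, and 50
seeded spliced genes for boundary recovery. Floating-point assertions use
exact equality where the arithmetic is discrete (counts, verdicts,
boundaries) and relative tolerances of 1e-6 for conserved sums (TPM = 10⁶).
Genome-scale quantities (hundreds of millions of reads, hundreds of
thousands of transcripts) are validated through the same partition
identities and oracle equivalences, not by re-running a full assembly.

## Known limitations

* The mapper and EM ignore indels, base qualities and fragment-length
  likelihoods; abundance on real data should come from a production
  quantifier, with this module as the arithmetic reference.
* Exact-match exon chaining fails across species with appreciable
  divergence and cannot place exons shorter than the 20 nt block minimum.
* ORF calling is homology-free; very short or heavily 5′-truncated coding
  sequences below `min_codons` are reported non-coding.
* Scorer stand-ins rank plausibly but are not calibrated against measured
  knockdown efficacy; the consensus and screening logic, which is the
  procedure's substance, does not depend on scorer calibration.
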