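# Methods

## The recognition model

A fungal defensin-like peptide (fDLP) gene encodes a precursor
`signal – [propeptide] – mature – [spacer propeptide – mature2] – [R/RR]`
whose mature domain(s) carry the CSαβ six-cysteine framework. The pipeline
recognizes candidates by two complementary signals:

- **Cysteine-spacing envelope.** The inter-cysteine gaps (C1..C6) observed
  in the packaged seed set, widened by ±2 residues per gap (minimum 1).
  With the default seeds this is `C x(7–15) C x(1–5) C x(7–13) C x(2–9)
  C x(1–3) C`. The envelope is applied as a regular expression to
  six-frame translations and to candidate precursors.
- **Seed similarity.** Smith–Waterman local alignment (BLOSUM62, gap open
  11, extension 1 per additional gap column) of translated windows (90 aa,
  45 aa step) against the seed set. The definite-hit threshold defaults to
  30% of the smallest seed self-score (floor 45); with the packaged seeds
  this is 67. Windows at ≥ 55% of the threshold, and partial-framework
  (three-cysteine prefix) regex hits, create *provisional* loci.

Provisional loci are only reported when spliced completion succeeds and
the completed model itself clears the similarity threshold; this keeps the
false-positive rate on random GC-matched sequence near zero (measured as
part of the acceptance script) while recovering genes whose framework is
interrupted by introns. A completion-less locus is kept as a *pseudogene
candidate* only with strong similarity (≥ 80% of the threshold) plus a
partial framework.

## Spliced-model completion

For each locus (expanded by a 700 bp margin) the search enumerates, from
every ATG, reading paths interrupted by up to two GT..AG introns of 60–300
bp. Pruning uses a cysteine-state machine: a path whose accumulated
translation violates the envelope mid-framework is abandoned, and each
start codon has a bounded exploration budget. A path is a candidate when
it ends at an in-frame stop, is stop-free after splicing, carries the full
envelope, has ≥ 46 residues, carries exactly one or two complete
frameworks (6 or 12 cysteines), and ends within 15 residues of the last
cysteine (compact defensin C-terminus).

Selection among candidates: all candidates within 5 score points of the
top Smith–Waterman score are ranked by (1) presence of a predicted signal
peptide, (2) number of complete frameworks, (3) fewer introns, (4) smaller
total intron length, (5) shorter CDS, (6) downstream-most start codon.
The small score band absorbs the couple of points a local alignment can
pick up from spurious junk prefixes; the structural keys then prefer the
biologically complete model (full precursor with signal, both domains of a
two-domain precursor) over truncated or junk-extended alternatives. When
several loci yield overlapping same-strand models, the pipeline keeps the
one with more frameworks, then a predicted signal, then fewer introns.

## Precursor segmentation

- **Signal peptide**: a transparent heuristic, not a re-implementation of
  any external predictor — require ≥ 6 consecutive residues of mean
  Kyte–Doolittle hydropathy ≥ 1.5 within the first 40 residues, then
  cleave after the first position ≥ 15 whose −3 and −1 residues are small
  (A/G/S/C/T/V). User-supplied cleavage overrides are accepted.
- **Propeptide**: the segment between signal end and the first framework
  cysteine qualifies when its chain net charge at pH 7 is negative
  (termini excluded — the segment is internal) and it ends in K, R, KR or
  RR; basic runs are scanned left to right, at most two basics cleaved.
- **Domains**: disjoint six-cysteine frameworks found left to right. Two
  frameworks separated by a spacer that satisfies the propeptide rule give
  an N and a C domain; the N domain ends at its sixth cysteine (the
  convention the generator also uses), the C domain runs to the precursor
  end. More than two frameworks is an error (unsupported architecture).
- **Amidation**: a C-terminal domain ending GR or GRR is flagged and the
  arginine(s) trimmed; the glycine amide donor is kept in the reported
  mature sequence by default (configurable), so reported sizes include it.
- **Extensions**: ≥ 15 residues between signal cleavage and C1 that fail
  the propeptide rule flag an N-terminal extension; ≥ 8 residues after C6
  with ≥ 40% R/P/G flag a C-terminal extension.

## Intron phase and region

Phase is the cumulative upstream coding length modulo 3. Region maps the
interrupted codon's residue onto the segmentation; because per-family
structures are unknown, the fold windows are heuristic, defined off the
first domain's framework in precursor coordinates: α-helix `[C2−2, C3]`,
c-loop `(C4, C5)`, n-loop `(C1, C2−3)`; signal and propeptide come from
the segmentation; anything else is `c_terminal`.

Pseudogene calls for completion-less loci: `truncated_exons` when a
stop-terminated reading with < 6 cysteines ends soon after its last
cysteine with a splice donor nearby (downstream exons lost);
`missing_cysteines` when a complete ORF simply lacks the framework;
`premature_stop` otherwise. These labels are best-effort diagnostics.

## Physicochemistry

Average molecular weight is the sum of average residue masses plus one
water (reduced form; no disulfide −2H correction by default). Net charge
is the Henderson–Hasselbalch sum with pKa values in the classic
protein-calculator family: N-terminus 8.0, C-terminus 3.1, K 10.0, R 12.0,
H 6.5, D 4.4, E 4.4, C 8.5, Y 10.0. Cysteines are ionizable by default
(reduced form); `n_disulfides` removes 2n cysteines from the pool for the
oxidized CSαβ state (3 disulfides).

## Classification

Distances are p-distances (1 − identity) from global Needleman–Wunsch
alignments (Poisson correction optional). Neighbor joining minimizes the
Q-criterion with deterministic tie-breaking (lexicographically smallest
pair of subtree keys, a subtree keyed by its smallest leaf label); negative
branch lengths are clamped to zero with the deficit moved to the sister
branch. Bootstrap support is column resampling over a star progressive
alignment (pairwise NW against the longest member as guide), NJ per
replicate, split frequency in percent; 500 replicates by default at the
operation level, 100 in the end-to-end pipeline configuration (adequate
for the ±50% reporting threshold at the pipeline's problem sizes).

Family assignment: the query takes the majority family of the anchors in
its smallest enclosing clade with ≥ 50% support, ties resolved by the
anchor with the highest pairwise identity to the query. A query below 30%
identity to every anchor that sits in a supported anchor-free clade of
size ≥ 2 is labelled `new`. With no informative supported clade the
nearest anchor's family is used as a fallback. The 30% new-family
threshold and the 50% support threshold are configurable defaults.

Seed anchors: the plectasin mature sequence is public knowledge and
included verbatim; the other family anchors are constructed synthetic
stand-ins with family-plausible cysteine spacings and composition, clearly
labelled in `data/seed_anchors_synthetic.faa`. They function as alignment
seeds and clade anchors, not as biological reference sequences.

## Duplication analysis

Tandem clusters are single-linkage chains of genes on one contig with
inter-gene gaps ≤ 30 kb (default chosen so the published malpisin contig
ranges chain correctly; configurable). Synonymous/nonsynonymous counts
compare equal-length in-frame CDSs codon by codon: a differing codon pair
translating identically contributes its nucleotide differences to the
synonymous count. No dN/dS rate estimation is attempted — only counts.

## The synthetic genome generator

The generator emulates the architectures the annotator must recognize:
0–2-intron genes with introns planted at chosen regions and phases,
acidic propeptides ending K/R/KR/RR, two-domain precursors with spacer
propeptides, Gly-Arg(-Arg) amidation signals, tandem clusters, exon-1-only
pseudogenes, and identical-protein paralog pairs with an exact number of
synonymous differences. Matures are drawn by seeded point substitution of
a family anchor (default substitution probability 0.3, i.e. ≈ 70% identity
— a realistic within-family divergence; pseudogenes use 0.12 to mirror
detection through high first-exon similarity). Back-translation uses the
standard nuclear codon table with uniform synonymous codon choice; no
codon-usage bias is modelled. Intergenic spacers are i.i.d. nucleotides at
a configurable GC fraction (default 0.45), 500–5000 bp between genes;
cluster gaps are capped at 10 kb; introns default to 60–300 bp.

The generator makes the planted truth *identifiable*: an in-frame stop
immediately 5' of each start codon delimits the ORF; planted introns carry
all-frame stop blocks behind the donor and before the acceptor, contain no
ATG, and the acceptor-overshoot zone of the downstream exon is
synonymously recoded to be AG-free; two-domain coding sequences are
recoded AG-free throughout; signal-peptide cores avoid M and the small
(−3/−1) residues; domains following a propeptide never start with K/R and
non-amidated domains never end GR. Without these guards, alternative
splice interpretations of identical protein content are genuinely
ambiguous and exact-coordinate recovery would be ill-posed. Consequences
for interpretation: passing the planted-truth benchmarks shows the search
recovers the intended structures when decoys are absent; it does not show
splice-site discrimination beyond GT..AG on real genomes, nor robustness
to repeats, codon bias, cysteine-containing signal peptides, or
assembly artifacts, none of which the generator models.

## Problem sizes and numerical choices

The standard benchmark plants 50 genes (plus a synonymous-paralog copy and
two pseudogenes) across tandem clusters of 4 and 7 and singleton contigs
(~95 kb genome); the pipeline completes it, including a 100-replicate
bootstrap, in well under a minute per stage on one core. The test suite
uses a 12-gene genome for module-level checks. Alignment-score checks run
against an independent brute-force Gotoh DP; NJ is checked exhaustively
against all unrooted topologies with up to 8 leaves (11,463 trees) and
cross-checked against scikit-bio's implementation. False-positive
calibration scans random GC-matched 5 kb contigs and requires ≥ 95% of
trials to yield no loci.

Determinism: every stochastic stage (generator, bootstrap) is driven by an
explicit integer seed; identical seeds give byte-identical outputs.

## Known limitations

- Splice sites are modelled as bare GT..AG dinucleotides; no
  branch-point or splice-strength scoring.
- Divergent (< 30% seed identity) genes are only found when intronless
  (the full envelope must surface in one frame); a new-family gene broken
  by introns is invisible to the scan.
- The signal-peptide heuristic is deliberately simple; on real precursors
  an override file is the intended escape hatch.
- Family assignment quality depends on anchor choice; the packaged
  anchors are synthetic stand-ins (plectasin excepted).
- Catalog tallies reproduce the published peptide/gene/isolate counts;
  per-phylum peptide tallies from the packaged tables give 27 Ascomycota /
  33 Zygomycota, which differs from the published 21/39 split whose basis
  is not stated; the tool reports the computed values.
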