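# Methods

fzkit re-implements, as a self-contained and testable pipeline, the
computational workflow used to characterize Fanzor (Fz) — a eukaryotic
transposon-encoded, RNA-guided DNA endonuclease of the OMEGA family — from
genome assemblies and screen read data. This note records the models, the
parameters that matter, and the choices made where the design was genuinely
open.

## Element model and the synthetic genome

The unit of analysis is an IR-delimited transposable element of the *Spu-1*
type. The packaged template (`fzkit.templates`) assembles, in element sense:

    CA | IR5 (30 nt) | ORF (1,920 nt) | scaffold (75 nt) + guide (14–15 nt) | IR3 (30 nt)

* **IRs.** 30-nt terminal inverted repeats; IR3 is the exact reverse
  complement of IR5 in the canonical template. A conserved `CA` dinucleotide
  sits immediately upstream (element sense) of the 5′ IR.
* **Ghost elements** keep the IR pair and a conserved ~550-nt core but lack
  the ORF (total span 2 + 30 + 550 + 30 = 612 nt). Their IRs diverge from the
  canonical IRs at seven positions. The seven divergent columns are placed
  contiguously at the IR 5′ end: this keeps the conserved 23-nt block
  discoverable as a single local alignment of the canonical seed
  (score 23 > 20, coverage 23 ≥ 17 under the nucleotide scoring below), which
  is what makes a coverage threshold of 17 nt meaningful at all.
* **Partial elements** are full elements whose ORF is 3′-truncated by a
  uniform 30–60 % (in-frame). This produces protein hits below the
  full-coverage threshold and exercises the classifier.
* **ncRNA (ωRNA).** Each full element carries a 75-nt scaffold between the
  ORF stop and the 3′ IR, ending in a variable guide slot of 14–15 nt; the
  expressed transcript is scaffold + guide (89–90 nt). In the organism the
  scaffold region overlaps the 3′ IR and the guide continues into flanking
  DNA; the template keeps the whole transcript inside the element, which
  fixes every coordinate relationship the pipeline needs without changing
  what any stage measures. One locus per genome can carry a fixed packaged
  15-nt guide (`GUIDE_CRYO_EM`, a synthetic stand-in for the structural
  construct's guide length).

The generator (`fzkit.simulate.generate_genome`) plants elements into i.i.d.
background contigs at a specified GC content — the simplest null that cannot
spuriously contain 30-nt IR seeds at appreciable probability. Defaults are
the benchmark conditions used throughout the tests: 5 contigs × 200 kb;
3 full, 2 partial, 4 ghost elements; 1 % per-copy substitutions. Two
placement rules matter:

* elements on one contig are separated by ≥ 30 kb (`min_separation`), so
  distinct planted elements remain distinct loci under the 25-kb aggregation
  rule — the genome-wide census counts loci under exactly that criterion;
* placement distributes the remaining contig slack uniformly between
  elements (stars-and-bars), so any feasible layout succeeds for every seed.

**Mutation model.** Substitutions only, i.i.d. at `mutation_rate` per nt per
element copy, *sparing the scaffold+guide transcript window*. The
cross-locus conservation of the scaffold is the empirical feature the
partition stage is defined on; mutating it at 1 % across four loci would
destroy at least one scaffold column with ~95 % probability and contradict
the premise being emulated. IRs, ORF and ghost core do mutate, so the miner
and consensus stages see realistic divergence. Background small-RNA reads
are uniform genomic fragments at a configurable rate (default 5 % of locus
reads); this background model is a stand-in, not a claim about native
small-RNA composition.

**Boundary jitter.** Small-RNA reads cover the transcript with at most 1 nt
of independent raggedness at each terminus, with the true terminus modal
(P(0) = 1/2, P(±1) = 1/4 each). A uniform three-way jitter would make the
modal terminus a tie and boundary refinement ill-posed; sharp-but-ragged
termini are also what the underlying small-RNA protocol produces.

## Locus mining

1. **Protein seed scan.** All six frames are translated (codons containing N
   give X); the Fz protein seed is aligned by Smith–Waterman (BLOSUM62, gap
   of length *k* costs 11 + *k*) inside windows around exact 3-aa word
   matches, BLAST-fashion. A hit is kept when its raw score reaches
   `min_score_fraction` (default 0.25) of the seed self-score — a monotone
   proxy for a translated-BLAST e-value cutoff, which is not computable
   without a database-size model; the calibration makes exact planted seeds
   always pass and random 200-kb contigs essentially never. Overlapping hits
   across frames are merged keeping the best score, then the longest, then
   the lowest start.
2. **IR scan.** Exact 7-mer seeding on both strands, then local alignment
   with match +1, mismatch −2, gap open −3, extend −1 (gap of length *k*
   costs 2 + *k*). This scheme is chosen so a perfect 30-nt IR scores 30 and
   the published thresholds — score strictly > 20, aligned seed coverage
   ≥ 17 nt — stay on their printed scale. Both the canonical and the ghost
   IR seed are scanned by default and overlapping hits deduplicated keeping
   the best.
3. **Aggregation.** Single-linkage clustering per contig: hits whose
   interval gap is < 25 kb join one locus. Aggregation is order-independent
   and never crosses contigs.
4. **IR pairing and classification.** The IR pair of a locus is the
   non-overlapping, inverted-orientation pair maximizing combined score then
   span. A locus is *full* when a protein hit covers ≥ 90 % of the seed
   (in nt) and lies inside an IR pair; *partial* when a protein hit falls
   short of that; *ghost* when an IR pair exists with no protein hit;
   *unresolved* otherwise (e.g. a lone IR hit). Loci with a protein hit but
   no IR pair trigger an automated ±50-kb rescan at relaxed thresholds
   (score > 14, coverage ≥ 12), flagged `rescan=True` — the automated
   stand-in for interactive curation of such loci.
5. **Element strand and CA motif.** Protein hits fix the element strand;
   for ghosts the conserved CA upstream of the candidate 5′ IR breaks the
   orientation symmetry. The CA flag is reported as absent (None) when the
   check would run off a contig edge.
6. **IR consensus.** Majority-rule column consensus over element-sense 5′ IR
   copies, reporting the modal aligned length; ties in a column resolve to
   the alphabetically first base (deterministic). Divergence between two
   consensus strings is a plain Hamming distance; unequal lengths are
   refused rather than implicitly aligned.

Alignment scores are validated against an independent pure-Python Gotoh
oracle on randomized instances ≤ 2 kb (both scoring schemes), translation
against an explicit codon table, and aggregation against a transitive-closure
oracle. The word-seeded search is heuristic in the same sense BLAST is: a hit
with no surviving exact word (for the IR scan, ≥ 4 substitutions arranged to
break every 7-mer) is invisible; with ≤ 3 substitutions in a 30-nt seed a
clean 7-mer always exists (pigeonhole), so the regimes the thresholds retain
are fully covered.

## Small-RNA mapping and the scaffold/guide partition

Reads (20–90 nt) are matched full-length, exact-or-≤1-mismatch
(substitutions only), against both strands of locus windows (span ± 200 nt).
At these sizes a heuristic external aligner adds nothing, and the package
must run with no external binaries. Reads tying across placements are
assigned fractionally (1/n): the loci are near-identical repeats, and
discarding multimappers would zero out coverage precisely where it matters.

Transcript units are maximal runs of coverage ≥ max(5, 10 × window median),
minimum length 40 nt, with each boundary refined to the modal read terminus
within ± 3 nt. The expression threshold is a package choice (none is
published) and is exposed as a parameter.

The partition anchors all transcripts at their 5′ ends and takes the
scaffold to be the maximal prefix over which the cross-locus per-column
identity (fraction of covering transcripts sharing the modal base) stays
≥ 0.9; the remainder of each transcript is that locus's guide. Fewer than
two loci is an error (the partition is undefined), as is a common prefix
shorter than 20 nt (the transcripts are then not homologous). Two identical
transcripts partition degenerately (scaffold = full length, guides 0,
flagged). Note the quantization: with 4 loci, a column passes 0.9 only at
4/4 agreement, so four guides that coincidentally share their first base
(probability 1/64 under uniform sampling) genuinely extend the measured
scaffold by one column. CDS–ωRNA overlap is the plain coordinate
intersection, reported in nt and floor(nt/3) aa.

## TAM screen

TAMs are the 8 nt immediately 5′ of an exact 12-nt protospacer anchor
(reads failing the anchor on both strands, or without 8 nt of context, are
unassigned). Enrichment keeps TAMs seen more than once in the cleaved set
and scores E = f_c / f_i, with f_c over the retained cleaved total and f_i
pseudocounted (0.5, input side only) so TAMs unseen in the input cannot give
infinite enrichment.

Two PWM constructions are provided, and the difference matters:

* **enrichment** — each position–base weight is the sum of E over retained
  TAMs carrying that base, column-normalized. This is the screen's literal
  definition, but it is background-limited: a motif at fold-enrichment E
  occupying probability q′ of a column drives that column's share only to
  about (Eq′ + (1 − q′)) / (E·4q′... ) ≈ 0.28 at E = 10 for a 4-nt motif —
  informative for ranking (argmax recovers the motif bases), but no
  dominance threshold can separate it from column noise in a shallow null.
* **corrected** (pipeline default for motif calling) — per position–base,
  the observed cleaved marginal count minus its input-expected value,
  thresholded at z* = 4.0 sampling standard deviations (binomial variance
  plus input-estimation variance) and floored at zero; all-zero columns
  become uniform. Null screens give uniform columns; genuinely enriched
  bases dominate theirs. z* = 4.0 was fixed from the familywise budget
  (32 position–base tests across 20-run property suites) before any
  recovery measurement.

Consensus calling works on the PWM alone: a column is *informative* when its
top weight is ≥ 0.5 and ≥ 2× the runner-up, *weak* when the top weight
reaches 0.5 without dominating the runner-up. The reported motif is the
informative run extended through adjacent weak columns (printed N), with
interior Ns retained and fully uninformative edges trimmed — this single
convention reproduces the different printed motif shapes (4-mers, a 5-mer
ending in N, 3-mers) without per-orthologue rules.

**Known statistical limits.** At 10⁴ reads over a 65,536-member 8N library,
individual 8-mer enrichment scores are undersampled (retained rows are
Poisson-tail selected and their E values are biased upward even under the
null); only position-level marginal enrichment is well-measured at that
depth, and that is what the null-band test asserts. Likewise, exact recovery
of a 4-nt motif at fold-enrichment 5 with 2×10⁴ reads sits below a ~1.4 %
absolute per-column excess and is not reliably attainable by any estimator;
the recovery property is therefore exercised at fold-enrichment 10 with
5×10⁴ reads per set, where the per-column signal is ≈ 10σ.

## Cut-site calling and end geometry

Coordinates are 1-based, "cut after the Nth base", counted from the
TAM-proximal first protospacer base on both strands — stated prominently
because an off-by-one here is the chief failure mode. Run-off polymerases
add one non-templated terminal base at some rate, observed as a terminal A
on the target-strand (TS) trace and a terminal T on the NTS trace; any
sample whose terminal base equals its strand's artifact base is decremented
by one position before calling (a neighbor-support rule cannot work at
artifact rates near 1, where no unshifted samples remain). The packaged
run-off target sequence contains no T at protospacer positions 9–21, so
templated terminal bases never collide with artifact bases in the profiled
window; on arbitrary targets a genuine cut whose templated terminal base
equals the artifact base would be over-corrected by 1 nt — a documented
limitation of run-off readout itself.

The profile reports every position whose corrected frequency is ≥ 50 % of
the modal frequency (`mode_frac`), so bimodal profiles report two positions.
Geometry: with t = TS and n = NTS called positions, min(t) > max(n) is a 5′
overhang of [min(t) − max(n), max(t) − min(n)] nt; identical singletons are
blunt; max(t) < min(n) is a 3′ overhang; everything else is mixed. Exactly
one class holds for any pair of non-empty sets, and swapping strand labels
exchanges 5′ and 3′ overhangs while fixing blunt. Overhang length is a range
because cut positions themselves are reported as ranges.

## Problem sizes and reproducibility

All randomness flows from one integer seed; per-stage sub-seeds are derived
deterministically and kept below 2³¹. Identical seed + configuration gives
byte-identical output trees (tested). The test suite and the reproduction
script run the benchmark genome at 5 × 200 kb (the locus-recovery check,
about half a minute), the expression analysis at 4 loci × depth 500, the
screen at 5×10⁴ reads per set, and cut calling at 5×10³ samples per strand
— sizes chosen so each stage's statistical claims are comfortably powered
while the whole suite stays interactive.

## Limitations

* The generator emulates architecture and sampling noise, not sequencing
  chemistry: substitution-only errors (default 0), no indels, PCR chimeras,
  adapter read-through, or chromatogram artifacts beyond the single
  non-templated terminal base.
* Background contigs are i.i.d.; real assemblies contain repeats that would
  stress locus aggregation and multimapping in ways the tests do not probe.
* The word-seeded scans inherit BLAST-style incompleteness for hits with no
  exact word match (irrelevant above the retained-score thresholds, see
  above).
* Passing recovery tests on this generator demonstrates correctness of the
  pipeline's logic under its stated statistical model — not performance on
  real assemblies, where seed choice, assembly quality and manual curation
  dominate.
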