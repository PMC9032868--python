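# Methods

This note records the models, rules and numerical choices behind each
stage, the assumptions of the synthetic data, and the known limitations.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Internally all spans are 0-based half-open.  Everything on disk —
12-column tabular alignments, GFF3, TSV reports, truth tables — is
1-based inclusive, matching the BLAST tabular and MISA conventions.
Minus-strand tabular rows (`sstart > send`) are normalised on ingest to
ascending coordinates plus an explicit strand flag.  Sequences are
uppercased on read; lowercase and IUPAC ambiguity codes other than N are
mapped to N with a logged warning, because every scanner in the package
defines its behaviour only over {A,C,G,T,N}.  A consequence: a
minus-strand HSP whose subject span is a single base cannot encode its
strand in the start>end convention; such degenerate rows round-trip as
plus strand.

## FLNC classification

A full-length read is `primer5 + insert + polyA + revcomp(primer3)`.

* **Primer matching** uses edit distance (edlib, infix mode), not
  Hamming distance, because long reads indel as well as substitute.
  Default tolerance is 3 edits; terminal primers must start (5′) or end
  (3′) within 100 bp of the respective read end.  Among equal-distance
  hits the outermost is taken.  Both read orientations are tried; a read
  detected in the flipped arrangement is reverse-complemented before
  reporting.
* **Poly(A) detection** anchors at the 3′-primer match and takes the
  maximal-scoring suffix window under +1 per A / −2 per non-A (ties to
  the shortest window) — the same family of rule used for quality
  trimming.  The window is accepted at ≥ 20 bp with ≤ 10 % non-A, which
  tolerates the isolated interruptions real tails show.  This boundary
  is intrinsically ambiguous when a transcript ends in genomic A's: the
  detector cannot distinguish them from the tail, so the synthetic
  generator forces the last six insert bases to be non-A (see below).
* **Chimera rule**: a read with the full-length structure that also
  contains any primer (either primer, either orientation) in its
  interior at ≤ 3 edits is classified CHIMERIC — the signature of two
  cDNAs fused in library preparation.  Everything else that fails the
  full-length test, including inserts shorter than 50 bp, is NON_FL.
* The minimum insert length of 50 bp mirrors the usual raw-data length
  filter; poly(A) minimum length and primer tolerance are exposed as
  parameters because published pipelines rarely state them.

## Isoform clustering

Neither iterative-consensus clustering nor CD-HIT publishes a single
testable identity definition, so the package uses its own, documented
one: a global alignment with free end gaps (match +2, mismatch −3, gap
open −5, extend −2; Biopython `PairwiseAligner`), identity = matches /
alignment columns between the first and last aligned pair, coverage =
the fraction of the shorter sequence inside that core.  Greedy
incremental clustering visits records longest-first (ties by id, which
makes the result independent of input order); a record joins the first
representative at identity ≥ 0.99 and coverage ≥ 0.9, else founds a new
cluster.  The 0.99 default reflects the post-correction accuracy
full-length consensus reads are selected at; the coverage default 0.9 is
a CD-HIT-style containment guard.  Collapse keeps the longest member per
cluster (ties by id) — representative selection stands in for consensus
polishing, which is out of scope.

A shared-15-mer prefilter skips alignments that cannot reach the
threshold: at ≥ 99 % identity over ≥ 90 % of the shorter sequence,
mismatches are ≥ ~100 bp apart on average, so a shared 15-mer is
unavoidable for any sequence long enough to cluster; sequences shorter
than 15 bp bypass the filter.  The suite checks that results are
identical with the filter on and off.

## SSR mining

Detection follows the MISA convention: per-unit minimum repeat counts
1-10 2-6 3-5 4-5 5-5 6-5 (configurable via the same definition string
MISA uses), N terminates any run, only complete units count toward the
reported span, and hits separated by ≤ 100 bp share a compound group.
For each unit size *u* the scanner locates maximal period-*u* intervals
(vectorised `s[i] == s[i+u]` run detection); an interval of length *L*
anchored at its left end yields `L // u` repeats.  Non-primitive motifs
(e.g. ATAT at *u* = 4) are skipped, which is exactly the rule that
reports each run once at its smallest primitive unit.  Density reports
group motifs by the canonical representative — the lexicographic minimum
over all rotations of the motif and of its reverse complement — so
(AG)n and (CT)n fall in one class.  The scanner is verified against an
independent brute-force per-position scanner on random sequences.

## ORF prediction

Six-frame enumeration with ATG starts and TAA/TAG/TGA stops under the
standard code.  The transcript ends open the partial classes: a stop-free
stretch reaching a stop with no upstream in-frame start is 5′-partial,
a start with no stop before the end is 3′-partial, neither is internal.
Selection: internal stretches rank below everything (an open stretch
with neither start nor stop is weak evidence however long); complete and
partial ORFs compete by peptide length, ties broken complete-first, then
forward strand, then smaller span start.  `min_aa` defaults to 100, the
convention of the tool this stage simplifies; there is deliberately no
hexamer/Markov coding-likelihood rescoring.  Reported spans include the
stop codon; peptide lengths exclude it.  Length bins for complete ORFs
are ≤ 1000, (1000, 2000] and > 2000 aa, with percentages over the
complete-ORF count.

All percentage arithmetic in reports uses exact decimal half-up rounding
computed from the integer counts, never through binary floats, so values
on a rounding boundary (e.g. 7/9 → 77.78) are stable.  Published tables
rounded by other means can disagree with recomputation in the last
digit; reports here always recompute from counts.

## lncRNA screening

The consensus set is transcripts strictly longer than 200 nt (the
length rule is read as strict; the cutoff is configurable) that every
supplied method votes non-coding.  External predictors are ingested as
two-column tables (running them is out of scope — their results are
database- and version-dependent).  The built-in heuristic calls a
transcript non-coding when it has no predicted ORF, or its best ORF is
both short (< 100 aa) and covers < 50 % of the transcript; partial ORFs
count as coding evidence.  Venn regions are computed over the supplied
method sets (the length filter gates only the consensus flag), so the
per-method totals match what each method reported.

## Alternative-splicing detection

The event rule operates on pairs of same-orientation HSPs between two
transcripts.  On the contiguous side the two spans must overlap or be
separated by strictly less than 5 bp (the published rule bounds only the
overlap; separation is bounded symmetrically, since both arise from the
same alignment wobble).  On the gapped side the spans must be separated
by a gap strictly greater than 100 bp, with both gap boundaries at least
100 bp from the sequence ends.  "Almost completely aligned" is
operationalised as an optional coverage filter, on by default: the two
HSPs must jointly cover ≥ 80 % of the contiguous sequence.  The rule is
evaluated over *every* HSP pair, not only pairs with exactly two HSPs,
and events are deduplicated by (gapped id, gap span).  Unordered
transcript pairs are evaluated once, with the lexicographically smaller
id as query, making the scan independent of input order.

HSP generation is delegated to NCBI `blastn` (task `blastn`, dusting
off, E ≤ 1e−5; bit score ≥ 50 and identity ≥ 90 % by default) rather
than to a single repeated Smith–Waterman: with affine-linear gap costs a
best local alignment *chains through* any internal gap once the flanks
are long enough, merging the two HSPs the rule needs into one gapped
alignment; BLAST's X-drop extension terminates at the gap and reports
the two segments separately, which is the geometry the criteria were
designed around.  Alignment ends can wobble by a few bases where flank
and gap sequence coincide by chance, so planted-event tests assert gap
spans within ±5 bp.  The same wobble interacts with the strict 5 bp
overlap tolerance: when an HSP happens to extend 5 or more bases past
the true breakpoint, the contiguous-side overlap criterion suppresses
the event.  This is the rule operating as stated, not an alignment
failure; on random flanks it costs on the order of one event per
hundred pairs, which is why measured recovery can occasionally be 9/10
at a given seed.

## Synthetic data

All randomness flows from one `numpy` generator, so a fixed seed yields
byte-identical FASTA and truth tables.

* **Read lengths**: log-normal with arithmetic mean 2000 bp and sd
  1000 bp by default — the ~2 kb-centred scale of real full-length cDNA
  datasets.  Label mixture: 80 % FLNC, 15 % missing a primer, 5 %
  chimeric (two cDNA units fused end to end), remainder full-length with
  an 8 bp (sub-threshold) tail.
* **Primers**: the ubiquitous template-switching adapter pair shipped in
  `isoscan/data/primers.fa`; configurable, since published studies
  rarely print theirs.
* **Poly(A) tails**: geometric lengths around mean 30 (floor 25) with
  0–2 non-A interruptions kept ≥ 5 bases from the tail ends, to
  exercise tolerant tail detection.
* **Boundary anchoring**: the final six insert bases are forced non-A.
  Without this the insert/tail boundary is genuinely ill-defined (a
  genomic terminal A is indistinguishable from the tail) and exact
  insert recovery would be unattainable by *any* detector, which would
  test the ambiguity of the construction rather than the classifier.
* **Planted SSRs/ORFs** are spliced into distinct FLNC inserts; one base
  on each side of an SSR block is rewritten so the repeat can neither
  extend nor shift anchor, and each ORF is preceded by an in-frame stop
  so no upstream ATG can extend it.  Plants that do not fit a short
  insert are skipped and simply absent from the truth table.
* **Isoform families**: each member carries independent substitutions at
  rate (1 − within_identity)/2 from a family ancestor, so *pairwise*
  member identity is ≈ within_identity — the quantity the clustering
  threshold acts on; family ancestors are independent random sequences,
  far below the between-family bound.
* **AS pairs**: sequence B equals sequence A with an internal block
  deleted; the truth records whether the planted geometry satisfies the
  event criteria.

What the generator does **not** emulate: instrument error profiles
(reads are error-free apart from what is planted), intron/exon gene
structure, expression-level skew, barcodes, or biologically realistic
base composition (inserts are uniform random).  Passing the recovery
tests therefore shows the detectors implement their stated rules
exactly on clean data; it does not measure robustness to sequencing
error or to compositional bias.

## Problem sizes and determinism

The default acceptance run simulates 1,000 reads (~2 kb mean), clusters
~800 FLNC inserts, and scans 10 planted AS pairs among 50 decoys; the
pipeline-determinism check runs 150 reads twice and compares all output
bytes.  These sizes were chosen so the whole suite exercises every stage
at realistic per-read scale while remaining a desk-scale computation.
Dataset-scale headline counts from any particular study (total SSR
counts, lncRNA counts, AS-event totals) depend on the full input data
and external predictor versions and are not reproduction targets;
percentage arithmetic on printed count tables, by contrast, is
recomputed exactly in the test suite.

## Known limitations

* No consensus polishing: cluster representatives are members, not
  error-corrected consensi.
* The built-in coding-potential heuristic is ORF-geometry only; it is a
  stand-alone voting method, not a reimplementation of any published
  classifier.
* AS events are called but not typed (exon skip vs intron retention
  etc.) — without a genome the distinction is not well defined.
* The greedy clustering is order-canonical but not globally optimal;
  a sequence joins the first acceptable cluster, not the best one.
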