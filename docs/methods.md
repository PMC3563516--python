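# Methods

`bovmir` implements a complete two-library small-RNA-seq analysis of the
kind used to profile miRNAs in paired tissue states (here styled as fetal
vs adult bovine muscle): read cleaning, perfect-match genome mapping,
RNA-category annotation, known-miRNA profiling, hairpin-criteria novel
miRNA discovery, an exact count-based differential-expression test, and
stem-loop qPCR quantification. Because studies of this design frequently
leave no raw data behind, the package carries a first-class synthetic-data
generator that plants full ground truth for every stage; all quantitative
claims below are the ones the test suite and `scripts/acceptance.py`
actually compute.

## Read cleaning

Every parseable read counts as high quality (no quality-score model; the
simulator emits constant Phred+33 'I' strings and the cleaner never
inspects them). Each read is assigned to exactly one ledger category, in a
fixed priority order: missing 3' adapter, empty insert, 5'-adapter
contaminant, shorter than 18 nt, polyA, clean. The 3' adapter is located
by an exact match of its first 8 bases (`adapter3_seed_len`); a
5'-contaminant is an insert beginning with the 5' adapter's last 6 bases
(`adapter5_tail_len`); polyA means >= 80% A after trimming
(`polya_fraction`). These three matchers are deterministic stand-ins for
unstated vendor filters; all are configurable. Two identities hold exactly
on any input and are re-checked by `validate_outputs`:
`clean = high_quality - sum(filters)`, and collapsed tag counts sum to
clean reads. U and T are interchangeable on input; the internal alphabet
is DNA.

## Mapping and annotation

Tags map to the genome by exact full-length matching on both strands (an
18-mer prefix index with verification, equivalent to a perfect-match
short-read aligner; property-tested against a naive sliding-window scan).
Each genome-matched tag gets one RNA category by the fixed priority
miRNA > rRNA > tRNA > snRNA > snoRNA > scRNA > srpRNA > repeat >
exon_sense > exon_antisense > intron_sense > intron_antisense > unknown,
with >= 1 bp overlap counting as containment and sense/antisense decided
by strand agreement. A multi-hit tag takes the highest-priority category
over all of its hits; read counts are never split, so the category table
is an exact partition of the genome-matched tags. Tags with no genome hit
are reported separately from genome-matched "unknown" tags.

## Known-miRNA profiling

A tag belongs to a known miRNA if it equals the reference mature exactly,
or lies wholly inside the annotated hairpin and overlaps the mature site
by >= 16 nt (`mature_overlap_min`) — the variant-inclusive count that
groups 1–5 nt end variants with their parent miRNA. Unmatched tags are
scanned for single base edits: a substitution is called when the Hamming
distance to an equal-length window of a reference mature (anchored at its
5' or 3' end) is exactly one, with ties broken toward the most abundant
reference; a tag equal to a mature plus one 3'-terminal A/U that the
hairpin does not template is an untemplated-addition call. A->G calls and
seed-region (positions 2–8) calls are flagged. End-variant offsets are
signed nt relative to the reference mature (positive 5' offset =
upstream start). Arm usage reports miR vs miR* reads per precursor; the
"near equal" flag fires when the minority arm holds at least a third of
the precursor's reads, a threshold chosen so the canonical nearly-equal
pairs in the literature (447/680 and 186/314 reads) qualify while
ordinary star arms (a few percent) do not. Families come from a
miFam.dat-style stanza file mapping precursors to families.

## Folding and novel discovery

The folding engine is an in-repo dynamic program over a deliberately
simple additive nearest-neighbour surrogate: pair energies GC -3.0,
AU -2.0, GU -1.0 kcal/mol; a -1.0 stacking bonus for each pair stacked
directly on another; hairpin-loop penalty 3.0 + 0.25/nt above the 3-nt
minimum; no other loop penalties. The model is rank-correct for hairpin
screening, not thermodynamically calibrated; its DP optimum is pinned by
an exhaustive-enumeration oracle on short sequences (an acceptance-level
property), and ViennaRNA's RNAfold can be swapped in behind the same
interface (`fold_rna(..., backend="viennarna")`) when physical energies
matter. AMFE is (-MFE/length)x100 and MFEI is AMFE divided by GC percent.

Discovery takes the unannotated genome-matched tags, drops any with more
than 10 perfect genome hits, clusters hits within 30 nt on one strand,
and evaluates clusters with at least 5 reads (`min_cluster_reads`; random
background fragments rarely pile up that high). The most abundant tag is
the mature candidate. Its flanked window (150 nt per side) is folded and
trimmed to a candidate precursor; because a ~320 nt window under a
permissive energy model often pairs part of the mature into random flank
sequence, trimming is a small search rather than a single cut: candidate
spans are proposed from the dominant contiguous duplex run on each
partner side, each side's full partner span, and the combined span; each
is refolded and re-trimmed to a fixed point; and if the wide window fails
the screen, narrower and asymmetric windows (100/100, 60/60, 10/45,
45/10 nt) are rescanned, reflecting that real precursors are short and
extend mostly to one side of the mature. The first span that passes wins;
every accepted candidate re-passes the evaluator on its final precursor.

The screening criteria on the trimmed precursor are: (a) the mature lies
wholly within one arm — some terminal loop separates it from all of its
pairing partners, with no loop overlap or break (side branches introduced
by the trimming pad are tolerated); (b) MFE < -20 kcal/mol; (c) MFEI >
0.85; (d) AU content within 30–70%; (e) fewer than six mature/star
mismatches, counted as one per unpaired base on either side of the duplex
— max(unpaired mature bases, unpaired star-span bases) — so a
substitution counts once and a bulge once per base (counting only the
mature side admits random stems whose partners sprawl across gappy
regions); (f) mature length 20–22 nt. A candidate whose star sequence is
itself observed among the tags is flagged high-confidence. All thresholds
live in `PipelineConfig`.

Known behaviour: at the default scale the screen accepts a few (2–5)
single-read candidates from unannotated random background clusters per
run. This is characteristic of purely structural hairpin screens; the
shuffled-genome negative control (below) is the calibrated specificity
check, and planted non-hairpin loci (rRNA, tRNA, repeats, ...) never pass.

## Differential expression

NE = count/total x 1e6 (TPM over clean reads). Fold change is
log2(NE1/NE2) with 0.01 TPM substituted for zeros in the ratio only (raw
NE stays 0). Significance uses the exact conditional test for digital
counts: given x reads at depth N1, the count y at depth N2 follows
p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)); the two-sided p is
2*min(C, D) capped at 1, with both tails including the observed count.
Tails are evaluated in log-gamma space; the small upper tail is summed
directly rather than via 1-C, which would cancel to noise. x and y are
raw integer counts (the factorial form requires integers), not normalised
values. Classes follow the ratio thresholds: up (> 2-fold), down
(<= 1/2, boundary included), unchanged between. Multiple testing is
Benjamini–Hochberg with alpha 0.01 by default; the package reports both
raw and adjusted p. No replicate-aware model is offered — the design is
one pooled library per condition.

## qPCR

2^-ddCt relative quantification against a reference gene (RPS18 by
default) and a user-chosen calibrator sample (no calibrator is implied by
the data, so it is a required argument). Replicates aggregate by
arithmetic mean; a replicate more than 0.5 cycles from its triplicate
median is flagged, not dropped. Ct above 40 cycles (or missing) is
non-detection, reported as NaN rather than zero expression. No
amplification-efficiency correction (pure 2^-ddCt).

## The synthetic study

The generator emulates the library properties such a study reports: a
random genome (300 kb, GC 0.42) carrying 30 known and 10 novel planted
miRNA hairpins plus 4 loci per other RNA class; two libraries of 2e5
reads each, dominated by 20–22 nt inserts with mode 22 (mature length
couples to abundance — 22-nt species carry full weight, 21 nt x0.4, 20 nt
x0.25 — as 22-mers dominate real libraries); 3' adapters on every genuine
insert; contaminant classes at Table-1-like rates (no-adapter 7e-4,
empty insert 3e-4, 5'-contaminant 1.5e-3, short 0.024, polyA 1e-5);
per-base error 0.005; isomiR rate 0.15 (90% 3'-biased, 1–2 nt, templated
on the precursor); edit rate 0.05 (70% substitutions, 30% untemplated 3'
A/U). Planted hairpins are built as mature + A/C loop + near-reverse-
complement star (0–3 star mismatches by default, never more than five)
and re-verified against the full discovery screen at construction. Twenty
known miRNAs carry a true 4-fold between-library change (ten up, ten
down); because those folds inflate the fetal miRNA pool, the pool is
scaled by a single common factor in both libraries when it would overflow,
keeping every planted ratio exact. Star arms get 8% of their mature's
reads except two precursors planted star-dominant (x1.5) and near-equal
(x0.9) to exercise the arm-usage flags. qPCR Ct values follow
Ct = 30 - log2(abundance) + N(0, 0.15) in triplicate, reference at
abundance 1.

What the generator does not model: indels, quality decay, ligation bias,
multi-chromosome genomes, or biological replicates (the emulated design
pools animals per stage). Passing tests therefore demonstrate pipeline
correctness against planted truth under idealised noise, not performance
on real sequencer output.

The negative control for discovery is an Altschul–Erickson dinucleotide
shuffle of the genome (exact dinucleotide composition preserved): the
same leftover tags are re-screened against the shuffled genome and the
accepted count must be zero.

## Problem sizes and numerics

Default test/acceptance scale: 2e5 reads per library, 300 kb genome —
about 13 s end-to-end on one core (the O(n^3) folding DP is
numba-compiled; a pure-Python fallback engages automatically if numba is
unavailable). Folding tracebacks break energy ties deterministically
(hairpin case, then stack, then leftmost bifurcation; 1e-7 tolerance).
Zero-GC precursors get MFEI 0 (fails the screen) rather than an error.
The exact-test upper tail switches from the 1-C identity to direct
chunked summation when C > 0.5, preserving ~10 significant digits across
the tested grid. Measured behaviour across ten seeds at the default
scale: planted-hairpin recovery 90–100%, shuffled-control acceptances 0,
planted-DE detection 95–100% at BH-adjusted p <= 0.01.
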