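# Methods

This note records the models, parameter choices and numerical conventions
behind `spaninscan`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and gene intervals

All internal coordinates are 0-based half-open on the forward strand;
GenBank and GFF3 input/output converts to and from the 1-based inclusive
convention at the I/O boundary. An `OrfCandidate` interval covers the coding
residues only (translating it reproduces `aa_seq`; the stop codon is
excluded), while *gene* intervals — used for architecture, overlap, gap and
frame arithmetic, and for all reported coordinates — include the stop codon,
matching the GenBank convention. Minus-strand arithmetic is done in
reading-direction coordinates obtained by reflecting through the genome
length.

## ORF enumeration and start refinement

Every maximal stop-to-stop segment in all six frames yields one candidate
per admissible start codon (default {ATG, GTG, TTG}, configurable) with at
least `min_aa` codons (default 40, matching the lower length gate of the
topology classifier). ORFs lacking a terminating stop codon are not
emitted. Unknown bases translate to X; ORFs with more than 10% X are
dropped as presumptive sequencing artifacts.

Ribosome-binding support is modelled as the best ungapped match of ≥4
consecutive bases to the AGGAGG Shine–Dalgarno consensus with a 4–14-nt
spacer, ties toward longer matches and shorter spacers. This is an
intentionally simple heuristic — it ranks alternative starts, it does not
gate candidates. Start refinement operates within a stop-sharing candidate
group: starts whose translation carries a valid membrane signal are
preferred, then stronger SD evidence, then length; if no start validates,
the longest is kept and flagged low-confidence.

The search runs the exhaustive scan on every genome and uses annotated CDSs
only to label candidates (`nested_in`). An annotation-first fast path would
be strictly less sensitive — embedded and overlapped o-spanin genes are
typically unannotated — and could never disagree with the scan on what it
finds, so the pipeline has a single code path.

## Topology model

TMDs are maximal runs of positions whose 19-residue Kyte–Doolittle window
mean is ≥ 1.6, merged across gaps < 3, kept at 15–30 residues (longer runs
are trimmed to their best 30-residue stretch). Window means at the termini
use truncated windows. This windowing scheme is the package's
self-contained TMD detector; externally computed TMD/lipobox coordinates
can be substituted through a simple TSV override table.

A lipobox is the first Cys at 1-based position 12–40 whose preceding
tripeptide matches `[LVI][ASTVI][GAS]` (strict) or is drawn position-wise
from `{A,L,V,I,F,G,S,T,W,M,N}` (relaxed — constructed to admit the deviant
but functional motifs AWAC, LNGC and FVGC while rejecting signal-less
sequences; N is included precisely so LNGC qualifies). Both modes also
require signal-peptide anatomy: at least one K/R in the first 7 residues
and a hydrophobic stretch of ≥6 residues before the box. The 12–40 window
brackets plausible lipoprotein signal lengths; the classifier defaults to
relaxed mode so AWAC-type u-spanins are not missed.

Typing applies, in order: u-spanin (lipobox + one TMD wholly within the
last 35 residues, downstream of the Cys), o-spanin (lipobox, no TMD
downstream of the Cys), i-spanin (exactly one TMD starting within the first
30 residues, no lipobox), else none. Lipobox-bearing types are tested first
so a lipoprotein with a C-terminal TMD is never mistyped as an IM protein.
Sequences outside 40–350 aa are not typed (the gate brackets observed
spanins, from 60-aa o-spanins to ~300-residue systems). A call whose
periplasmic interval would be empty is demoted to none.

Periplasmic domains: i — downstream of the TMD; o — downstream of the
lipoylated Cys (the Cys itself is membrane-anchored and excluded, so a
60-aa o-spanin with the Cys at residue 21 has a 39-aa mature domain); u —
between the Cys and the C-terminal TMD.

## Pairing and architecture

Each o-candidate pairs with the nearest same-strand i-candidate that starts
upstream and lies within `max_gap` = 1000 bp (or overlaps), greedily by
ascending gap; exact ties keep the upstream-nearest i and are flagged
ambiguous rather than resolved. The 1-kb ceiling reflects the most extreme
separated system the search strategy can support; systems separated further
are deliberately out of reach. Unpaired lipoproteins are reported, not
discarded.

Architecture: *embedded* iff o ⊆ i; *overlapped* iff the overlap exceeds
`sep_threshold` = 10 bp; otherwise *separated*. The threshold sits between
the 8-bp start/stop-idiom overlaps that behave as separated genes and the
≥70-bp overlaps of genuinely overlapped systems; any value in that range is
consistent, and the parameter is exposed. Frame offset is defined only for
overlapping pairs: `(o_start − i_start) mod 3` of 1 → +1, 2 → −1; a
same-frame overlap is rejected as an error, since a same-frame nested start
is a truncated variant, not a distinct gene. Relative o-gene position is
reported in units of L (i-gene length in bp).

## Clustering

Pairwise relatedness is the best Smith–Waterman local alignment under
BLOSUM62 with gap open 11 / extend 1 (biopython's `PairwiseAligner`);
identity is matches over aligned columns including gaps, coverage is the
aligned fraction of each sequence, and a non-positive score is a no-hit
sentinel. Families are connected components of the graph with edges at
≥40% identity and ≥40% coverage; by default coverage is required of *both*
sequences (`cov_rule` exposed, since a reference length is a genuine
convention choice). Sequences shorter than 50 aa are excluded from the
graph stage — a deep scoring matrix over-scores fragments under local
alignment — and attached afterwards to the family of their best end-gap-free
global-identity partner meeting the same 40/40 rule, ties toward higher
identity then lexicographic representative; otherwise they found new
singletons. Identical sets (100% identity over 100% full length including
the signal) are computed by exact hashing, which provably agrees with
clustering at id=100/cov=1. Representatives are the longest member, ties
lexicographic.

## Cysteine statistics

Periplasmic cysteines power the intermolecular disulfide bonds that
two-component spanin function depends on, so counts exclude the lipoylated
Cys by construction (the periplasmic domain starts after it). Normalized
positions are reported on two scales: the *complex* coordinate — the i
periplasmic domain (IM end first) concatenated with the reversed o
periplasmic domain (OM end last); the concatenation order is a recorded
convention, isolated so alternatives can be recomputed — and per-component
coordinates (distance to the membrane anchor and to the C-terminal
interaction interface, as percent of that component's periplasmic length).
Relative-position histograms use 0.1 L bins. Lipobox position-frequency
matrices count residues at the three pre-Cys positions plus the Cys; the
package emits the matrix, not a logo graphic.

## Synthetic-genome generator

The generator plants spanin systems with the gene-level anatomy the
detector relies on: i-genes encode Met + a charged N-tail + a 21-residue
hydrophobic block + a hydrophilic tail with planted Cys; o-genes encode a
lipoprotein signal (charged tail, ≥6-residue hydrophobic core, a lipobox
drawn from a configurable mix, default 60% LSGC / 20% LAGC / 20% AWAC) + a
Pro/Ser-rich tail; u-genes add a C-terminal hydrophobic block and are
cysteine-free. Per-component planted-Cys counts are drawn from
distributions approximating the observed census (most common combination:
0 in the i-spanin, 2 in the o-spanin; a few percent of pairs fully
Cys-free). Codons are drawn uniformly among synonyms.

Embedded systems are built by writing the o-gene inside the i-gene tail in
the +1 or −1 frame (default mix 50/50): synonymous-codon space is searched
depth-first so that no stop codon appears in the i-frame across the shared
region; the i-protein residues over that region are whatever the o-gene's
codons induce, and truth records therefore report *realized* cysteine
counts from the final translation. Overlapped systems place the i-gene's
stop inside the o-gene's 5′ region (overlap 30–200 bp, the frame offset
fixed by overlap mod 3); separated systems use 17–900-bp gaps; about 30% of
systems go on the minus strand. Cassettes are interleaved with decoys
(soluble proteins, a non-spanin type-II membrane protein, and a stray
lipoprotein with no i-gene within pairing range) and stop-rich spacers of
≥1050 bp, so no decoy or neighbouring system falls inside another system's
1-kb pairing radius. Annotation omits embedded o-genes and perturbs 20% of
annotated starts, mimicking the documented annotation biases.

Construction is self-checking: each gene must classify to its intended
topology type, each cassette and finally the assembled genome are screened
so that no accidental signal-bearing ORF (including antisense shadows and
junction-spanning ORFs) survives outside the planted genes; failures
re-draw codons deterministically. These checks use the typing layer only —
never the pairing/architecture layer whose accuracy the recovery tests
measure. The guarantee is intentional: the generator's contract is that
planted signals are the *only* signals, so recovery metrics isolate the
search logic itself.

What passing the recovery suite shows: the scanner finds genes the
annotation hides (embedded, frame-shifted, minus-strand, start-perturbed),
the pairing and architecture arithmetic is exact, and decoys within the
modelled classes are rejected. What it does not show: performance on real
genomes with atypical signal anatomy (marginal hydropathy, non-canonical
lipoboxes outside the relaxed set, signals shorter than the 12–40 Cys
window), compositional biases of real phage DNA, or discrimination against
host-like lipoproteins that resemble o-spanins more closely than the
simulated decoys do.

## Problem sizes and numerics

The recovery suite uses 50 simulated genomes of ~15 kb (4 planted systems +
5 decoys each); the clustering cross-check uses 200 random instances of 4
sequences (55–80 aa, up to 45% mutations); the lipobox enumeration covers
all 8000 tripeptide contexts. The whole test suite runs in well under a
minute. Determinism: all generator randomness flows from a single integer
seed through `numpy.random.default_rng`; alignment, clustering and
classification are deterministic, with explicit tie-break rules
(lexicographic ids, upstream-nearest pairing) wherever an order is not
forced.

## Known limitations

* TMD and lipobox detection are heuristic stand-ins for HMM-based
  predictors; the override table exists precisely so external predictions
  can be dropped in.
* Only the canonical topologies are searched: a type-I (N-out/C-in) IM
  protein, an IM lipoprotein acting as i-spanin, or an OMP acting as
  o-spanin would be missed by design.
* Systems separated by more than 1 kb are not paired; lysis-cassette
  proximity is accepted as a hint (`--cassette-hint`) but never used as a
  filter.
* The "score coverage threshold 40" of the emulated clustering regime is
  read as percent identity (consistent with the 40%-identity family
  definition), not as a bit-score density.
* Spliced CDS features are skipped with a warning; they do not occur in the
  phage genomes of interest.
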