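# Methods

## The conformation model

A multipartite mitogenome is represented as an assembly graph: segments
(contigs and repeats) with sequences and integer copy numbers
(*multiplicity*), and oriented links closed under reverse-complement
symmetry (a link `a+ → b+` implies `b- → a-`). A **conformation** is a set
of circular signed-segment paths that together traverse every segment
exactly its multiplicity, moving only along declared links. Enumeration is
an exhaustive backtracking search over the oriented-segment transition
graph; each circle is canonicalised to the lexicographically minimal
representative over all rotations and the reverse-complement traversal, and
conformations are deduplicated as multisets of canonical circles. Two
invariants hold by construction and are asserted: every conformation of a
graph has the same total length and the same multiset of segment usages.

Choices worth knowing:

* **Direct junctions only.** Links are traversed in their declared
  orientations; inversion-mediated recombination (using a repeat as its
  reverse complement where no such link exists) is not enumerated.
* **The single-circle decomposition is reported.** For the two-repeat
  topology, crossing both repeats simultaneously fuses everything into one
  circle. It falls out of the same pairing logic, so it is enumerated and
  carried through ranking, flagged in the report
  (`note: requires simultaneous crossing of both repeats`) since genome
  announcements for this genome type typically present only the
  multi-circle forms.
* **Overlaps.** Circle length is the sum of member segment lengths minus
  link overlaps; the default overlap is 0, under which the large and small
  chromosomes of the reference topology come out at exactly
  324,581 bp (ctg1+ctg2+R1+R2) and 42,766 bp (ctg4+R2). The middle
  chromosome computes to 50,347 bp (ctg3 + R1 = 42,563 + 7,784); the
  deposited record for that molecule is 4 bp shorter (50,343), a
  discrepancy the source data leave unexplained. We do not force agreement;
  the arithmetic value is what the code reports.
* **Ordering.** Conformations sort by descending circle count, then
  canonical key, so the fully-resolved (most-circles) conformation is first
  and wins ties in ranking.

## Junction support

For a repeat `R`, every admissible ordered pair of (incoming flank,
outgoing flank) defines a junction reference `flankA + R + flankB`, with
flanks being the terminal `flank_len` bases of the adjacent contigs
(default 2,000 bp; truncation is recorded when a contig is shorter).
References equivalent under reverse complement are built once.

Reads are aligned with the package's seed-and-extend aligner (below). An
alignment is **spanning** when it covers
`[repeat_start − min_anchor, repeat_end + min_anchor]` (clipped to the
reference) at identity ≥ `min_identity`. The anchor default is 200 bp: the
source data never state how much flank a counted read must cover, and
200 bp is consistent with every read record in the published support table
(the tightest row spans 1,089–6,858 around a repeat at 2,001–5,519).
The identity floor is 80% (published records range 84.4–97.8%).

Each read is assigned to the path of its highest-scoring spanning
alignment; exact score ties mark the read ambiguous and exclude it from
all counts. A conformation's support is the number of assigned reads whose
path is one of the junctions realised by its circles. Note that
conformations share junctions — the recombinant two-circle forms each
realise both junctions of one repeat's resolved form — so per-conformation
counts deliberately overlap; `path_counts` gives the disjoint per-junction
breakdown, and "alternative-specific" support is the count on paths not
realised by the primary conformation. Coordinates in all tables are
1-based inclusive, with reverse-strand reads reported `read_start >
read_end`, following the conventions of published read-validation tables.

## The aligner

Local alignment is seed-and-extend: exact k-mer anchors (default k = 13,
both strands), anchors clustered by diagonal, and each cluster extended by
a banded affine-gap Smith–Waterman/Gotoh DP (numba-compiled) over a window
around the cluster. Scoring is blastn-like: match +2, mismatch −3, and a
length-L gap costs 5 + 2L. The band is the cluster's diagonal range padded
by `max(24, min(160, window/8))`, and windows extend up to 2.5 kb beyond
the anchored region, so on short pairs the DP is effectively exhaustive —
tests assert score equality with a full dynamic-programming oracle on
≤ 2 kb pairs. Hyper-repetitive seeds (> 200 reference positions) are
dropped; queries shorter than k return no alignments. Identity is
matches / alignment columns (gaps included) × 100, reported to 3 decimals.

Limits: extension is banded, so an alignment whose optimal path drifts more
than the band width off the seeded diagonals (indel imbalance ≫ 160 bp)
can score below the full-DP optimum; at the ≤ 10% indel rates used
throughout this is not observed. Local extension may also run a few
coincidentally matching bases past a planted feature's boundary, which is
why interval-recovery checks allow small slop.

## Repeat scanning

**SSRs** are maximal perfect tandem repeats of 1–6 bp units with MISA-style
minimum copy numbers (`1-10 2-5 3-4 4-3 5-3 6-3`); units that are
themselves periodic are reported at their smallest period. Records are
anchored at the left end of the maximal periodic region and truncated to
whole copies, so `end − start + 1 = unit × copies` always holds. Adjacent
records within `compound_max_gap` (default 0, i.e. directly abutting) are
flagged compound; they are kept as individual records rather than merged so
the length invariant survives. Runs of N break the scan.

**Dispersed repeats** are interval pairs (within or between chromosomes)
with an alignment ≥ `min_len` (default 30 bp) at ≥ `min_identity` (default
90%), classified forward vs palindromic. At `min_identity = 100` the
scanner switches to exact k-mer-seeded maximal extension — the DP would
prefer higher-scoring mismatch-containing alignments that the 100% filter
would then discard. Pairs are reported once, unordered; the trivial
self-hit is excluded.

**Tandem arrays** (periods above the SSR range, default 7–500 bp) come from
shifted self-comparison: runs of agreement between the sequence and itself
offset by the period, merged across short disagreements while the match
fraction stays above `min_pct_match` (default 80%). Copy numbers may be
fractional; overlapping calls at different periods keep the best percent
match (smaller period on ties). This is a deliberately simple periodicity
scanner; parity with Tandem Repeats Finder's scoring is not attempted.

Circular chromosomes are scanned for SSRs and tandem arrays with a wrap
window appended so origin-crossing arrays are found once (their end
coordinate may exceed the sequence length); dispersed-pair scanning is
linear, so a dispersed copy split exactly by the origin would be missed —
a known limitation.

## MTPT detection

Each mitochondrial chromosome is aligned against the plastome on both
strands; hits pass at identity ≥ 80% and e-value ≤ 1e-5. E-values use the
ungapped Karlin–Altschul formula `E = K·m·n·e^(−λS)` with λ solved at run
time from the match/mismatch scores under uniform base composition and
K = 0.41; NCBI parity is not claimed — the thresholding behaviour at 1e-5
is what matters. Hits sharing ≥ 80% of a mitochondrial interval merge into
one fragment carrying several plastid intervals (an IR-resident transfer
hits both IR copies). Labels `MTPT1..n` follow mitochondrial coordinate
order, chromosomes in input order.

The plastome's inverted repeat is the longest interval pair in which one
copy matches the reverse complement of the other at ≥ 95% identity over
≥ 1 kb, found by self-comparison; a sequence that is one whole palindrome
splits at its centre. A fragment is a **transfer hotspot** when all its
plastid hits lie inside the IR (10 bp slop for coincidental extension) and
no other fragment shares half of its mitochondrial interval. A plastome
gene is *completely* transferred when its whole interval lies inside a
fragment's plastid interval; boundary overlaps are reported as partial.
The cumulative transferred length is the union of mitochondrial intervals,
and its percentage of the mitogenome is rounded half-up to 2 decimals
(union of 4,594 bp on a 417,690 bp genome → 1.10%).

## RNA-editing effects

Edited positions arrive as (gene, CDS position, probability) records from
upstream predictors; sites below the probability floor (default 0.9) are
excluded from summaries. The affected codon is `ceil(pos/3)` with offset
`((pos−1) mod 3)+1`; the base must be C (DNA input accepted, codons
reported in RNA alphabet). Categories, in precedence order: *start_gain*
(codon 1 becomes AUG from non-AUG — internal ACG→AUG is just
nonsynonymous), *stop_gain* (new codon is a stop, old is not), then
*synonymous* / *nonsynonymous* by amino-acid comparison under the standard
genetic code (plant mitochondria use it; the NCBI table number is
swappable). Stop- and start-gains count inside the nonsynonymous total, so
`n_sites = n_synonymous + n_nonsynonymous` always holds. Tests check every
category against re-translation of the full edited vs unedited CDS.

## Synthetic data: what it does and does not show

Generators are deterministic (numpy Generator seeded per generator with a
salted stream so same-seed runs of different generators never replay the
same bases) and record exact ground truth.

* The toy graph defaults to a **1/100 scale-down** of the real topology
  (contigs 2,225 / 908 / 426 / 392 bp) with repeats floored at 300 bp so
  junction-spanning reads remain meaningful at simulation read lengths;
  `scale=1.0` reproduces the published segment lengths. Sequences are
  i.i.d. random at the target GC (0.46).
* Long reads: conformation mixture weights, circles sampled proportional
  to weight × length, uniform start (reads cross the origin), uniform
  strand, log-normal lengths (default mean 1,500 bp at toy scale, sd
  800–1,000 — a Nanopore-like heavy right tail), and i.i.d. per-base
  substitution/insertion/deletion errors (default 4/2/2% ≈ 8% total).
  The error model has no homopolymer bias and no chimeras; it exercises
  the thresholding logic, not basecaller realism.
* The toy plastome is LSC + IRa + SSC + IRb with IRb an exact reverse
  complement of IRa; transfers are copied into the mitochondrial sequences
  with a chosen substitution divergence, optionally sourced inside the IR
  to plant hotspots.
* Planted SSRs and dispersed pairs have their boundaries adjusted so the
  planted array is maximal exactly as placed, making truth intervals exact.
* Edit sites are sampled from real C positions and categorised by direct
  translation, with probabilities uniform in [0.9, 1.0].

Because every sequence is i.i.d. random, passing tests demonstrate the
combinatorics, thresholding and coordinate bookkeeping — not robustness to
the repeat-dense, compositionally biased sequence of real organelle
genomes, nor to structured Nanopore error. Genome-scale published counts
(e.g. SSR or scattered-repeat totals per chromosome) depend on the
deposited accessions and on unstated tool settings, and are treated as
optional external validation rather than test targets.

## Problem sizes and defaults used in the test suite

End-to-end recovery runs 20 replicates of the 1/100-scale genome at depth
30 with 8% read error and a 0.8/0.1/0.1 mixture, asserting the three-circle
conformation dominant in ≥ 95% of replicates. Oracle-equivalence suites use
50 kb (SSR), 8–10 kb (dispersed, exact), ≤ 2 kb (aligner DP) and ≤ 600 bp
CDSs (editing). These sizes keep the whole suite around a minute on one
CPU while leaving every detector's search space non-trivial.
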