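# Methods

`duplexfid` measures the fidelity of RNA synthesis and reverse transcription
from duplex circular-consensus sequencing of reverse-transcribed RNA
amplicons, and ships a truth-annotated simulator so the whole measurement
chain can be validated by parameter recovery.  This note records the model,
the tunable parameters, the numerical choices, and what the synthetic data
do and do not establish.

## Measurement model

A double-stranded DNA product of an RNA template carries errors from three
stages: RNA synthesis by the RNA polymerase (RNAP), first-strand (cDNA)
synthesis by the reverse transcriptase (RT1), and second-strand synthesis by
the same enzyme on a DNA template (RT2).  Sequencing both strands of each
molecule lets the pipeline separate two quantities:

* **First-strand errors** — discrepancies between the cDNA and the reference
  (RNA-sense) sequence that are *also present, identically, in the second
  strand*.  Duplex confirmation removes consensus/sequencing artifacts; the
  remaining events are the cumulative errors of RNAP and RT1.  The two are
  intrinsically indistinguishable from one observed mismatch, so every
  substitution carries both equivalence labels: for reference base A read as
  C in the cDNA, `rA->rG / dT->dC` — either the RNAP put G opposite template
  dT, or the RT put dC opposite template rA.  The labels satisfy a complement
  identity (the RNAP product base is the Watson-Crick complement of the RT
  product base) that the test suite checks exhaustively over all 12
  mismatches.
* **Second-strand errors** — loci where the second strand differs from the
  first while the first matches the reference.  These isolate RT fidelity on
  DNA templates.  Labels are written (expected base) -> (observed base) in
  second-strand frame.

Loci where both strands differ from the reference *discordantly* fit neither
definition; they are dropped from both classes and counted in the audit log.
This drop-and-log rule is a package decision (the definitions are silent on
the case); the discordant counter makes it auditable, and in all simulated
runs with realistic rates the count is zero or negligible.  Every discrepant
locus therefore lands in exactly one of {first-strand, second-strand,
unconfirmed-first, discordant} — a partition property under test.

Indels spanning multiple consecutive bases are collapsed into a single
event (one slippage event, regardless of length).  When the two strands
carry same-locus indels of different lengths, the shared length is counted
as a first-strand event and the difference as a second-strand event,
preserving the partition.  Same-locus insertions with no common prefix are
dropped as discordant.

## Rates, fold changes, statistics

Error rates divide collapsed event counts by the total number of analyzable
sequenced bases (reference positions covered by both strands of accepted
molecules, primer regions excluded; deleted positions consume denominator,
inserted bases do not).  Replicate templates give a mean ± SD per condition.
The effect of a base modification is the relative fold change `(M - S)/S`
per substitution subtype (M = rate on modified RNA, S = unmodified; 0 means
no change, -1 complete suppression).  Condition comparisons use a two-sided
Welch t-test — "t-test" is underspecified with n = 4 replicate templates of
unequal variance, and Welch is the safer default — with the significance
level Bonferroni-divided by the number of comparisons.

## Filters (defaults, all configurable in `RunConfig`)

| parameter | default | role |
|---|---|---|
| `min_passes` | 15 | minimum subread passes per strand consensus |
| `qual_threshold` | 93 | minimum event Phred on both strands |
| `min_mapq` | 60 | minimum mapping quality |
| span rules | — | alignment must start in the 5'-primer and end in the 3'-primer interval (boundaries inclusive) |
| chimera | — | any supplementary (split) mapping rejects the read |
| `max_len_dev` | 50 | max deviation of read length from the expected (amplicon) length |

"Expected read length" is taken as the amplicon length (per-amplicon, not a
library-wide mode).  Primer annotation defaults to 20 bases at each end (40
excluded bases total); the intervals are explicit in the `Amplicon` type and
in the FASTA JSON sidecar, so other layouts are expressible.

Event quality for indels is defined as the minimum Phred over inserted bases
(insertions) or over the two read bases flanking the gap (deletions), since a
gap itself has no base quality.  The threshold applies to substitutions and
indels alike.  With the package's majority-vote consensus, per-base quality
is the Phred-scaled column agreement, `min(93, round(-10 log10(max(1 - f,
10^-9.3))))`, which saturates at 93 only when every pass agrees; at finite
raw error the distribution of true-event qualities sits well below 93, so
runs on simulated subreads set `qual_threshold` accordingly (0 in the
recovery studies — duplex confirmation, not the quality cut, is what rejects
artifacts there).  The default of 93 matches pipelines whose consensus
quality scale saturates.

## Consensus

The per-strand consensus is a column-wise majority vote: subreads are
aligned pairwise (unit-cost edit distance, edlib) to a draft — the longest
subread, ties broken lexicographically — and votes tallied per draft column,
ties broken by fixed base priority A < C < G < T with gap last, so the
result is independent of subread order.  The draft is polished by re-voting
until a fixed point, then residual ambiguities are repaired by maximum
parsimony: candidate edits suggested by the vote structure are accepted only
if they strictly reduce the total edit distance of the subreads to the
consensus.  The repair step matters almost exclusively around homopolymer
runs, where optimal per-read alignments represent the same indel in
structurally different ways and would otherwise split its votes.  Insertions
relative to the draft are emitted on plurality support from more than a
third of the reads (chance co-occurrence of raw-noise insertions at one
anchor is orders of magnitude rarer).  At 20 passes and 10% raw error this
recovers the exact strand sequence in ≥ 99% of molecules (measured 100% over
300 in the suite).  This is an intentionally simple consensus with an
explicit contract, not a pulse-level HMM polisher; externally produced
consensus FASTQ (e.g. real CCS output) can be substituted via
`read_consensus_fastq`.

## Alignment

Reads are aligned to the reference with an affine-gap Gotoh dynamic program
(numba kernel) under overlap (free-terminal-gap) boundary conditions;
default scores match +2 / mismatch -4 / gap open -6 / extend -1 per gap base
(BWA-MEM-like; any concordant scheme suffices given the downstream duplex
confirmation).  Internal unique alignments get a sentinel mapping quality of
60; externally supplied SAM/BAM (with real MAPQ and supplementary flags) can
be imported instead.  After traceback every indel run is shifted to its
leftmost score-equivalent placement against the reference — mandatory,
because first- and second-strand events can only be matched positionally if
both strands normalize indels identically.  The DP optimum and the
left-normalization are verified against an exhaustive-enumeration oracle on
small instances in the test suite.  Ties in the DP are broken
deterministically (diagonal, then reference-gap, then read-gap).

## Simulator

`simulate_molecule` pushes a reference through the three stages in order,
recording every injected event with its stage and a left-aligned reference
coordinate.  Stage error models are 4×4 substitution matrices (template ->
product, in the physical frame of the stage: RNA frame for RNAP, cDNA frame
for RT1, second-strand frame for RT2) plus per-base deletion/insertion rates
with a size distribution, an optional 5'-context multiplier (emulating
context-dependent misincorporation), and a per-locus slippage rate that
gains or loses one whole unit at tandem repeats (detected by scanning the
reference for primitive units of 1-6 bases with at least 3 copies and 6
bases total).  Non-slippage insertions draw bases uniformly; slippage
inserts or deletes whole repeat units, which is what produces triplet
insertions at GCT repeats.  A base modification is represented purely as a
different stage model (e.g. elevated rA->rU for an isomerized uridine);
the chemistry is invisible downstream, as it is in the real assay.

Errors are injected only in the analyzable region, and insertion anchors are
kept interior to it, so truth events are always positionally comparable to
called events.  Raw subreads add per-pass substitution (90%) and single-base
indel (10%) noise at a configurable rate.  Chimeras fuse two independently
simulated molecules at offset breakpoints (loop-out template switching), so
their length deviates and the read-length filter removes them; the simulator
default chimera rate (1% where enabled) is a placeholder, as the artifact
rate is not a measured quantity.  A single dataset seed fans out to
per-molecule generators via `default_rng([seed, molecule_index])`, making
any molecule individually reproducible.

What the simulator does *not* emulate: pulse-level sequencing physics,
modification-dependent polymerase kinetics, adaptor artifacts, coverage
biases, or correlated (burst) errors.  Passing recovery tests therefore
demonstrates that the measurement chain is unbiased under the stated error
processes — not that real-instrument artifacts are fully handled; for real
data the external-consensus and external-SAM entry points exist precisely
so the measured components can be swapped in.

## Study scales and numerical notes

The validation studies use 500-bp amplicons containing all 256 overlapping
4-mers (a randomized order-4 de Bruijn circuit; such a circuit caps
homopolymer runs at 4 automatically, since a run of 5 would traverse a
homopolymer edge twice) with 20-base primers at each end — near-equimolar
composition, no long homopolymers.  Attribution soundness is checked on
2 000 noiseless-consensus molecules per stage at 5×10⁻⁴ events/base;
parameter recovery on ~10⁶ analyzable bases per condition sequenced as
20-pass subreads at 5% raw error, with injected per-subtype rates spanning
5×10⁻⁵–5×10⁻⁴ recovered within 3 binomial SE; the acceptance script runs
4 replicate templates × 250 molecules per condition.  These sizes were
chosen to give 3-sigma-resolvable counts for every tested quantity on a
single CPU.  Degenerate inputs are defined errors: empty subread lists,
zero-base denominators, fold changes with S = 0 (reported as missing, never
as a number), and comparisons with fewer than two replicates all raise.
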