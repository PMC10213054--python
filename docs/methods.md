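# Methods

## Scope and model

`oligostore` implements a complete desk-scale DNA data-storage codec for
nanopore readout.  A byte stream is protected by two nested codes and mapped
to short oligonucleotides; reads come back not as base strings but as CTC
posterior matrices - per-time-step probability rows over (blank, A, C, G, T),
the native output of neural-network basecallers - and the inner decoder
consumes those probabilities directly, so soft information in the signal is
available for error correction instead of being collapsed into a basecall
first.

The layered model:

1. **Whitening.** The file is XORed with a seeded PCG64 keystream so the
   encoder input looks random and the 2-bits/base mapping produces no long
   homopolymers.  A production system would compress and encrypt instead;
   whitening is the invertible, dependency-free stand-in, and the seed is in
   the manifest.
2. **Outer code.** The whitened file is split into fixed-size data segments
   (default 64 data bits, i.e. 8 bytes per oligo) and extended with
   Reed-Solomon parity segments over GF(256) in evaluation (generalized RS)
   form, k data + p parity per block with any k of k+p sufficient.  Whole
   oligos missing from the read set are erasures; segments that fail the
   inner CRC are simply discarded upstream, so the outer channel is
   erasure-only and no RS error decoding is needed.  Blocks interleave
   segments round-robin because coverage skew tends to hit runs of adjacent
   oligos.  Duplicate decodes of one index are reconciled by per-byte
   majority, ties to first received.
3. **Inner code.** Each segment message is `index | data | CRC-8` and is
   encoded by a feed-forward convolutional code with memory m (state = last
   m input bits) and zero-tail termination (m zero flush bits).  Rates above
   the 1/2 mother rate come from periodic puncturing; the decoder treats
   punctured positions as erasures.  Default generator taps are the
   published maximum-free-distance pairs (m=6: 133/171, m=8: 561/753,
   m=11: 5537/6131, octal), free distances 10/12/14 (verified in-code by a
   weight search).  The CRC-8 is polynomial 0x07, xorout 0 and - after a
   lesson the simulator taught us - init 0xFF rather than 0 (check value
   0xFB; the init-0 SMBUS variant, check 0xF4, remains available): a
   homopolymer slip in the channel yields a *rotated* codeword,
   convolutional codes are time-invariant (a rotation is again nearly a
   codeword), and a zero-init CRC is shift-covariant, so slipped reads'
   frames passed the check at ~20x the random rate and the
   accepted-but-wrong rate sat near 3%.  The nonzero init injects a
   constant that rotations do not preserve and returns the undetected-error
   rate to the generic ~L/256 floor (0.4% measured at the default operating
   point).  A two-CRC mode protecting the two message halves separately
   exists as a config option and is off by default.
4. **DNA mapping.** Coded bits map 2 bits/base (00:A, 01:C, 10:G, 11:T); an
   odd punctured stream gets one 0 pad bit, recorded in the manifest.
   Oligos are `25-nt primer | payload | 25-nt primer`, kept under 200 nt.

## The integrated CTC list-Viterbi decoder

The decoder's trellis nodes are `(augmented encoder state, position in the
base sequence)`.  One base carries two transmitted bits while an encoder
step emits one or two transmitted bits depending on the puncture phase, so
the augmented state carries at most one *pending* transmitted bit beside the
m-bit register; which positions have a pending bit is fixed by the puncture
schedule, only its value is state.  Transitions out of position j emit one
base and consume the input bits whose outputs fall inside it (flush and pad
bits forced to zero).

Per node the decoder keeps the top L candidate message prefixes (default
L = 8; larger lists buy little).  Each candidate stores two log scores -
paths ending in blank and paths ending in the last emitted base - per the
CTC convention that a sequence's probability sums over all state paths
collapsing to it.  At every time step a candidate can stay (emit blank, or
re-emit its last base without collapse) or extend along a trellis
transition; candidates reaching the same node with the same message merge by
logsumexp, and pruning happens only after that merge.  Ties in score resolve
to the lexicographically smaller message, making lists reproducible.
Probabilities are floored at 1e-12 before the log.  The final list is read
off the (end state, full length) node and CRC-checked; the filter accepts
the best-scoring candidate whose CRC passes, otherwise the read is
discarded.

Two approximations keep this desk-scale, both disabled in "exact mode"
(`beam_width=None, score_window=None`, used by the oracle-equivalence
tests):

* a global beam capping live candidates per time step.  The default is
  strictly proportional to the code, `2 * 2^m` (floor 64, cap 8192): a
  fixed beam — or a floor that binds only for small codes — prunes
  high-memory codes harder *relative to their state count* than small ones
  and distorts comparisons across m, so pruning severity is kept
  proportional.  Conversely, when sweeping the list size L the beam must
  not be the binding constraint, so those experiments run at a wide fixed
  beam;
* a score window (15 log units) dropping candidates hopelessly behind the
  per-read best (verified to leave decoded fractions unchanged relative to
  a 40-unit window).

Correctness of the exact algorithm is established against an independent
brute-force oracle that scores every codeword with a standard CTC forward
pass on the interleaved-blank lattice.

Primer trimming locates both primers by affine-gap local alignment (match
+1, mismatch -1, open -2, extend -1), acceptance threshold 60% of the
perfect score, with a 0.5/base discount for primer bases truncated off a
read end, and flags reads whose forward primer starts suspiciously late as
chimera suspects (trimming at the hit anyway).  The basecall-coordinate
window maps to posterior rows as [first payload base's dwell start, first
rev-primer base's dwell start): an earlier midpoint rule occasionally leaked
one primer dwell row into the window, which at sharp posteriors lets a
shifted codeword outscore the truth.

## Synthetic nanopore channel

The simulator models the basecaller's posterior, not raw current - the
decoder consumes posteriors, so this is the correct interface.  Per true
base it draws a geometric dwell (mean `dwell_mean`, default 2.0 rows) of
rows favoring that base, separated by blank-favoring gaps (mean set by
`blank_bias`, default 0.35; a gap is forced between equal consecutive bases
so the emitted posterior is always CTC-consistent).  Rows are softmaxes of a
one-hot logit (scale 4) plus Gaussian noise scaled by
`confusion_temperature` (default 0.25, giving confident rows whose greedy
argmax is essentially always the favored state).  Substitution, insertion
and deletion events change which base a dwell favors or whether it exists;
their rates default to 33% / 27% / 40% of `target_error_rate` (default
0.055), the rough indel-heavy nanopore profile.  The calibration test
confirms the resulting greedy-basecall edit error lands inside the 4.5-7%
window typical of recent flowcells, and that error grows monotonically with
`confusion_temperature`.

Pool-level simulation adds coverage skew (default lognormal with sigma 0.5,
emulating the elevated coverage variance of bead-bound pools; uniform mode
for the aqueous control), per-oligo dropout, and chimeric reads formed by
prefixing a fragment of another oligo.  A truth table records each read's
source oligo and payload row window.

What the channel does *not* model: raw squiggle statistics, pore chemistry
differences, basecaller-specific error correlations, flowcell quality drift
beyond the error-rate knob, and strand orientation (forward-strand reads by
default; a reverse-complement pre-pass is available).  Passing tests
therefore show the codec handles an indel-heavy soft channel at realistic
error rates with realistic coverage pathologies - not that real-flowcell
reading costs are reproduced, which depend on hardware beyond desk scale.

## Combinatorial barcode addresses

48 barcode 20-mers plus 7 scaffold 20-mers (and one linker) are rejection
sampled so that no two sequences share any 9-mer; each of 6 subunits owns 8
barcodes, giving 8^6 = 262,144 addresses from 48 oligos.  Constructs are
`scaffold1 barcode scaffold2 ... scaffold7 linker payload`.  Decoding finds
scaffold anchors by k-mer lookup, cuts subunit windows between consecutive
anchors (5 nt slack only on sides whose anchor is imperfect or inferred -
exact windows contain no junction-spanning k-mers, so error-free constructs
always decode strictly), and counts each candidate barcode's twelve 9-mers
in the window; the argmax calls the state, ties call nothing.  Strict mode
additionally demands zero k-mer counts for every competing barcode at every
subunit - the inclusion rule used for lookup-table construction.  From a
full-address success rate s over n independent subunits the per-subunit
failure is 1 - s^(1/n).

Hierarchical access is modeled as six deterministic selection rounds: round
i multiplies matching constructs' abundance by a gain g (default 500) and
the rest by a leak fraction (default 0.05), then renormalizes - a gain/leak
recurrence, not a PCR biochemistry model.

## Costs and experiment orchestration

Writing cost is bases synthesized per information bit
(`n_oligos x payload_bases / file_bits`), reading cost bases sequenced per
information bit, both excluding primer bases; coverage = reading/writing and
coding density = 1/writing cost.  One source describes the cost formulas in
bits/base while defining the metrics in prose as bases/bit; this package
implements the bases-per-bit convention and exposes density as the
reciprocal.  Minimum reads for recovery subsamples the read set on a
geometric grid (factor 1.25) refined by bisection, N = 10 seeded trials per
size, requiring byte-exact recovery in *all* trials (inner decodes are
deterministic per read and therefore cached across subsamples).

The manifest (JSON sidecar) carries everything needed to decode - geometry,
code parameters, whitening seed, primers - and decoding refuses to run
against a mismatched configuration.

## Problem sizes and numerical choices

Tests and the acceptance script run deliberately small instances chosen as
realistic miniatures: files of 48-96 bytes, pools of 10-20 oligos, read sets
of 300-1000, 64-bit per-oligo frames for the monotonicity sweeps, and
m = 2 codes with 16-bit frames where exhaustive enumeration is the oracle.
Degenerate inputs are defined: empty messages encode to the termination
flush alone; an all-erasure received stream decodes to the all-zero message
via the deterministic tie-break (prefer the input-0 branch); posteriors
shorter than the codeword's base count raise an undecodable error rather
than returning garbage.

## Known limitations

* The exact generator polynomials, puncturing patterns and CRC variant of
  any particular deployment are conventions; ours are declared in the
  manifest and bitstream parity with other implementations is not promised.
* The global beam and score window make high-memory decoding approximate;
  monotonicity comparisons across m are meaningful under the proportional
  beam policy but absolute decoded fractions depend on it.
* The outer channel is erasure-only: a wrong message that passes CRC
  (probability ~2^-8 per accepted candidate) can poison its segment if no
  correct duplicate outvotes it.
* Whitening is not encryption and provides no confidentiality.
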