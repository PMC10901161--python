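# Methods

## Problem and approach

`vectorfree` verifies that a genome-edited plant line carries no DNA
from the binary vector used during editing. Where a null segregant
cannot be bred (vegetatively propagated crops such as potato), this
verification rests entirely on molecular evidence. The package
implements the sequence-level form of that evidence chain:

1. **k-mer screening.** Every position *i* of the vector (length *L*,
   circular) contributes one k-mer. For a read library, `counts[i]` is
   the number of reads containing that k-mer (each read counted at most
   once per position). If any vector fragment is present in the plant
   genome, the positions it covers accumulate hits in proportion to
   sequencing depth.
2. **Per-position G-test.** For the edited line (library size n₁,
   hits a) against a wild-type control (n₂, c), the 2×2 table
   (a, n₁−a; c, n₂−c) yields the log-likelihood-ratio statistic
   G = 2·Σ O·ln(O/E), asymptotically χ²(1) under equal hit
   proportions. Using library sizes as margins is the minimal
   correction for unequal sequencing depth. Positions with
   G > χ²₀.₉₉(1) = 6.635 are flagged (strictly greater; a tie is not
   significant).
3. **Peak calling and replicate intersection.** Maximal runs of
   significant positions (gaps ≤ k−1 merged) become candidate
   segments; each end is extended by k−1 because a hit at a start
   position implies shared sequence through start+k−1. No per-position
   multiple-testing correction is applied — instead, the screen is
   repeated with an independent sequencing run and only peaks whose
   spans overlap across runs count. Under independence the
   per-position false-positive rate falls from ≈α to ≈α².
4. **Orthogonal channels.** In-silico PCR over a primer panel tiled
   across T-DNA and backbone (a band requires both primers inside a
   genomic template), restriction-digest fragment prediction with a
   probe-overlap test (the expected-fragment logic of a Southern), and
   global-alignment classification of cloned target-site amplicons
   (indel events, reading-frame consequence, per-line disruption
   status, off-target homolog check).

A line is reported `transgene_free` only when every detection channel
that ran is clean: no replicated k-mer peak at any configured k and no
vector-panel PCR band while the genomic control set amplifies. The
verdict is fail-closed — with no detection channel, or a failed stage,
it cannot be true.

## Counting and canonicalisation choices

* **Canonical k-mers** (lexicographic minimum of k-mer and reverse
  complement): shotgun sequencing is strand-agnostic, so matching must
  be too. The 2-bit encoding (A<C<G<T) preserves lexicographic order,
  letting the scanner canonicalise on integers.
* **Read-level presence, not occurrence counts:** a read increments a
  position at most once, so `library_size` is a clean margin for the
  2×2 table and `counts[i] ≤ library_size` always holds.
* **Circular topology by default** (binary plasmids are circular), so
  positions L−k+2..L carry wrap-around k-mers; a linear mode exists
  for linearised references.
* **Duplicate vector k-mers** map one key to many positions; every
  position sharing a k-mer receives the same increment.
* Reads shorter than k contribute nothing but stay in `library_size`
  (it measures sequencing effort, not usable k-mers).
* Positions whose k-mer contains a non-ACGT base are absent from the
  index and always count zero.

The production scanner vectorises 2-bit rolling k-mer codes per read
(k ≤ 31; longer k falls back to a per-read dictionary scan) and is
required by the test suite to agree **exactly** with a brute-force
substring-scan oracle.

## Statistical conventions

* 0·ln 0 = 0; a table with a zero row sum is undefined (NaN) and
  treated as non-significant.
* df = 1, α = 0.01 by default; both k = 20 and k = 25 are screened and
  the verdict requires all configured k to be clean.
* No Williams or Yates correction by default (both available as
  flags): the printed 6.634/6.635 threshold is the uncorrected
  chi-square limit.
* Peak calling considers only *sample-excess* positions (sample hit
  proportion above control): the question is presence in the edited
  line, not depletion. Depleted-direction significance is still
  visible in the track output.
* Single significant positions are reported as peaks; `max_gap`
  defaults to k−1.

## What the generator emulates — and what it does not

`simulate` produces: i.i.d.-base host genomes at a plant-like GC
(0.36 default in the studies), circular vectors partitioned into
T-DNA [1, tdna_len] and backbone with nested marker/nuclease-cassette/
probe features, optional integration of a (possibly truncated,
possibly origin-spanning) vector segment at a chosen host locus,
optional vector tracts copied verbatim into the host (plant-derived
promoter/terminator-scale elements that create genuine background
signal in a wild type), and uniform single-end reads with i.i.d.
substitution errors and constant placeholder qualities.

Not modelled: indel sequencing errors, GC-biased or otherwise
non-uniform coverage, adapter contamination, paired ends, repeat
structure of real plant genomes, and quality values. Consequently the
studies below demonstrate the statistical behaviour of the method
under its own assumptions — clean nulls, calibrated type-I error,
sharp power — not its robustness to real-library artefacts such as
coverage waves or repeat-induced multi-mapping k-mers, which in real
data are absorbed by the wild-type control sharing those artefacts.

## Reference study conditions

Fixed in `vectorfree.experiments` as package defaults: 100 bp
single-end reads, 30× coverage per library, substitution rate 0.001
(0 for power runs), vector 2 kb T-DNA + 3 kb backbone, k ∈ {20, 25},
α = 0.01. Desk-scale genome sizes: 10 kb host for calibration, 20 kb
for the replicate-null study, 50 kb for power and end-to-end runs.

* **Null calibration** embeds one full vector copy in the host so all
  positions are testable, then splits each of 50 libraries into
  even/odd halves — equal hit proportions hold by construction. The
  significant fraction is measured over positions spaced 150 bp apart:
  adjacent positions share reads (decorrelation length ≈ read_length −
  k ≈ 80 bp), so only well-spaced positions give the independent
  Bernoulli trials a 3-binomial-SD comparison assumes. An exact
  pre-design calculation (Poisson hit totals, binomial split) puts the
  true per-position level at ≈0.011 for these counts — within the band
  at the study's n, and the measured fractions agree.
* **Replicate-null study** uses the wild-type background with two
  300 bp vector-homologous tracts; each of 100 pairs runs two
  independent sample/control experiments. Observed: ≈0.2 raw peaks per
  run per k, and ≥95% (measured 99%) of pairs with zero replicated
  peaks.
* **Power study** integrates the whole 2 kb T-DNA into a host that
  shares no sequence with the vector — power is defined for segments
  that are actually foreign; a plant-derived element inside T-DNA is
  invisible to any host-vs-vector comparison by construction. At 30×
  error-free, ≈99% of segment positions are significant (the final
  k−1 positions have junction k-mers that do not exist in any read)
  and the strongest peak recovers both breakpoints exactly after the
  k−1 end-extension.
* **k-sensitivity:** with errors, the probability an error-free copy
  of a k-mer survives is (1−e)^k, so 25-mer tracks are never more
  sensitive than 20-mer tracks on the same data.

## Orthogonal-channel conventions

* **PCR matching:** ≤2 mismatches per primer, 0 mismatches in the
  3'-terminal 3 bases, products ≤5 kb; both orientations of the pair
  are searched and circular templates may yield origin-spanning
  products. These are conventional in-silico PCR defaults, exposed in
  the API.
* **Digest:** exact recognition motifs with a per-enzyme cut offset
  (built-in BamHI=G^GATCC, HindIII=A^AGCTT, EcoRI=G^AATTC; both
  strands cut for non-palindromic motifs). Fragment sizes always sum
  to genome length; a probe-hit requires ≥50 bp overlap with the
  integrated probe copy, located via simulation ground truth.
  Incomplete digestion is out of scope.
* **Alignment:** Biopython global pairwise alignment, match +2,
  mismatch −3, gap open −5, gap extend −2; the first optimal alignment
  is taken, making event coordinates deterministic. Clones under 70%
  identity are excluded with a warning. `intact` means no event
  overlaps the target interval; the frame call uses the net indel over
  the whole amplicon (0 → intact frame, ≡0 mod 3 → in-frame,
  else frameshift), so a substitution-only clone is "not intact,
  frame-preserving".
* **Line status** reports distinct observed alleles only; clone
  sampling cannot resolve whether two homologous chromosomes carry the
  same mutation, so copy numbers are never claimed.

## Known limitations

* Breakpoints are resolved only to ±k; split-read or assembly methods
  would be needed for base-pair precision (out of scope).
* The G-test's χ²(1) calibration needs moderate per-position hit
  totals (≈10+); at very low depth the test becomes conservative.
* Vector regions shared with the host genome (homology tracts) are
  fundamentally undetectable by any read-vs-vector comparison; the
  verdict therefore concerns vector-unique sequence.
* The in-silico PCR has no thermodynamic model; a "band" is a match
  pattern, not a predicted yield.
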