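# Methods

## The construction

The system couples a mathematical layer (a chaotic-keystream one-time pad
with permutation diffusion) to a molecular layer (encoding-rule selection, a
protein-alphabet parameter cipher, and a simulated synthesis/sequencing
channel).  Security rests on the secrecy of the session parameters, not on
any biochemical realism: the "central dogma" steps are deterministic
character maps chosen to mimic transcription (T→U), reverse transcription
(U→T) and base pairing (A↔U, C↔G position-wise, no strand reversal).

### Keystream

Bits come from two logistic orbits x_{i+1} = μ·x·(1−x) thresholded at 0.5
(the lower interval closed: f(0.5) = 0) and XORed.  Choices that matter:

* **μ ∈ [3.569946, 4], x₀ ∈ (0, 1)** — enforced at construction.  Inside
  this window the map is predominantly chaotic but contains periodic
  windows; the package treats the whole stated interval as valid.
* **burn_in = 1000 iterates (default)** — the transient is discarded before
  bits are emitted.  Nothing in the construction pins this; it is exposed so
  burn_in = 0 reproduces a strict no-transient reading.  Encryption and
  decryption must agree on it; it is stored in the session file.
* **Determinism** — the literal IEEE-754 double expression `mu*x*(1.0-x)`
  is used in both the pure-Python and the numba-accelerated loop, so
  streams are bit-identical across paths and platforms.  A test asserts the
  two paths agree.
* **Degeneracy** — an orbit that lands exactly on 0 or 1 (e.g. μ=4,
  x₀=0.5) is permanently stuck; this raises an error naming the iterate
  rather than silently emitting constant bits.
* The 0.001-increment parameter schedule (μ_j = μ₁ + 0.001(j−1), g_j
  iterated under μ₁) is provided as a derivation utility but does not feed
  the default keystream, which iterates the two initial pairs directly; the
  construction's wiring of the schedule into key generation is ambiguous in
  its source description, and the direct path is the simpler consistent
  reading.

### Parameter cipher

Parameters travel as decimal *texts* ("3.78" stays "3.78"), because the
ASCII serialization is part of the cipher: re-formatting floats would
change the ciphertext.  The midpoint cut of the DNA sequence gives the
first half the extra residue when the length is odd (ASCII input always
produces equal halves).  Coordinates are 4-bit nibbles, so each ASCII byte
contributes exactly two; the tRNA-derived sequence supplies row
coordinates M and the rRNA-derived sequence column coordinates N.

The digram table scrambles by moving the content of cell (x, y) to
(x′, y′) per Arnold step; equivalently, the table at iteration pk read at
(M, N) equals the initial table at the pk-fold *inverse* image of (M, N)
— for pk = 1, initial[2M−N mod 16][N−M mod 16].  This orientation is the
unique convention reproducing all 22 digrams of the packaged
walk-through, and it is pinned by test (including a step-by-step vs
closed-form equivalence over all pk).  The period of the 16×16 grid (12)
is computed by brute force, never assumed, and pk is validated against it.

**Chaff.** The number of inserted T/V/W/Y letters defaults to
round(0.25 × core length), the approximate density of the reference
ciphertexts; positions are uniform without replacement, letters uniform
over the four.  Decryption strips all four letters unconditionally, so it
is provably independent of the chaff seed, count and positions (tested
across seeds).  Exact-seed reproduction of any particular published
chaffed string is not claimed — the insertion positions are not specified
by the construction.

**Tamper behaviour.** Every two-letter combination over the 16-letter grid
alphabet is a valid digram, so a corrupted core never fails at table
lookup; it fails at ASCII/parse validation or decodes to a *different*
valid parameter set.  The guaranteed property — asserted by an exhaustive
single-letter corruption scan — is that corruption never silently returns
the original parameters.  Wrong-Pk decryption likewise either errors or
yields parameters different from the truth.

### Data cipher

* **Padding then XOR.**  Plaintext bits are zero-padded to a whole number
  of 2¹⁸-bit blocks *before* the XOR, and the keystream covers the padded
  length.  The padding region is therefore encrypted too: the ciphertext
  is uniformly pseudorandom end to end (this is what makes the ≥7.9-bit
  ciphertext-entropy property hold), and decryption truncates to the
  recorded plaintext bit length after the inverse XOR.  The recorded
  length lives in the session file, never in the ciphertext.
* **Arnold scrambling of blocks** uses m = n = 1 and t = 1 iteration by
  default (configurable, stored in the session); the construction fixes
  the use of the map but not (m, n, t) at the 512×512 stage.  Bit k of a
  block maps to row ⌊k/512⌋, column k mod 512 — the same (row, column) =
  (x, y) convention as the confusion table, and a cross-module test checks
  the two implementations agree cell-for-cell at N = 16.
* XOR + permutation is *confusion without diffusion amplification*: one
  flipped plaintext bit flips exactly one pre-DNA ciphertext bit,
  relocated by the permutation.  Consequently NPCR between ciphertexts of
  one-pixel-different images is necessarily tiny under this construction;
  the NPCR/UACI metrics are provided, but no high-NPCR claim is made or
  tested.

### DNA library channel

Record layout: adapter(15) + index(5) + payload(160) + index(5) +
adapter(15) = 200 nt, adapter outermost (it models the sequencing-primer
binding site), index inside.  Fragment order is restored via a secret
*ordered* index list shared in the session file — record k carries indexes
i₂ₖ₋₁, i₂ₖ — since no in-band order encoding is part of the construction.

**Index capacity.**  With 5-nt indexes only 4⁵ = 1024 distinct values
exist, but one padded block already needs 820 fragments (1640 indexes), so
globally unique barcodes cannot address even a minimal message.  The
package therefore guarantees distinct ordered (left, right) index *pairs*
(4¹⁰ ≈ 1.05M addressable fragments) and additionally draws globally
distinct indexes whenever 2n ≤ 1024.  `strict_unique=True` restores the
hard 512-fragment bound for users who need physically unique barcodes.
Splicing is pair-based either way, deduplicates identical reads, ignores
records whose flanks don't match the adapter exactly (decoy tolerance),
and reports missing ordinals explicitly.

The channel is noiseless by design: no sequencing-error model, PCR bias,
consensus calling, or synthesis constraints (GC content, homopolymers).
A real DNA channel would need error correction layered on top; passing
round trips here show only logical invertibility of the scheme.

### Metrics

* Histogram variance is the double-sum form over n bins (n = 256 for gray
  images — the bin count is the natural reading of the formula's n); it
  algebraically equals the population variance of the counts, which tests
  use as an independent oracle.
* Key space is computed exactly (Fraction arithmetic, sympy
  factorization).  The published component values are kept literally: the
  μ component is 0.5×10¹⁶ (not the 0.43×10¹⁶ the μ-range would imply) and
  the table component is 256¹² even though Pk has only 13 attainable
  values — the product is a property of the scheme as stated, and the
  discrepancy is surfaced here rather than silently corrected.

## Synthetic data

`fixtures.random_text` draws uniform printable ASCII; `fixtures.gray_image`
produces uniform-random or gradient 8-bit images.  These emulate the
*statistics* the metrics need (arbitrary byte plaintexts; images with
non-flat histograms) but none of the structure of real documents or
photographs; passing tests demonstrate invertibility and ciphertext
uniformity, not performance on natural data.  The packaged walk-through
fixture carries the reference parameter-cipher intermediates verbatim for
character-exact comparison.

## Problem sizes and tolerances

The round-trip property suite runs 1000 fully random sessions with
plaintext lengths drawn log-uniformly up to ~2000 characters plus fixed
sizes of 10⁴, 5×10⁴ and 10⁵ characters, duplicated mixtures every tenth
session — sizes chosen to cover 1–4 cipher blocks and multi-thousand-record
libraries while keeping the suite fast.  Statistical bands (keystream
ones-fraction in [0.45, 0.55] at n = 10⁵; ciphertext entropy ≥ 7.9 bits on
a 160×160 random image) are loose relative to the asymptotic expectations
(0.5 ± 0.003 and ≈7.994 bits respectively) and are not tuned quantities.
Floating-point comparisons in tests use explicit absolute/relative
tolerances; all integer/string reproductions are exact.

## Known limitations

* The keystream is a chaotic PRNG, not a vetted CSPRNG, and no randomness
  certification (e.g. NIST STS) is attempted — the package reproduces the
  construction, it does not endorse its cryptographic strength.
* Threshold bits of a logistic orbit are biased (the invariant density of
  the map is not symmetric about 0.5 for μ < 4); the XOR of two orbits
  reduces but does not eliminate this.
* No authentication/integrity: a tampered mixture or parameter ciphertext
  can decode to wrong plaintext without detection beyond parse failures.
* `a = 2` encodings only; codon (triplet) schemes are out of scope.
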