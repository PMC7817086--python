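# dnaotp

A one-time-pad cipher system built on DNA data-storage primitives, for
researchers studying molecular cryptography and DNA information channels.
The package implements, end to end and exactly invertibly:

* **Chaotic keystream generation** — two logistic-map orbits
  x<sub>i+1</sub> = μx<sub>i</sub>(1−x<sub>i</sub>), μ ∈ [3.569946, 4],
  thresholded at 0.5 and XORed into the pad bits
  K<sub>i</sub> = f(x<sub>i</sub>) ⊕ f(x′<sub>i</sub>).
* **Binary↔nucleotide encoding** — the 24 bijections between
  {A, T/U, C, G} and the four 2-bit values, selected by secret rule ids
  key₀/key₁/key₂.
* **A parameter cipher simulating the central dogma** — the data-cipher
  secrets (key₀, μ₀, g₀, μ₁, g₁) are serialized to ASCII, encoded as DNA,
  split into a transcribed/complemented tRNA half and a transcribed rRNA
  half, re-binarized, folded into 4-bit coordinates (Mᵢ, Nᵢ), substituted
  through a 16×16 amino-acid digram table scrambled Pk Arnold-map steps,
  and salted with removable chaff letters T/V/W/Y — yielding protein-alphabet
  ciphertexts C₀ (security parameters) and C₁ (the confounding parameters
  key₁, key₂, Pk, via the unscrambled table).
* **A block data cipher** — plaintext bits XORed with the pad, partitioned
  into 2¹⁸-bit blocks viewed as 512×512 binary matrices, bit-scrambled by
  the Arnold map (x′ = x+my, y′ = nx+(mn+1)y mod N), and emitted as DNA at
  2 bits/nt under rule key₀.
* **An in-silico DNA library channel** — the DNA ciphertext is cut into
  160-nt payloads, flanked by 20-nt reassembly regions (15-nt shared
  adapter + 5-nt index) into 200-nt sequencing structures, shuffled and
  duplicated into an anonymized multi-FASTA "mixture"; splicing filters by
  adapter, orders by the secret index list, and reassembles exactly.
* **Cipher-quality metrics** — histogram variance, Shannon entropy,
  NPCR/UACI, and the exact key-space product
  24³ · (0.5·10¹⁶)² · (10¹⁶)² · 256¹² · 4⁴⁰ = 3³·5⁶⁴·2²⁴⁷ ≈ 3.31×10¹²⁰.

## Worked example

```python
from dnaotp import params

tr = params.security_confusion_trace("12,3.78,0.51,3.92,0.44", key1=4, key2=7, pk=1)
print(tr.dna[:16])              # ACAGACATATCAACAC   (ASCII bits -> DNA under rule 4)
print(tr.trna[:16])             # UGUCUGUAUAGUUGUG   (first half -> mRNA -> tRNA)
print(" ".join(tr.digrams[:5])) # AD FQ NR IH MQ     (coordinate pairs -> digram table, Pk=1)
```

The full pipeline, with the shuffled FASTA channel (from
`examples/03_data_roundtrip.py`):

```
C1 (confounding,   15 aa)  : DDRDTDTNGMYNDMN
mixture: 820 sequencing structures of 200 nt each
round trip exact: True
```

`C1` decrypts first (chaff stripped, initial digram table) to recover
key₁/key₂/Pk, which unlock `C0`; the mixture is spliced by adapter+index
into the DNA ciphertext; the regenerated keystream and inverse Arnold
scrambling recover the plaintext exactly.  Every plaintext produces at
least one padded 2¹⁸-bit block, hence the 820 × 200-nt structures even for
a one-line message.

More narrative walk-throughs live in `examples/` (keystream sensitivity,
the parameter cipher stage by stage, image-cipher metrics).  A thin CLI
(`dnaotp init-session / encrypt / decrypt / encrypt-params / decrypt-params /
synthesize / splice / metrics / fixtures`) wraps the same library calls.

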