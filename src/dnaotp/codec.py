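"""Binary <-> nucleotide encoding rules and central-dogma sequence transforms.

With 2-bit groups there are 4! = 24 bijections between {A, T/U, C, G} and
{00, 01, 10, 11}.  The 24 numbered rules are embedded as literal data in the
published column order (a startup self-check asserts each column is a
bijection and that the 24 exhaust all bijections).  Rule ids act as the
encoding-mapping secrets key0/key1/key2 elsewhere in the package.

ASCII serialization is most-significant-bit-first: '1' -> 00110001.

The "central dogma" transforms are position-wise character maps only:
transcription T->U, reverse transcription U->T, and the RNA complement
A<->U / C<->G (no strand reversal) used to model the mRNA->tRNA step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlphabetError, ParameterError

# Table of the 24 encoding rules: (A, T/U, C, G) 2-bit codes per column.
_RULE_COLUMNS: tuple[tuple[str, str, str, str], ...] = (
    ("00", "01", "10", "11"),  # 1
    ("00", "01", "11", "10"),  # 2
    ("00", "10", "01", "11"),  # 3
    ("00", "10", "11", "01"),  # 4
    ("00", "11", "01", "10"),  # 5
    ("00", "11", "10", "01"),  # 6
    ("01", "00", "10", "11"),  # 7
    ("01", "00", "11", "10"),  # 8
    ("01", "10", "00", "11"),  # 9
    ("01", "10", "11", "00"),  # 10
    ("01", "11", "00", "10"),  # 11
    ("01", "11", "10", "00"),  # 12
    ("10", "00", "01", "11"),  # 13
    ("10", "00", "11", "01"),  # 14
    ("10", "01", "00", "11"),  # 15
    ("10", "01", "11", "00"),  # 16
    ("10", "11", "00", "01"),  # 17
    ("10", "11", "01", "00"),  # 18
    ("11", "00", "01", "10"),  # 19
    ("11", "00", "10", "01"),  # 20
    ("11", "01", "00", "10"),  # 21
    ("11", "01", "10", "00"),  # 22
    ("11", "10", "00", "01"),  # 23
    ("11", "10", "01", "00"),  # 24
)

_BASES = ("A", "T", "C", "G")
DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class EncodingRule:
    """One of the 24 bijections between bases and 2-bit values.

    ``mapping`` is keyed by DNA bases (T stands for T/U); RNA sequences are
    handled by treating U as T.
    """

    id: int
    mapping: dict[str, str]

    def encode(self, base: str) -> str:
        return self.mapping[base]

    @property
    def inverse(self) -> dict[str, str]:
        return {v: k for k, v in self.mapping.items()}


def _build_rules() -> tuple[EncodingRule, ...]:
    rules = tuple(
        EncodingRule(i + 1, dict(zip(_BASES, col)))
        for i, col in enumerate(_RULE_COLUMNS)
    )
    # Self-check: each column a bijection, all 24 pairwise distinct, space exhausted.
    seen = set()
    for r in rules:
        codes = tuple(r.mapping[b] for b in _BASES)
        if sorted(codes) != ["00", "01", "10", "11"]:
            raise AssertionError(f"rule {r.id} is not a bijection: {codes}")
        seen.add(codes)
    if len(seen) != 24:
        raise AssertionError("the 24 rules do not exhaust all base/2-bit bijections")
    return rules


_RULES = _build_rules()


def rule(rule_id: int) -> EncodingRule:
    """Return encoding rule ``rule_id`` (1..24) in published column order."""
    if not isinstance(rule_id, (int, np.integer)) or not (1 <= rule_id <= 24):
        raise ParameterError(f"encoding rule id must be in [1, 24], got {rule_id!r}")
    return _RULES[int(rule_id) - 1]


def all_rules() -> tuple[EncodingRule, ...]:
    return _RULES


# ---------------------------------------------------------------------------
# bit-string <-> sequence


def _check_bits(bits: str) -> None:
    if bits.strip("01"):
        raise ParameterError("bit strings may contain only '0' and '1'")


def bits_to_seq(bits: str, r: EncodingRule, alphabet: str = "DNA") -> str:
    """Map consecutive bit pairs to residues; DNA emits T, RNA emits U."""
    _check_bits(bits)
    if len(bits) % 2:
        raise ParameterError(f"bit count must be even, got {len(bits)}")
    if alphabet not in ("DNA", "RNA"):
        raise ParameterError(f"alphabet must be 'DNA' or 'RNA', got {alphabet!r}")
    inv = r.inverse
    seq = "".join(inv[bits[i : i + 2]] for i in range(0, len(bits), 2))
    return seq.replace("T", "U") if alphabet == "RNA" else seq


def seq_to_bits(seq: str, r: EncodingRule) -> str:
    """Exact inverse of bits_to_seq under the same rule; U is read as T/U."""
    out = []
    for ch in seq:
        base = "T" if ch == "U" else ch
        if base not in r.mapping:
            raise AlphabetError(f"residue {ch!r} not in the nucleic alphabet")
        out.append(r.mapping[base])
    return "".join(out)


# ---------------------------------------------------------------------------
# central-dogma transforms (position-wise, no reversal)

_RNA_COMPLEMENT = str.maketrans("AUCG", "UAGC")


def _require_alphabet(seq: str, alphabet: frozenset, kind: str) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise AlphabetError(f"{kind} sequence contains invalid residues {sorted(bad)}")


def transcribe(dna: str) -> str:
    """DNA -> mRNA: replace T with U."""
    _require_alphabet(dna, DNA_ALPHABET, "DNA")
    return dna.replace("T", "U")


def reverse_transcribe(rna: str) -> str:
    """RNA -> DNA: replace U with T."""
    _require_alphabet(rna, RNA_ALPHABET, "RNA")
    return rna.replace("U", "T")


def rna_complement(rna: str) -> str:
    """Position-wise A<->U, C<->G swap (models the mRNA -> tRNA pairing)."""
    _require_alphabet(rna, RNA_ALPHABET, "RNA")
    return rna.translate(_RNA_COMPLEMENT)


# ---------------------------------------------------------------------------
# ASCII <-> bits

def text_to_bits(text: str) -> str:
    """Each character becomes its 8-bit ASCII code, most significant bit first."""
    try:
        data = text.encode("ascii")
    except UnicodeEncodeError as exc:
        raise ParameterError(f"text is not pure ASCII: {exc}") from None
    return "".join(f"{byte:08b}" for byte in data)


def bits_to_text(bits: str) -> str:
    _check_bits(bits)
    if len(bits) % 8:
        raise ParameterError(f"bit length must be divisible by 8, got {len(bits)}")
    codes = [int(bits[i : i + 8], 2) for i in range(0, len(bits), 8)]
    if any(c > 127 for c in codes):
        raise ParameterError("byte value above 127 is not ASCII")
    return bytes(codes).decode("ascii")


# ---------------------------------------------------------------------------
# array helpers for the bulk data path (datacipher / library)


def bitstring_to_array(bits: str) -> np.ndarray:
    _check_bits(bits)
    return np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")


def array_to_bitstring(arr: np.ndarray) -> str:
    return (np.asarray(arr, dtype=np.uint8) + ord("0")).tobytes().decode("ascii")


def bytes_to_bits(data: bytes) -> np.ndarray:
    """MSB-first bit array of a byte string."""
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bits_to_bytes(bits: np.ndarray) -> bytes:
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.size % 8:
        raise ParameterError(f"bit length must be divisible by 8, got {arr.size}")
    return np.packbits(arr).tobytes()


def bits_array_to_seq(bits: np.ndarray, r: EncodingRule) -> str:
    """Vectorized bits -> DNA for block-scale data (2 bits per nucleotide)."""
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.size % 2:
        raise ParameterError(f"bit count must be even, got {arr.size}")
    values = (arr[0::2] << 1) | arr[1::2]
    inv = r.inverse
    codes = np.zeros(4, dtype=np.uint8)
    for v in range(4):
        codes[v] = ord(inv[f"{v:02b}"])
    return codes[values].tobytes().decode("ascii")


def seq_to_bits_array(seq: str, r: EncodingRule) -> np.ndarray:
    """Vectorized DNA -> bits, inverse of bits_array_to_seq."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for base, code in r.mapping.items():
        lut[ord(base)] = int(code, 2)
        if base == "T":
            lut[ord("U")] = int(code, 2)
    values = lut[raw]
    if values.size and values.max() == 255:
        bad = chr(int(raw[int(np.argmax(values == 255))]))
        raise AlphabetError(f"residue {bad!r} not in the nucleic alphabet")
    bits = np.empty(values.size * 2, dtype=np.uint8)
    bits[0::2] = values >> 1
    bits[1::2] = values & 1
    return bits


# ---------------------------------------------------------------------------
# single-record FASTA convenience


def seq_to_fasta(seq: str, name: str = "seq") -> str:
    lines = [f">{name}"] + [seq[i : i + 70] for i in range(0, len(seq), 70)]
    return "\n".join(lines) + "\n"


def fasta_to_seq(text: str) -> str:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise ParameterError("not a FASTA record")
    return "".join(lines[1:])
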