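"""Encryption of the session parameters as amino-acid ciphertexts.

Two texts travel out-of-band as protein-alphabet strings:

* C0 — the *security* parameters (key0, mu0, g0, mu1, g1) that drive the
  data cipher, confused under the *confounding* parameters (key1, key2, Pk)
  by a simulated DNA -> mRNA -> tRNA / rRNA flow followed by a digram-table
  substitution.
* C1 — the confounding parameters themselves, protected only by the initial
  (Pk = 0) digram table and chaff letters.

Parameters travel as decimal *texts* (never re-formatted floats) so the
ASCII serialization is exactly reproducible: "3.78" stays "3.78".

The chaff step inserts the four non-grid amino-acid letters T, V, W, Y at
random positions; because they never occur in the digram alphabet, stripping
them at decryption is unambiguous and the decryption result is independent
of the insertion seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chaos import CHAOTIC_MU_MIN, CHAOTIC_MU_MAX
from .codec import (
    bits_to_seq,
    bits_to_text,
    rna_complement,
    reverse_transcribe,
    rule,
    seq_to_bits,
    text_to_bits,
    transcribe,
)
from .confusion import REDUNDANT_LETTERS, TABLE_LETTERS, build_table, table_period
from .errors import CorruptionError, PairingError, ParameterError

#: Default chaff density: insertions = round(0.25 * core length), matching the
#: published example's 12 insertions into 44 letters and 3 into 10 (~27%).
REDUNDANCY_FRACTION = 0.25


def _parse_rule_id(text: str, name: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise CorruptionError(f"{name} is not an integer: {text!r}") from None
    if not (1 <= value <= 24):
        raise CorruptionError(f"{name}={value} outside [1, 24]")
    return value


@dataclass(frozen=True)
class SecurityParams:
    """key0 plus the two logistic parameter pairs, values kept as typed texts."""

    key0: int
    mu0: str
    g0: str
    mu1: str
    g1: str

    def __post_init__(self):
        if not (1 <= self.key0 <= 24):
            raise ParameterError(f"key0={self.key0} outside [1, 24]")
        for name in ("mu0", "mu1"):
            v = float(getattr(self, name))
            if not (CHAOTIC_MU_MIN <= v <= CHAOTIC_MU_MAX):
                raise ParameterError(f"{name}={v} outside [{CHAOTIC_MU_MIN}, {CHAOTIC_MU_MAX}]")
        for name in ("g0", "g1"):
            v = float(getattr(self, name))
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name}={v} outside (0, 1)")

    def serialize(self) -> str:
        return serialize_params([str(self.key0), self.mu0, self.g0, self.mu1, self.g1])

    @classmethod
    def parse(cls, text: str) -> "SecurityParams":
        fields = text.split(",")
        if len(fields) != 5:
            raise CorruptionError(f"expected 5 security fields, got {len(fields)}: {text!r}")
        key0 = _parse_rule_id(fields[0], "key0")
        try:
            return cls(key0, *fields[1:])
        except (ParameterError, ValueError) as exc:
            raise CorruptionError(f"security parameter text invalid: {exc}") from None


@dataclass(frozen=True)
class ConfoundingParams:
    """Rule selectors for the confusion path plus the table iteration count."""

    key1: int
    key2: int
    pk: int

    def __post_init__(self):
        for name in ("key1", "key2"):
            v = getattr(self, name)
            if not (1 <= v <= 24):
                raise ParameterError(f"{name}={v} outside [1, 24]")
        if not (0 <= self.pk <= table_period()):
            raise ParameterError(f"pk={self.pk} outside [0, {table_period()}]")

    def serialize(self) -> str:
        return serialize_params([str(self.key1), str(self.key2), str(self.pk)])

    @classmethod
    def parse(cls, text: str) -> "ConfoundingParams":
        fields = text.split(",")
        if len(fields) != 3:
            raise CorruptionError(f"expected 3 confounding fields, got {len(fields)}: {text!r}")
        key1 = _parse_rule_id(fields[0], "key1")
        key2 = _parse_rule_id(fields[1], "key2")
        try:
            pk = int(fields[2])
        except ValueError:
            raise CorruptionError(f"pk is not an integer: {fields[2]!r}") from None
        if not (0 <= pk <= table_period()):
            raise CorruptionError(f"pk={pk} outside [0, {table_period()}]")
        return cls(key1, key2, pk)


def serialize_params(values) -> str:
    """Comma-join decimal texts with no spaces; inverse is a plain split."""
    values = list(values)
    if not values:
        raise ParameterError("cannot serialize an empty parameter list")
    return ",".join(str(v) for v in values)


def parse_params(text: str) -> list[str]:
    return text.split(",")


# ---------------------------------------------------------------------------
# forward traces


def _bits_to_nibbles(bits: str) -> list[int]:
    if len(bits) % 4:
        raise PairingError(f"bit length {len(bits)} not divisible by 4")
    return [int(bits[i : i + 4], 2) for i in range(0, len(bits), 4)]


def _nibbles_to_bits(values) -> str:
    out = []
    for v in values:
        if not (0 <= v <= 15):
            raise CorruptionError(f"coordinate {v} outside [0, 15]")
        out.append(f"{v:04b}")
    return "".join(out)


@dataclass(frozen=True)
class SecurityTrace:
    """Every intermediate of the security-parameter confusion, for inspection."""

    text: str
    bits: str
    dna: str
    dna_first_half: str
    dna_second_half: str
    mrna: str
    trna: str
    rrna: str
    trna_bits: str
    rrna_bits: str
    m_values: tuple[int, ...]
    n_values: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    digrams: tuple[str, ...]
    core: str


def security_confusion_trace(text: str, key1: int, key2: int, pk: int) -> SecurityTrace:
    """Run the DNA->RNA->protein confusion on a parameter text, keeping all steps.

    Pipeline: ASCII -> bits; bits -> DNA under key1; midpoint cut (first half
    takes any extra residue); first half -> mRNA (T->U) -> tRNA (A<->U, C<->G),
    second half -> rRNA (T->U); both -> bits under key2; 4-bit nibbles ->
    decimal coordinates; tRNA-derived M paired position-wise with
    rRNA-derived N; digram lookup in the Pk-scrambled table.
    """
    r1, r2 = rule(key1), rule(key2)
    bits = text_to_bits(text)
    dna = bits_to_seq(bits, r1, "DNA")
    cut = (len(dna) + 1) // 2
    first, second = dna[:cut], dna[cut:]
    mrna = transcribe(first)
    trna = rna_complement(mrna)
    rrna = transcribe(second)
    trna_bits = seq_to_bits(trna, r2)
    rrna_bits = seq_to_bits(rrna, r2)
    m_values = tuple(_bits_to_nibbles(trna_bits))
    n_values = tuple(_bits_to_nibbles(rrna_bits))
    if len(m_values) != len(n_values):
        raise PairingError(
            f"coordinate halves differ in length: {len(m_values)} vs {len(n_values)}"
        )
    pairs = tuple(zip(m_values, n_values))
    table = build_table(pk)
    digrams = tuple(table.lookup(M, N) for M, N in pairs)
    return SecurityTrace(
        text=text,
        bits=bits,
        dna=dna,
        dna_first_half=first,
        dna_second_half=second,
        mrna=mrna,
        trna=trna,
        rrna=rrna,
        trna_bits=trna_bits,
        rrna_bits=rrna_bits,
        m_values=m_values,
        n_values=n_values,
        pairs=pairs,
        digrams=digrams,
        core="".join(digrams),
    )


@dataclass(frozen=True)
class ConfoundingTrace:
    """Every intermediate of the confounding-parameter encryption."""

    text: str
    bits: str
    decimals: tuple[int, ...]
    m_values: tuple[int, ...]
    n_values: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    digrams: tuple[str, ...]
    core: str


def confounding_encryption_trace(text: str) -> ConfoundingTrace:
    """ASCII -> bits -> nibbles; first half = M, second half = N; Pk=0 table."""
    bits = text_to_bits(text)
    decimals = tuple(_bits_to_nibbles(bits))
    if len(decimals) % 2:
        raise PairingError(f"odd decimal count {len(decimals)} cannot be halved")
    half = len(decimals) // 2
    m_values, n_values = decimals[:half], decimals[half:]
    pairs = tuple(zip(m_values, n_values))
    table = build_table(0)
    digrams = tuple(table.lookup(M, N) for M, N in pairs)
    return ConfoundingTrace(
        text=text,
        bits=bits,
        decimals=decimals,
        m_values=m_values,
        n_values=n_values,
        pairs=pairs,
        digrams=digrams,
        core="".join(digrams),
    )


# ---------------------------------------------------------------------------
# chaff insertion / removal


def insert_redundant(core: str, rng: np.random.Generator, count: int | None = None) -> str:
    """Insert chaff letters from {T, V, W, Y} at rng-chosen positions.

    ``count`` defaults to round(0.25 * len(core)).  Positions are drawn
    uniformly without replacement over the expanded string; letters uniformly
    over the four chaff letters.  Decryption never depends on any of this.
    """
    if count is None:
        count = round(REDUNDANCY_FRACTION * len(core))
    if count < 0:
        raise ParameterError("chaff count must be non-negative")
    total = len(core) + count
    slots = rng.choice(total, size=count, replace=False) if count else np.array([], dtype=int)
    chaff_at = set(int(s) for s in slots)
    letters = rng.choice(list(REDUNDANT_LETTERS), size=count) if count else []
    out, it = [], iter(letters)
    core_iter = iter(core)
    for pos in range(total):
        out.append(next(it) if pos in chaff_at else next(core_iter))
    return "".join(out)


def strip_redundant(ciphertext: str) -> str:
    """Remove every T, V, W, Y; the residual digram text must be even-length."""
    bad = set(ciphertext) - set(TABLE_LETTERS) - set(REDUNDANT_LETTERS)
    if bad:
        raise CorruptionError(f"non-amino-acid letters present: {sorted(bad)}")
    core = "".join(ch for ch in ciphertext if ch not in REDUNDANT_LETTERS)
    if len(core) % 2:
        raise CorruptionError(f"stripped core has odd length {len(core)}")
    return core


# ---------------------------------------------------------------------------
# public encrypt / decrypt


def confuse_security(
    sp: SecurityParams,
    cp: ConfoundingParams,
    rng: np.random.Generator,
    chaff_count: int | None = None,
) -> str:
    """Produce the amino-acid ciphertext C0 for the security parameters."""
    trace = security_confusion_trace(sp.serialize(), cp.key1, cp.key2, cp.pk)
    return insert_redundant(trace.core, rng, chaff_count)


def encrypt_confounding(
    cp: ConfoundingParams,
    rng: np.random.Generator,
    chaff_count: int | None = None,
) -> str:
    """Produce the amino-acid ciphertext C1 for the confounding parameters."""
    trace = confounding_encryption_trace(cp.serialize())
    return insert_redundant(trace.core, rng, chaff_count)


def decrypt_confounding(c1: str) -> ConfoundingParams:
    """Invert C1: strip chaff, unlookup on the initial table, nibbles -> text."""
    core = strip_redundant(c1)
    table = build_table(0)
    pairs = [table.unlookup(core[i : i + 2]) for i in range(0, len(core), 2)]
    decimals = [M for M, _ in pairs] + [N for _, N in pairs]
    text = _safe_bits_to_text(_nibbles_to_bits(decimals))
    return ConfoundingParams.parse(text)


def decrypt_security(c0: str, cp: ConfoundingParams) -> SecurityParams:
    """Invert C0 given recovered confounding parameters."""
    core = strip_redundant(c0)
    table = build_table(cp.pk)
    pairs = [table.unlookup(core[i : i + 2]) for i in range(0, len(core), 2)]
    m_values = [M for M, _ in pairs]
    n_values = [N for _, N in pairs]
    r2 = rule(cp.key2)
    trna = bits_to_seq(_nibbles_to_bits(m_values), r2, "RNA")
    rrna = bits_to_seq(_nibbles_to_bits(n_values), r2, "RNA")
    mrna = rna_complement(trna)
    dna = reverse_transcribe(mrna) + reverse_transcribe(rrna)
    bits = seq_to_bits(dna, rule(cp.key1))
    text = _safe_bits_to_text(bits)
    return SecurityParams.parse(text)


def _safe_bits_to_text(bits: str) -> str:
    try:
        return bits_to_text(bits)
    except ParameterError as exc:
        raise CorruptionError(f"recovered bits are not ASCII: {exc}") from None
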