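"""In-silico DNA library construction and sequencing/splicing channel.

The DNA ciphertext is cut into 160-nt payloads; each payload is flanked by
two 20-nt reassembly regions (a shared 15-nt adapter outermost, a 5-nt index
inside), giving 200-nt sequencing structures:

    adapter(15) + index(5) + payload(<=160) + index(5) + adapter(15)

The "mixture" a receiver obtains is a shuffled, possibly duplicated,
anonymously-headered multi-FASTA of those structures.  Splicing filters on
exact adapter flanks, extracts the two indexes, deduplicates, orders
payloads by the secret ordered index list (record k carries indexes
i_{2k-1}, i_{2k}), strips the final payload pad, and concatenates.

Index capacity: all ordered (left, right) index *pairs* are kept distinct,
addressing up to 4^10 fragments; indexes are additionally globally distinct
whenever 2n <= 4^5 = 1024.  ``strict_unique=True`` enforces global
distinctness only, capping the library at 512 fragments.  Synthesis and
sequencing are simulated noiselessly; adapter matching is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CapacityError,
    EmptyMixtureError,
    ParameterError,
    ReconstructionError,
)

ADAPTER_LEN = 15
INDEX_LEN = 5
PAYLOAD_LEN = 160
RECORD_LEN = ADAPTER_LEN + INDEX_LEN + PAYLOAD_LEN + INDEX_LEN + ADAPTER_LEN

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_INDEX_SPACE = 4**INDEX_LEN  # 1024 distinct 5-mers
_PAIR_SPACE = 4 ** (2 * INDEX_LEN)  # ~1.05M distinct ordered pairs


def _int_to_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[value % 4])
        value //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class ChannelSecret:
    """Adapter, ordered index list (i_1..i_2n), and final-payload pad length."""

    adapter: str
    index_list: tuple[str, ...]
    payload_pad: int = 0

    def __post_init__(self):
        if len(self.adapter) != ADAPTER_LEN or set(self.adapter) - set("ACGT"):
            raise ParameterError(f"adapter must be {ADAPTER_LEN} nt of ACGT")
        if len(self.index_list) % 2:
            raise ParameterError("index list must pair up: even length required")
        for idx in self.index_list:
            if len(idx) != INDEX_LEN or set(idx) - set("ACGT"):
                raise ParameterError(f"index {idx!r} must be {INDEX_LEN} nt of ACGT")
        pairs = set(zip(self.index_list[0::2], self.index_list[1::2]))
        if len(pairs) != len(self.index_list) // 2:
            raise ParameterError("index pairs must be pairwise distinct")
        if not (0 <= self.payload_pad < PAYLOAD_LEN):
            raise ParameterError(f"payload_pad={self.payload_pad} outside [0, {PAYLOAD_LEN})")

    @property
    def n_fragments(self) -> int:
        return len(self.index_list) // 2


@dataclass(frozen=True)
class LibraryRecord:
    """One 200-nt sequencing structure; the ordinal is secret, never serialized."""

    adapter: str
    left_index: str
    payload: str
    right_index: str
    ordinal: int

    def sequence(self) -> str:
        return (
            self.adapter
            + self.left_index
            + self.payload
            + self.right_index
            + self.adapter
        )


def fragment(c_dna: str, payload_len: int = PAYLOAD_LEN) -> tuple[list[str], int]:
    """Cut into consecutive payloads; pad the final one with 'A' to full length.

    Returns (payloads, pad_len).
    """
    if payload_len <= 0:
        raise ParameterError("payload length must be positive")
    if not c_dna:
        raise ParameterError("cannot fragment an empty ciphertext")
    payloads = [c_dna[i : i + payload_len] for i in range(0, len(c_dna), payload_len)]
    pad = payload_len - len(payloads[-1])
    if pad:
        payloads[-1] = payloads[-1] + "A" * pad
    return payloads, pad


def make_secret(
    n_fragments: int,
    rng: np.random.Generator,
    payload_pad: int = 0,
    strict_unique: bool = False,
) -> ChannelSecret:
    """Draw a random adapter and an ordered list of 2n indexes.

    Ordered (left, right) index pairs are always pairwise distinct.  When
    2n <= 1024 the indexes themselves are drawn without replacement (globally
    distinct).  ``strict_unique=True`` demands global distinctness outright,
    raising CapacityError beyond 512 fragments.
    """
    if n_fragments < 1:
        raise ParameterError("need at least one fragment")
    adapter = "".join("ACGT"[b] for b in rng.integers(0, 4, size=ADAPTER_LEN))
    if strict_unique and 2 * n_fragments > _INDEX_SPACE:
        raise CapacityError(
            f"{2 * n_fragments} globally unique {INDEX_LEN}-nt indexes requested; "
            f"only {_INDEX_SPACE} exist"
        )
    if n_fragments > _PAIR_SPACE:
        raise CapacityError(
            f"{n_fragments} fragments exceed the {_PAIR_SPACE} distinct index pairs"
        )
    if 2 * n_fragments <= _INDEX_SPACE:
        draws = rng.choice(_INDEX_SPACE, size=2 * n_fragments, replace=False)
        indexes = tuple(_int_to_kmer(int(v), INDEX_LEN) for v in draws)
    else:
        pair_draws = rng.choice(_PAIR_SPACE, size=n_fragments, replace=False)
        indexes = []
        for v in pair_draws:
            indexes.append(_int_to_kmer(int(v) // _INDEX_SPACE, INDEX_LEN))
            indexes.append(_int_to_kmer(int(v) % _INDEX_SPACE, INDEX_LEN))
        indexes = tuple(indexes)
    return ChannelSecret(adapter=adapter, index_list=indexes, payload_pad=payload_pad)


def assemble_library(payloads: list[str], secret: ChannelSecret) -> list[LibraryRecord]:
    """Flank payload k with indexes i_{2k-1}, i_{2k} and the shared adapter."""
    if len(secret.index_list) < 2 * len(payloads):
        raise ParameterError(
            f"index list covers {len(secret.index_list) // 2} payloads, "
            f"got {len(payloads)}"
        )
    records = []
    for k, payload in enumerate(payloads):
        if len(payload) > PAYLOAD_LEN:
            raise ParameterError(f"payload {k} longer than {PAYLOAD_LEN} nt")
        records.append(
            LibraryRecord(
                adapter=secret.adapter,
                left_index=secret.index_list[2 * k],
                payload=payload,
                right_index=secret.index_list[2 * k + 1],
                ordinal=k,
            )
        )
    return records


def synthesize_mixture(
    records: list[LibraryRecord],
    rng: np.random.Generator,
    copies: int = 1,
) -> str:
    """Duplicate, shuffle and anonymize the library into multi-FASTA text.

    Headers are opaque serial numbers assigned *after* shuffling, so they
    carry no ordering information.
    """
    if copies < 1:
        raise ParameterError("copies must be >= 1")
    pool = [rec.sequence() for rec in records for _ in range(copies)]
    order = rng.permutation(len(pool))
    seq_records = [
        SeqRecord(Seq(pool[j]), id=f"mol{i:07d}", description="")
        for i, j in enumerate(order)
    ]
    buf = io.StringIO()
    SeqIO.write(seq_records, buf, "fasta")
    return buf.getvalue()


def sequence_and_splice(fasta, secret: ChannelSecret) -> str:
    """Demultiplex a mixture FASTA and splice the DNA ciphertext back together.

    ``fasta`` may be FASTA text, a path, or an open handle.  Records whose
    flanks do not match the adapter exactly (decoys) are ignored; duplicates
    collapse; a missing index pair raises ReconstructionError naming the
    missing ordinals.
    """
    if isinstance(fasta, str) and "\n" in fasta:
        handle = io.StringIO(fasta)
    elif hasattr(fasta, "read"):
        handle = fasta
    else:
        handle = open(fasta)
    try:
        reads = [str(rec.seq) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if handle is not fasta:
            handle.close()

    pair_to_payload: dict[tuple[str, str], str] = {}
    matched = 0
    for seq in reads:
        if len(seq) != RECORD_LEN:
            continue
        if not (seq.startswith(secret.adapter) and seq.endswith(secret.adapter)):
            continue
        matched += 1
        left = seq[ADAPTER_LEN : ADAPTER_LEN + INDEX_LEN]
        right = seq[-(ADAPTER_LEN + INDEX_LEN) : -ADAPTER_LEN]
        payload = seq[ADAPTER_LEN + INDEX_LEN : -(ADAPTER_LEN + INDEX_LEN)]
        pair_to_payload[(left, right)] = payload
    if matched == 0:
        raise EmptyMixtureError("no record in the mixture matched the adapter")

    n = secret.n_fragments
    payloads, missing = [], []
    for k in range(n):
        pair = (secret.index_list[2 * k], secret.index_list[2 * k + 1])
        if pair not in pair_to_payload:
            missing.append(k)
        else:
            payloads.append(pair_to_payload[pair])
    if missing:
        raise ReconstructionError(
            f"mixture is incomplete: missing fragment ordinals {missing}",
            missing=tuple(missing),
        )
    c_dna = "".join(payloads)
    if secret.payload_pad:
        c_dna = c_dna[: -secret.payload_pad]
    return c_dna
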