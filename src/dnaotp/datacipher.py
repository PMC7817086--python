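"""Block data cipher: one-time-pad XOR plus Arnold bit scrambling, emitted as DNA.

The plaintext's ASCII bits are zero-padded to a whole number of 2^18-bit
blocks, XORed with the keystream over the full padded length (so the padding
region is encrypted too and the ciphertext is uniformly pseudorandom), and
each block — viewed as a 512 x 512 binary matrix, row-major — is scrambled
by t forward Arnold steps.  The scrambled bits are finally mapped to
nucleotides two-bits-per-base under encoding rule key0.  Decryption inverts
each stage exactly, truncating to the recorded original bit length at the
end.

One ciphertext block is always 2^18 bits = 131072 nt, whatever the
plaintext length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import codec
from .chaos import KeyStream
from .confusion import ArnoldMap
from .errors import ParameterError

BLOCK_BITS = 2**18
BLOCK_SIDE = 512


@dataclass(frozen=True)
class DataCipherConfig:
    """Everything needed to invert the data path (bar the keystream).

    ``bit_length`` is the pre-padding plaintext bit count; it is recorded by
    ``encrypt_data`` and required by ``decrypt_data``.
    """

    key0: int
    arnold_iterations: int = 1
    arnold_m: int = 1
    arnold_n: int = 1
    bit_length: int | None = None

    def __post_init__(self):
        if not (1 <= self.key0 <= 24):
            raise ParameterError(f"key0={self.key0} outside [1, 24]")
        if self.arnold_iterations < 0:
            raise ParameterError("arnold_iterations must be >= 0")


def _key_bits(k) -> np.ndarray:
    return k.bits if isinstance(k, KeyStream) else np.asarray(k, dtype=np.uint8)


def xor_bits(data: np.ndarray, k) -> np.ndarray:
    """Position-wise XOR, truncating the keystream to the data length."""
    data = np.asarray(data, dtype=np.uint8)
    kb = _key_bits(k)
    if kb.size < data.size:
        raise ParameterError(
            f"keystream too short: {kb.size} bits for {data.size} data bits"
        )
    return np.bitwise_xor(data, kb[: data.size])


def block_partition(bits: np.ndarray) -> tuple[list[np.ndarray], int]:
    """Zero-pad to a multiple of 2^18 bits and cut into 512x512 matrices.

    Returns (blocks, pad_len).  An empty input still yields one all-zero
    block (pad_len = 2^18) so the ciphertext shape is never degenerate.
    """
    bits = np.asarray(bits, dtype=np.uint8).ravel()
    n_blocks = max(1, -(-bits.size // BLOCK_BITS))
    pad_len = n_blocks * BLOCK_BITS - bits.size
    padded = np.concatenate([bits, np.zeros(pad_len, dtype=np.uint8)])
    blocks = [
        padded[i * BLOCK_BITS : (i + 1) * BLOCK_BITS].reshape(BLOCK_SIDE, BLOCK_SIDE)
        for i in range(n_blocks)
    ]
    return blocks, pad_len


def block_join(blocks: list[np.ndarray], pad_len: int) -> np.ndarray:
    """Concatenate blocks row-major and strip exactly pad_len trailing bits."""
    if not blocks:
        raise ParameterError("no blocks to join")
    if not (0 <= pad_len <= BLOCK_BITS * len(blocks)):
        raise ParameterError(
            f"pad_len={pad_len} inconsistent with {len(blocks)} block(s)"
        )
    flat = np.concatenate([np.asarray(b, dtype=np.uint8).reshape(-1) for b in blocks])
    return flat[: flat.size - pad_len]


# ---------------------------------------------------------------------------
# Arnold scrambling of a block

_PERM_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def _permutation(side: int, t: int, m: int, n: int) -> np.ndarray:
    """Flat index permutation: destination[i] for each source cell i, t steps."""
    key = (side, t, m, n)
    if key not in _PERM_CACHE:
        a = ArnoldMap(m, n, side)
        x, y = np.meshgrid(
            np.arange(side, dtype=np.int64), np.arange(side, dtype=np.int64), indexing="ij"
        )
        x, y = x.ravel(), y.ravel()
        for _ in range(t):
            x, y = a.forward_grid(x, y)
        _PERM_CACHE[key] = x * side + y
    return _PERM_CACHE[key]


def arnold_scramble_block(
    block: np.ndarray, t: int, m: int = 1, n: int = 1
) -> np.ndarray:
    """Move the bit at (x, y) to (x', y'), t forward Arnold steps."""
    block = np.asarray(block, dtype=np.uint8)
    if block.shape != (BLOCK_SIDE, BLOCK_SIDE) and block.shape[0] != block.shape[1]:
        raise ParameterError("block must be a square matrix")
    side = block.shape[0]
    perm = _permutation(side, t, m, n)
    out = np.empty(side * side, dtype=np.uint8)
    out[perm] = block.ravel()
    return out.reshape(side, side)


def arnold_unscramble_block(
    block: np.ndarray, t: int, m: int = 1, n: int = 1
) -> np.ndarray:
    """Exact inverse of arnold_scramble_block."""
    block = np.asarray(block, dtype=np.uint8)
    side = block.shape[0]
    perm = _permutation(side, t, m, n)
    return block.ravel()[perm].reshape(side, side)


# ---------------------------------------------------------------------------
# full data path


def _to_bits(plaintext) -> np.ndarray:
    if isinstance(plaintext, str):
        try:
            plaintext = plaintext.encode("ascii")
        except UnicodeEncodeError as exc:
            raise ParameterError(f"plaintext is not pure ASCII: {exc}") from None
    return codec.bytes_to_bits(bytes(plaintext))


def encrypt_data(
    plaintext, k: KeyStream, cfg: DataCipherConfig
) -> tuple[str, DataCipherConfig]:
    """Encrypt text/bytes to a DNA ciphertext string.

    Returns (C_DNA, cfg') where cfg' carries the recorded plaintext bit
    length.  The keystream must cover the padded length
    (ceil(bits / 2^18) * 2^18, minimum one block).
    """
    bits = _to_bits(plaintext)
    blocks, pad_len = block_partition(bits)
    padded = block_join(blocks, 0)
    cipher = xor_bits(padded, k)
    cblocks, _ = block_partition(cipher)
    scrambled = [
        arnold_scramble_block(b, cfg.arnold_iterations, cfg.arnold_m, cfg.arnold_n)
        for b in cblocks
    ]
    joined = block_join(scrambled, 0)
    c_dna = codec.bits_array_to_seq(joined, codec.rule(cfg.key0))
    return c_dna, replace(cfg, bit_length=int(bits.size))


def decrypt_data_bytes(c_dna: str, k: KeyStream, cfg: DataCipherConfig) -> bytes:
    """Invert encrypt_data to raw bytes; cfg.bit_length must be set."""
    if cfg.bit_length is None:
        raise ParameterError("cfg.bit_length is required for decryption")
    bits = codec.seq_to_bits_array(c_dna, codec.rule(cfg.key0))
    if bits.size % BLOCK_BITS:
        raise ParameterError(
            f"ciphertext bit count {bits.size} is not a multiple of 2^18"
        )
    blocks, _ = block_partition(bits)
    unscrambled = [
        arnold_unscramble_block(b, cfg.arnold_iterations, cfg.arnold_m, cfg.arnold_n)
        for b in blocks
    ]
    padded = block_join(unscrambled, 0)
    plain_padded = xor_bits(padded, k)
    plain_bits = plain_padded[: cfg.bit_length]
    return codec.bits_to_bytes(plain_bits)


def decrypt_data(c_dna: str, k: KeyStream, cfg: DataCipherConfig) -> str:
    """Invert encrypt_data for ASCII plaintexts."""
    return decrypt_data_bytes(c_dna, k, cfg).decode("ascii")


def required_keystream_bits(plaintext_bits: int) -> int:
    """Padded bit count the keystream must cover for a given plaintext size."""
    return max(1, -(-plaintext_bits // BLOCK_BITS)) * BLOCK_BITS
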