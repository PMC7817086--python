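"""Cipher-quality metrics and the key-space calculator.

Implements the standard image-cipher diagnostics — histogram variance,
Shannon entropy of the 256-bin pixel histogram, NPCR (number-of-pixels
change rate) and UACI (unified average changing intensity) — plus the exact
key-space product of the scheme's secret components, and a minimal PGM
(P2/P5) reader/writer for grayscale fixtures.

Histogram variance is the double-sum form

    var(Z) = (1/n^2) * sum_i sum_j (z_i - z_j)^2 / 2

over the n histogram bins (n = 256 for gray images), which algebraically
equals the population variance of the bin counts; the double-sum form is
what is implemented, the identity is exploited only by tests as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import sympy

from .errors import ParameterError

GRAY_LEVELS = 256


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2-D gray image, got shape {arr.shape}")
    if arr.size == 0:
        raise ParameterError("image is empty")
    if arr.min() < 0 or arr.max() > 255:
        raise ParameterError("pixel values must lie in [0, 255]")
    return arr.astype(np.int64)


def hist_variance(histogram) -> float:
    """Double-sum histogram variance over the bin counts z_1..z_n."""
    z = np.asarray(histogram, dtype=np.float64).ravel()
    if z.size == 0:
        raise ParameterError("histogram must have at least one bin")
    n = z.size
    diff = z[:, None] - z[None, :]
    return float((diff**2).sum() / (2 * n * n))


def gray_histogram(img) -> np.ndarray:
    """256-bin pixel histogram of a gray image."""
    return np.bincount(_as_image(img).ravel(), minlength=GRAY_LEVELS)


def entropy(img) -> float:
    """Shannon entropy (bits) of the 256-bin pixel histogram; 0*log0 = 0."""
    counts = gray_histogram(img)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def npcr(c1, c2) -> float:
    """Percent of pixel positions at which the two images differ."""
    a, b = _as_image(c1), _as_image(c2)
    if a.shape != b.shape:
        raise ParameterError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float((a != b).mean() * 100.0)


def uaci(c1, c2) -> float:
    """Mean absolute pixel difference scaled by 255, as a percent."""
    a, b = _as_image(c1), _as_image(c2)
    if a.shape != b.shape:
        raise ParameterError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float((np.abs(a - b) / 255.0).mean() * 100.0)


# ---------------------------------------------------------------------------
# key space


@dataclass(frozen=True)
class KeySpaceSpec:
    """Component cardinalities of the secret space.

    precision is the assumed computational accuracy (default 10^-16): a real
    parameter contributes range/precision choices.  The published component
    values are kept literally: the mu-range factor is 0.5 * precision^-1 and
    the table-iteration component is 256^12 (its redundancy relative to the
    13 attainable Pk values is a documented property of the source scheme,
    not silently corrected here).
    """

    precision: Fraction = Fraction(1, 10**16)
    rule_count: int = 24
    rule_selectors: int = 3
    pk_space: int = 256**12
    reassembly_len: int = 40

    def __post_init__(self):
        if self.precision <= 0 or self.rule_count < 1 or self.rule_selectors < 1:
            raise ParameterError("key-space components must be positive")


@dataclass(frozen=True)
class KeySpace:
    """Exact key-space product with per-component factors."""

    s_key: int
    s_mu: Fraction
    s_g: Fraction
    s_pk: int
    s_r: int
    total: Fraction

    @property
    def exact_int(self) -> int:
        if self.total.denominator != 1:
            raise ParameterError("key space is not an exact integer for this spec")
        return int(self.total)

    @property
    def prime_powers(self) -> str:
        """E.g. '2^247 * 3^3 * 5^64'."""
        factors = sympy.factorint(self.exact_int)
        return " * ".join(f"{p}^{e}" for p, e in sorted(factors.items()))

    @property
    def factor_dict(self) -> dict[int, int]:
        return {int(p): int(e) for p, e in sympy.factorint(self.exact_int).items()}

    @property
    def magnitude(self) -> float:
        return float(self.total)


def key_space(spec: KeySpaceSpec = KeySpaceSpec()) -> KeySpace:
    """Total secret space: rule selectors x mu-pairs x g-pairs x Pk x reassembly.

    S = 24^3 * (0.5/precision)^2 * (1/precision)^2 * 256^12 * 4^40
    with the default spec, which simplifies exactly to 3^3 * 5^64 * 2^247.
    """
    p = Fraction(spec.precision)
    s_key = spec.rule_count**spec.rule_selectors
    s_mu = Fraction(1, 2) / p  # one mu parameter
    s_g = 1 / p  # one g parameter
    s_pk = spec.pk_space
    s_r = 4**spec.reassembly_len
    total = Fraction(s_key) * s_mu**2 * s_g**2 * s_pk * s_r
    return KeySpace(s_key=s_key, s_mu=s_mu, s_g=s_g, s_pk=s_pk, s_r=s_r, total=total)


# ---------------------------------------------------------------------------
# PGM (P2 ascii / P5 binary)


def write_pgm(path, img, binary: bool = False) -> None:
    arr = _as_image(img).astype(np.uint8)
    h, w = arr.shape
    if binary:
        with open(path, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
            fh.write(arr.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write(f"P2\n{w} {h}\n255\n")
            for row in arr:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_pgm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:2] not in (b"P2", b"P5"):
        raise ParameterError("not a PGM (P2/P5) file")
    # Tokenize the header: magic, width, height, maxval; '#' starts a comment.
    tokens, pos = [], 0
    while len(tokens) < 4:
        while pos < len(data) and data[pos : pos + 1].isspace():
            pos += 1
        if data[pos : pos + 1] == b"#":
            pos = data.index(b"\n", pos) + 1
            continue
        start = pos
        while pos < len(data) and not data[pos : pos + 1].isspace():
            pos += 1
        tokens.append(data[start:pos])
    magic, w, h, maxval = tokens[0], int(tokens[1]), int(tokens[2]), int(tokens[3])
    if maxval > 255:
        raise ParameterError("only 8-bit PGM is supported")
    pos += 1  # single whitespace after maxval
    if magic == b"P5":
        pixels = np.frombuffer(data[pos : pos + w * h], dtype=np.uint8)
    else:
        pixels = np.array(data[pos:].split(), dtype=np.int64)
    if pixels.size != w * h:
        raise ParameterError(f"PGM payload has {pixels.size} pixels, expected {w * h}")
    return pixels.reshape(h, w).astype(np.uint8)
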