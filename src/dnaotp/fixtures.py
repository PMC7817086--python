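"""Packaged fixtures: the published worked example and synthetic generators.

``worked_example()`` carries, verbatim, the printed intermediates of the
parameter-cipher walk-through (input texts "12,3.78,0.51,3.92,0.44" and
"4,7,1" with key1=4, key2=7, Pk=1) so tests and demos can compare every
stage character-for-character.  The synthetic generators produce seeded
random ASCII plaintexts and grayscale PGM test images (uniform-random or
structured gradient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class WorkedExample:
    """The printed parameter-cipher walk-through, whitespace removed."""

    security_text: str
    confounding_text: str
    key1: int
    key2: int
    pk: int
    step1_bits: str
    step2_dna: str
    step3_trna: str
    step3_rrna: str
    step4_trna_bits: str
    step4_rrna_bits: str
    step5_m: tuple[int, ...]
    step5_n: tuple[int, ...]
    step6_a0: str
    step7_c0: str
    step8_bits: str
    step9_m: tuple[int, ...]
    step9_n: tuple[int, ...]
    step10_a1: str
    step11_c1: str


_WE = WorkedExample(
    security_text="12,3.78,0.51,3.92,0.44",
    confounding_text="4,7,1",
    key1=4,
    key2=7,
    pk=1,
    step1_bits=(
        "00110001 00110010 00101100 00110011 00101110 00110111 00111000 00101100 "
        "00110000 00101110 00110101 00110001 00101100 00110011 00101110 00111001 "
        "00110010 00101100 00110000 00101110 00110100 00110100"
    ).replace(" ", ""),
    step2_dna=(
        "ACAG ACAT ATCA ACAC ATCT ACGC ACTA ATCA ACAA ATCT ACGG "
        "ACAG ATCA ACAC ATCT ACTG ACAT ATCA ACAA ATCT ACGA ACGA"
    ).replace(" ", ""),
    step3_trna=(
        "UGUC UGUA UAGU UGUG UAGA UGCG UGAU UAGU UGUU UAGA UGCC"
    ).replace(" ", ""),
    step3_rrna=(
        "ACAG AUCA ACAC AUCU ACUG ACAU AUCA ACAA AUCU ACGA ACGA"
    ).replace(" ", ""),
    step4_trna_bits=(
        "00110010 00110001 00011100 00110011 00011101 00111011 00110100 00011100 "
        "00110000 00011101 00111010"
    ).replace(" ", ""),
    step4_rrna_bits=(
        "01100111 01001001 01100110 01001000 01100011 01100100 01001001 01100101 "
        "01001000 01101101 01101101"
    ).replace(" ", ""),
    step5_m=(3, 2, 3, 1, 1, 12, 3, 3, 1, 13, 3, 11, 3, 4, 1, 12, 3, 0, 1, 13, 3, 10),
    step5_n=(6, 7, 4, 9, 6, 6, 4, 8, 6, 3, 6, 4, 4, 9, 6, 5, 4, 8, 6, 13, 6, 13),
    step6_a0=(
        "AD FQ NR IH MQ NL NR PQ MQ GE AD NI NR SQ MQ DI NR HH MQ FA AD GD"
    ).replace(" ", ""),
    step7_c0="ADFVQNRIHYVMQWTNLNRPQMQGEVADNINRSYQMWQDIVNRTHHMQFAADWGTD",
    step8_bits=(
        "00110100 00101100 00110111 00101100 00110001"
    ).replace(" ", ""),
    step9_m=(3, 4, 2, 12, 3),
    step9_n=(7, 2, 12, 3, 1),
    step10_a1="DGCNNMMDDR",
    step11_c1="DTGCNNMYMDWDR",
)


def worked_example() -> WorkedExample:
    """The packaged walk-through with all printed intermediates."""
    return _WE


_PRINTABLE = "".join(chr(c) for c in range(32, 127))


def random_text(rng: np.random.Generator, length: int) -> str:
    """Seeded random printable-ASCII plaintext of the given length."""
    if not (1 <= length <= 10**6):
        raise ParameterError(f"length must be in [1, 10^6], got {length}")
    idx = rng.integers(0, len(_PRINTABLE), size=length)
    return "".join(_PRINTABLE[i] for i in idx)


def gray_image(
    rng: np.random.Generator, width: int = 160, height: int = 160, kind: str = "random"
) -> np.ndarray:
    """Synthetic 8-bit gray image: uniform-random noise or a structured gradient."""
    if kind == "random":
        return rng.integers(0, 256, size=(height, width), dtype=np.int64).astype(np.uint8)
    if kind == "gradient":
        x = np.linspace(0, 255, width)
        y = np.linspace(0, 255, height)
        img = (np.add.outer(y, x) / 2).astype(np.uint8)
        return img
    raise ParameterError(f"unknown image kind {kind!r}")
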