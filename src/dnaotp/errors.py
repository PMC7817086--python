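"""Exception hierarchy for the cipher pipeline.

Three broad failure families matter to callers (and get distinct CLI exit
codes): invalid parameters, corrupted ciphertext, and channel-reconstruction
failures.
"""

from __future__ import annotations


class DnaOtpError(Exception):
    """Base class for all package errors."""


class ParameterError(DnaOtpError, ValueError):
    """A parameter is outside its stated domain (rule id, mu-range, pk, ...)."""


class DegenerateOrbitError(ParameterError):
    """A logistic-map iterate landed exactly on 0 or 1 and the orbit collapsed."""

    def __init__(self, index: int):
        self.index = index
        super().__init__(
            f"logistic orbit degenerated at iterate {index}: value reached 0 or 1"
        )


class AlphabetError(ParameterError):
    """A sequence contains a residue outside its tagged alphabet."""


class CapacityError(ParameterError):
    """The 5-nt index space cannot address this many fragments."""


class CorruptionError(DnaOtpError):
    """Ciphertext failed structural checks during decryption."""


class PairingError(CorruptionError):
    """Coordinate halves have mismatched lengths and cannot be paired."""


class ReconstructionError(DnaOtpError):
    """The DNA mixture could not be spliced back into a ciphertext."""

    def __init__(self, message: str, missing: tuple[int, ...] = ()):
        self.missing = tuple(missing)
        super().__init__(message)


class EmptyMixtureError(ReconstructionError):
    """No record in the mixture matched the adapter."""
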