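"""Chaotic keystream generation.

Two logistic-map orbits, x_{i+1} = mu * x_i * (1 - x_i), are thresholded at
0.5 into bit sequences and XORed position-wise to form a one-time-pad
keystream.  The map is chaotic for mu in [3.569946, 4] (with periodic
windows), and its extreme sensitivity to (mu, x0) is what makes the stream
session-unique: the parameter pairs are the key-generation secret.

Arithmetic is IEEE-754 double precision with the literal expression
``mu * x * (1.0 - x)``, so identical parameters yield bit-identical streams
across platforms.  A configurable burn-in (default 1000 iterates) discards
the transient before bits are emitted; burn_in=0 reproduces a strict
no-transient reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateOrbitError, ParameterError

#: Lower edge of the control-parameter window in which the map is chaotic.
CHAOTIC_MU_MIN = 3.569946
CHAOTIC_MU_MAX = 4.0

#: Default number of initial iterates discarded before bits are emitted.
DEFAULT_BURN_IN = 1000


def _orbit_py(mu: float, x: float, n: int, burn_in: int) -> tuple[np.ndarray, int]:
    """Pure-Python orbit loop. Returns (orbit, degenerate_index|-1)."""
    out = np.empty(n, dtype=np.float64)
    total = burn_in + n
    for i in range(total):
        x = mu * x * (1.0 - x)
        if x <= 0.0 or x >= 1.0:
            return out, i + 1
        if i >= burn_in:
            out[i - burn_in] = x
    return out, -1


try:  # pragma: no cover - exercised indirectly; fallback tested explicitly
    import numba

    _orbit_jit = numba.njit(cache=False)(_orbit_py)

    def _orbit_core(mu, x, n, burn_in):
        return _orbit_jit(mu, x, n, burn_in)

except Exception:  # pragma: no cover
    _orbit_jit = None

    def _orbit_core(mu, x, n, burn_in):
        return _orbit_py(mu, x, n, burn_in)


@dataclass(frozen=True)
class LogisticParams:
    """Control parameter and initial value of one logistic orbit.

    mu must lie in the chaotic window [3.569946, 4]; x0 strictly inside (0, 1).
    """

    mu: float
    x0: float

    def __post_init__(self):
        if not (CHAOTIC_MU_MIN <= self.mu <= CHAOTIC_MU_MAX):
            raise ParameterError(
                f"mu={self.mu} outside chaotic range [{CHAOTIC_MU_MIN}, {CHAOTIC_MU_MAX}]"
            )
        if not (0.0 < self.x0 < 1.0):
            raise ParameterError(f"x0={self.x0} outside the open interval (0, 1)")


@dataclass(frozen=True)
class KeyStream:
    """A one-time-pad bit sequence together with its generating parameters."""

    bits: np.ndarray  # uint8 array of 0/1
    provenance: tuple[LogisticParams, LogisticParams]
    burn_in: int

    def __len__(self) -> int:
        return int(self.bits.size)

    def to_bitstring(self) -> str:
        """One line of '0'/'1' characters."""
        return "".join("1" if b else "0" for b in self.bits)

    def to_bytes(self) -> bytes:
        """Packed bytes, most-significant-bit first; zero-padded at the tail."""
        return np.packbits(self.bits).tobytes()

    def save_bittext(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_bitstring() + "\n")


def logistic_orbit(p: LogisticParams, n: int, burn_in: int = 0) -> np.ndarray:
    """Iterate the logistic map, returning x_1..x_n after ``burn_in`` discards.

    Raises DegenerateOrbitError (naming the offending 1-based iterate) if the
    orbit ever lands exactly on 0 or 1 — e.g. mu=4, x0=0.5 maps to 1 at the
    first step — since the orbit is then permanently stuck.
    """
    if n < 0 or burn_in < 0:
        raise ParameterError("n and burn_in must be non-negative")
    # Validate even if constructed by other means.
    LogisticParams(p.mu, p.x0)
    orbit, bad = _orbit_core(p.mu, p.x0, n, burn_in)
    if bad != -1 and bad <= burn_in + n:
        # Degeneracy inside the requested window (burn-in included: the orbit
        # cannot recover once collapsed).
        raise DegenerateOrbitError(bad)
    return orbit


def threshold_bits(orbit: np.ndarray) -> np.ndarray:
    """Map orbit values in (0,1) to bits: value <= 0.5 -> 0, value > 0.5 -> 1.

    The lower interval is closed at 0.5, so f(0.5) = 0 exactly.
    """
    arr = np.asarray(orbit, dtype=np.float64)
    if arr.size and (arr.min() <= 0.0 or arr.max() >= 1.0):
        raise ParameterError("orbit values must lie strictly inside (0, 1)")
    return (arr > 0.5).astype(np.uint8)


def derive_params(mu1: float, g1: float, j: int) -> tuple[float, float]:
    """Parameter-derivation schedule: mu_j = mu_1 + 0.001*(j-1); g_j iterated.

    g_j is obtained by applying g <- mu_1 * g * (1 - g) exactly j-1 times to
    g_1 (the control parameter stays mu_1 throughout the g recursion).  This
    is exposed as a standalone utility; the default keystream path iterates
    the two initial parameter pairs directly.
    """
    if j < 1:
        raise ParameterError("j must be >= 1")
    LogisticParams(mu1, g1)
    mu_j = mu1 + 0.001 * (j - 1)
    if not (CHAOTIC_MU_MIN <= mu_j <= CHAOTIC_MU_MAX):
        raise ParameterError(
            f"derived mu_{j}={mu_j} leaves the chaotic range [{CHAOTIC_MU_MIN}, {CHAOTIC_MU_MAX}]"
        )
    g = g1
    for i in range(j - 1):
        g = mu1 * g * (1.0 - g)
        if g <= 0.0 or g >= 1.0:
            raise DegenerateOrbitError(i + 1)
    return mu_j, g


def keystream(
    p0: LogisticParams,
    p1: LogisticParams,
    n: int,
    burn_in: int = DEFAULT_BURN_IN,
) -> KeyStream:
    """K_i = f(orbit(p0)_i) XOR f(orbit(p1)_i) for i = 1..n."""
    b0 = threshold_bits(logistic_orbit(p0, n, burn_in))
    b1 = threshold_bits(logistic_orbit(p1, n, burn_in))
    return KeyStream(bits=np.bitwise_xor(b0, b1), provenance=(p0, p1), burn_in=burn_in)
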