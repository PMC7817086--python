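"""Arnold (cat) map scrambling and the 16x16 amino-acid digram table.

The Arnold map is the modular linear transform

    x' = (x + m*y) mod N
    y' = (n*x + (m*n + 1)*y) mod N

whose matrix [[1, m], [n, m*n+1]] has determinant 1, so it permutes the
cells of an N x N grid and is periodic.  For m = n = 1 on a 16 x 16 grid the
period is 12 (computed, never assumed).

The confusion table starts from the outer product of a fixed 16-letter
amino-acid alphabet (A R N D C Q E G H I L K M F P S — the four letters
T, V, W, Y are reserved as removable chaff) and is scrambled Pk Arnold
steps, each step moving the digram at cell (x, y) to cell (x', y').  A
coordinate pair (M, N) = (row, column) then selects one of 256 distinct
digrams; the lookup is invertible, which is what makes the table usable as
a substitution layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: The 16 grid letters, in fixed row/column order.
TABLE_LETTERS = "ARNDCQEGHILKMFPS"
#: The four amino-acid letters excluded from the grid and used as chaff.
REDUNDANT_LETTERS = "TVWY"

GRID_SIDE = 16


@dataclass(frozen=True)
class ArnoldMap:
    """Scrambling parameters (m, n) on an N x N grid."""

    m: int = 1
    n: int = 1
    N: int = GRID_SIDE

    def __post_init__(self):
        if self.m < 1 or self.n < 1 or self.N < 1:
            raise ParameterError("Arnold parameters m, n, N must be positive integers")

    def _check(self, x: int, y: int) -> None:
        if not (0 <= x < self.N and 0 <= y < self.N):
            raise ParameterError(f"coordinate ({x}, {y}) outside the {self.N}x{self.N} grid")

    def forward(self, x: int, y: int) -> tuple[int, int]:
        self._check(x, y)
        return (x + self.m * y) % self.N, (self.n * x + (self.m * self.n + 1) * y) % self.N

    def inverse(self, xp: int, yp: int) -> tuple[int, int]:
        """Inverse transform; forward o inverse is the identity on the grid."""
        self._check(xp, yp)
        # [[1,m],[n,mn+1]]^-1 = [[mn+1,-m],[-n,1]] (determinant 1).
        return (
            ((self.m * self.n + 1) * xp - self.m * yp) % self.N,
            (-self.n * xp + yp) % self.N,
        )

    def forward_grid(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized forward transform for integer coordinate arrays."""
        return (x + self.m * y) % self.N, (self.n * x + (self.m * self.n + 1) * y) % self.N


def arnold_forward(point: tuple[int, int], a: ArnoldMap) -> tuple[int, int]:
    return a.forward(*point)


def arnold_inverse(point: tuple[int, int], a: ArnoldMap) -> tuple[int, int]:
    return a.inverse(*point)


def arnold_period(a: ArnoldMap, max_iter: int = 10_000_000) -> int:
    """Smallest p > 0 whose p-fold forward transform fixes every grid cell.

    Brute force on the full permutation; a period always exists because the
    map is a bijection on a finite grid.
    """
    x0, y0 = np.meshgrid(np.arange(a.N), np.arange(a.N), indexing="ij")
    x, y = a.forward_grid(x0, y0)
    p = 1
    while not (np.array_equal(x, x0) and np.array_equal(y, y0)):
        x, y = a.forward_grid(x, y)
        p += 1
        if p > max_iter:  # pragma: no cover - defensive only
            raise RuntimeError("period search exceeded max_iter")
    return p


class ConfusionTable:
    """16 x 16 digram grid at Arnold iteration count pk.

    ``grid[M][N]`` is the digram at row M, column N.  All 256 digrams are
    pairwise distinct at every pk, so ``unlookup`` is total on the grid's
    digram set.
    """

    def __init__(self, grid: list[list[str]], pk: int):
        self.grid = grid
        self.pk = pk
        self._inverse = {
            grid[i][j]: (i, j) for i in range(GRID_SIDE) for j in range(GRID_SIDE)
        }
        if len(self._inverse) != GRID_SIDE * GRID_SIDE:
            raise ParameterError("confusion table digrams are not pairwise distinct")

    def lookup(self, M: int, N: int) -> str:
        if not (0 <= M < GRID_SIDE and 0 <= N < GRID_SIDE):
            raise ParameterError(f"coordinate ({M}, {N}) outside the 16x16 grid")
        return self.grid[M][N]

    def unlookup(self, digram: str) -> tuple[int, int]:
        try:
            return self._inverse[digram]
        except KeyError:
            raise ParameterError(f"digram {digram!r} not present in the confusion table") from None

    def digrams(self) -> frozenset:
        return frozenset(self._inverse)

    def to_tsv(self) -> str:
        """Tab-separated layout matching the published table orientation."""
        header = "\t" + "\t".join(str(j) for j in range(GRID_SIDE))
        rows = [
            f"{i}\t" + "\t".join(self.grid[i]) for i in range(GRID_SIDE)
        ]
        return "\n".join([header, *rows]) + "\n"

    def __eq__(self, other):
        return isinstance(other, ConfusionTable) and self.grid == other.grid

    def __hash__(self):  # pragma: no cover
        return hash(tuple(map(tuple, self.grid)))


def initial_table() -> ConfusionTable:
    """The unscrambled table: grid[i][j] = letters[i] + letters[j]."""
    grid = [
        [TABLE_LETTERS[i] + TABLE_LETTERS[j] for j in range(GRID_SIDE)]
        for i in range(GRID_SIDE)
    ]
    return ConfusionTable(grid, pk=0)


_PERIOD_16: int | None = None


def table_period() -> int:
    """Arnold period of the 16x16 grid with m = n = 1 (computed once)."""
    global _PERIOD_16
    if _PERIOD_16 is None:
        _PERIOD_16 = arnold_period(ArnoldMap(1, 1, GRID_SIDE))
    return _PERIOD_16


_TABLE_CACHE: dict[int, ConfusionTable] = {}


def build_table(pk: int) -> ConfusionTable:
    """Scramble the initial table pk Arnold steps (m = n = 1, N = 16).

    Each step places the digram at cell (x, y) into cell (x', y'); pk must
    lie in [0, period] where the period (12) is computed at first use.
    """
    period = table_period()
    if not (0 <= pk <= period):
        raise ParameterError(f"pk must be in [0, {period}], got {pk}")
    if pk in _TABLE_CACHE:
        return _TABLE_CACHE[pk]
    a = ArnoldMap(1, 1, GRID_SIDE)
    grid = initial_table().grid
    for _ in range(pk):
        new = [[""] * GRID_SIDE for _ in range(GRID_SIDE)]
        for x in range(GRID_SIDE):
            for y in range(GRID_SIDE):
                xp, yp = a.forward(x, y)
                new[xp][yp] = grid[x][y]
        grid = new
    table = ConfusionTable(grid, pk=pk)
    _TABLE_CACHE[pk] = table
    return table


def lookup(t: ConfusionTable, M: int, N: int) -> str:
    return t.lookup(M, N)


def unlookup(t: ConfusionTable, digram: str) -> tuple[int, int]:
    return t.unlookup(digram)
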