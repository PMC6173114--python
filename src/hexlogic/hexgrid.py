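"""Hexagonal lattice topology: coordinates, adjacency, distance bands.

Cells are addressed with 0-based offset coordinates ``(col, row)`` on a
pointy-top hexagonal lattice in "odd-r" layout (odd rows shifted half a cell
to the right). Borders may be connected pairwise, giving rectangular,
cylindrical or toroidal tissues. Distances are shortest-path lengths in the
adjacency graph, so border wrapping is respected by construction.

Vertical wrapping requires an even number of rows: joining an odd row to row
0 would break the row-parity consistency that odd-r adjacency relies on.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator, NamedTuple

from .errors import ValidationError

__all__ = ["CellCoord", "GridTopology"]


class CellCoord(NamedTuple):
    col: int
    row: int


# odd-r offset neighbour deltas, indexed by row parity
_DELTAS_EVEN = ((+1, 0), (-1, 0), (0, -1), (-1, -1), (0, +1), (-1, +1))
_DELTAS_ODD = ((+1, 0), (-1, 0), (+1, -1), (0, -1), (+1, +1), (0, +1))


@dataclass(frozen=True)
class GridTopology:
    """Dimensions and border wrapping of the hexagonal grid.

    ``(wrap_horizontal, wrap_vertical)`` of ``(False, False)`` is a rectangle,
    one ``True`` a cylinder, both ``True`` a torus.
    """

    width: int
    height: int
    wrap_horizontal: bool = False
    wrap_vertical: bool = False

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValidationError(
                f"grid dimensions must be >= 1, got {self.width}x{self.height}"
            )
        if self.wrap_vertical and self.height % 2 != 0:
            raise ValidationError(
                "vertical wrapping requires an even number of rows "
                f"(got height={self.height}): odd-r row parity would not match "
                "across the joined border"
            )

    # -- basics ------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    def contains(self, c: CellCoord) -> bool:
        return 0 <= c[0] < self.width and 0 <= c[1] < self.height

    def check(self, c: CellCoord) -> None:
        if not self.contains(c):
            raise ValidationError(f"coordinate {tuple(c)} outside {self.width}x{self.height} grid")

    def cells(self) -> Iterator[CellCoord]:
        """All cells in canonical row-major order."""
        for row in range(self.height):
            for col in range(self.width):
                yield CellCoord(col, row)

    def flat_index(self, c: CellCoord) -> int:
        return c[1] * self.width + c[0]

    # -- adjacency ---------------------------------------------------------

    def neighbors(self, c: CellCoord) -> set[CellCoord]:
        """The up-to-six adjacent cells of ``c``.

        Candidates across a wrapped border are mapped back modularly;
        candidates across a hard border are dropped.
        """
        self.check(CellCoord(*c))
        col, row = c
        deltas = _DELTAS_ODD if row % 2 else _DELTAS_EVEN
        out = set()
        for dc, dr in deltas:
            nc, nr = col + dc, row + dr
            if self.wrap_horizontal:
                nc %= self.width
            elif not 0 <= nc < self.width:
                continue
            if self.wrap_vertical:
                nr %= self.height
            elif not 0 <= nr < self.height:
                continue
            out.add(CellCoord(nc, nr))
        return out

    def _bfs_rings(self, c: CellCoord, dmax: int) -> dict[CellCoord, int]:
        """Distance of every cell within ``dmax`` of ``c`` (frontier expansion)."""
        dist = {CellCoord(*c): 0}
        frontier = deque([CellCoord(*c)])
        while frontier:
            x = frontier.popleft()
            d = dist[x]
            if d == dmax:
                continue
            for y in self.neighbors(x):
                if y not in dist:
                    dist[y] = d + 1
                    frontier.append(y)
        return dist

    def hex_distance(self, a: CellCoord, b: CellCoord) -> int:
        """Shortest-path length between ``a`` and ``b`` in the adjacency graph."""
        self.check(CellCoord(*a))
        self.check(CellCoord(*b))
        a, b = CellCoord(*a), CellCoord(*b)
        if a == b:
            return 0
        dist = {a: 0}
        frontier = deque([a])
        while frontier:
            x = frontier.popleft()
            for y in self.neighbors(x):
                if y not in dist:
                    dist[y] = dist[x] + 1
                    if y == b:
                        return dist[y]
                    frontier.append(y)
        raise ValidationError(f"no path between {tuple(a)} and {tuple(b)}")

    def cells_at_distance(self, c: CellCoord, dmin: int, dmax: int) -> set[CellCoord]:
        """All cells whose distance from ``c`` lies in ``[dmin, dmax]``."""
        if not 0 <= dmin <= dmax:
            raise ValidationError(f"invalid distance band [{dmin}:{dmax}]")
        dist = self._bfs_rings(CellCoord(*c), dmax)
        return {x for x, d in dist.items() if dmin <= d <= dmax}
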