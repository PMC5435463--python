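"""Geometry of the retinotopic hexagonal column lattice.

The fly medulla repeats one module ("column") per ommatidium, arranged on a
hexagonal lattice.  Columns are addressed by integer axial coordinates
``(q, r)`` with the Home column at the origin; the Cartesian embedding uses
*ommatidial units*, i.e. the centre-to-centre distance between two adjacent
columns is exactly 1.0.  The orientation is "pointy-top": the first axial
basis vector maps to +x and the second to a 60 degree direction.  All
anatomical subfield analyses reduce to synapse-count-weighted centres of
mass on this lattice, so the weighted centroid lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np

__all__ = [
    "HexCoord",
    "CartPoint",
    "ColumnLattice",
    "AXIAL_DIRECTIONS",
    "axial_to_cart",
    "neighbours",
    "rotate60",
    "weighted_centroid",
    "hex_disc",
    "ring_of",
]

_SQRT3_2 = math.sqrt(3.0) / 2.0


class HexCoord(NamedTuple):
    """Integer axial coordinate of a column; (0, 0) is the Home column."""

    q: int
    r: int


class CartPoint(NamedTuple):
    """Point in the lattice plane, in ommatidial units (adjacent spacing = 1)."""

    x: float
    y: float


#: The six axial unit directions, in counter-clockwise order starting at +x.
AXIAL_DIRECTIONS: tuple[HexCoord, ...] = (
    HexCoord(1, 0),
    HexCoord(0, 1),
    HexCoord(-1, 1),
    HexCoord(-1, 0),
    HexCoord(0, -1),
    HexCoord(1, -1),
)

#: Conventional labels of the six Home-column neighbours, counter-clockwise
#: from (1, 0).  Labels are cosmetic; every algorithm works on HexCoord.
RING1_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")


def axial_to_cart(c: HexCoord | tuple[int, int]) -> CartPoint:
    """Map an axial coordinate to the plane with unit column spacing.

    Basis: (1, 0) -> (1, 0) and (0, 1) -> (1/2, sqrt(3)/2), i.e. the two
    axial axes meet at 60 degrees and all six lattice neighbours of a
    column lie at distance exactly 1.
    """
    q, r = c
    return CartPoint(q + 0.5 * r, _SQRT3_2 * r)


def neighbours(c: HexCoord | tuple[int, int]) -> set[HexCoord]:
    """The six lattice neighbours of a column (each at distance 1.0)."""
    q, r = c
    return {HexCoord(q + dq, r + dr) for dq, dr in AXIAL_DIRECTIONS}


def rotate60(c: HexCoord | tuple[int, int], n: int = 1) -> HexCoord:
    """Rotate an axial coordinate about the origin by n * 60 degrees CCW."""
    q, r = int(c[0]), int(c[1])
    for _ in range(n % 6):
        q, r = -r, q + r
    return HexCoord(q, r)


def ring_of(c: HexCoord | tuple[int, int]) -> int:
    """Hex ring index (axial hex distance from the origin)."""
    q, r = c
    return int((abs(q) + abs(r) + abs(q + r)) // 2)


def weighted_centroid(
    pairs: Iterable[tuple[HexCoord | tuple[int, int], float]],
) -> CartPoint:
    """Synapse-count-weighted centre of mass of columns on the ideal lattice.

    Parameters
    ----------
    pairs
        ``(column, weight)`` items; weights are non-negative synapse counts
        (or completeness-adjusted counts) and at least one must be positive.

    Returns
    -------
    CartPoint
        ``sum(w_i * cart(c_i)) / sum(w_i)``; always inside the convex hull
        of the contributing columns.

    Raises
    ------
    ValueError
        If no pairs are given, any weight is negative, or all weights are
        zero (a degenerate input, never silently mapped to the origin).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("weighted_centroid: no (column, weight) pairs given")
    w = np.array([float(p[1]) for p in pairs])
    if np.any(w < 0):
        raise ValueError("weighted_centroid: negative weight")
    total = w.sum()
    if total <= 0:
        raise ValueError("weighted_centroid: all weights are zero")
    xy = np.array([axial_to_cart(p[0]) for p in pairs])
    cx, cy = (w[:, None] * xy).sum(axis=0) / total
    return CartPoint(float(cx), float(cy))


def hex_disc(radius: int) -> list[HexCoord]:
    """All axial coordinates within hex distance ``radius`` of the origin.

    Yields ``1 + 3 * radius * (radius + 1)`` columns, sorted for determinism.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    out = [
        HexCoord(q, r)
        for q in range(-radius, radius + 1)
        for r in range(max(-radius, -q - radius), min(radius, -q + radius) + 1)
    ]
    return sorted(out)


@dataclass
class ColumnLattice:
    """A connected set of columns with optional labels (Home, A-F, ...)."""

    columns: set[HexCoord]
    labels: dict[HexCoord, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.columns = {HexCoord(*c) for c in self.columns}
        if HexCoord(0, 0) not in self.columns:
            raise ValueError("lattice must contain the Home column (0, 0)")
        if not self._connected():
            raise ValueError("lattice is not connected under 6-neighbour adjacency")

    def _connected(self) -> bool:
        seen = {HexCoord(0, 0)}
        frontier = [HexCoord(0, 0)]
        while frontier:
            c = frontier.pop()
            for n in neighbours(c):
                if n in self.columns and n not in seen:
                    seen.add(n)
                    frontier.append(n)
        return seen == self.columns

    def __contains__(self, c: object) -> bool:
        try:
            return HexCoord(*c) in self.columns  # type: ignore[misc]
        except TypeError:
            return False

    def __len__(self) -> int:
        return len(self.columns)

    def sorted_columns(self) -> list[HexCoord]:
        return sorted(self.columns)

    @classmethod
    def disc(cls, radius: int) -> "ColumnLattice":
        """Hex disc of the given radius; radius 1 is the 7-column geometry."""
        if radius < 1:
            raise ValueError("lattice radius must be >= 1")
        cols = hex_disc(radius)
        labels = {HexCoord(0, 0): "Home"}
        for lab, d in zip(RING1_LABELS, AXIAL_DIRECTIONS):
            labels[d] = lab
        return cls(columns=set(cols), labels=labels)

    def label(self, c: HexCoord) -> str:
        return self.labels.get(HexCoord(*c), f"{c[0]},{c[1]}")

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("q\tr\tlabel\n")
            for c in self.sorted_columns():
                fh.write(f"{c.q}\t{c.r}\t{self.labels.get(c, '')}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ColumnLattice":
        cols: set[HexCoord] = set()
        labels: dict[HexCoord, str] = {}
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:2] != ["q", "r"]:
                raise ValueError(f"{path}: expected header 'q\\tr\\tlabel'")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                c = HexCoord(int(parts[0]), int(parts[1]))
                cols.add(c)
                if len(parts) > 2 and parts[2]:
                    labels[c] = parts[2]
        return cls(columns=cols, labels=labels)
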