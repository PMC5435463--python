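"""Core connectome data types.

The counting convention throughout the package is PSD-level: one synaptic
input = one postsynaptic density = one row of the synapse table.  Fly
synapses are polyadic (one presynaptic T-bar ribbon contacts several
postsynaptic sites), so one ``tbar_id`` may appear in many rows; T-bar-level
counts are a derived quantity, never the primary one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .hexgrid import CartPoint, ColumnLattice, HexCoord

__all__ = [
    "CellType",
    "UNICOLUMNAR_TYPES",
    "MULTICOLUMNAR_TYPES",
    "T4_SUBTYPES",
    "Neuron",
    "Skeleton",
    "Box",
    "SYNAPSE_COLUMNS",
    "make_synapse_table",
    "GroundTruth",
    "ConnectomeDataset",
]


class CellType(str, enum.Enum):
    """Cell types appearing in the T4 input circuit."""

    Mi1 = "Mi1"
    Tm3 = "Tm3"
    Mi4 = "Mi4"
    Mi9 = "Mi9"
    C3 = "C3"
    CT1 = "CT1"
    TmY15 = "TmY15"
    Mi10 = "Mi10"
    T4a = "T4a"
    T4b = "T4b"
    T4c = "T4c"
    T4d = "T4d"
    L1 = "L1"
    L3 = "L3"
    L5 = "L5"
    R8 = "R8"
    unknown = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_t4(self) -> bool:
        return self in T4_SUBTYPES


T4_SUBTYPES: frozenset[CellType] = frozenset(
    {CellType.T4a, CellType.T4b, CellType.T4c, CellType.T4d}
)

#: Fixed deterministic ordering of the four subtypes.
T4_SUBTYPE_ORDER: tuple[CellType, ...] = (
    CellType.T4a,
    CellType.T4b,
    CellType.T4c,
    CellType.T4d,
)

#: Unit vector along which each subtype's dendritic arbour extends from its
#: trunk, in lattice Cartesian coordinates (ommatidial units).  The lattice
#: orientation relative to the fly's body axes is a free configuration, so
#: the axes below are a package convention, not an anatomical claim.
ARBOR_AXES: dict[CellType, tuple[float, float]] = {
    CellType.T4a: (1.0, 0.0),
    CellType.T4b: (-1.0, 0.0),
    CellType.T4c: (0.0, 1.0),
    CellType.T4d: (0.0, -1.0),
}

#: Preferred-direction unit vector per subtype.  T4 dendrites extend
#: opposite to the preferred direction (tips lie on the null-direction
#: side; PD points from the dendritic tips toward the base), so PD is the
#: negation of the arbour axis.
PD_VECTORS: dict[CellType, tuple[float, float]] = {
    t: (-ax, -ay) for t, (ax, ay) in ARBOR_AXES.items()
}

#: Types whose arbour is confined to one column and can carry a home column.
#: CT1 qualifies through its per-column terminal units.
UNICOLUMNAR_TYPES: frozenset[CellType] = frozenset(
    {
        CellType.Mi1,
        CellType.Mi4,
        CellType.Mi9,
        CellType.C3,
        CellType.CT1,
        CellType.Mi10,
        CellType.L1,
        CellType.L3,
        CellType.L5,
        CellType.R8,
    }
    | T4_SUBTYPES
)

#: Types spanning several columns without columnar subdivision; these can
#: never be assigned a home column.
MULTICOLUMNAR_TYPES: frozenset[CellType] = frozenset({CellType.Tm3, CellType.TmY15})


@dataclass
class Neuron:
    """A typed cell (or, for CT1, one per-column terminal unit).

    ``completeness`` is the fraction of the cell's synapses captured inside
    the reconstructed volume, in (0, 1]; for synthetic data it is ground
    truth, for real data a user-supplied estimate.  ``parent_id`` groups
    CT1 terminal units belonging to one biological cell.
    """

    id: str
    cell_type: CellType
    home_column: Optional[HexCoord] = None
    completeness: Optional[float] = None
    skeleton_id: Optional[str] = None
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.cell_type = CellType(self.cell_type)
        if self.home_column is not None:
            # Multicolumnar types must not carry a home column; this is
            # surfaced by io.validate as a report finding, not an exception,
            # so that faulty tables can be loaded and audited.
            self.home_column = HexCoord(*self.home_column)
        if self.completeness is not None:
            if not (0.0 < self.completeness <= 1.0):
                raise ValueError(
                    f"completeness must be in (0, 1], got {self.completeness} "
                    f"(neuron {self.id!r})"
                )


class Skeleton:
    """Rooted-tree morphology in micrometres (SWC semantics).

    Nodes carry 1-based ids; the single root has parent -1.  Construction
    enforces the tree invariant (one root, every node reachable, no cycles).
    """

    def __init__(
        self,
        node_ids: np.ndarray,
        parent_ids: np.ndarray,
        xyz: np.ndarray,
        radius: np.ndarray | None = None,
    ) -> None:
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.parent_ids = np.asarray(parent_ids, dtype=np.int64)
        self.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        n = len(self.node_ids)
        self.radius = (
            np.asarray(radius, dtype=float) if radius is not None else np.full(n, 0.2)
        )
        if not (len(self.parent_ids) == n == len(self.xyz) == len(self.radius)):
            raise ValueError("skeleton arrays have inconsistent lengths")
        if len(np.unique(self.node_ids)) != n:
            raise ValueError("duplicate node ids in skeleton")
        self._index = {int(i): k for k, i in enumerate(self.node_ids)}
        roots = np.flatnonzero(self.parent_ids == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self._root_idx = int(roots[0])
        self._parent_idx = np.empty(n, dtype=np.int64)
        for k in range(n):
            p = int(self.parent_ids[k])
            if p == -1:
                self._parent_idx[k] = -1
            else:
                if p not in self._index:
                    raise ValueError(f"node {self.node_ids[k]} has unknown parent {p}")
                self._parent_idx[k] = self._index[p]
        self._check_tree()
        self._path_dist: np.ndarray | None = None

    def _check_tree(self) -> None:
        n = len(self.node_ids)
        state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 on path, 2 done
        for start in range(n):
            if state[start]:
                continue
            path = []
            k = start
            while k != -1 and state[k] == 0:
                state[k] = 1
                path.append(k)
                k = int(self._parent_idx[k])
            if k != -1 and state[k] == 1:
                raise ValueError("cycle detected in skeleton")
            for k in path:
                state[k] = 2

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def root_id(self) -> int:
        return int(self.node_ids[self._root_idx])

    @property
    def root_xyz(self) -> np.ndarray:
        return self.xyz[self._root_idx]

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def edge_length(self, idx: int) -> float:
        p = int(self._parent_idx[idx])
        if p == -1:
            return 0.0
        return float(np.linalg.norm(self.xyz[idx] - self.xyz[p]))

    def path_distances(self) -> np.ndarray:
        """Distance from the root to every node along the tree, in µm."""
        if self._path_dist is None:
            n = self.n_nodes
            dist = np.full(n, np.nan)
            dist[self._root_idx] = 0.0
            for k in range(n):
                if not np.isnan(dist[k]):
                    continue
                chain = []
                j = k
                while np.isnan(dist[j]):
                    chain.append(j)
                    j = int(self._parent_idx[j])
                for j2 in reversed(chain):
                    dist[j2] = dist[int(self._parent_idx[j2])] + self.edge_length(j2)
            self._path_dist = dist
        return self._path_dist

    def max_path_distance(self) -> float:
        return float(self.path_distances().max())

    def total_cable_length(self) -> float:
        return float(sum(self.edge_length(k) for k in range(self.n_nodes)))

    def nearest_node(self, point: np.ndarray) -> tuple[int, float]:
        """(index, Euclidean distance) of the node closest to ``point``."""
        d = np.linalg.norm(self.xyz - np.asarray(point, dtype=float), axis=1)
        k = int(np.argmin(d))
        return k, float(d[k])


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in µm."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, float)
        hi = np.asarray(self.hi, float)
        if np.any(hi < lo):
            raise ValueError("box has hi < lo")

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def intersect(self, other: "Box") -> Optional["Box"]:
        lo = np.maximum(self.lo, other.lo)
        hi = np.minimum(self.hi, other.hi)
        if np.any(hi < lo):
            return None
        return Box(tuple(lo), tuple(hi))

    def to_dict(self) -> dict:
        return {"lo": list(self.lo), "hi": list(self.hi)}

    @classmethod
    def from_dict(cls, d: dict) -> "Box":
        return cls(tuple(d["lo"]), tuple(d["hi"]))


SYNAPSE_COLUMNS = ["pre_id", "post_id", "tbar_id", "x", "y", "z"]


def make_synapse_table(rows: Iterable[tuple] | None = None) -> pd.DataFrame:
    """Build a synapse table (one row = one PSD) with canonical columns."""
    df = pd.DataFrame(list(rows) if rows is not None else [], columns=SYNAPSE_COLUMNS)
    for c in ("x", "y", "z"):
        df[c] = df[c].astype(float)
    for c in ("pre_id", "post_id", "tbar_id"):
        df[c] = df[c].astype(str)
    return df


@dataclass
class GroundTruth:
    """Planted truth of a synthetic dataset (never present for real data).

    ``cell_centres`` holds the exact expected field centre of each generated
    input cell on the lattice (in ommatidial units); ``completeness`` the
    true retained-PSD fraction after truncation; ``t4`` per-T4 facts:
    subtype, preferred-direction unit vector, arbour axis, and the exact
    expected (planted) subfield centres per input type.
    """

    cell_centres: dict[str, CartPoint] = field(default_factory=dict)
    completeness: dict[str, float] = field(default_factory=dict)
    t4: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cell_centres": {k: list(v) for k, v in self.cell_centres.items()},
            "completeness": dict(self.completeness),
            "t4": self.t4,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cell_centres={k: CartPoint(*v) for k, v in d.get("cell_centres", {}).items()},
            completeness=dict(d.get("completeness", {})),
            t4=dict(d.get("t4", {})),
        )


@dataclass
class ConnectomeDataset:
    """Neurons + synapse table + lattice + volume bounds: the pipeline input."""

    neurons: dict[str, Neuron]
    synapses: pd.DataFrame
    lattice: ColumnLattice
    volume_bounds: Box
    skeletons: dict[str, Skeleton] = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        missing = set(SYNAPSE_COLUMNS) - set(self.synapses.columns)
        if missing:
            raise ValueError(f"synapse table missing columns: {sorted(missing)}")

    # -- lookups ----------------------------------------------------------
    def neuron(self, cell_id: str) -> Neuron:
        try:
            return self.neurons[cell_id]
        except KeyError:
            raise KeyError(f"unknown neuron id {cell_id!r}") from None

    def cell_type_of(self, cell_id: str) -> CellType:
        return self.neuron(cell_id).cell_type

    def ids_of_type(self, cell_type: CellType | str) -> list[str]:
        t = CellType(cell_type)
        return sorted(i for i, n in self.neurons.items() if n.cell_type == t)

    def t4_ids(self) -> list[str]:
        return sorted(i for i, n in self.neurons.items() if n.cell_type.is_t4)

    def synapses_onto(self, post_id: str) -> pd.DataFrame:
        self.neuron(post_id)
        return self.synapses[self.synapses["post_id"] == post_id]

    def skeleton_of(self, cell_id: str) -> Skeleton:
        n = self.neuron(cell_id)
        key = n.skeleton_id or cell_id
        try:
            return self.skeletons[key]
        except KeyError:
            raise KeyError(f"no skeleton for neuron {cell_id!r}") from None

    def with_synapses(self, synapses: pd.DataFrame) -> "ConnectomeDataset":
        """Shallow copy carrying a different synapse table (a 'view')."""
        return ConnectomeDataset(
            neurons=self.neurons,
            synapses=synapses.reset_index(drop=True),
            lattice=self.lattice,
            volume_bounds=self.volume_bounds,
            skeletons=self.skeletons,
            ground_truth=self.ground_truth,
        )

    @property
    def n_psds(self) -> int:
        return len(self.synapses)

    @property
    def n_tbars(self) -> int:
        return int(self.synapses["tbar_id"].nunique())
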