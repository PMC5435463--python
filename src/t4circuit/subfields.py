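"""Anatomical subfield centres and offsets on the column lattice.

A presynaptic type's *anatomical subfield centre* for one T4 is the centre
of mass of its cells' home columns on the ideal hexagonal array, weighted
by the PSD count each cell makes onto that T4.  Offsets are reported
relative to the Mi1 centre of the same T4, in ommatidial units.

For multicolumnar Tm3 cells, which have no home column, a cell-level field
centre is first derived from the cell's L1 inputs (assumed to originate on
the regular hexagonal grid), weighted by L1 synapse counts; the T4-level
Tm3 centre is then the PSD-count-weighted mean of those per-cell centres.
Partially reconstructed cells bias this estimate because they lose synapse
count; the *adjusted* mode divides each cell's weight by its completeness
(inverse-completeness reweighting), which removes the bias when synapse
loss is uniform over the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .connectivity import per_column_counts
from .hexgrid import CartPoint, HexCoord, weighted_centroid
from .model import CellType, ConnectomeDataset

__all__ = [
    "SubfieldResult",
    "OffsetVector",
    "subfield_centre",
    "offset_from_mi1",
    "l1_field_centre",
    "tm3_mi1_offset",
    "offset_alignment",
    "subfield_report",
]


@dataclass(frozen=True)
class SubfieldResult:
    """Synapse-weighted subfield centre of one input type for one T4."""

    t4_id: str
    pre_type: CellType
    centre: CartPoint
    column_weights: dict[HexCoord, float]
    n_synapses: int


@dataclass(frozen=True)
class OffsetVector:
    """Displacement between two subfield centres, in ommatidial units."""

    dx: float
    dy: float
    mode: str = "raw"  # 'raw' | 'adjusted'

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dx) and math.isfinite(self.dy)):
            raise ValueError("offset must be finite")
        if self.mode not in ("raw", "adjusted"):
            raise ValueError(f"unknown offset mode {self.mode!r}")

    @property
    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)


def subfield_centre(
    dataset: ConnectomeDataset,
    t4_id: str,
    pre_type: CellType | str,
) -> SubfieldResult:
    """Centre of mass of an input type's home columns, weighted by the PSD
    count each presynaptic cell makes onto the T4.

    The type must be column-assignable (unicolumnar, or CT1 via its
    per-column terminal units).  Apply
    :func:`~t4circuit.connectivity.exclude_weak` first to reproduce
    analyses that drop single-synapse connections.
    """
    t = CellType(pre_type)
    counts = per_column_counts(dataset, t4_id, t)
    if not counts:
        raise ValueError(f"{t4_id!r} has no inputs of type {t.value}")
    centre = weighted_centroid(list(counts.items()))
    return SubfieldResult(
        t4_id=t4_id,
        pre_type=t,
        centre=centre,
        column_weights={c: float(n) for c, n in counts.items()},
        n_synapses=int(sum(counts.values())),
    )


def offset_from_mi1(
    dataset: ConnectomeDataset,
    t4_id: str,
    pre_type: CellType | str,
) -> OffsetVector:
    """Displacement of a type's subfield centre from the Mi1 centre of the
    same T4 (Mi1 itself maps to the zero vector)."""
    mi1 = subfield_centre(dataset, t4_id, CellType.Mi1)
    other = subfield_centre(dataset, t4_id, pre_type)
    return OffsetVector(
        dx=other.centre.x - mi1.centre.x, dy=other.centre.y - mi1.centre.y
    )


def l1_field_centre(dataset: ConnectomeDataset, cell_id: str) -> CartPoint:
    """Field centre of a cell derived from its L1 inputs.

    The centre of mass of the presynaptic L1 cells' home columns (L1 is
    strictly one per column on the regular grid), weighted by their synapse
    counts onto the cell.  This is how a field centre is assigned to
    multicolumnar cells that have no home column of their own.
    """
    syn = dataset.synapses_onto(cell_id)
    weights: dict[HexCoord, float] = {}
    for pre_id, n in syn["pre_id"].value_counts().items():
        pre = dataset.neuron(pre_id)
        if pre.cell_type != CellType.L1:
            continue
        if pre.home_column is None:
            raise ValueError(f"L1 neuron {pre_id!r} has no home column")
        weights[pre.home_column] = weights.get(pre.home_column, 0.0) + float(n)
    if not weights:
        raise ValueError(f"neuron {cell_id!r} receives no L1 inputs")
    return weighted_centroid(list(weights.items()))


def _weighted_mean_of_centres(
    dataset: ConnectomeDataset,
    t4_id: str,
    pre_type: CellType,
    adjusted: bool,
) -> CartPoint:
    syn = dataset.synapses_onto(t4_id)
    pts: list[np.ndarray] = []
    ws: list[float] = []
    for pre_id, n in sorted(syn["pre_id"].value_counts().items()):
        pre = dataset.neuron(pre_id)
        if pre.cell_type != pre_type:
            continue
        w = float(n)
        if adjusted:
            if pre.completeness is None:
                raise ValueError(
                    f"adjusted mode requires a completeness estimate for "
                    f"{pre_id!r}"
                )
            w /= pre.completeness
        pts.append(np.array(l1_field_centre(dataset, pre_id)))
        ws.append(w)
    if not pts:
        raise ValueError(f"{t4_id!r} has no {pre_type.value} inputs")
    w_arr = np.array(ws)
    centre = (w_arr[:, None] * np.vstack(pts)).sum(axis=0) / w_arr.sum()
    return CartPoint(float(centre[0]), float(centre[1]))


def tm3_mi1_offset(
    dataset: ConnectomeDataset, t4_id: str, mode: str = "raw"
) -> OffsetVector:
    """Tm3-to-Mi1 field-centre offset for one T4, from L1-derived centres.

    Both the Mi1 and the Tm3 field centres are synapse-count-weighted means
    of the contributing cells' L1-derived field centres.  In ``adjusted``
    mode each cell's weight is its PSD count divided by its completeness,
    compensating the synapse loss of partially reconstructed cells (most
    Tm3s extend beyond a finite imaged volume).
    """
    if mode not in ("raw", "adjusted"):
        raise ValueError(f"mode must be 'raw' or 'adjusted', got {mode!r}")
    adjusted = mode == "adjusted"
    tm3 = _weighted_mean_of_centres(dataset, t4_id, CellType.Tm3, adjusted)
    mi1 = _weighted_mean_of_centres(dataset, t4_id, CellType.Mi1, adjusted)
    return OffsetVector(dx=tm3.x - mi1.x, dy=tm3.y - mi1.y, mode=mode)


def offset_alignment(
    offset: OffsetVector, preferred_direction: float | tuple[float, float]
) -> float:
    """Cosine of the angle between an offset and a preferred direction.

    +1 along the PD, -1 opposite, 0 orthogonal; NaN (undefined) for a
    zero-length offset.  ``preferred_direction`` is an angle in radians or
    a direction vector.
    """
    if isinstance(preferred_direction, (tuple, list, np.ndarray)):
        px, py = float(preferred_direction[0]), float(preferred_direction[1])
    else:
        px, py = math.cos(preferred_direction), math.sin(preferred_direction)
    norm_pd = math.hypot(px, py)
    if norm_pd == 0:
        raise ValueError("preferred direction must be non-zero")
    if offset.magnitude == 0:
        return float("nan")
    return (offset.dx * px + offset.dy * py) / (offset.magnitude * norm_pd)


def subfield_report(
    dataset: ConnectomeDataset,
    t4_ids: Iterable[str],
    pre_types: Iterable[CellType | str],
    path: Optional[str | Path] = None,
    header_lines: Iterable[str] = (),
) -> list[dict]:
    """Per-(T4, type) subfield centres and Mi1-referenced offsets.

    Returns records with t4_id, pre_type, cx, cy, dx, dy, n_synapses and
    optionally writes them as TSV.
    """
    rows: list[dict] = []
    for t4_id in t4_ids:
        try:
            mi1 = subfield_centre(dataset, t4_id, CellType.Mi1)
        except ValueError:
            continue
        for t in pre_types:
            try:
                res = subfield_centre(dataset, t4_id, t)
            except ValueError:
                continue
            rows.append(
                {
                    "t4_id": t4_id,
                    "subtype": dataset.cell_type_of(t4_id).value[-1],
                    "pre_type": CellType(t).value,
                    "cx": res.centre.x,
                    "cy": res.centre.y,
                    "dx": res.centre.x - mi1.centre.x,
                    "dy": res.centre.y - mi1.centre.y,
                    "mode": "raw",
                    "n_synapses": res.n_synapses,
                }
            )
    if path is not None:
        import pandas as pd

        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pd.DataFrame(
                rows,
                columns=[
                    "t4_id",
                    "subtype",
                    "pre_type",
                    "cx",
                    "cy",
                    "dx",
                    "dy",
                    "mode",
                    "n_synapses",
                ],
            ).to_csv(fh, sep="\t", index=False)
    return rows
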