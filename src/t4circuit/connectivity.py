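"""Connection counting, input fractions, per-column maps and strength bins.

All counts are PSD-level (one synapse-table row = one postsynaptic density =
one countable input).  A "connection" is an ordered (presynaptic cell,
postsynaptic cell) pair with its PSD count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .hexgrid import HexCoord
from .model import CellType, ConnectomeDataset, MULTICOLUMNAR_TYPES

__all__ = [
    "count_connection",
    "connection_counts",
    "input_fractions",
    "exclude_weak",
    "per_column_counts",
    "bin_strength",
    "percent_increase",
    "type_connectivity_matrix",
    "ConnectivityMatrix",
]


def count_connection(dataset: ConnectomeDataset, pre_id: str, post_id: str) -> int:
    """PSD count of the (pre, post) connection (0 if none)."""
    dataset.neuron(pre_id)
    dataset.neuron(post_id)
    syn = dataset.synapses
    return int(((syn["pre_id"] == pre_id) & (syn["post_id"] == post_id)).sum())


def connection_counts(dataset: ConnectomeDataset) -> pd.DataFrame:
    """All (pre_id, post_id) pairs with their PSD counts."""
    return (
        dataset.synapses.groupby(["pre_id", "post_id"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )


def exclude_weak(dataset: ConnectomeDataset, min_synapses: int = 2) -> ConnectomeDataset:
    """Drop every connection with fewer than ``min_synapses`` PSDs.

    With the default threshold of 2, single-synapse connections — too weak
    to interpret — are removed, as in the published per-column plots.
    Returns a dataset view sharing neurons and skeletons.
    """
    if min_synapses < 1:
        raise ValueError("min_synapses must be >= 1")
    if min_synapses == 1 or not len(dataset.synapses):
        return dataset.with_synapses(dataset.synapses)
    syn = dataset.synapses
    sizes = syn.groupby(["pre_id", "post_id"])["tbar_id"].transform("size")
    return dataset.with_synapses(syn[sizes >= min_synapses])


def input_fractions(
    dataset: ConnectomeDataset, post_id: str, min_synapses: int = 1
) -> dict[CellType, float]:
    """Fraction of a cell's synaptic inputs contributed by each cell type.

    ``min_synapses`` drops connections below the threshold *before* the
    fractions are computed; the returned fractions sum to 1 over the
    included synapses.
    """
    view = exclude_weak(dataset, min_synapses) if min_synapses > 1 else dataset
    syn = view.synapses_onto(post_id)
    if not len(syn):
        raise ValueError(f"neuron {post_id!r} has no synaptic inputs (after threshold)")
    types = syn["pre_id"].map(lambda i: dataset.cell_type_of(i))
    counts = types.value_counts()
    total = int(counts.sum())
    return {CellType(t): int(n) / total for t, n in counts.items()}


def per_column_counts(
    dataset: ConnectomeDataset, post_id: str, pre_type: CellType | str
) -> dict[HexCoord, int]:
    """Synaptic input counts to one cell from a column-assignable type,
    keyed by the presynaptic cells' home columns.

    Multicolumnar types (Tm3, TmY15) cannot be assigned to single columns
    and are rejected.
    """
    t = CellType(pre_type)
    if t in MULTICOLUMNAR_TYPES:
        raise ValueError(
            f"{t.value} cells cannot be assigned to a particular column "
            "(multicolumnar); per-column counts are undefined"
        )
    syn = dataset.synapses_onto(post_id)
    out: dict[HexCoord, int] = {}
    for pre_id, n in syn["pre_id"].value_counts().items():
        neuron = dataset.neuron(pre_id)
        if neuron.cell_type != t:
            continue
        if neuron.home_column is None:
            raise ValueError(
                f"{t.value} neuron {pre_id!r} has no home column assignment"
            )
        out[neuron.home_column] = out.get(neuron.home_column, 0) + int(n)
    return out


def bin_strength(count: int) -> str:
    """Connection-strength bin: <10 weak, 10-20 (inclusive) medium, >20 strong."""
    if count < 0:
        raise ValueError("synapse count cannot be negative")
    if count < 10:
        return "weak"
    if count <= 20:
        return "medium"
    return "strong"


def percent_increase(new_counts: Sequence[float], old_counts: Sequence[float]) -> int:
    """Percent change of summed counts, rounded to the nearest integer.

    E.g. the four per-subtype Mi1+Tm3 totals of a denser reconstruction
    against an earlier one: ([116, 109, 113, 104], [97, 69, 85, 81]) -> 33.
    """
    old = float(np.sum(old_counts))
    if old <= 0:
        raise ValueError("old counts sum to zero; percent change undefined")
    new = float(np.sum(new_counts))
    return int(round(100.0 * (new / old - 1.0)))


@dataclass
class ConnectivityMatrix:
    """Integer PSD-count matrix between ordered pre and post labels."""

    table: pd.DataFrame  # rows = pre labels, columns = post labels
    min_synapses: int = 1

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates or self.table.columns.has_duplicates:
            raise ValueError("matrix labels must be unique")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("matrix counts must be non-negative")

    def count(self, pre: str, post: str) -> int:
        return int(self.table.loc[pre, post])

    def strength_bins(self) -> pd.DataFrame:
        return self.table.map(lambda n: bin_strength(int(n)) if n > 0 else "none")

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index_label="pre\\post")

    @property
    def total(self) -> int:
        return int(self.table.to_numpy().sum())


def type_connectivity_matrix(
    dataset: ConnectomeDataset,
    pre_types: Optional[Sequence[CellType | str]] = None,
    post_types: Optional[Sequence[CellType | str]] = None,
    min_synapses: int = 1,
) -> ConnectivityMatrix:
    """Cell-type x cell-type PSD-count matrix (T4 subtypes pooled as 'T4').

    ``min_synapses`` thresholds at the *cell pair* level before pooling by
    type, so weak pairs never contribute.
    """
    view = exclude_weak(dataset, min_synapses) if min_synapses > 1 else dataset
    pairs = connection_counts(view)

    def type_label(cid: str) -> str:
        t = dataset.cell_type_of(cid)
        return "T4" if t.is_t4 else t.value

    pairs = pairs.assign(
        pre_type=pairs["pre_id"].map(type_label),
        post_type=pairs["post_id"].map(type_label),
    )
    mat = pairs.pivot_table(
        index="pre_type", columns="post_type", values="count", aggfunc="sum", fill_value=0
    ).astype(int)

    def _order(requested, found):
        if requested is None:
            return sorted(found)
        labels = ["T4" if CellType(t).is_t4 else CellType(t).value for t in requested]
        seen: list[str] = []
        for lab in labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    rows = _order(pre_types, mat.index)
    cols = _order(post_types, mat.columns)
    mat = mat.reindex(index=rows, columns=cols, fill_value=0)
    return ConnectivityMatrix(table=mat, min_synapses=min_synapses)
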