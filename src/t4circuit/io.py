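"""Readers and writers for the formats the pipeline touches.

SWC for skeletons, CSV/TSV for synapse and neuron tables, JSON for the
dataset manifest and ground truth.  All I/O is loss-free round-trip for
finite decimal inputs; malformed rows are reported with line numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .hexgrid import ColumnLattice, HexCoord
from .model import (
    Box,
    CellType,
    ConnectomeDataset,
    GroundTruth,
    MULTICOLUMNAR_TYPES,
    Neuron,
    SYNAPSE_COLUMNS,
    Skeleton,
    make_synapse_table,
)

__all__ = [
    "FormatError",
    "read_synapse_table",
    "write_synapse_table",
    "read_neuron_table",
    "write_neuron_table",
    "read_swc",
    "write_swc",
    "save_dataset",
    "load_dataset",
    "validate",
    "ValidationReport",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# synapse table


def read_synapse_table(path: str | Path, allow_autapses: bool = False) -> pd.DataFrame:
    """Read a synapse table (one row = one PSD).

    Requires the header columns ``pre_id, post_id, tbar_id, x, y, z``.
    Non-numeric coordinates are reported with their line numbers; autapses
    (pre_id == post_id) are rejected unless ``allow_autapses``.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in SYNAPSE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    bad_lines: list[str] = []
    coords = {}
    for c in ("x", "y", "z"):
        vals = pd.to_numeric(df[c], errors="coerce")
        for i in np.flatnonzero(vals.isna().to_numpy()):
            # +2: one for the header line, one for 1-based numbering
            bad_lines.append(f"line {i + 2}: non-numeric {c}={df[c].iloc[i]!r}")
        coords[c] = vals
    if bad_lines:
        raise FormatError(f"{path}: malformed rows:\n" + "\n".join(bad_lines))
    out = df[SYNAPSE_COLUMNS].copy()
    for c in ("x", "y", "z"):
        out[c] = coords[c].astype(float)
    if not allow_autapses:
        aut = out["pre_id"] == out["post_id"]
        if aut.any():
            first = int(np.flatnonzero(aut.to_numpy())[0])
            raise FormatError(
                f"{path}: autapse at line {first + 2} "
                f"(pre_id == post_id == {out['pre_id'].iloc[first]!r}); "
                "pass allow_autapses=True to accept"
            )
    return out.reset_index(drop=True)


def write_synapse_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SYNAPSE_COLUMNS].to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# neuron table

NEURON_COLUMNS = ["id", "cell_type", "home_q", "home_r", "completeness", "parent_id"]


def write_neuron_table(neurons: dict[str, Neuron], path: str | Path) -> None:
    rows = []
    for nid in sorted(neurons):
        n = neurons[nid]
        rows.append(
            {
                "id": n.id,
                "cell_type": n.cell_type.value,
                "home_q": "" if n.home_column is None else n.home_column.q,
                "home_r": "" if n.home_column is None else n.home_column.r,
                "completeness": "" if n.completeness is None else repr(n.completeness),
                "parent_id": n.parent_id or "",
            }
        )
    pd.DataFrame(rows, columns=NEURON_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_neuron_table(path: str | Path) -> dict[str, Neuron]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in ("id", "cell_type") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    neurons: dict[str, Neuron] = {}
    for i, row in df.iterrows():
        home = None
        if row.get("home_q", "") != "" and row.get("home_r", "") != "":
            home = HexCoord(int(row["home_q"]), int(row["home_r"]))
        comp = None
        if row.get("completeness", "") != "":
            comp = float(row["completeness"])
        try:
            n = Neuron(
                id=row["id"],
                cell_type=CellType(row["cell_type"]),
                home_column=home,
                completeness=comp,
                parent_id=row.get("parent_id") or None,
            )
        except ValueError as e:
            raise FormatError(f"{path}: line {i + 2}: {e}") from None
        if n.id in neurons:
            raise FormatError(f"{path}: line {i + 2}: duplicate neuron id {n.id!r}")
        neurons[n.id] = n
    return neurons


# ---------------------------------------------------------------------------
# SWC


def read_swc(path: str | Path) -> Skeleton:
    """Read a standard SWC file (1-based ids, parent -1 for the root, µm)."""
    ids, parents, xyz, radius = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise FormatError(
                    f"{path}: line {lineno}: expected 7 whitespace-separated "
                    f"fields, got {len(parts)}"
                )
            try:
                ids.append(int(parts[0]))
                xyz.append((float(parts[2]), float(parts[3]), float(parts[4])))
                radius.append(float(parts[5]))
                parents.append(int(parts[6]))
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
    if not ids:
        raise FormatError(f"{path}: empty SWC file")
    try:
        return Skeleton(np.array(ids), np.array(parents), np.array(xyz), np.array(radius))
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from None


def write_swc(skeleton: Skeleton, path: str | Path, structure_type: int = 3) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(skeleton.n_nodes):
            x, y, z = (float(v) for v in skeleton.xyz[k])
            fh.write(
                f"{int(skeleton.node_ids[k])} {structure_type} {x!r} {y!r} {z!r} "
                f"{float(skeleton.radius[k])!r} {int(skeleton.parent_ids[k])}\n"
            )


# ---------------------------------------------------------------------------
# dataset directory


def save_dataset(
    dataset: ConnectomeDataset,
    directory: str | Path,
    provenance: Optional[dict] = None,
) -> Path:
    """Write a dataset as a directory of plain-text files plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.lattice.to_tsv(directory / "lattice.tsv")
    write_neuron_table(dataset.neurons, directory / "neurons.tsv")
    write_synapse_table(dataset.synapses, directory / "synapses.tsv")
    manifest: dict = {
        "lattice": "lattice.tsv",
        "neurons": "neurons.tsv",
        "synapses": "synapses.tsv",
        "volume_bounds": dataset.volume_bounds.to_dict(),
        "skeletons": {},
    }
    if dataset.skeletons:
        (directory / "skeletons").mkdir(exist_ok=True)
        for sid in sorted(dataset.skeletons):
            rel = f"skeletons/{sid}.swc"
            write_swc(dataset.skeletons[sid], directory / rel)
            manifest["skeletons"][sid] = rel
    if dataset.ground_truth is not None:
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(dataset.ground_truth.to_dict(), fh, indent=1)
        manifest["ground_truth"] = "ground_truth.json"
    if provenance:
        manifest["provenance"] = provenance
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return directory


def load_dataset(directory: str | Path, allow_autapses: bool = False) -> ConnectomeDataset:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    lattice = ColumnLattice.from_tsv(directory / manifest["lattice"])
    neurons = read_neuron_table(directory / manifest["neurons"])
    synapses = read_synapse_table(
        directory / manifest["synapses"], allow_autapses=allow_autapses
    )
    skeletons = {
        sid: read_swc(directory / rel)
        for sid, rel in manifest.get("skeletons", {}).items()
    }
    gt = None
    if "ground_truth" in manifest:
        with open(directory / manifest["ground_truth"]) as fh:
            gt = GroundTruth.from_dict(json.load(fh))
    return ConnectomeDataset(
        neurons=neurons,
        synapses=synapses,
        lattice=lattice,
        volume_bounds=Box.from_dict(manifest["volume_bounds"]),
        skeletons=skeletons,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Findings of a dataset audit; a report, never an exception."""

    findings: list[dict] = field(default_factory=list)

    def add(self, kind: str, message: str, subject: str = "") -> None:
        self.findings.append({"kind": kind, "subject": subject, "message": message})

    @property
    def ok(self) -> bool:
        return not self.findings

    def by_kind(self, kind: str) -> list[dict]:
        return [f for f in self.findings if f["kind"] == kind]

    def __len__(self) -> int:
        return len(self.findings)


def validate(dataset: ConnectomeDataset) -> ValidationReport:
    """Audit a dataset: dangling synapse references, out-of-bounds synapse
    locations, column-assignment violations, autapses, home columns outside
    the lattice."""
    report = ValidationReport()
    syn = dataset.synapses
    known = set(dataset.neurons)
    for col in ("pre_id", "post_id"):
        for cid in sorted(set(syn[col]) - known):
            report.add(
                "dangling_reference",
                f"synapse {col} {cid!r} does not resolve to a neuron",
                subject=cid,
            )
    if len(syn):
        inside = dataset.volume_bounds.contains(syn[["x", "y", "z"]].to_numpy())
        for i in np.flatnonzero(~inside):
            report.add(
                "out_of_bounds",
                f"synapse row {i} at "
                f"({syn['x'].iloc[i]}, {syn['y'].iloc[i]}, {syn['z'].iloc[i]}) "
                "lies outside the volume bounds",
                subject=str(syn["tbar_id"].iloc[i]),
            )
        aut = syn["pre_id"] == syn["post_id"]
        for i in np.flatnonzero(aut.to_numpy()):
            report.add(
                "autapse",
                f"synapse row {i}: pre_id == post_id == {syn['pre_id'].iloc[i]!r}",
                subject=str(syn["pre_id"].iloc[i]),
            )
    for nid in sorted(dataset.neurons):
        n = dataset.neurons[nid]
        if n.cell_type in MULTICOLUMNAR_TYPES and n.home_column is not None:
            report.add(
                "invariant_violation",
                f"{n.cell_type.value} neuron {nid!r} carries a home column but "
                "is multicolumnar",
                subject=nid,
            )
        if n.home_column is not None and n.home_column not in dataset.lattice:
            report.add(
                "home_outside_lattice",
                f"neuron {nid!r} home column {tuple(n.home_column)} is not in "
                "the lattice",
                subject=nid,
            )
    return report
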