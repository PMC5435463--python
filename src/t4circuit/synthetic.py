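"""Seeded generator of toy connectomes with the structure the analyses assume.

The generator emulates, at desk scale, the features of the seven-column
medulla reconstruction that the pipeline's statistics rest on:

* a hexagonal disc of retinotopic columns (Home + A-F at radius 1);
* eight input cell types with per-column synapse-weight templates onto T4;
* polyadic T-bars (one presynaptic ribbon, several PSDs);
* synapse placement along T4 dendrites following per-type profiles over
  normalized dendritic path position (tip-, base- or shaft-biased);
* four T4 subtypes whose dendrites extend along four cardinal axes over
  roughly 2-3 column spacings (opposite to the preferred direction);
* multicolumnar Tm3 cells whose anatomical field centre is defined by their
  L1 inputs, not a home column;
* volume truncation producing partially reconstructed cells with known
  ground-truth completeness (a geometric box cut, and a per-cell uniform
  thinning model under which inverse-completeness reweighting is unbiased).

Every generated quantity that an analysis later estimates (field centres,
offsets, subtype, preferred direction, completeness) is recorded exactly in
the dataset's :class:`~t4circuit.model.GroundTruth`.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .hexgrid import (
    AXIAL_DIRECTIONS,
    CartPoint,
    ColumnLattice,
    HexCoord,
    axial_to_cart,
    hex_disc,
    ring_of,
)
from .model import (
    ARBOR_AXES,
    Box,
    CellType,
    ConnectomeDataset,
    GroundTruth,
    Neuron,
    PD_VECTORS,
    Skeleton,
    T4_SUBTYPE_ORDER,
    make_synapse_table,
)

__all__ = [
    "TypeTemplate",
    "CircuitTemplate",
    "default_template",
    "make_lattice",
    "make_t4",
    "make_circuit",
    "truncate",
    "thin_cells",
    "completeness_ladder",
    "COMPLETENESS_LADDER",
    "DEFAULT_COLUMN_SPACING_UM",
]

DEFAULT_COLUMN_SPACING_UM = 8.0

#: Completeness regime of the eight partially reconstructed Tm3 cells
#: feeding one fully contained T4 (per cent / 100).
COMPLETENESS_LADDER: tuple[float, ...] = (1.0, 1.0, 0.94, 0.85, 0.72, 0.61, 0.49, 0.42)


# ---------------------------------------------------------------------------
# templates


@dataclass
class TypeTemplate:
    """Generator parameters for one presynaptic cell type.

    fraction
        Share of a T4's total synaptic inputs contributed by this type.
    profile
        Beta(a, b) over normalized dendritic path position in [0, 1]
        (0 = base/trunk, 1 = dendritic tip).
    sign
        Putative transmitter sign: '+' excitatory, '-' inhibitory,
        '?' undetermined.
    shift
        Planted displacement of the type's subfield centre along the T4's
        arbour axis, in ommatidial units (columnar and t4 placements).
    ring_frac
        Mass spread symmetrically over the six ring-1 columns (contributes
        no net displacement).
    placement
        'columnar' (one cell per column, weight map over column offsets),
        'pool' (multicolumnar cells selected by field-centre proximity),
        't4' (same-subtype T4 partners on the tip side), or 'unknown'
        (unidentified profiles with no home column).
    psds_per_tbar
        Mean PSDs per presynaptic T-bar; group sizes are 1 + Poisson(mean-1).
    """

    fraction: float
    profile: tuple[float, float] = (2.0, 2.0)
    sign: str = "?"
    shift: float = 0.0
    ring_frac: float = 0.0
    placement: str = "columnar"
    psds_per_tbar: float = 6.0

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError("fraction must be non-negative")
        if self.profile[0] <= 0 or self.profile[1] <= 0:
            raise ValueError("Beta profile parameters must be positive")


@dataclass
class CircuitTemplate:
    """Full generator configuration.

    The per-type fractions loosely follow the measured T4 input composition
    (Mi1 ~0.35, Tm3 ~0.16, Mi9 ~0.13, ...); spatial profiles are Beta
    distributions realizing the qualitative tip/shaft/base pattern.  All
    values are generator defaults, never assertions about real data.
    """

    types: dict[CellType, TypeTemplate]
    n_inputs_per_t4: int = 300
    tm3_per_t4: int = 8
    tm3_l1_inputs: int = 120  # Tm3 cells collect L1 input over several columns
    tm3_shift: float = 0.35  # target of the Tm3 field centre along the arbour axis
    tm3_kernel_sigma: float = 0.8
    tm3_select_sigma: float = 0.6
    mi1_l1_inputs: int = 30
    column_spacing_um: float = DEFAULT_COLUMN_SPACING_UM

    def support_radius(self) -> int:
        """Largest hex ring touched by any columnar/t4 weight map."""
        r = 0
        for t, tt in self.types.items():
            if tt.placement in ("columnar", "t4"):
                if tt.ring_frac > 0 or abs(tt.shift) > 1e-12 or tt.placement == "t4":
                    r = max(r, 1)
        return r


def default_template(
    n_inputs_per_t4: int = 300,
    mi9_sign: str = "-",
    mi9_shift: float = 0.70,
    tm3_shift: float = 0.35,
) -> CircuitTemplate:
    """The study-condition template.

    Mi9's transmitter sign is tentative; it is a parameter here (default
    inhibitory) and both signs are runnable.  ``mi9_shift`` is the planted
    displacement of the Mi9 subfield from the T4 home column along the
    arbour axis (tip side); Mi1 sits mid-shaft at 0.35.
    """
    types = {
        CellType.Mi1: TypeTemplate(0.35, (2.0, 2.0), "+", shift=0.35, ring_frac=0.30),
        CellType.Tm3: TypeTemplate(0.16, (2.0, 2.0), "+", placement="pool"),
        CellType.Mi9: TypeTemplate(0.13, (5.0, 1.5), mi9_sign, shift=mi9_shift),
        CellType.Mi4: TypeTemplate(0.06, (1.5, 5.0), "-", ring_frac=0.20),
        CellType.C3: TypeTemplate(0.04, (1.5, 5.0), "-", ring_frac=0.20),
        CellType.CT1: TypeTemplate(0.08, (1.5, 5.0), "-", ring_frac=0.20),
        CellType.TmY15: TypeTemplate(0.07, (2.0, 2.0), "-", placement="pool"),
        CellType.T4a: TypeTemplate(0.06, (5.0, 1.5), "+", placement="t4"),
        CellType.Mi10: TypeTemplate(0.006, (2.0, 2.0), "?"),
        CellType.unknown: TypeTemplate(0.044, (2.0, 2.0), "?", placement="unknown"),
    }
    return CircuitTemplate(
        types=types, n_inputs_per_t4=n_inputs_per_t4, tm3_shift=tm3_shift
    )


# ---------------------------------------------------------------------------
# randomness: one global seed, per-cell streams by stable hashing


def cell_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-cell random stream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# lattice and skeletons


def make_lattice(radius: int) -> ColumnLattice:
    """Hex disc of columns; radius 1 reproduces the 7-column geometry."""
    return ColumnLattice.disc(radius)


def make_t4(
    subtype: CellType | str,
    column: HexCoord | tuple[int, int],
    seed: int,
    spacing_um: float = DEFAULT_COLUMN_SPACING_UM,
    n_branches: int = 4,
    extent_columns: tuple[float, float] = (2.1, 2.6),
) -> tuple[Neuron, Skeleton]:
    """Generate a T4 neuron and its rooted dendritic skeleton.

    The trunk (SWC root) sits at the column centre; branches fan out
    predominantly along the subtype's arbour axis, spanning ~2-3 column
    spacings along it and much less orthogonally.  Dendrites extend
    opposite to the preferred direction (tips on the null-direction side).
    """
    sub = CellType(subtype if str(subtype).startswith("T4") else f"T4{subtype}")
    if sub not in ARBOR_AXES:
        raise ValueError(f"not a T4 subtype: {subtype!r}")
    col = HexCoord(*column)
    cid = f"{sub.value}_{col.q}_{col.r}"
    rng = cell_rng(seed, cid)
    cx, cy = axial_to_cart(col)
    root = np.array([cx * spacing_um, cy * spacing_um, 2.5])
    axis_angle = math.atan2(*ARBOR_AXES[sub][::-1])

    ids = [1]
    parents = [-1]
    pts = [root]
    step = 1.2  # µm between consecutive nodes
    fan = np.deg2rad([-15.0, -5.0, 5.0, 15.0])[:n_branches]
    next_id = 2
    for bi, dtheta in enumerate(fan):
        extent = rng.uniform(*extent_columns) * spacing_um
        n_nodes = max(3, int(round(extent / step)))
        theta = axis_angle + dtheta
        parent = 1
        pos = root.copy()
        for k in range(n_nodes):
            jitter = rng.normal(0.0, 0.12, size=2)
            zjit = rng.normal(0.0, 0.15)
            pos = pos + np.array(
                [
                    step * math.cos(theta) + jitter[0],
                    step * math.sin(theta) + jitter[1],
                    zjit,
                ]
            )
            ids.append(next_id)
            parents.append(parent)
            pts.append(pos.copy())
            parent = next_id
            next_id += 1
    skel = Skeleton(
        np.array(ids), np.array(parents), np.vstack(pts), np.full(len(ids), 0.25)
    )
    neuron = Neuron(id=cid, cell_type=sub, home_column=col, skeleton_id=cid)
    return neuron, skel


# ---------------------------------------------------------------------------
# per-type column weight maps


def _axis_columns(axis: tuple[float, float]) -> list[tuple[HexCoord, float]]:
    """Ring-1 columns realizing a unit displacement along a cardinal axis.

    ±x is itself a lattice direction; ±y is realized by splitting mass over
    the two flanking 60-degree neighbours (combined centroid sqrt(3)/2 per
    unit mass along ±y).
    """
    ax, ay = axis
    if abs(ay) < 1e-12:
        c = HexCoord(1, 0) if ax > 0 else HexCoord(-1, 0)
        return [(c, 1.0)]
    if ay > 0:
        return [(HexCoord(0, 1), 0.5), (HexCoord(-1, 1), 0.5)]
    return [(HexCoord(0, -1), 0.5), (HexCoord(1, -1), 0.5)]


def _axis_projection(axis: tuple[float, float]) -> float:
    """Displacement per unit mass moved onto the axis columns."""
    cols = _axis_columns(axis)
    vx = sum(w * axial_to_cart(c).x for c, w in cols)
    vy = sum(w * axial_to_cart(c).y for c, w in cols)
    return math.hypot(vx, vy)


def columnar_weights(
    subtype: CellType, shift: float, ring_frac: float
) -> dict[HexCoord, float]:
    """Column-offset weight map with exact planted centroid shift·(arbour axis).

    Mass layout: a symmetric ring-1 fraction (zero net displacement), a
    directed mass on the axis column(s) producing exactly the requested
    shift, and the remainder on the home column.
    """
    axis = ARBOR_AXES[subtype]
    weights: dict[HexCoord, float] = {d: ring_frac / 6.0 for d in AXIAL_DIRECTIONS}
    weights[HexCoord(0, 0)] = 0.0
    if abs(shift) > 1e-12:
        # negative shift: place the directed mass on the opposite-side columns
        direction = axis if shift > 0 else (-axis[0], -axis[1])
        proj = _axis_projection(direction)
        m = abs(shift) / proj
        for c, w in _axis_columns(direction):
            weights[c] = weights.get(c, 0.0) + m * w
    total_moved = sum(weights.values())
    if total_moved > 1.0 + 1e-9:
        raise ValueError(
            f"ring_frac={ring_frac} + shift={shift} exceed unit mass for {subtype}"
        )
    weights[HexCoord(0, 0)] = 1.0 - total_moved
    return {c: w for c, w in weights.items() if w > 0}


def _weights_centroid(weights: dict[HexCoord, float]) -> CartPoint:
    tot = sum(weights.values())
    x = sum(w * axial_to_cart(c).x for c, w in weights.items()) / tot
    y = sum(w * axial_to_cart(c).y for c, w in weights.items()) / tot
    return CartPoint(x, y)


# ---------------------------------------------------------------------------
# circuit generation


def _place_on_skeleton(
    skel: Skeleton, u: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Map normalized path positions to node coordinates (plus sub-µm jitter)."""
    d = skel.path_distances()
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    targets = u * d_sorted[-1]
    pos = np.searchsorted(d_sorted, targets)
    pos = np.clip(pos, 0, len(d_sorted) - 1)
    left = np.clip(pos - 1, 0, len(d_sorted) - 1)
    pick = np.where(
        np.abs(d_sorted[left] - targets) < np.abs(d_sorted[pos] - targets), left, pos
    )
    idx = order[pick]
    return skel.xyz[idx] + rng.normal(0.0, 0.2, size=(len(idx), 3))


def _same_subtype_partner_columns(subtype: CellType) -> list[tuple[HexCoord, float]]:
    """Columns of presynaptic same-subtype T4s: the tip side (opposite PD)."""
    return _axis_columns(ARBOR_AXES[subtype])


@dataclass
class _Builder:
    """Mutable state while assembling one synthetic dataset."""

    neurons: dict[str, Neuron] = field(default_factory=dict)
    skeletons: dict[str, Skeleton] = field(default_factory=dict)
    rows: list[tuple] = field(default_factory=list)
    gt: GroundTruth = field(default_factory=GroundTruth)

    def add_neuron(self, n: Neuron) -> None:
        self.neurons[n.id] = n


def _col_id(t: CellType, c: HexCoord) -> str:
    return f"{t.value}_{c.q}_{c.r}"


def make_circuit(
    template: CircuitTemplate,
    lattice: ColumnLattice,
    seed: int,
    t4_columns: Optional[Sequence[HexCoord | tuple[int, int]]] = None,
    include_types: Optional[Iterable[CellType | str]] = None,
) -> ConnectomeDataset:
    """Generate a synthetic connectome with recorded ground truth.

    T4 neurons (with skeletons) are created in every lattice column; full
    input complements are generated only for T4s whose template weight maps
    fit inside the lattice (by default the interior columns), mirroring the
    real situation where only the central column's T4 dendrites are wholly
    contained in the imaged volume.

    ``include_types`` restricts which presynaptic types are generated (the
    support cells they need, e.g. L1, are always created); this keeps
    special-purpose simulation studies cheap.
    """
    rad_needed = template.support_radius()
    interior = [
        c
        for c in lattice.sorted_columns()
        if all(
            HexCoord(c.q + d.q, c.r + d.r) in lattice
            for d in hex_disc(rad_needed)
        )
    ]
    if t4_columns is None:
        t4_cols = interior
    else:
        t4_cols = [HexCoord(*c) for c in t4_columns]
        for c in t4_cols:
            for d in hex_disc(rad_needed):
                if HexCoord(c.q + d.q, c.r + d.r) not in lattice:
                    raise ValueError(
                        f"template weight map of T4 at {tuple(c)} references "
                        f"column {(c.q + d.q, c.r + d.r)} outside the lattice"
                    )
    wanted = (
        None
        if include_types is None
        else {CellType(t) for t in include_types}
    )

    def _want(t: CellType) -> bool:
        if wanted is None:
            return True
        if t in ARBOR_AXES:  # the t4-partner entry covers all four subtypes
            return any(s in wanted for s in ARBOR_AXES)
        return t in wanted

    spacing = template.column_spacing_um
    b = _Builder()

    # -- support and columnar cells --------------------------------------
    columnar_types = [
        t
        for t, tt in sorted(template.types.items(), key=lambda kv: kv[0].value)
        if tt.placement == "columnar" and _want(t)
    ]
    for c in lattice.sorted_columns():
        b.add_neuron(Neuron(id=_col_id(CellType.L1, c), cell_type=CellType.L1, home_column=c))
        for t in columnar_types:
            parent = "CT1" if t == CellType.CT1 else None
            b.add_neuron(
                Neuron(id=_col_id(t, c), cell_type=t, home_column=c, parent_id=parent)
            )
            b.gt.cell_centres[_col_id(t, c)] = axial_to_cart(c)

    # -- L1 -> Mi1 synapses (field-centre scaffolding) --------------------
    if CellType.Mi1 in columnar_types:
        for c in lattice.sorted_columns():
            mid = _col_id(CellType.Mi1, c)
            rng = cell_rng(seed, f"l1.{mid}")
            cart = axial_to_cart(c)
            loc = rng.normal(0.0, 0.5, size=(template.mi1_l1_inputs, 3)) + np.array(
                [cart.x * spacing, cart.y * spacing, 9.0]
            )
            for k in range(template.mi1_l1_inputs):
                b.rows.append(
                    (_col_id(CellType.L1, c), mid, "", loc[k, 0], loc[k, 1], loc[k, 2])
                )

    # -- Tm3 / TmY15 pools -------------------------------------------------
    tm3_ids: list[str] = []
    if CellType.Tm3 in template.types and _want(CellType.Tm3):
        tm3_ids = _make_tm3_pool(b, template, lattice, seed, spacing)
    tmy_ids: list[str] = []
    if CellType.TmY15 in template.types and _want(CellType.TmY15):
        for k in range(3):
            nid = f"TmY15_{k}"
            b.add_neuron(Neuron(id=nid, cell_type=CellType.TmY15))
            tmy_ids.append(nid)

    unknown_ids: list[str] = []
    if any(tt.placement == "unknown" and _want(t) for t, tt in template.types.items()):
        for k in range(3):
            nid = f"unk_{k}"
            b.add_neuron(Neuron(id=nid, cell_type=CellType.unknown))
            unknown_ids.append(nid)

    # -- T4 cells everywhere ----------------------------------------------
    for c in lattice.sorted_columns():
        for sub in T4_SUBTYPE_ORDER:
            neuron, skel = make_t4(sub, c, seed, spacing_um=spacing)
            b.add_neuron(neuron)
            b.skeletons[neuron.id] = skel
            b.gt.t4[neuron.id] = {
                "subtype": sub.value[-1],
                "column": [c.q, c.r],
                "arbor_axis": list(ARBOR_AXES[sub]),
                "pd": list(PD_VECTORS[sub]),
                "planted_centres": {},
            }

    # -- inputs for interior T4s ------------------------------------------
    for c in t4_cols:
        for sub in T4_SUBTYPE_ORDER:
            _make_t4_inputs(
                b, template, lattice, seed, c, sub, tm3_ids, tmy_ids, unknown_ids
            )

    # -- polyadic T-bar grouping ------------------------------------------
    rows = _group_tbars(b.rows, template, seed, {i: n.cell_type for i, n in b.neurons.items()})

    syn = make_synapse_table(rows)
    xy = np.array([axial_to_cart(c) for c in lattice.sorted_columns()])
    margin = 3.2 * spacing
    bounds = Box(
        (
            float(xy[:, 0].min() * spacing - margin),
            float(xy[:, 1].min() * spacing - margin),
            -2.0,
        ),
        (
            float(xy[:, 0].max() * spacing + margin),
            float(xy[:, 1].max() * spacing + margin),
            12.0,
        ),
    )
    for nid in b.neurons:
        b.gt.completeness[nid] = 1.0
    return ConnectomeDataset(
        neurons=b.neurons,
        synapses=syn,
        lattice=lattice,
        volume_bounds=bounds,
        skeletons=b.skeletons,
        ground_truth=b.gt,
    )


def _make_tm3_pool(
    b: _Builder,
    template: CircuitTemplate,
    lattice: ColumnLattice,
    seed: int,
    spacing: float,
) -> list[str]:
    """Two Tm3 cells per column at mirrored lateral offsets.

    Each Tm3's anatomical field centre is defined by its L1 inputs: weights
    over nearby columns follow a Gaussian kernel around the cell's latent
    position, and the exact weight centroid is recorded as ground truth.
    """
    cols = lattice.sorted_columns()
    col_cart = {c: axial_to_cart(c) for c in cols}
    delta = np.array([0.28, 0.12])
    sigma = template.tm3_kernel_sigma
    ids: list[str] = []
    k = 0
    for c in cols:
        for s in (+1, -1):
            nid = f"Tm3_{k}"
            k += 1
            centre_latent = np.array(col_cart[c]) + s * delta
            w = {}
            for c2 in cols:
                d2 = float(np.sum((np.array(col_cart[c2]) - centre_latent) ** 2))
                if d2 <= (2.0) ** 2:
                    w[c2] = math.exp(-d2 / (2.0 * sigma * sigma))
            centre = _weights_centroid(w)
            b.add_neuron(Neuron(id=nid, cell_type=CellType.Tm3))
            b.gt.cell_centres[nid] = centre
            ids.append(nid)
            # realized L1 -> Tm3 synapses
            rng = cell_rng(seed, f"l1.{nid}")
            wcols = sorted(w)
            probs = np.array([w[c2] for c2 in wcols])
            probs = probs / probs.sum()
            counts = rng.multinomial(template.tm3_l1_inputs, probs)
            loc_centre = np.array(
                [centre_latent[0] * spacing, centre_latent[1] * spacing, 9.0]
            )
            for c2, n in zip(wcols, counts):
                if n == 0:
                    continue
                loc = rng.normal(0.0, 0.6, size=(n, 3)) + loc_centre
                for j in range(n):
                    b.rows.append(
                        (_col_id(CellType.L1, c2), nid, "", loc[j, 0], loc[j, 1], loc[j, 2])
                    )
    return ids


def _recentre_weights(
    kernel: np.ndarray, centres: np.ndarray, target: np.ndarray
) -> np.ndarray:
    """Adjust selection weights so their expected centroid equals the target.

    The pool of multicolumnar cells is discrete, so raw kernel weights land
    the planted field centre only near the target; a minimal least-squares
    correction (subject to the centroid and normalization constraints, with
    non-negativity restored iteratively) pins it exactly, making the planted
    value a true ground truth rather than an approximation.  If the target
    is outside the convex hull of the pool centres the kernel weights are
    returned unchanged.
    """
    w = kernel.astype(float).copy()
    A = np.vstack([centres.T, np.ones(len(w))])  # 3 x n
    bvec = np.array([target[0], target[1], 1.0])
    for _ in range(20):
        lam, *_ = np.linalg.lstsq(A @ A.T, bvec - A @ w, rcond=None)
        w = w + A.T @ lam
        if np.all(w >= -1e-12):
            w = np.clip(w, 0.0, None)
            break
        w = np.clip(w, 0.0, None)
    w_sum = w.sum()
    if w_sum <= 0 or abs(w @ centres[:, 0] / w_sum - target[0]) > 1e-6 or abs(
        w @ centres[:, 1] / w_sum - target[1]
    ) > 1e-6:
        return kernel
    return w / w_sum


def _make_t4_inputs(
    b: _Builder,
    template: CircuitTemplate,
    lattice: ColumnLattice,
    seed: int,
    home: HexCoord,
    sub: CellType,
    tm3_ids: list[str],
    tmy_ids: list[str],
    unknown_ids: list[str],
) -> None:
    t4_id = f"{sub.value}_{home.q}_{home.r}"
    skel = b.skeletons[t4_id]
    home_cart = np.array(axial_to_cart(home))
    axis = np.array(ARBOR_AXES[sub])
    gt4 = b.gt.t4[t4_id]
    n_total = template.n_inputs_per_t4

    for t in sorted(template.types, key=lambda t: t.value):
        tt = template.types[t]
        if tt.placement == "columnar":
            if _col_id(t, home) not in b.neurons:
                continue  # excluded via include_types
        elif tt.placement == "pool":
            pool = tm3_ids if t == CellType.Tm3 else tmy_ids
            if not pool:
                continue
        elif tt.placement == "t4":
            if f"{sub.value}_0_0" not in b.neurons:
                continue
        elif tt.placement == "unknown" and not unknown_ids:
            continue
        n_type = int(round(tt.fraction * n_total))
        if n_type == 0:
            continue
        rng = cell_rng(seed, f"in.{t4_id}.{t.value}")
        u = rng.beta(tt.profile[0], tt.profile[1], size=n_type)
        locs = _place_on_skeleton(skel, u, rng)

        if tt.placement == "columnar":
            weights = columnar_weights(sub, tt.shift, tt.ring_frac)
            offs = sorted(weights)
            probs = np.array([weights[o] for o in offs])
            probs = probs / probs.sum()
            counts = rng.multinomial(n_type, probs)
            pres: list[str] = []
            for o, n in zip(offs, counts):
                col = HexCoord(home.q + o.q, home.r + o.r)
                pres.extend([_col_id(t, col)] * int(n))
            gt4["planted_centres"][t.value] = [
                home_cart[0] + tt.shift * axis[0],
                home_cart[1] + tt.shift * axis[1],
            ]
        elif tt.placement == "pool" and t == CellType.Tm3:
            target = home_cart + template.tm3_shift * axis
            centres = {j: np.array(b.gt.cell_centres[j]) for j in tm3_ids}
            d2 = {j: float(np.sum((c - target) ** 2)) for j, c in centres.items()}
            chosen = sorted(sorted(d2), key=lambda j: d2[j])[: template.tm3_per_t4]
            s2 = 2.0 * template.tm3_select_sigma**2
            kw = np.array([math.exp(-d2[j] / s2) for j in chosen])
            kw = kw / kw.sum()
            kw = _recentre_weights(
                kw, np.vstack([centres[j] for j in chosen]), target
            )
            counts = rng.multinomial(n_type, kw)
            pres = []
            for j, n in zip(chosen, counts):
                pres.extend([j] * int(n))
            exp_centre = sum(w * centres[j] for j, w in zip(chosen, kw))
            gt4["tm3_centre"] = [float(exp_centre[0]), float(exp_centre[1])]
            gt4["tm3_members"] = list(chosen)
            gt4["planted_centres"][t.value] = gt4["tm3_centre"]
        elif tt.placement == "pool":  # TmY15: no columnar structure
            counts = rng.multinomial(n_type, np.full(len(tmy_ids), 1.0 / len(tmy_ids)))
            pres = []
            for j, n in zip(tmy_ids, counts):
                pres.extend([j] * int(n))
        elif tt.placement == "t4":
            partner_cols = _same_subtype_partner_columns(sub)
            pres_opts = []
            probs = []
            for o, w in partner_cols:
                col = HexCoord(home.q + o.q, home.r + o.r)
                pres_opts.append(f"{sub.value}_{col.q}_{col.r}")
                probs.append(w)
            probs_arr = np.array(probs) / sum(probs)
            counts = rng.multinomial(n_type, probs_arr)
            pres = []
            for p, n in zip(pres_opts, counts):
                pres.extend([p] * int(n))
            cen = sum(
                w * np.array(axial_to_cart(HexCoord(home.q + o.q, home.r + o.r)))
                for o, w in partner_cols
            ) / sum(w for _, w in partner_cols)
            gt4["planted_centres"]["T4"] = [float(cen[0]), float(cen[1])]
        else:  # unknown
            counts = rng.multinomial(
                n_type, np.full(len(unknown_ids), 1.0 / len(unknown_ids))
            )
            pres = []
            for j, n in zip(unknown_ids, counts):
                pres.extend([j] * int(n))

        for k in range(n_type):
            b.rows.append((pres[k], t4_id, "", locs[k, 0], locs[k, 1], locs[k, 2]))


def _group_tbars(
    rows: list[tuple],
    template: CircuitTemplate,
    seed: int,
    types: dict[str, CellType],
) -> list[tuple]:
    """Assign polyadic T-bar ids: PSDs of one presynaptic cell are grouped
    into ribbons of size 1 + Poisson(mean - 1)."""
    by_pre: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        by_pre.setdefault(r[0], []).append(i)
    out = list(rows)
    for pre in sorted(by_pre):
        idxs = by_pre[pre]
        t = types.get(pre)
        tt = template.types.get(t) if t is not None else None
        mean = tt.psds_per_tbar if tt is not None else 6.0
        rng = cell_rng(seed, f"tb.{pre}")
        perm = rng.permutation(len(idxs))
        k = 0
        tb = 0
        while k < len(idxs):
            size = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
            tbar_id = f"{pre}.tb{tb}"
            for j in perm[k : k + size]:
                i = idxs[int(j)]
                r = out[i]
                out[i] = (r[0], r[1], tbar_id, r[3], r[4], r[5])
            k += size
            tb += 1
    return out


# ---------------------------------------------------------------------------
# truncation


def _clip_skeleton(skel: Skeleton, box: Box) -> Optional[Skeleton]:
    """Remove nodes outside the box together with their subtrees."""
    inside = box.contains(skel.xyz)
    if not inside[skel.index_of(skel.root_id)]:
        return None
    keep = np.zeros(skel.n_nodes, dtype=bool)
    # a node survives iff it and all its ancestors are inside
    for k in range(skel.n_nodes):
        j = k
        ok = True
        while j != -1:
            if not inside[j]:
                ok = False
                break
            j = int(skel._parent_idx[j])
        keep[k] = ok
    if keep.all():
        return skel
    return Skeleton(
        skel.node_ids[keep], skel.parent_ids[keep], skel.xyz[keep], skel.radius[keep]
    )


def _with_completeness(
    dataset: ConnectomeDataset, new_syn, skeletons, bounds
) -> ConnectomeDataset:
    """Rebuild a dataset after synapse removal, recording per-cell
    completeness = retained PSDs / original PSDs (over all PSDs in which the
    cell takes part, pre- or postsynaptically)."""
    import pandas as pd

    def _counts(df) -> dict[str, int]:
        c: dict[str, int] = {}
        for col in ("pre_id", "post_id"):
            for cid, n in df[col].value_counts().items():
                c[cid] = c.get(cid, 0) + int(n)
        return c

    orig = _counts(dataset.synapses)
    kept = _counts(new_syn)
    gt = dataset.ground_truth
    new_gt = (
        GroundTruth(
            cell_centres=dict(gt.cell_centres),
            completeness=dict(gt.completeness),
            t4={k: dict(v) for k, v in gt.t4.items()},
        )
        if gt is not None
        else None
    )
    neurons = {}
    for nid, n in dataset.neurons.items():
        comp = None
        if nid in orig and orig[nid] > 0:
            comp = kept.get(nid, 0) / orig[nid]
        if comp is not None and comp > 0:
            neurons[nid] = replace(n, completeness=comp)
        else:
            neurons[nid] = replace(n)
        if new_gt is not None and comp is not None:
            new_gt.completeness[nid] = comp
    return ConnectomeDataset(
        neurons=neurons,
        synapses=new_syn.reset_index(drop=True),
        lattice=dataset.lattice,
        volume_bounds=bounds,
        skeletons=skeletons,
        ground_truth=new_gt,
    )


def truncate(dataset: ConnectomeDataset, box: Box) -> ConnectomeDataset:
    """Geometric truncation: clip synapses and skeleton nodes to a box.

    Emulates the finite imaged volume: cells extending past the box lose
    the synapses (and skeleton subtrees) outside it, and their recorded
    completeness drops accordingly.
    """
    inter = box.intersect(dataset.volume_bounds)
    if inter is None:
        raise ValueError("truncation box does not intersect the volume bounds")
    syn = dataset.synapses
    mask = inter.contains(syn[["x", "y", "z"]].to_numpy()) if len(syn) else np.array([], bool)
    new_syn = syn[mask] if len(syn) else syn
    skeletons = {}
    for sid, skel in dataset.skeletons.items():
        clipped = _clip_skeleton(skel, inter)
        if clipped is not None:
            skeletons[sid] = clipped
    return _with_completeness(dataset, new_syn, skeletons, inter)


def thin_cells(
    dataset: ConnectomeDataset,
    fractions: dict[str, float],
    seed: int,
) -> ConnectomeDataset:
    """Uniform per-cell truncation: each PSD involving a listed cell is
    retained independently with that cell's probability (probabilities
    multiply if both partners are listed).

    This is the uniform-truncation model: the retained synapses of a cell
    are an unbiased subsample of its true ones, so the only systematic
    effect of partial reconstruction is the loss of synapse *count* —
    exactly the regime in which inverse-completeness reweighting of field
    centres is unbiased.
    """
    for cid, f in fractions.items():
        if not (0.0 < f <= 1.0):
            raise ValueError(f"retention fraction for {cid!r} must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x7E1A]))
    syn = dataset.synapses
    p = np.ones(len(syn))
    for col in ("pre_id", "post_id"):
        vals = syn[col].to_numpy()
        for cid, f in fractions.items():
            p = np.where(vals == cid, p * f, p)
    keep = rng.random(len(syn)) < p
    return _with_completeness(
        dataset, syn[keep], dict(dataset.skeletons), dataset.volume_bounds
    )


def completeness_ladder(
    dataset: ConnectomeDataset,
    cell_ids: Sequence[str],
    fractions: Sequence[float] = COMPLETENESS_LADDER,
    seed: int = 0,
) -> ConnectomeDataset:
    """Apply the graded-completeness regime to a set of cells.

    Cells are ordered by the x coordinate of their true field centre and
    the retention fractions (sorted descending) are assigned so that cells
    closer to the +x volume edge are less complete — the spatially graded
    incompleteness a finite imaged volume produces.
    """
    if dataset.ground_truth is None:
        raise ValueError("completeness_ladder needs ground-truth cell centres")
    cells = sorted(cell_ids, key=lambda i: dataset.ground_truth.cell_centres[i].x)
    fr = sorted(fractions, reverse=True)
    if len(fr) < len(cells):
        raise ValueError("fewer fractions than cells")
    return thin_cells(dataset, dict(zip(cells, fr)), seed=seed)
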