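import math

import numpy as np
import pytest

from t4circuit import subfields as subf
from t4circuit import synthetic as synth
from t4circuit.hexgrid import ColumnLattice, HexCoord, axial_to_cart
from t4circuit.model import (
    Box,
    CellType,
    ConnectomeDataset,
    Neuron,
    make_synapse_table,
)


def column_dataset(per_column: dict[HexCoord, int], pre_type=CellType.Mi4,
                   mi1_counts: dict[HexCoord, int] | None = None):
    """One T4 with the given per-column input counts of one type (plus Mi1)."""
    neurons = {"t4": Neuron("t4", CellType.T4a, home_column=HexCoord(0, 0))}
    rows = []
    k = 0
    mi1_counts = mi1_counts if mi1_counts is not None else {HexCoord(0, 0): 10}
    for t, counts in ((pre_type, per_column), (CellType.Mi1, mi1_counts)):
        for col, n in counts.items():
            cid = f"{t.value}_{col.q}_{col.r}"
            neurons[cid] = Neuron(cid, t, home_column=HexCoord(*col))
            for _ in range(n):
                rows.append((cid, "t4", f"tb{k}", 0.0, 0.0, 0.0))
                k += 1
    return ConnectomeDataset(
        neurons=neurons,
        synapses=make_synapse_table(rows),
        lattice=ColumnLattice.disc(2),
        volume_bounds=Box((-99, -99, -99), (99, 99, 99)),
    )


class TestSubfieldCentre:
    def test_home_only(self):
        ds = column_dataset({HexCoord(0, 0): 12})
        res = subf.subfield_centre(ds, "t4", CellType.Mi4)
        assert res.centre == pytest.approx((0.0, 0.0))
        assert res.n_synapses == 12

    def test_symmetric_columns_cancel(self):
        ds = column_dataset({HexCoord(1, 0): 5, HexCoord(-1, 0): 5})
        assert subf.subfield_centre(ds, "t4", CellType.Mi4).centre == pytest.approx(
            (0.0, 0.0)
        )

    def test_thirty_ten_split(self):
        ds = column_dataset({HexCoord(0, 0): 30, HexCoord(1, 0): 10})
        assert subf.subfield_centre(ds, "t4", CellType.Mi4).centre == pytest.approx(
            (0.25, 0.0)
        )

    def test_missing_type_rejected(self):
        ds = column_dataset({HexCoord(0, 0): 3})
        with pytest.raises(ValueError):
            subf.subfield_centre(ds, "t4", CellType.C3)

    def test_matches_per_synapse_oracle_on_synthetic_data(self, default_dataset):
        """The weighted centre equals a brute-force mean over individual
        synapses' column positions."""
        ds = default_dataset
        for t in (CellType.Mi1, CellType.Mi9, CellType.CT1):
            res = subf.subfield_centre(ds, "T4b_0_0", t)
            pts = []
            syn = ds.synapses_onto("T4b_0_0")
            for pre_id in syn["pre_id"]:
                n = ds.neuron(pre_id)
                if n.cell_type == t:
                    pts.append(axial_to_cart(n.home_column))
            oracle = np.mean(pts, axis=0)
            assert res.centre == pytest.approx(tuple(oracle), abs=1e-9)


class TestOffsetFromMi1:
    def test_mi1_self_reference_is_zero(self):
        ds = column_dataset({HexCoord(0, 0): 4})
        off = subf.offset_from_mi1(ds, "t4", CellType.Mi1)
        assert (off.dx, off.dy) == pytest.approx((0.0, 0.0))

    def test_constructed_displacement(self):
        # Mi4 field centred at (-0.5, 0), Mi1 at (0, 0)
        ds = column_dataset({HexCoord(-1, 0): 5, HexCoord(0, 0): 5})
        off = subf.offset_from_mi1(ds, "t4", CellType.Mi4)
        assert (off.dx, off.dy) == pytest.approx((-0.5, 0.0))

    def test_planted_offset_recovered(self):
        """Generator plants Mi9 at +0.35 units from Mi1 along the arbour
        axis; the estimate from ~200 synapses lands within 0.1 units."""
        tpl = synth.default_template(n_inputs_per_t4=1600)
        ds = synth.make_circuit(
            tpl, synth.make_lattice(1), seed=9, t4_columns=[(0, 0)]
        )
        off = subf.offset_from_mi1(ds, "T4a_0_0", CellType.Mi9)
        assert math.hypot(off.dx - 0.35, off.dy) < 0.1


class TestL1FieldCentre:
    def test_single_l1_home(self):
        neurons = {
            "l1": Neuron("l1", CellType.L1, home_column=HexCoord(0, 0)),
            "mi1": Neuron("mi1", CellType.Mi1, home_column=HexCoord(0, 0)),
        }
        ds = ConnectomeDataset(
            neurons=neurons,
            synapses=make_synapse_table([("l1", "mi1", "tb0", 0, 0, 0)]),
            lattice=ColumnLattice.disc(1),
            volume_bounds=Box((-9, -9, -9), (9, 9, 9)),
        )
        assert subf.l1_field_centre(ds, "mi1") == pytest.approx((0.0, 0.0))

    def test_weighted_two_l1s(self):
        neurons = {
            "l1a": Neuron("l1a", CellType.L1, home_column=HexCoord(0, 0)),
            "l1b": Neuron("l1b", CellType.L1, home_column=HexCoord(1, 0)),
            "tm3": Neuron("tm3", CellType.Tm3),
        }
        rows = [("l1a", "tm3", f"t{k}", 0, 0, 0) for k in range(3)]
        rows += [("l1b", "tm3", "t9", 0, 0, 0)]
        ds = ConnectomeDataset(
            neurons=neurons,
            synapses=make_synapse_table(rows),
            lattice=ColumnLattice.disc(1),
            volume_bounds=Box((-9, -9, -9), (9, 9, 9)),
        )
        assert subf.l1_field_centre(ds, "tm3") == pytest.approx((0.25, 0.0))

    def test_no_l1_inputs_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="L1"):
            subf.l1_field_centre(default_dataset, "T4a_1_0")

    def test_synthetic_mi1_centre_near_home(self, default_dataset):
        centre = subf.l1_field_centre(default_dataset, "Mi1_1_0")
        assert math.hypot(centre.x - 1.0, centre.y) < 0.2


class TestTm3Mi1Offset:
    def test_raw_equals_adjusted_at_full_completeness(self, default_dataset):
        from dataclasses import replace

        # a copy where every neuron carries an explicit completeness of 1
        ds = default_dataset.with_synapses(default_dataset.synapses)
        ds.neurons = {
            i: replace(n, completeness=1.0) for i, n in ds.neurons.items()
        }
        raw = subf.tm3_mi1_offset(ds, "T4a_0_0", "raw")
        adj = subf.tm3_mi1_offset(ds, "T4a_0_0", "adjusted")
        assert (raw.dx, raw.dy) == pytest.approx((adj.dx, adj.dy))
        assert raw.mode == "raw" and adj.mode == "adjusted"

    def test_planted_zero_offset_small(self, default_dataset):
        off = subf.tm3_mi1_offset(default_dataset, "T4a_0_0", "raw")
        assert off.magnitude < 0.15

    def test_adjusted_requires_completeness(self, default_dataset):
        gt = default_dataset.ground_truth.t4["T4b_0_0"]
        with pytest.raises(ValueError, match="completeness"):
            subf.tm3_mi1_offset(default_dataset, "T4b_0_0", "adjusted")

    def test_unknown_mode_rejected(self, default_dataset):
        with pytest.raises(ValueError):
            subf.tm3_mi1_offset(default_dataset, "T4a_0_0", "corrected")


class TestOffsetAlignment:
    @pytest.mark.parametrize(
        "offset, pd, expected",
        [
            ((1.0, 0.0), 0.0, 1.0),
            ((-1.0, 0.0), 0.0, -1.0),
            ((0.0, 1.0), 0.0, 0.0),
            ((0.5, 0.5), math.pi / 4, 1.0),
        ],
    )
    def test_cosine(self, offset, pd, expected):
        ov = subf.OffsetVector(*offset)
        assert subf.offset_alignment(ov, pd) == pytest.approx(expected, abs=1e-12)

    def test_zero_offset_undefined(self):
        assert math.isnan(subf.offset_alignment(subf.OffsetVector(0.0, 0.0), 0.0))

    def test_zero_pd_rejected(self):
        with pytest.raises(ValueError):
            subf.offset_alignment(subf.OffsetVector(1.0, 0.0), (0.0, 0.0))
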