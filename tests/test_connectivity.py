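import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t4circuit import connectivity as conn
from t4circuit.hexgrid import ColumnLattice, HexCoord
from t4circuit.model import (
    Box,
    CellType,
    ConnectomeDataset,
    Neuron,
    make_synapse_table,
)


def tiny_dataset(counts: dict[tuple[str, str], int], types: dict[str, CellType]):
    """Dataset with the given per-pair PSD counts; unicolumnar cells get a
    home column from their id suffix when it parses as 'q_r'."""
    neurons = {}
    for cid, t in types.items():
        home = None
        parts = cid.split("_")
        if len(parts) == 3:
            home = HexCoord(int(parts[1]), int(parts[2]))
        neurons[cid] = Neuron(cid, t, home_column=home)
    rows = []
    k = 0
    for (pre, post), n in counts.items():
        for _ in range(n):
            rows.append((pre, post, f"tb{k}", 0.0, 0.0, 0.0))
            k += 1
    return ConnectomeDataset(
        neurons=neurons,
        synapses=make_synapse_table(rows),
        lattice=ColumnLattice.disc(2),
        volume_bounds=Box((-99, -99, -99), (99, 99, 99)),
    )


class TestCounting:
    def test_absent_connection_is_zero(self):
        ds = tiny_dataset({("a", "x"): 2}, {"a": CellType.Mi1, "x": CellType.T4a})
        assert conn.count_connection(ds, "a", "x") == 2
        assert conn.count_connection(ds, "x", "a") == 0

    def test_unknown_id_rejected(self):
        ds = tiny_dataset({("a", "x"): 1}, {"a": CellType.Mi1, "x": CellType.T4a})
        with pytest.raises(KeyError):
            conn.count_connection(ds, "nope", "x")

    def test_conservation_over_presynaptic_cells(self, default_dataset):
        """Summing counts over all presynaptic partners recovers the total
        input count of the postsynaptic cell."""
        ds = default_dataset
        t4 = "T4c_0_0"
        total = len(ds.synapses_onto(t4))
        pairs = conn.connection_counts(ds)
        assert pairs.loc[pairs["post_id"] == t4, "count"].sum() == total


class TestInputFractions:
    def test_single_type(self):
        ds = tiny_dataset({("a", "x"): 5}, {"a": CellType.Mi1, "x": CellType.T4a})
        assert conn.input_fractions(ds, "x") == {CellType.Mi1: 1.0}

    def test_two_types_equal_counts(self):
        ds = tiny_dataset(
            {("a", "x"): 4, ("b", "x"): 4},
            {"a": CellType.Mi1, "b": CellType.Mi9, "x": CellType.T4a},
        )
        fr = conn.input_fractions(ds, "x")
        assert fr[CellType.Mi1] == pytest.approx(0.5)
        assert fr[CellType.Mi9] == pytest.approx(0.5)

    def test_no_inputs_is_degenerate(self):
        ds = tiny_dataset({("a", "x"): 1}, {"a": CellType.Mi1, "x": CellType.T4a})
        with pytest.raises(ValueError):
            conn.input_fractions(ds, "a")

    def test_fractions_sum_to_one_after_threshold(self, default_dataset):
        for min_syn in (1, 2):
            fr = conn.input_fractions(default_dataset, "T4b_0_0", min_synapses=min_syn)
            assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_fractions_within_three_se_of_template(self):
        from t4circuit import synthetic as synth

        tpl = synth.default_template(n_inputs_per_t4=2000)
        ds = synth.make_circuit(tpl, synth.make_lattice(1), seed=3, t4_columns=[(0, 0)])
        fr = conn.input_fractions(ds, "T4d_0_0")
        n = len(ds.synapses_onto("T4d_0_0"))
        for t, tt in tpl.types.items():
            key = CellType.T4d if tt.placement == "t4" else t
            se = math.sqrt(tt.fraction * (1 - tt.fraction) / n)
            assert abs(fr.get(key, 0.0) - tt.fraction) < 3 * se + 1 / n


class TestExcludeWeak:
    def test_boundary_cases(self):
        ds = tiny_dataset(
            {("a", "x"): 1, ("b", "x"): 2},
            {"a": CellType.Mi1, "b": CellType.Mi4, "x": CellType.T4a},
        )
        view = conn.exclude_weak(ds, min_synapses=2)
        assert conn.count_connection(view, "a", "x") == 0  # single synapse dropped
        assert conn.count_connection(view, "b", "x") == 2  # boundary retained

    def test_toy_table_survivors(self):
        ds = tiny_dataset(
            {("a", "x"): 1, ("b", "x"): 3, ("c", "x"): 2},
            {
                "a": CellType.Mi1,
                "b": CellType.Mi4,
                "c": CellType.Mi9,
                "x": CellType.T4a,
            },
        )
        assert conn.exclude_weak(ds, 2).n_psds == 5

    def test_invalid_threshold(self):
        ds = tiny_dataset({("a", "x"): 1}, {"a": CellType.Mi1, "x": CellType.T4a})
        with pytest.raises(ValueError):
            conn.exclude_weak(ds, 0)


class TestPerColumnCounts:
    def test_all_inputs_from_home(self):
        ds = tiny_dataset(
            {("Mi1_0_0", "x"): 7}, {"Mi1_0_0": CellType.Mi1, "x": CellType.T4a}
        )
        assert conn.per_column_counts(ds, "x", CellType.Mi1) == {HexCoord(0, 0): 7}

    def test_multicolumnar_type_rejected(self, default_dataset):
        with pytest.raises(ValueError, match="multicolumnar"):
            conn.per_column_counts(default_dataset, "T4a_0_0", CellType.Tm3)

    def test_planted_column_weights_recovered(self, default_dataset):
        """Multinomial recovery: realized per-column Mi1 counts match the
        planted weight map within 3 SEs."""
        from t4circuit.synthetic import columnar_weights, default_template

        ds = default_dataset
        counts = conn.per_column_counts(ds, "T4a_0_0", CellType.Mi1)
        onto = ds.synapses_onto("T4a_0_0")
        n_mi1 = sum(
            ds.cell_type_of(i) == CellType.Mi1 for i in onto["pre_id"]
        )
        assert sum(counts.values()) == n_mi1
        tt = default_template().types[CellType.Mi1]
        weights = columnar_weights(CellType.T4a, tt.shift, tt.ring_frac)
        n = sum(counts.values())
        for offset, w in weights.items():
            se = math.sqrt(w * (1 - w) / n)
            assert abs(counts.get(offset, 0) / n - w) < 3 * se + 1 / n


class TestBinStrength:
    @pytest.mark.parametrize(
        "count, expected",
        [(0, "weak"), (9, "weak"), (10, "medium"), (20, "medium"), (21, "strong")],
    )
    def test_boundaries(self, count, expected):
        assert conn.bin_strength(count) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            conn.bin_strength(-1)

    @given(st.integers(0, 200), st.integers(0, 200))
    @settings(derandomize=True)
    def test_monotone(self, a, b):
        order = {"weak": 0, "medium": 1, "strong": 2}
        lo, hi = min(a, b), max(a, b)
        assert order[conn.bin_strength(lo)] <= order[conn.bin_strength(hi)]


class TestPercentIncrease:
    def test_printed_reconstruction_totals(self):
        assert conn.percent_increase([116, 109, 113, 104], [97, 69, 85, 81]) == 33

    @pytest.mark.parametrize(
        "new, old, expected", [([5, 5], [5, 5], 0), ([2], [1], 100)]
    )
    def test_simple_cases(self, new, old, expected):
        assert conn.percent_increase(new, old) == expected

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            conn.percent_increase([1], [0])


class TestTypeMatrix:
    def test_totals_and_export(self, default_dataset, tmp_path):
        m = conn.type_connectivity_matrix(default_dataset)
        assert m.total == default_dataset.n_psds
        assert (m.table.to_numpy() >= 0).all()
        p = tmp_path / "matrix.tsv"
        m.to_tsv(p, header_lines=["seed=7"])
        text = p.read_text()
        assert text.startswith("# seed=7")
        assert "Mi1" in text

    def test_threshold_reduces_totals(self, default_dataset):
        m1 = conn.type_connectivity_matrix(default_dataset, min_synapses=1)
        m5 = conn.type_connectivity_matrix(default_dataset, min_synapses=5)
        assert m5.total <= m1.total
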