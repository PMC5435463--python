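import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from t4circuit import io as tio
from t4circuit import synthetic as synth
from t4circuit.hexgrid import HexCoord, axial_to_cart
from t4circuit.model import ARBOR_AXES, Box, CellType


class TestMakeLattice:
    @pytest.mark.parametrize("radius, n", [(1, 7), (2, 19)])
    def test_hex_disc_sizes(self, radius, n):
        assert len(synth.make_lattice(radius)) == n

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            synth.make_lattice(0)


class TestMakeT4:
    @pytest.mark.parametrize("subtype", ["a", "b", "c", "d"])
    def test_arbor_extends_along_subtype_axis(self, subtype):
        neuron, skel = make = synth.make_t4(subtype, (0, 0), seed=3)
        axis = np.array(ARBOR_AXES[neuron.cell_type])
        disp = (skel.xyz[:, :2] - skel.root_xyz[:2]).mean(axis=0)
        cos = disp @ axis / np.linalg.norm(disp)
        assert cos > math.cos(math.radians(45))

    def test_span_anisotropy(self):
        _, skel = synth.make_t4("a", (0, 0), seed=3)
        rel = skel.xyz[:, :2] - skel.root_xyz[:2]
        span_along = rel[:, 0].max() - rel[:, 0].min()
        span_ortho = rel[:, 1].max() - rel[:, 1].min()
        assert span_along / span_ortho > 1.5
        # spans roughly 2-3 column spacings along the axis
        assert 1.5 * synth.DEFAULT_COLUMN_SPACING_UM < span_along < 3.5 * synth.DEFAULT_COLUMN_SPACING_UM

    def test_rooted_at_column_centre(self):
        neuron, skel = synth.make_t4("b", (1, 0), seed=3)
        cx, cy = axial_to_cart((1, 0))
        s = synth.DEFAULT_COLUMN_SPACING_UM
        assert skel.root_xyz[:2] == pytest.approx([cx * s, cy * s])
        assert neuron.home_column == HexCoord(1, 0)


class TestMakeCircuit:
    def test_single_pre_type_all_from_home(self):
        lat = synth.make_lattice(1)
        tpl = synth.default_template()
        tpl.types = {
            CellType.Mi1: replace(
                tpl.types[CellType.Mi1], fraction=1.0, shift=0.0, ring_frac=0.0
            )
        }
        tpl.n_inputs_per_t4 = 50
        ds = synth.make_circuit(tpl, lat, seed=0, t4_columns=[(0, 0)])
        onto = ds.synapses[ds.synapses["post_id"] == "T4a_0_0"]
        assert set(onto["pre_id"]) == {"Mi1_0_0"}

    def test_fixed_seed_reproduces_byte_identical_output(self, tmp_path):
        lat = synth.make_lattice(1)
        tpl = synth.default_template()
        d1 = tio.save_dataset(synth.make_circuit(tpl, lat, seed=11), tmp_path / "a")
        d2 = tio.save_dataset(synth.make_circuit(tpl, lat, seed=11), tmp_path / "b")
        for rel in sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file()):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_different_seeds_differ(self):
        lat = synth.make_lattice(1)
        tpl = synth.default_template()
        a = synth.make_circuit(tpl, lat, seed=1).synapses
        b = synth.make_circuit(tpl, lat, seed=2).synapses
        assert not a.equals(b)

    def test_fractions_converge_to_template(self):
        """Law of large numbers: realized per-type input fractions approach
        the template fractions (within 3 multinomial SEs at n = 10^4)."""
        lat = synth.make_lattice(1)
        tpl = synth.default_template(n_inputs_per_t4=10_000)
        ds = synth.make_circuit(tpl, lat, seed=5, t4_columns=[(0, 0)])
        onto = ds.synapses[ds.synapses["post_id"] == "T4a_0_0"]
        n = len(onto)
        types = onto["pre_id"].map(lambda i: ds.cell_type_of(i))
        realized = types.value_counts() / n
        for t, tt in tpl.types.items():
            key = CellType.T4a if tt.placement == "t4" else t
            se = math.sqrt(tt.fraction * (1 - tt.fraction) / n)
            assert abs(realized.get(key, 0.0) - tt.fraction) < 3 * se + 1 / n

    def test_polyadic_tbar_accounting(self, default_dataset):
        ds = default_dataset
        assert ds.n_tbars <= ds.n_psds
        ratio = ds.n_psds / ds.n_tbars
        assert 4.0 < ratio < 8.0  # generated around 6 PSDs per T-bar

    def test_template_support_outside_lattice_rejected(self):
        lat = synth.make_lattice(1)
        with pytest.raises(ValueError, match="outside the lattice"):
            synth.make_circuit(
                synth.default_template(), lat, seed=0, t4_columns=[(1, 0)]
            )

    def test_ground_truth_records_planted_centres(self, default_dataset):
        gt = default_dataset.ground_truth
        t4 = gt.t4["T4a_0_0"]
        assert t4["subtype"] == "a"
        assert t4["pd"] == [-1.0, -0.0]
        assert t4["planted_centres"]["Mi1"] == pytest.approx([0.35, 0.0])
        assert t4["planted_centres"]["Mi9"] == pytest.approx([0.70, 0.0])
        # planted Tm3 centre coincides with the Mi1 centre (zero offset)
        assert t4["tm3_centre"] == pytest.approx([0.35, 0.0], abs=1e-9)


class TestTruncation:
    def test_full_box_keeps_everything(self, default_dataset):
        ds = synth.truncate(default_dataset, default_dataset.volume_bounds)
        assert ds.n_psds == default_dataset.n_psds
        assert all(
            c == pytest.approx(1.0) for c in ds.ground_truth.completeness.values()
        )

    def test_box_excluding_region_drops_those_synapses(self, default_dataset):
        full = default_dataset.volume_bounds
        # cut away everything at x beyond the home column
        box = Box(full.lo, (4.0, full.hi[1], full.hi[2]))
        ds = synth.truncate(default_dataset, box)
        assert ds.n_psds < default_dataset.n_psds
        assert (ds.synapses["x"] <= 4.0).all()
        # counts never increase, completeness <= 1
        assert all(c <= 1.0 + 1e-12 for c in ds.ground_truth.completeness.values())

    def test_completeness_monotone_as_box_shrinks(self, default_dataset):
        full = default_dataset.volume_bounds
        prev = None
        for xhi in (20.0, 8.0, 2.0):
            ds = synth.truncate(default_dataset, Box(full.lo, (xhi, full.hi[1], full.hi[2])))
            comp = ds.ground_truth.completeness
            if prev is not None:
                for cid in comp:
                    assert comp[cid] <= prev[cid] + 1e-12
            prev = comp

    def test_empty_intersection_rejected(self, default_dataset):
        with pytest.raises(ValueError):
            synth.truncate(default_dataset, Box((500, 500, 500), (600, 600, 600)))

    def test_thinning_matches_requested_fractions(self, default_dataset):
        gt = default_dataset.ground_truth.t4["T4a_0_0"]
        members = gt["tm3_members"]
        ds = synth.completeness_ladder(default_dataset, members, seed=3)
        comps = sorted(
            ds.ground_truth.completeness[m] for m in members
        )
        targets = sorted(synth.COMPLETENESS_LADDER)
        # realized completeness is binomial around each target
        for got, want in zip(comps, targets):
            assert abs(got - want) < 0.12
        # untouched cells stay complete
        assert ds.ground_truth.completeness["Mi1_0_0"] == pytest.approx(1.0)

    def test_thinning_never_adds_synapses(self, default_dataset):
        members = default_dataset.ground_truth.t4["T4a_0_0"]["tm3_members"]
        ds = synth.thin_cells(default_dataset, {m: 0.5 for m in members}, seed=1)
        assert ds.n_psds < default_dataset.n_psds
        merged = ds.synapses.merge(
            default_dataset.synapses, how="left", indicator=True
        )
        assert (merged["_merge"] == "both").all()
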