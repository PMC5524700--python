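"""Back-projection of influential descriptors into 3D."""

import numpy as np
import pandas as pd
import pytest

from gridqsar.errors import GridQSARError, ParseError
from gridqsar.grid import GridSpec, IEDTensor, Probe
from gridqsar.mapping import (cluster_nodes, export_dx, export_pseudoatoms,
                              neighbor_residues, parse_label, read_dx,
                              select_top_ieds)

from conftest import make_ensemble


GRID = GridSpec(origin=(0.0, 0.0, 0.0), edge_length=4.0, spacing=1.0)


def test_label_round_trip_bijection():
    from gridqsar.grid import descriptor_labels
    probe = Probe("O-H", 0.4, 1.0, 1.0)
    labels = descriptor_labels(GRID, [probe])
    decoded = set()
    for label in labels:
        idx, pname, kind = parse_label(label)
        assert pname == "O-H" and kind in ("LJ", "C")
        decoded.add((idx, kind))
        np.testing.assert_allclose(GRID.node_position(idx),
                                   np.asarray(idx, dtype=float))
    assert len(decoded) == len(labels)


def test_malformed_label_rejected():
    with pytest.raises(ParseError):
        parse_label("nonsense")


class TestSelectTop:
    weights = {"0,0,0_p_LJ": -0.7, "1,0,0_p_LJ": -0.5, "2,0,0_p_C": 0.65}

    def test_cutoff_and_sign_filter(self):
        out = select_top_ieds(self.weights, GRID, cutoff=0.6, sign="negative")
        assert [m.label for m in out] == ["0,0,0_p_LJ"]
        assert out[0].sign == "negative"
        assert out[0].kind == "LJ"

    def test_zero_cutoff_returns_all(self):
        assert len(select_top_ieds(self.weights, GRID, cutoff=0.0)) == 3

    def test_constructed_count(self, rng):
        # a weight table with exactly 240 strong-negative entries
        labels = [f"{i % 5},{(i // 5) % 5},{i // 25}_p_C" for i in range(125)]
        weights = pd.Series(-0.3, index=labels)
        strong = rng.choice(125, size=60, replace=False)
        weights.iloc[strong] = -0.7
        out = select_top_ieds(weights, GRID, cutoff=0.6, sign="negative")
        assert len(out) == 60

    def test_sign_partition_exhaustive(self, rng):
        labels = [f"{i},0,0_p_LJ" for i in range(5)]
        weights = pd.Series(rng.normal(size=5), index=labels)
        pos = select_top_ieds(weights, GRID, 0.0, sign="positive")
        neg = select_top_ieds(weights, GRID, 0.0, sign="negative")
        nonzero = (weights != 0).sum()
        assert len(pos) + len(neg) == nonzero


class TestNeighborResidues:
    def structure(self):
        coords = np.array([[[0.5, 0.0, 0.0],   # residue 1, inside 2.0 of node
                            [10.0, 10.0, 10.0],  # residue 2, far away
                            [0.0, 1.9, 0.0]]])   # residue 3 (substrate)
        ens = make_ensemble(coords, roles=["enzyme", "enzyme", "substrate"])
        for i, a in enumerate(ens.topology):
            a.residue_number = i + 1
        return ens

    def ieds(self):
        return select_top_ieds({"0,0,0_p_C": -0.8}, GRID, cutoff=0.5)

    def test_inside_radius_included(self):
        report = neighbor_residues(self.ieds(), self.structure(), radius=2.0)
        assert list(report.residue_number) == [1, 3]
        assert list(report.n_ieds) == [1, 1]
        assert report.sum_weight.iloc[0] == pytest.approx(-0.8)

    def test_outside_radius_excluded(self):
        report = neighbor_residues(self.ieds(), self.structure(), radius=0.4)
        assert report.empty

    def test_radius_monotone(self):
        small = neighbor_residues(self.ieds(), self.structure(), 1.0)
        huge = neighbor_residues(self.ieds(), self.structure(), 100.0)
        assert len(small) <= len(huge)
        assert len(huge) == 3  # every residue within an unbounded radius

    def test_empty_ied_list_gives_empty_report(self):
        report = neighbor_residues([], self.structure(), radius=2.0)
        assert report.empty


def test_cluster_nodes_connected_components():
    labels = {"0,0,0_p_C": -0.9, "1,0,0_p_C": -0.8,  # one 26-connected blob
              "4,4,4_p_C": -0.7}                      # an isolated corner
    ieds = select_top_ieds(labels, GRID, 0.5)
    comps = cluster_nodes(ieds, GRID)
    assert [len(c) for c in comps] == [2, 1]


class TestExports:
    def test_pseudoatom_records(self, tmp_path):
        ieds = select_top_ieds({"0,0,0_p_LJ": -0.8, "1,2,3_p_C": 0.4},
                               GRID, 0.0)
        path = tmp_path / "ieds.pdb"
        export_pseudoatoms(ieds, path)
        lines = [l for l in path.read_text().splitlines()
                 if l.startswith("HETATM")]
        assert len(lines) == 2
        # B-factor column carries the raw weight
        assert float(lines[0][60:66]) == pytest.approx(-0.8)
        # occupancy is |weight| scaled to [0, 1]
        assert float(lines[0][54:60]) == pytest.approx(1.0)
        x, y, z = (float(lines[1][30:38]), float(lines[1][38:46]),
                   float(lines[1][46:54]))
        np.testing.assert_allclose([x, y, z], [1.0, 2.0, 3.0], atol=1e-3)

    def test_empty_export_rejected(self, tmp_path):
        with pytest.raises(GridQSARError):
            export_pseudoatoms([], tmp_path / "x.pdb")

    def test_dx_round_trip(self, tmp_path, rng):
        grid = GridSpec(origin=(-1.0, 0.0, 2.0), edge_length=2.0, spacing=1.0)
        probe = Probe("p", 0.1, 1.0, 1.0)
        values = rng.normal(size=(1, 2, grid.n_nodes))
        tensor = IEDTensor(code="A", grid=grid, probes=[probe], values=values)
        path = tmp_path / "field.dx"
        export_dx(tensor, "p", "LJ", path)
        header = path.read_text().splitlines()[0]
        assert "counts 3 3 3" in header
        spec, back = read_dx(path)
        assert spec.compatible_with(grid)
        np.testing.assert_allclose(back, values[0, 0], atol=1e-4)

    def test_unknown_probe_rejected(self, tmp_path, rng):
        grid = GridSpec(edge_length=1.0)
        tensor = IEDTensor(code="A", grid=grid,
                           probes=[Probe("p", 0.1, 1, 1)],
                           values=rng.normal(size=(1, 2, 8)))
        with pytest.raises(GridQSARError):
            export_dx(tensor, "nope", "LJ", tmp_path / "x.dx")
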