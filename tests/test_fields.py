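import numpy as np
import pytest

import qsar3d as q
from qsar3d.fields import (
    COULOMB_CONSTANT,
    ENERGY_CUTOFF,
    ELEMENT_LJ_EPS,
    parse_field_selection,
)
from qsar3d.structures import COMSIA_PROPERTIES


def naive_comfa(molecule, grid, probe):
    """Triple-loop oracle for the probe energies (independent of the
    vectorised implementation)."""
    nodes = grid.nodes()
    steric = np.zeros(len(nodes))
    elec = np.zeros(len(nodes))
    capped = np.zeros(len(nodes), bool)
    for qi, node in enumerate(nodes):
        s = e = 0.0
        for atom in molecule.atoms:
            r = max(float(np.linalg.norm(node - atom.coords)), 1e-6)
            eps = np.sqrt(ELEMENT_LJ_EPS.get(atom.element, 0.107) * probe.lj_well_depth)
            rmin = atom.vdw_radius + probe.vdw_radius
            s += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
            e += COULOMB_CONSTANT * probe.charge * atom.partial_charge / r**2
        capped[qi] = s > ENERGY_CUTOFF
        steric[qi] = min(s, ENERGY_CUTOFF)
        elec[qi] = min(max(e, -ENERGY_CUTOFF), ENERGY_CUTOFF)
    return steric, elec, capped


def naive_comsia(molecule, grid, probe, alpha):
    nodes = grid.nodes()
    out = {p: np.zeros(len(nodes)) for p in COMSIA_PROPERTIES}
    for qi, node in enumerate(nodes):
        for atom in molecule.atoms:
            r2 = float(((node - atom.coords) ** 2).sum())
            g = np.exp(-alpha * r2)
            for p in COMSIA_PROPERTIES:
                out[p][qi] += probe.comsia_weights[p] * atom.comsia_weights[p] * g
    return out


class TestGrid:
    def test_snapping_single_atom(self):
        mol = q.Molecule("a", [q.Atom("C", [0, 0, 0])])  # C radius 1.70
        grid = q.build_grid([mol], spacing=2.0, margin=4.0)
        # hull [-5.7, 5.7] -> snapped nodes -6..+6, 7 per axis
        assert grid.dims == (7, 7, 7)
        np.testing.assert_allclose(grid.axis_coords(0), np.arange(-6, 7, 2))

    def test_degenerate_hull_single_point(self):
        mol = q.Molecule("a", [q.Atom("C", [0.0, 0.0, 0.0], vdw_radius=1e-9)])
        grid = q.build_grid([mol], spacing=2.0, margin=0.0)
        assert grid.dims == (1, 1, 1)
        assert grid.nodes().shape == (1, 3)

    def test_hull_monotonicity(self, toy_molecule):
        grid1 = q.build_grid([toy_molecule])
        inner = q.Molecule("inner", [q.Atom("H", [0.2, 0.1, 0.0])])
        grid2 = q.build_grid([toy_molecule, inner])
        assert grid1 == grid2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            q.build_grid([])

    def test_node_order_x_fastest(self):
        grid = q.GridSpec(origin=(0, 0, 0), spacing=1.0, dims=(2, 2, 2))
        nodes = grid.nodes()
        np.testing.assert_allclose(nodes[0], [0, 0, 0])
        np.testing.assert_allclose(nodes[1], [1, 0, 0])  # x moves first
        np.testing.assert_allclose(nodes[2], [0, 1, 0])
        np.testing.assert_allclose(nodes[4], [0, 0, 1])


class TestComfaFields:
    def test_far_probe_decays(self):
        mol = q.Molecule("a", [q.Atom("C", [0, 0, 0], partial_charge=1.0)])
        far = q.GridSpec(origin=(100.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        f = q.comfa_fields(mol, far)
        assert abs(f["steric"][0]) < 1e-4
        # 1/r^2 Coulomb decay: 332.0636 / 100^2 at 100 A, vanishing further out
        assert abs(f["electrostatic"][0]) == pytest.approx(COULOMB_CONSTANT / 1e4)
        very_far = q.GridSpec(origin=(2000.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        f2 = q.comfa_fields(mol, very_far)
        assert abs(f2["electrostatic"][0]) < 1e-4

    def test_steric_capped_at_overlap(self):
        mol = q.Molecule("a", [q.Atom("C", [0, 0, 0])])
        grid = q.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        f = q.comfa_fields(mol, grid)
        assert f["steric"][0] == ENERGY_CUTOFF
        assert f["steric_capped"][0]

    def test_coulomb_closed_form_then_cap(self):
        # unit charge at 2 A with eps(r)=r: 332.0636 / 4 ~ 83 kcal/mol -> capped
        mol = q.Molecule("a", [q.Atom("C", [0, 0, 0], partial_charge=1.0, vdw_radius=0.01)])
        grid = q.GridSpec(origin=(2.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        raw = COULOMB_CONSTANT / 4.0
        assert raw == pytest.approx(83.0159, abs=1e-3)
        f = q.comfa_fields(mol, grid)
        assert f["electrostatic"][0] == ENERGY_CUTOFF
        # a smaller charge stays below the cap and matches the closed form
        mol.atoms[0].partial_charge = 0.25
        f = q.comfa_fields(mol, grid)
        assert f["electrostatic"][0] == pytest.approx(raw * 0.25, rel=1e-10)

    def test_matches_naive_oracle(self, toy_molecule):
        grid = q.build_grid([toy_molecule], spacing=2.0, margin=2.0)
        probe = q.Probe()
        f = q.comfa_fields(toy_molecule, grid, probe)
        s, e, c = naive_comfa(toy_molecule, grid, probe)
        np.testing.assert_allclose(f["steric"], s, atol=1e-10)
        np.testing.assert_allclose(f["electrostatic"], e, atol=1e-10)
        np.testing.assert_array_equal(f["steric_capped"], c)

    def test_no_nan_inf(self, toy_molecule):
        grid = q.build_grid([toy_molecule], spacing=1.0, margin=2.0)
        f = q.comfa_fields(toy_molecule, grid)
        for key in ("steric", "electrostatic"):
            assert np.all(np.isfinite(f[key]))
        assert f["steric"].max() <= ENERGY_CUTOFF


class TestComsiaFields:
    def test_closed_form_at_zero_and_one_angstrom(self):
        atom = q.Atom("C", [0, 0, 0],
                      comsia_weights={p: 1.0 for p in COMSIA_PROPERTIES})
        mol = q.Molecule("a", [atom])
        at_zero = q.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        at_one = q.GridSpec(origin=(1.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        assert q.comsia_fields(mol, at_zero)["steric"][0] == pytest.approx(1.0)
        assert q.comsia_fields(mol, at_one)["steric"][0] == pytest.approx(
            np.exp(-0.3), rel=1e-12
        )

    def test_additivity_two_equidistant_atoms(self):
        w = {p: 1.0 for p in COMSIA_PROPERTIES}
        one = q.Molecule("one", [q.Atom("C", [1.5, 0, 0], comsia_weights=dict(w))])
        two = q.Molecule("two", [q.Atom("C", [1.5, 0, 0], comsia_weights=dict(w)),
                                 q.Atom("C", [-1.5, 0, 0], comsia_weights=dict(w))])
        grid = q.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        a1 = q.comsia_fields(one, grid)["steric"][0]
        a2 = q.comsia_fields(two, grid)["steric"][0]
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_matches_naive_oracle(self, toy_molecule):
        grid = q.build_grid([toy_molecule], spacing=2.0, margin=2.0)
        probe = q.Probe()
        got = q.comsia_fields(toy_molecule, grid, probe)
        expected = naive_comsia(toy_molecule, grid, probe, 0.3)
        for p in COMSIA_PROPERTIES:
            np.testing.assert_allclose(got[p], expected[p], atol=1e-10)

    def test_bounded_by_weight_sum(self, toy_molecule):
        grid = q.build_grid([toy_molecule], spacing=2.0, margin=2.0)
        got = q.comsia_fields(toy_molecule, grid)
        for p in COMSIA_PROPERTIES:
            bound = np.abs(toy_molecule.weights(p)).sum()
            assert np.abs(got[p]).max() <= bound + 1e-12

    def test_bad_alpha_rejected(self, toy_molecule):
        grid = q.build_grid([toy_molecule])
        with pytest.raises(ValueError):
            q.comsia_fields(toy_molecule, grid, alpha=0.0)


class TestEquivariance:
    def test_rigid_motion_leaves_fields_unchanged(self, toy_molecule):
        """Transforming molecule AND grid by one rigid motion preserves values."""
        rng = np.random.default_rng(17)
        a = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(a)
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        trans = rng.normal(scale=3.0, size=3)

        grid = q.build_grid([toy_molecule], spacing=2.0, margin=2.0)
        nodes_moved = grid.nodes() @ rot.T + trans
        moved = toy_molecule.transformed(rot, trans)

        # evaluate on explicit node lists via a 1-point grid sweep
        for field_fn, keys in [
            (q.comfa_fields, ("steric", "electrostatic")),
            (q.comsia_fields, COMSIA_PROPERTIES),
        ]:
            ref = field_fn(toy_molecule, grid)
            for qi in range(0, grid.n_points, max(1, grid.n_points // 17)):
                probe_grid = q.GridSpec(origin=tuple(nodes_moved[qi]), spacing=1.0,
                                        dims=(1, 1, 1))
                got = field_fn(moved, probe_grid)
                for k in keys:
                    assert got[k][0] == pytest.approx(ref[k][qi], abs=1e-9)


class TestAssembly:
    def test_shapes_and_meta(self, toy_molecule):
        grid = q.GridSpec(origin=(-2.0, -2.0, -2.0), spacing=2.0, dims=(2, 2, 2))
        maps = [q.comsia_fields(toy_molecule, grid) for _ in range(3)]
        block = q.assemble_matrix(maps, "S,E", grid)
        assert block.matrix.shape == (3, 16)
        assert block.fields == ("steric", "electrostatic")
        assert len({f for f, _ in block.column_meta}) == 2

    def test_selection_parsing(self):
        assert parse_field_selection("S,E,D,H") == (
            "steric", "electrostatic", "donor", "hydrophobic")
        assert parse_field_selection("S+E") == ("steric", "electrostatic")
        with pytest.raises(ValueError):
            parse_field_selection("S,X")

    def test_deterministic_reassembly(self, toy_molecule):
        grid = q.build_grid([toy_molecule], spacing=2.0, margin=2.0)
        maps = [q.comfa_fields(toy_molecule, grid)]
        b1 = q.assemble_matrix(maps, "S,E", grid)
        b2 = q.assemble_matrix(maps, "S,E", grid)
        assert np.array_equal(b1.matrix, b2.matrix)

    def test_grid_mismatch_rejected(self, toy_molecule):
        g1 = q.GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(2, 2, 2))
        g2 = q.GridSpec(origin=(0, 0, 0), spacing=2.0, dims=(3, 2, 2))
        maps = [q.comsia_fields(toy_molecule, g1), q.comsia_fields(toy_molecule, g2)]
        with pytest.raises(ValueError, match="grid mismatch"):
            q.assemble_matrix(maps, "S", g1)

    def test_capped_electrostatics_replaced_by_column_mean(self):
        # molecule A clashes with the node, molecule B does not
        clasher = q.Molecule("a", [q.Atom("C", [0, 0, 0], partial_charge=0.5)])
        distant = q.Molecule("b", [q.Atom("C", [4.0, 0, 0], partial_charge=0.5)])
        grid = q.GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, dims=(1, 1, 1))
        maps = [q.comfa_fields(m, grid) for m in (clasher, distant)]
        assert maps[0]["steric_capped"][0] and not maps[1]["steric_capped"][0]
        block = q.assemble_matrix(maps, "S,E", grid)
        e_col = block.matrix[:, block.field_slice("electrostatic")][:, 0]
        # clashing molecule's electrostatic value equals the non-clashing mean
        assert e_col[0] == pytest.approx(maps[1]["electrostatic"][0])

    def test_save_load_roundtrip(self, tmp_path, toy_molecule):
        block = q.comsia_block([toy_molecule], fields="S,E", spacing=3.0, margin=1.0)
        block.save(tmp_path / "blk")
        back = q.FieldBlock.load(tmp_path / "blk")
        np.testing.assert_allclose(back.matrix, block.matrix, atol=1e-10)
        assert back.fields == block.fields
        assert back.grid == block.grid
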