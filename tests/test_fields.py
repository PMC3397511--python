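import numpy as np
import pytest

from gridqsar.chem_dataset import Molecule, MoleculeSet
from gridqsar.fields import (
    COULOMB_CONSTANT,
    DescriptorBlock,
    GridSpec,
    ProbeSpec,
    assemble_block,
    comfa_electrostatic,
    comfa_steric,
    comsia_field,
    inside_envelope,
    load_vdw_params,
    make_grid,
)

PARAMS = load_vdw_params()


def _atom(element="C", xyz=(0.0, 0.0, 0.0), charge=0.0, mol_id="a"):
    return Molecule(id=mol_id, elements=[element], coords=np.array([xyz]),
                    charges=np.array([charge]))


def _point_grid(xyz):
    return GridSpec(origin=tuple(xyz), spacing=1.0, counts=(1, 1, 1))


class TestMakeGrid:
    def test_single_atom_forced_geometry(self):
        molset = MoleculeSet([_atom()])
        grid = make_grid(molset, spacing=2.0, padding=4.0)
        assert grid.counts == (5, 5, 5)
        assert grid.origin == (-4.0, -4.0, -4.0)
        center = grid.points().mean(axis=0)
        assert np.allclose(center, 0.0)

    def test_padding_monotone(self, rng):
        molset = MoleculeSet([Molecule(id="m", elements=["C"] * 5,
                                       coords=rng.normal(size=(5, 3)) * 3)])
        small = make_grid(molset, 2.0, 2.0)
        big = make_grid(molset, 2.0, 6.0)
        assert big.n_points > small.n_points

    def test_containment_with_padding(self, aligned_series):
        result, _ = aligned_series
        grid = make_grid(result.molecules, spacing=2.0, padding=4.0)
        lo = np.array(grid.origin)
        hi = lo + grid.spacing * (np.array(grid.counts) - 1)
        coords = result.molecules.all_coords()
        assert np.all(coords - lo >= 4.0 - 1e-9)
        # upper face may exceed padding by < one spacing due to ceil
        assert np.all(hi - coords >= 4.0 - 1e-9)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            make_grid(MoleculeSet([]))

    def test_doubling_spacing_reduces_points(self, aligned_series):
        result, _ = aligned_series
        fine = make_grid(result.molecules, 2.0, 4.0)
        coarse = make_grid(result.molecules, 4.0, 4.0)
        assert coarse.n_points < fine.n_points

    def test_point_order_x_fastest(self):
        grid = GridSpec(origin=(0.0, 0.0, 0.0), spacing=1.0, counts=(2, 3, 4))
        pts = grid.points()
        assert np.allclose(pts[0], [0, 0, 0])
        assert np.allclose(pts[1], [1, 0, 0])  # x varies first
        assert np.allclose(pts[2], [0, 1, 0])  # then y
        assert np.allclose(pts[6], [0, 0, 1])  # then z
        back = grid.to_3d(np.arange(grid.n_points))
        assert back[1, 0, 0] == 1 and back[0, 1, 0] == 2 and back[0, 0, 1] == 6


class TestComfaSteric:
    def test_distant_probe_decays(self):
        val = comfa_steric(_atom(), _point_grid((50.0, 0.0, 0.0)))
        assert abs(val[0]) < 1e-6

    def test_clamped_at_atom_center(self):
        val = comfa_steric(_atom(), _point_grid((0.0, 0.0, 0.0)), cutoff=30.0)
        assert val[0] == 30.0

    def test_closed_form_single_carbon(self):
        # hand-evaluated eps*[(R*/r)^12 - 2 (R*/r)^6] with the bundled table
        r = 4.0
        eps = np.sqrt(PARAMS["elements"]["C"]["epsilon"] * 0.107)
        rij = PARAMS["elements"]["C"]["r_star"] + 1.70
        expected = eps * ((rij / r) ** 12 - 2 * (rij / r) ** 6)
        val = comfa_steric(_atom(), _point_grid((r, 0.0, 0.0)))
        assert val[0] == pytest.approx(expected, abs=1e-8)

    def test_missing_element_parameters(self):
        with pytest.raises(KeyError, match="Uub"):
            comfa_steric(_atom("Uub"), _point_grid((3.0, 0.0, 0.0)))

    def test_values_within_cutoff(self, aligned_series):
        result, _ = aligned_series
        grid = make_grid(result.molecules, 2.0, 4.0)
        for mol in list(result.molecules)[:5]:
            v = comfa_steric(mol, grid)
            assert v.min() >= -30.0 and v.max() <= 30.0

    def test_additive_over_disjoint_fragments(self, rng):
        a = Molecule(id="a", elements=["C", "N"], coords=rng.normal(size=(2, 3)))
        b = Molecule(id="b", elements=["O", "S"],
                     coords=rng.normal(size=(2, 3)) + 8.0)
        both = Molecule(id="ab", elements=a.elements + b.elements,
                        coords=np.vstack([a.coords, b.coords]))
        grid = GridSpec(origin=(-4, -4, -4), spacing=2.0, counts=(9, 9, 9))
        va = comfa_steric(a, grid, clamp=False)
        vb = comfa_steric(b, grid, clamp=False)
        vab = comfa_steric(both, grid, clamp=False)
        assert np.allclose(vab, va + vb, atol=1e-10)


class TestComfaElectrostatic:
    def test_zero_charges_zero_field(self):
        mol = _atom(charge=0.0)
        val = comfa_electrostatic(mol, _point_grid((2.0, 0.0, 0.0)))
        assert np.allclose(val, 0.0)

    def test_hand_formula_then_clamp(self):
        # 332.0 * 0.5 / (2.0 * 2.0) = 41.5 -> clamped to +30
        mol = _atom(charge=0.5)
        val = comfa_electrostatic(mol, _point_grid((2.0, 0.0, 0.0)), cutoff=30.0)
        assert val[0] == 30.0
        raw = comfa_electrostatic(mol, _point_grid((2.0, 0.0, 0.0)), clamp=False)
        assert raw[0] == pytest.approx(COULOMB_CONSTANT * 0.5 / 4.0, abs=1e-10)

    def test_mirror_symmetric_pair(self):
        mol = Molecule(id="pair", elements=["O", "O"],
                       coords=np.array([[-1.5, 0, 0], [1.5, 0, 0]]),
                       charges=np.array([-0.3, -0.3]))
        val = comfa_electrostatic(mol, _point_grid((0.0, 0.0, 0.0)), clamp=False)
        single = comfa_electrostatic(
            _atom("O", (-1.5, 0, 0), -0.3), _point_grid((0.0, 0.0, 0.0)), clamp=False)
        assert val[0] == pytest.approx(2 * single[0], abs=1e-10)

    def test_zero_distance_clamps_not_inf(self):
        val = comfa_electrostatic(_atom(charge=0.4), _point_grid((0.0, 0.0, 0.0)))
        assert val[0] == 30.0

    def test_needs_charges(self):
        mol = Molecule(id="x", elements=["C"], coords=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="charges"):
            comfa_electrostatic(mol, _point_grid((1.0, 0, 0)))

    def test_inside_envelope_flags(self):
        mol = _atom("C")
        grid = GridSpec(origin=(0, 0, 0), spacing=2.0, counts=(3, 1, 1))
        mask = inside_envelope(mol, grid)
        assert mask.tolist() == [True, False, False]  # r* C = 1.7


class TestComsia:
    def test_atom_on_lattice_point_steric(self):
        val = comsia_field(_atom("C"), _point_grid((0.0, 0.0, 0.0)), "S")
        assert val[0] == pytest.approx(-1.0 * 1.7**3, abs=1e-10)

    def test_closed_form_single_carbon(self):
        d = 3.0
        val = comsia_field(_atom("C"), _point_grid((d, 0.0, 0.0)), "S", alpha=0.3)
        assert val[0] == pytest.approx(-(1.7**3) * np.exp(-0.3 * d * d), abs=1e-8)

    def test_monotone_decay(self):
        dists = [0.5, 1.0, 2.0, 4.0]
        vals = [abs(comsia_field(_atom("C"), _point_grid((d, 0, 0)), "S")[0])
                for d in dists]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="kind"):
            comsia_field(_atom("C"), _point_grid((1.0, 0, 0)), "Z")

    def test_no_singularities_and_sign(self, aligned_series):
        result, _ = aligned_series
        grid = make_grid(result.molecules, 2.0, 4.0)
        v = comsia_field(result.molecules["70"], grid, "S")
        assert np.all(np.isfinite(v))
        assert np.all(v <= 0)  # attractive similarity convention

    def test_donor_acceptor_typing(self, aligned_series):
        result, _ = aligned_series
        mol = result.molecules["70"]
        grid = _point_grid(tuple(mol.coords.mean(axis=0)))
        vd = comsia_field(mol, grid, "D")
        va = comsia_field(mol, grid, "A")
        assert vd[0] < 0 and va[0] < 0  # series has both donors and acceptors


class TestAssembleBlock:
    def _toy_set(self, rng, n=6):
        mols = []
        for i in range(n):
            mols.append(Molecule(
                id=f"t{i}", elements=["C", "O"],
                coords=np.array([[0.0, 0, 0], [1.4 + 0.1 * i, 0, 0]]),
                charges=np.array([0.1, -0.1]),
            ))
        return MoleculeSet(mols)

    def test_constant_column_dropped(self, rng):
        molset = self._toy_set(rng)
        grid = make_grid(molset, 2.0, 4.0)
        block = assemble_block(molset, grid, min_sigma=1e-9, scaling="none")
        sd = block.X.std(axis=0, ddof=1)
        assert np.all(sd >= 1e-9)
        assert block.kept.sum() == block.n_columns

    def test_min_sigma_zero_no_scaling_is_raw(self, rng):
        molset = self._toy_set(rng)
        grid = make_grid(molset, 2.0, 4.0)
        block = assemble_block(molset, grid, fields=("comfa_S",), min_sigma=0.0,
                               scaling="none")
        raw = np.vstack([comfa_steric(m, grid) for m in molset])
        assert np.allclose(block.X, raw)
        assert block.n_columns == grid.n_points

    def test_comfa_std_equalizes_field_variance(self, rng):
        molset = self._toy_set(rng)
        grid = make_grid(molset, 2.0, 4.0)
        block = assemble_block(molset, grid, min_sigma=0.01, scaling="comfa_std")
        totals = []
        for kind in block.fields:
            cols = block.columns_for(kind)
            totals.append(np.sum(block.X[:, cols].var(axis=0, ddof=1)))
        assert totals[0] == pytest.approx(totals[1], abs=1e-10)

    def test_all_dropped_errors(self, rng):
        molset = self._toy_set(rng)
        grid = make_grid(molset, 2.0, 4.0)
        with pytest.raises(ValueError, match="min_sigma"):
            assemble_block(molset, grid, min_sigma=1e9)

    def test_block_is_finite(self, aligned_series):
        result, _ = aligned_series
        block = assemble_block(result.molecules, min_sigma=2.0)
        assert np.all(np.isfinite(block.X))


class TestRigidMotionInvariance:
    def test_translation_exact(self, rng):
        mol = Molecule(id="m", elements=["C", "N", "O"],
                       coords=rng.normal(size=(3, 3)), charges=np.array([0.2, -0.5, 0.3]))
        grid = GridSpec(origin=(-3, -3, -3), spacing=2.0, counts=(4, 4, 4))
        shift = np.array([5.0, -2.0, 1.0])
        mol2 = Molecule(id="m", elements=mol.elements, coords=mol.coords + shift,
                        charges=mol.charges)
        grid2 = GridSpec(origin=tuple(np.array(grid.origin) + shift),
                         spacing=2.0, counts=(4, 4, 4))
        for fn in (comfa_steric, comfa_electrostatic):
            assert np.allclose(fn(mol, grid), fn(mol2, grid2), atol=1e-8)
        assert np.allclose(comsia_field(mol, grid, "S"),
                           comsia_field(mol2, grid2, "S"), atol=1e-8)

    def test_rotation_via_point_array(self, rng):
        from scipy.spatial.transform import Rotation
        mol = Molecule(id="m", elements=["C", "N", "O"],
                       coords=rng.normal(size=(3, 3)), charges=np.array([0.2, -0.5, 0.3]))
        pts = rng.normal(size=(40, 3)) * 4
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        mol_rot = Molecule(id="m", elements=mol.elements, coords=mol.coords @ R.T,
                           charges=mol.charges)
        for fn in (comfa_steric, comfa_electrostatic):
            assert np.allclose(fn(mol, pts), fn(mol_rot, pts @ R.T), atol=1e-8)
        assert np.allclose(comsia_field(mol, pts, "E"),
                           comsia_field(mol_rot, pts @ R.T, "E"), atol=1e-8)


def test_probe_spec_defaults():
    probe = ProbeSpec()
    assert probe.charge == 1.0 and probe.radius == 1.0
    assert probe.hydrophobicity == 1.0 and probe.donor == 1.0 and probe.acceptor == 1.0


def test_descriptor_block_rejects_nonfinite():
    with pytest.raises(ValueError):
        DescriptorBlock(
            X=np.array([[np.nan]]), compound_ids=["a"],
            field_kinds=np.array(["comfa_S"]), lattice_idx=np.array([0]),
            kept=np.array([True]),
            grid=GridSpec(origin=(0, 0, 0), spacing=1.0, counts=(1, 1, 1)),
            fields=("comfa_S",),
        )
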