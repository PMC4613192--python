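import numpy as np
import pytest

from qsar3d.fields import (FieldGrid, ProbeSpec, VDW_PARAMS,
                           assemble_descriptor_matrix, assign_property_weights,
                           build_grid, comfa_blocks, comfa_electrostatic,
                           comfa_steric, comsia_blocks, comsia_field)

from conftest import molecule_from_smiles, single_atom_molecule


@pytest.fixture
def carbon_at_origin():
    return single_atom_molecule("C", (0.0, 0.0, 0.0))


def small_grid(center=(0, 0, 0), half=6.0, spacing=2.0):
    c = np.asarray(center, float)
    n = int(2 * half / spacing) + 1
    return FieldGrid(origin=c - half, spacing=spacing, dims=(n, n, n))


class TestGrid:
    def test_single_atom_forced_dimensions(self, carbon_at_origin):
        grid = build_grid([carbon_at_origin], spacing=2.0, margin=4.0)
        assert grid.dims == (5, 5, 5)
        assert np.allclose(grid.origin, [-4, -4, -4])
        center = grid.origin + 2.0 * np.array([2, 2, 2])
        assert np.allclose(center, 0)

    def test_translation_equivariance(self, ethanol):
        g1 = build_grid([ethanol], conformers=[0])
        shifted = single_atom_molecule("C")  # placeholder replaced below
        import copy
        from qsar3d.chem import Molecule
        from rdkit import Chem
        m2 = Molecule("shift", Chem.Mol(ethanol.rdmol))
        m2.set_coords(m2.coords() + np.array([10.0, 0, 0]))
        g2 = build_grid([m2], conformers=[0])
        assert g2.dims == g1.dims
        assert np.allclose(g2.origin - g1.origin, [10, 0, 0])

    def test_margin_invariant(self, ethanol, pyridine):
        grid = build_grid([ethanol, pyridine], spacing=2.0, margin=4.0,
                          conformers=[0, 0])
        lo = grid.origin
        hi = grid.origin + (np.array(grid.dims) - 1) * grid.spacing
        xyz = np.vstack([ethanol.coords(), pyridine.coords()])
        assert (xyz - lo >= 4.0 - 1e-9).all()
        assert (hi - xyz >= 4.0 - 1e-9).all()

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])

    def test_point_indexing_z_fastest(self):
        grid = FieldGrid(np.zeros(3), 1.0, (2, 3, 4))
        pts = grid.points()
        assert np.allclose(pts[1], [0, 0, 1])       # z moves fastest
        assert np.allclose(pts[4], [0, 1, 0])       # then y
        assert np.allclose(pts[12], [1, 0, 0])      # x slowest
        assert np.allclose(grid.point(13), [1, 0, 1])


class TestComfaSteric:
    def test_decay_at_distance(self, carbon_at_origin):
        grid = FieldGrid(np.array([20.0, 0, 0]), 2.0, (2, 2, 2))
        vals = comfa_steric(carbon_at_origin, grid, conformer=0)
        assert np.abs(vals).max() < 1e-3

    def test_clipped_inside_atom(self, carbon_at_origin):
        grid = FieldGrid(np.zeros(3), 2.0, (1, 1, 1))  # the atom position
        vals = comfa_steric(carbon_at_origin, grid, conformer=0)
        assert vals[0] == pytest.approx(30.0)

    def test_additivity_before_clipping(self):
        m1 = single_atom_molecule("C", (0.0, 0.0, 0.0))
        m2 = single_atom_molecule("C", (3.0, 0.0, 0.0))
        both = single_atom_molecule("C", (0.0, 0.0, 0.0))
        # build a genuine two-atom molecule
        from rdkit import Chem
        from qsar3d.chem import Molecule
        rw = Chem.RWMol()
        for _ in range(2):
            a = Chem.Atom("C")
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        rd = rw.GetMol()
        Chem.SanitizeMol(rd)
        pair = Molecule("pair", rd)
        pair.add_conformer(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        grid = small_grid(half=6.0)
        huge = 1e12  # disable clipping
        v = comfa_steric(pair, grid, conformer=0, cutoff=huge)
        v1 = comfa_steric(m1, grid, conformer=0, cutoff=huge)
        v2 = comfa_steric(m2, grid, conformer=0, cutoff=huge)
        assert np.allclose(v, v1 + v2, rtol=1e-9, atol=1e-9)

    def test_unknown_element_named(self):
        mol = single_atom_molecule("Se", (0, 0, 0))
        with pytest.raises(ValueError, match="Se"):
            comfa_steric(mol, small_grid(), conformer=0)


class TestComfaElectrostatic:
    def _charged_atom(self, q, pos):
        mol = single_atom_molecule("C", pos)
        from qsar3d.chem import _CHARGE_PROP
        mol.rdmol.GetAtomWithIdx(0).SetDoubleProp(_CHARGE_PROP, q)
        return mol

    def test_positive_and_monotone(self):
        mol = self._charged_atom(1.0, (0, 0, 0))
        grid = FieldGrid(np.array([2.0, 0, 0]), 2.0, (5, 1, 1))
        vals = comfa_electrostatic(mol, grid, conformer=0)
        assert (vals > 0).all()
        assert (np.diff(vals) < 0).all()

    def test_mirror_antisymmetry(self):
        from rdkit import Chem
        from qsar3d.chem import Molecule, _CHARGE_PROP
        rw = Chem.RWMol()
        for _ in range(2):
            a = Chem.Atom("C")
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        rd = rw.GetMol()
        Chem.SanitizeMol(rd)
        mol = Molecule("dipole", rd)
        mol.add_conformer(np.array([[-2.0, 0, 0], [2.0, 0, 0]]))
        rd.GetAtomWithIdx(0).SetDoubleProp(_CHARGE_PROP, 1.0)
        rd.GetAtomWithIdx(1).SetDoubleProp(_CHARGE_PROP, -1.0)
        # points mirrored across the x=0 plane carry opposite field values
        grid_p = FieldGrid(np.array([4.0, 0, 0]), 1.0, (3, 1, 1))
        grid_m = FieldGrid(np.array([-6.0, 0, 0]), 1.0, (3, 1, 1))
        vp = comfa_electrostatic(mol, grid_p, conformer=0)
        vm = comfa_electrostatic(mol, grid_m, conformer=0)
        assert np.allclose(vp, -vm[::-1], atol=1e-12)

    def test_matches_brute_force(self, ethanol):
        grid = small_grid(half=4.0)
        vals = comfa_electrostatic(ethanol, grid, conformer=0)
        q = ethanol.charges
        xyz = ethanol.coords()
        expect = np.zeros(grid.n_points)
        for p_idx, p in enumerate(grid.points()):
            acc = 0.0
            for qi, xi in zip(q, xyz):
                r = max(np.linalg.norm(p - xi), 1e-6)
                acc += 332.0 * qi / r ** 2
            expect[p_idx] = np.clip(acc, -30, 30)
        assert np.allclose(vals, expect, atol=1e-9)

    def test_uncharged_molecule_warns_zero_field(self):
        mol = self._charged_atom(0.0, (0, 0, 0))
        with pytest.warns(UserWarning):
            vals = comfa_electrostatic(mol, small_grid(), conformer=0)
        assert np.allclose(vals, 0)


class TestComsia:
    def test_unit_weight_at_probe_point(self, carbon_at_origin):
        grid = FieldGrid(np.zeros(3), 2.0, (1, 1, 1))
        v = comsia_field(carbon_at_origin, grid, prop="steric", conformer=0,
                         weights=np.array([1.0]))
        assert v[0] == pytest.approx(-1.0, abs=1e-15)

    def test_gaussian_attenuation_at_one_angstrom(self, carbon_at_origin):
        grid = FieldGrid(np.array([1.0, 0, 0]), 2.0, (1, 1, 1))
        v = comsia_field(carbon_at_origin, grid, prop="steric", conformer=0,
                         weights=np.array([1.0]))
        assert v[0] == pytest.approx(-np.exp(-0.3), abs=1e-12)

    def test_matches_brute_force_sum(self, ethanol):
        grid = small_grid(half=4.0)
        probe = ProbeSpec()
        for prop in ("steric", "electrostatic", "hydrophobic"):
            w = assign_property_weights(ethanol, prop)
            vals = comsia_field(ethanol, grid, probe, prop, conformer=0)
            xyz = ethanol.coords()
            expect = np.zeros(grid.n_points)
            for p_idx, p in enumerate(grid.points()):
                expect[p_idx] = -sum(
                    probe.weight(prop) * wi * np.exp(-0.3 * ((p - xi) ** 2).sum())
                    for wi, xi in zip(w, xyz))
            assert np.allclose(vals, expect, atol=1e-12)

    def test_doubling_atoms_doubles_field(self, carbon_at_origin):
        from rdkit import Chem
        from qsar3d.chem import Molecule
        rw = Chem.RWMol()
        for _ in range(2):
            a = Chem.Atom("C")
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        rd = rw.GetMol()
        Chem.SanitizeMol(rd)
        double = Molecule("double", rd)
        double.add_conformer(np.zeros((2, 3)))
        grid = small_grid(half=4.0)
        v1 = comsia_field(carbon_at_origin, grid, prop="steric", conformer=0,
                          weights=np.array([1.0]))
        v2 = comsia_field(double, grid, prop="steric", conformer=0,
                          weights=np.array([1.0, 1.0]))
        assert np.allclose(v2, 2 * v1, atol=1e-12)

    def test_smoothness_lipschitz_bound(self, ethanol):
        grid = small_grid(half=6.0, spacing=2.0)
        w = assign_property_weights(ethanol, "steric")
        vals = comsia_field(ethanol, grid, prop="steric", conformer=0)
        cube = vals.reshape(grid.dims)
        # |d/dr exp(-a r^2)| peaks at sqrt(2a)·e^{-1/2}
        lipschitz = np.abs(w).sum() * np.sqrt(2 * 0.3) * np.exp(-0.5)
        for axis in range(3):
            diffs = np.abs(np.diff(cube, axis=axis))
            assert diffs.max() <= lipschitz * grid.spacing + 1e-12

    def test_rigid_translation_invariance(self, ethanol):
        from rdkit import Chem
        from qsar3d.chem import Molecule
        grid1 = build_grid([ethanol], conformers=[0])
        m2 = Molecule("shift", Chem.Mol(ethanol.rdmol))
        m2.set_coords(m2.coords() + np.array([5.0, -3.0, 2.0]))
        grid2 = FieldGrid(grid1.origin + np.array([5.0, -3.0, 2.0]),
                          grid1.spacing, grid1.dims)
        for fn, kw in ((comfa_steric, {}), (comsia_field, {"prop": "steric"})):
            v1 = fn(ethanol, grid1, conformer=0, **kw)
            v2 = fn(m2, grid2, conformer=0, **kw)
            assert np.allclose(v1, v2, atol=1e-9)


class TestPropertyWeights:
    def test_carbonyl_oxygen_is_acceptor_not_donor(self):
        mol = molecule_from_smiles("CC(C)=O", "acetone")
        o = mol.elements.index("O")
        assert assign_property_weights(mol, "acceptor")[o] == 1.0
        assert assign_property_weights(mol, "donor")[o] == 0.0

    def test_amide_nh_is_donor(self):
        mol = molecule_from_smiles("CC(=O)NC", "amide")
        n = mol.elements.index("N")
        assert assign_property_weights(mol, "donor")[n] == 1.0

    def test_hydrophobic_weights_sum_to_clogp(self, ethanol):
        w = assign_property_weights(ethanol, "hydrophobic")
        assert w.sum() == pytest.approx(ethanol.properties["clogp"], abs=1e-6)

    def test_unknown_property_rejected(self, ethanol):
        with pytest.raises(ValueError):
            assign_property_weights(ethanol, "magnetism")


class TestAssembly:
    def test_identical_molecules_all_filtered(self, ethanol):
        grid = build_grid([ethanol], conformers=[0])
        blocks = comfa_blocks([ethanol, ethanol], grid, conformers=[0, 0])
        with pytest.raises(ValueError):
            assemble_descriptor_matrix(blocks, grid, sigma_threshold=1e-6)

    def test_clogp_adds_exactly_one_column(self, small_series):
        dm = small_series.descriptors
        mols = small_series.molecules
        grid = small_series.grid
        blocks = comfa_blocks(mols, grid)
        clogp = np.array([m.properties["clogp"] for m in mols])
        a = assemble_descriptor_matrix(blocks, grid, sigma_threshold=2.0)
        b = assemble_descriptor_matrix(blocks, grid, clogp=clogp,
                                       sigma_threshold=2.0)
        assert b.X.shape[1] == a.X.shape[1] + 1
        assert b.columns[-1].field == "clogp"
        assert b.columns[-1].lattice_index == -1

    def test_block_scaling_equalizes_variance(self, small_series):
        mols, grid = small_series.molecules, small_series.grid
        blocks = comfa_blocks(mols, grid)
        dm = assemble_descriptor_matrix(blocks, grid, sigma_threshold=2.0)
        totals = {}
        for j, info in enumerate(dm.columns):
            totals.setdefault(info.field, 0.0)
            totals[info.field] += dm.X[:, j].var(ddof=1)
        vals = list(totals.values())
        assert np.allclose(vals, vals[0], atol=1e-6)

    def test_electrostatic_column_mean_at_excluded_points(self, small_series):
        mols, grid = small_series.molecules, small_series.grid
        blocks = comfa_blocks(mols, grid)
        steric, elec = blocks["steric"], blocks["electrostatic"]
        excl = steric >= 30.0
        assert excl.any()
        for j in np.where(excl.any(axis=0))[0]:
            inside = excl[:, j]
            if inside.all():
                continue
            col_mean = elec[~inside, j].mean()
            assert np.allclose(elec[inside, j], col_mean, atol=1e-9)

    def test_comsia_truncation_flag(self, ethanol, pyridine):
        mols = [ethanol, pyridine]
        grid = build_grid(mols, conformers=[0, 0])
        raw = comsia_blocks(mols, grid, conformers=[0, 0], truncate=None)
        cut = comsia_blocks(mols, grid, conformers=[0, 0], truncate=0.3)
        assert np.abs(raw["steric"]).max() > 0.3
        assert np.abs(cut["steric"]).max() <= 0.3

    def test_probe_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            ProbeSpec(alpha=0.0)
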