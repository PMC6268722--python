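"""Conformers, alignment, lattice fields, column filter, q² matrix."""

import numpy as np
import pytest
from rdkit import Chem

from qsarkit.field3d import (COMFA_FIELDS, SIMILARITY_FIELDS, Conformer,
                             FieldQSAR, GridSpec, align_to_template,
                             column_filter, common_core_map, compute_fields,
                             embed_and_minimize, field_subset_labels,
                             q2_matrix)
from qsarkit.synthetic import example_scaffolds, generate_library


@pytest.fixture(scope="module")
def aligned_set():
    """12 aligned conformers of one scaffold group, with fields."""
    recs = generate_library(example_scaffolds()[0], 12, seed=4)
    confs = [embed_and_minimize(r.mol, seed=7, compound_id=r.id)
             for r in recs]
    template = confs[0]
    aligned = [template]
    for c in confs[1:]:
        a, rmsd = align_to_template(c, template, common_core_map(c, template))
        assert rmsd < 2.0
        aligned.append(a)
    block = compute_fields(aligned)
    return recs, aligned, block


class TestEmbedMinimize:
    def test_methane_is_tetrahedral(self):
        conf = embed_and_minimize(Chem.MolFromSmiles("C"), seed=1)
        coords = conf.coords
        c, hs = coords[0], coords[1:]
        angles = []
        for i in range(4):
            for j in range(i + 1, 4):
                u, v = hs[i] - c, hs[j] - c
                cosa = u @ v / np.linalg.norm(u) / np.linalg.norm(v)
                angles.append(np.degrees(np.arccos(cosa)))
        assert np.allclose(angles, 109.47, atol=1.0)

    def test_minimization_reduces_energy(self):
        from rdkit.Chem import AllChem
        mol = Chem.AddHs(Chem.MolFromSmiles("CCCCO"))
        params = AllChem.ETKDGv3()
        params.randomSeed = 5
        AllChem.EmbedMolecule(mol, params)
        props = AllChem.MMFFGetMoleculeProperties(mol)
        e0 = AllChem.MMFFGetMoleculeForceField(mol, props).CalcEnergy()
        conf = embed_and_minimize(Chem.MolFromSmiles("CCCCO"), seed=5)
        mh = conf.mol
        props2 = AllChem.MMFFGetMoleculeProperties(mh)
        e1 = AllChem.MMFFGetMoleculeForceField(mh, props2).CalcEnergy()
        assert e1 <= e0 + 1e-6

    def test_same_seed_same_coordinates(self):
        a = embed_and_minimize(Chem.MolFromSmiles("CCOCC"), seed=9)
        b = embed_and_minimize(Chem.MolFromSmiles("CCOCC"), seed=9)
        assert np.allclose(a.coords, b.coords, atol=1e-12)

    def test_charges_sum_to_formal_charge(self, aligned_set):
        _, aligned, _ = aligned_set
        for c in aligned:
            assert abs(c.charges.sum()
                       - Chem.GetFormalCharge(c.mol)) < 0.01


class TestAlignment:
    def test_template_to_itself_identity(self, aligned_set):
        _, aligned, _ = aligned_set
        t = aligned[0]
        pairs = [(i, i) for i in range(min(10, len(t.coords)))]
        moved, rmsd = align_to_template(t, t, pairs)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved.coords, t.coords, atol=1e-9)

    def test_known_rotation_recovered(self, aligned_set):
        _, aligned, _ = aligned_set
        t = aligned[0]
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        rotated = t.transformed(R, np.array([3.0, -1.0, 2.0]))
        pairs = [(i, i) for i in range(len(t.coords))]
        back, rmsd = align_to_template(rotated, t, pairs)
        assert rmsd < 1e-6
        assert np.allclose(back.coords, t.coords, atol=1e-6)

    def test_rigidity_preserves_internal_distances(self, aligned_set):
        _, aligned, _ = aligned_set
        t, other = aligned[0], aligned[1]
        before = np.linalg.norm(
            other.coords[:, None] - other.coords[None, :], axis=2)
        moved, _ = align_to_template(other, t,
                                     common_core_map(other, t))
        after = np.linalg.norm(
            moved.coords[:, None] - moved.coords[None, :], axis=2)
        assert np.allclose(before, after, atol=1e-9)

    def test_fewer_than_three_pairs_rejected(self, aligned_set):
        _, aligned, _ = aligned_set
        with pytest.raises(ValueError):
            align_to_template(aligned[1], aligned[0], [(0, 0), (1, 1)])


class TestFields:
    def test_distant_probe_sees_nothing(self):
        conf = embed_and_minimize(Chem.MolFromSmiles("CO"), seed=2)
        grid = GridSpec(origin=conf.coords.mean(axis=0) + 50.0, shape=(1, 1, 1))
        block = compute_fields([conf], grid, fields=("fa", "fe"))
        assert np.all(np.abs(block.matrix) < 1e-3)

    def test_probe_at_atom_center_truncated_to_cutoff(self):
        conf = embed_and_minimize(Chem.MolFromSmiles("C"), seed=3)
        grid = GridSpec(origin=conf.coords[0], shape=(1, 1, 1))
        block = compute_fields([conf], grid, fields=("fa",))
        assert block.matrix[0, 0] == pytest.approx(30.0)

    def test_neutral_atoms_give_zero_electrostatics(self):
        # MMFF94 assigns zero charge to saturated-hydrocarbon C and H
        conf = embed_and_minimize(Chem.MolFromSmiles("CC"), seed=4)
        assert np.allclose(conf.charges, 0.0)
        grid = GridSpec.from_conformers([conf], spacing=3.0, margin=3.0)
        block = compute_fields([conf], grid, fields=("fe",))
        assert np.allclose(block.matrix, 0.0)

    def test_rigid_transform_covariance(self):
        """Transforming conformers and grid together leaves fields fixed."""
        conf = embed_and_minimize(Chem.MolFromSmiles("CCO"), seed=6)
        grid = GridSpec.from_conformers([conf], spacing=2.0, margin=3.0)
        block = compute_fields([conf], grid)
        theta = 1.1
        R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        t = np.array([2.0, -3.0, 1.0])
        moved = conf.transformed(R, t)
        pts = grid.points() @ R.T + t
        # recompute the steric field at the co-transformed lattice points
        from qsarkit.field3d import _atom_lj, PROBE_RADIUS, PROBE_EPS
        d2 = np.sum((pts[:, None] - moved.coords[None]) ** 2, axis=2)
        r_a, eps_a = _atom_lj(moved.mol)
        frac6 = ((PROBE_RADIUS + r_a)[None] ** 2 / d2) ** 3
        lj = (np.sqrt(PROBE_EPS * eps_a)[None] * (frac6 ** 2 - 2 * frac6)).sum(axis=1)
        lj = np.clip(lj, -30, 30)
        fa = block.matrix[0][block.col_fields == "fa"]
        assert np.allclose(fa, lj, atol=1e-9)

    def test_energy_truncation_bounds(self, aligned_set):
        _, _, block = aligned_set
        for f in COMFA_FIELDS:
            vals = block.matrix[:, block.col_fields == f]
            assert np.all(np.abs(vals) <= 30.0 + 1e-9)

    def test_column_layout(self, aligned_set):
        _, _, block = aligned_set
        assert block.matrix.shape[1] == block.grid.n_points * len(block.fields)
        sub = block.select_fields(("s", "e"))
        assert sub.matrix.shape[1] == 2 * block.grid.n_points


class TestColumnFilter:
    def test_constant_column_dropped_at_any_positive_threshold(self, rng):
        from qsarkit.field3d import FieldBlock
        grid = GridSpec(origin=np.zeros(3), shape=(2, 1, 1))
        M = np.column_stack([np.full(5, 7.0), rng.normal(size=5) * 10])
        block = FieldBlock(grid, ("fa",), M,
                           np.array(["fa", "fa"], dtype=object),
                           np.arange(2))
        out = column_filter(block, 0.5)
        assert out.matrix.shape[1] == 1

    def test_zero_threshold_keeps_everything(self, aligned_set):
        _, _, block = aligned_set
        out = column_filter(block, 0.0)
        assert out.matrix.shape == block.matrix.shape

    def test_retained_set_matches_per_column_recount(self, aligned_set):
        _, _, block = aligned_set
        thr = 2.0
        out = column_filter(block, thr)
        sd = block.matrix.std(axis=0)
        assert out.matrix.shape[1] == int((sd >= thr).sum())

    def test_all_dropped_raises(self, aligned_set):
        _, _, block = aligned_set
        with pytest.raises(ValueError, match="every column"):
            column_filter(block, 1e9)


class TestQ2Matrix:
    def test_shape_is_32_rows_by_5_filters(self, aligned_set):
        recs, _, block = aligned_set
        y = np.arange(len(recs), dtype=float)
        qm = q2_matrix(block, y, max_components=2)
        assert qm.shape == (32, 5)
        assert list(qm.columns) == [1, 2, 3, 4, 5]

    def test_rows_are_canonical_sorted_subsets(self):
        labels = field_subset_labels()
        assert len(labels) == 32
        assert len(set(labels)) == 32
        assert labels[-1] == "CoMFA"
        for lab in labels[:-1]:
            parts = lab.split(".")
            assert len(set(parts)) == len(parts)
            order = {f: i for i, f in enumerate(SIMILARITY_FIELDS)}
            assert parts == sorted(parts, key=order.get)

    def test_steric_ground_truth_puts_s_row_on_top(self, aligned_set):
        """Activity driven purely by substituent bulk: the steric-similarity
        row must contain the matrix maximum."""
        recs, aligned, block = aligned_set
        sval = block.matrix[:, block.col_fields == "s"]
        # a steric feature: total steric similarity near the varying site
        col = np.argmax(sval.std(axis=0))
        y = sval[:, col] * 0.5
        y = y + np.linspace(0, 0.01, len(y))  # break exact degeneracy
        qm = q2_matrix(block, y, max_components=2)
        best_label, best_thr, _k = qm.attrs["best"]
        assert "s" in best_label.replace("CoMFA", "")
        assert qm.loc["s"].max() == pytest.approx(
            qm.to_numpy().max(), abs=1e-9)


class TestFieldQSAR:
    def test_fit_predict_round_trip(self, aligned_set):
        recs, aligned, block = aligned_set
        sval = block.matrix[:, block.col_fields == "s"]
        y = sval[:, np.argmax(sval.std(axis=0))]
        est = FieldQSAR(fields=("s",), sigma_threshold=0.5,
                        n_components=2).fit(block, y)
        assert est.r2_ > 0.9
        assert np.allclose(est.predict(block), y, atol=np.abs(y).max())
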