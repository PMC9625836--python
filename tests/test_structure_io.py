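import numpy as np
import pytest

import trxss
from trxss.structure_io import (AtomSet, DataError, DisplacementField,
                                adjust_disordered, apply_deformation,
                                count_atoms, displaced_residue_count,
                                extract_displacement_field,
                                mean_ca_displacement, read_structure,
                                write_structure)


def _ca_trace(res_ids, coords):
    """Minimal AtomSet of C-alpha atoms only."""
    n = len(res_ids)
    return AtomSet(np.full(n, "C"), np.asarray(coords, float),
                   np.asarray(res_ids, int), np.full(n, "ALA"),
                   np.full(n, "A"), np.full(n, "CA"),
                   np.full(n, "protein"), np.zeros(n, int))


class TestPdbIO:
    def test_round_trip_preserves_coordinates_and_tags(self, tiny_system,
                                                       tmp_path):
        traj = trxss.make_trajectory(tiny_system, 3, seed=4)
        path = tmp_path / "traj.pdb"
        write_structure(traj, path)
        back = read_structure(path, {"DET": "micelle"})
        assert len(back) == len(traj)
        assert back.n_models == 3
        # PDB prints coordinates to 1e-3 A
        assert np.abs(back.coords - traj.coords).max() <= 1e-3
        assert (back.component == traj.component).all()
        assert (back.element == traj.element).all()
        assert (back.res_id == traj.res_id).all()

    def test_empty_model_file(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        assert len(read_structure(p)) == 0

    def test_single_water_tagged_water(self, tmp_path, tiny_system):
        w = tiny_system.by_component("water")
        one = w.select(w.res_id == w.res_id[0])
        p = tmp_path / "w.pdb"
        write_structure(one, p)
        back = read_structure(p)
        assert len(back) == 3
        assert set(back.component) == {"water"}

    def test_unknown_element_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1 XX   UNK A   1      0.000   0.000   0.000"
            "  1.00  0.00          XX\n")
        with pytest.raises(Exception):
            read_structure(p)


class TestCountAtoms:
    def test_empty(self):
        from trxss.structure_io import empty_atomset
        assert count_atoms(empty_atomset()) == (0, 0, 0)

    def test_one_detergent_molecule_formula(self):
        # C14H28O6-like pseudo-detergent: 48 atoms, 28 H, 20 heavy
        spec = trxss.ToySystemSpec(n_helices=3, residues_per_helix=4,
                                   detergent_count=1, micelle_radius=20.0,
                                   seed=0)
        mic = trxss.make_toy_system(spec).by_component("micelle")
        assert count_atoms(mic) == (48, 28, 20)

    def test_additive_over_components(self, tiny_system):
        total = count_atoms(tiny_system, "all")
        parts = [count_atoms(tiny_system, c)
                 for c in ("protein", "micelle", "water")]
        assert total == tuple(map(sum, zip(*parts)))

    def test_total_is_h_plus_heavy(self, tiny_system):
        tot, h, heavy = count_atoms(tiny_system)
        assert tot == h + heavy


class TestDisplacementField:
    def test_identity_gives_zero_field(self):
        a = _ca_trace([1, 2, 3], [[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        f = extract_displacement_field(a, a, (1, 3))
        assert np.allclose(f.vectors, 0.0)

    def test_translation_gives_constant_field(self):
        a = _ca_trace([1, 2, 3], [[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        b = a.with_coords(a.coords + [1.0, 0.0, 0.0])
        f = extract_displacement_field(a, b, (1, 3))
        assert np.allclose(f.vectors, [[1, 0, 0]] * 3)

    def test_known_per_residue_offsets_recovered(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(5, 3)) * 5
        offsets = rng.normal(size=(5, 3))
        a = _ca_trace(range(10, 15), coords)
        b = a.with_coords(coords + offsets)
        f = extract_displacement_field(a, b, (10, 14))
        assert np.allclose(f.vectors, offsets, atol=1e-12)

    def test_missing_residue_marked_for_adjustment(self):
        a = _ca_trace([1, 2, 3], np.zeros((3, 3)))
        b = _ca_trace([1, 3], np.ones((2, 3)))  # residue 2 missing in target
        f = extract_displacement_field(a, b, (1, 3))
        assert f.needs_adjustment == [2]

    def test_empty_span_raises(self):
        a = _ca_trace([1], [[0, 0, 0]])
        with pytest.raises(ValueError):
            extract_displacement_field(a, a, (5, 3))

    def test_no_ca_in_span_raises(self):
        a = _ca_trace([1], [[0, 0, 0]])
        with pytest.raises(DataError):
            extract_displacement_field(a, a, (100, 110))


class TestAdjustDisordered:
    def _field(self, vecs, start=10):
        return DisplacementField(start, start + len(vecs) - 1,
                                 np.asarray(vecs, float))

    def test_no_residues_listed_unchanged(self):
        f = self._field([[1, 0, 0], [2, 0, 0], [3, 0, 0]])
        g = adjust_disordered(f, [])
        assert np.allclose(g.vectors, f.vectors)

    def test_midpoint_symmetric_average(self):
        v, w = [2.0, 0.0, 0.0], [0.0, 4.0, 0.0]
        f = self._field([v, [99, 99, 99], w])
        g = adjust_disordered(f, [11])
        assert np.allclose(g.vectors[1], [(2 + 0) / 2, (0 + 4) / 2, 0.0])

    def test_block_linear_ramp(self):
        # anchors at residues 10 and 14; block 11-13 interpolates linearly:
        # res 11 -> (3a + 1b)/4, res 12 -> (2a + 2b)/4, res 13 -> (1a + 3b)/4
        a, b = np.array([1.0, 0, 0]), np.array([0, 4.0, 0])
        f = self._field([a, [9, 9, 9], [9, 9, 9], [9, 9, 9], b])
        g = adjust_disordered(f, [11, 12, 13])
        assert np.allclose(g.vectors[1], (3 * a + 1 * b) / 4)
        assert np.allclose(g.vectors[2], (2 * a + 2 * b) / 4)
        assert np.allclose(g.vectors[3], (1 * a + 3 * b) / 4)

    def test_boundary_residue_raises(self):
        f = self._field([[1, 0, 0], [2, 0, 0]])
        with pytest.raises(DataError):
            adjust_disordered(f, [10])


class TestApplyDeformation:
    def test_zero_amplitudes_identity(self, tiny_spec, tiny_system):
        fields = trxss.toy_displacement_fields(tiny_spec)
        # zero out the fixed-amplitude G field too
        fields["G"].vectors[:] = 0.0
        out = apply_deformation(tiny_system, fields, 0.0, 0.0)
        assert np.allclose(out.coords, tiny_system.coords)

    def test_unit_x_field_moves_ca_by_one(self):
        a = _ca_trace([1, 2, 3], np.zeros((3, 3)))
        f = DisplacementField(1, 3, np.tile([1.0, 0, 0], (3, 1)), "EF")
        out = apply_deformation(a, {"EF": f}, 1.0, 0.0)
        assert np.allclose(out.coords[:, 0], 1.0)

    def test_overlapping_spans_rejected(self):
        a = _ca_trace([1, 2, 3], np.zeros((3, 3)))
        f1 = DisplacementField(1, 2, np.zeros((2, 3)), "EF")
        f2 = DisplacementField(2, 3, np.zeros((2, 3)), "C")
        with pytest.raises(ValueError):
            apply_deformation(a, {"EF": f1, "C": f2}, 1.0, 1.0)

    def test_displaced_residue_count_for_canonical_spans(self):
        # helix C Pro77-Pro91, helices EF Leu152-Pro186, helix G Leu211-Phe219
        fields = [DisplacementField(77, 91, np.zeros((15, 3)), "C"),
                  DisplacementField(152, 186, np.zeros((35, 3)), "EF"),
                  DisplacementField(211, 219, np.zeros((9, 3)), "G")]
        assert displaced_residue_count(fields) == 59

    def test_extract_then_apply_reproduces_target(self, tiny_spec,
                                                  tiny_system):
        fields = trxss.toy_displacement_fields(tiny_spec, ef_amplitude=1.7)
        target = apply_deformation(tiny_system, fields, 1.0, 1.0)
        span = (fields["EF"].start, fields["EF"].stop)
        re_extracted = extract_displacement_field(tiny_system, target, span)
        out = apply_deformation(
            tiny_system, {"EF": re_extracted}, 1.0, 0.0)
        prot = tiny_system.component == "protein"
        in_span = (tiny_system.res_id >= span[0]) & \
                  (tiny_system.res_id <= span[1])
        ca = prot & in_span & (tiny_system.atom_name == "CA")
        assert np.allclose(out.coords[ca], target.coords[ca], atol=1e-10)


class TestMeanCaDisplacement:
    def test_identical_structures(self):
        a = _ca_trace([1, 2], [[0, 0, 0], [3, 3, 3]])
        assert mean_ca_displacement(a, a, (1, 2)) == 0.0

    def test_rigid_translation(self):
        a = _ca_trace([1, 2], [[0, 0, 0], [3, 3, 3]])
        b = a.with_coords(a.coords + [0.0, 0.0, 2.0])
        assert mean_ca_displacement(a, b, (1, 2)) == pytest.approx(2.0)

    def test_disjoint_residues_raise(self):
        a = _ca_trace([1], [[0, 0, 0]])
        b = _ca_trace([5], [[0, 0, 0]])
        with pytest.raises(DataError):
            mean_ca_displacement(a, b, (1, 5))
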