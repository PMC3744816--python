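"""Conformer construction, dihedral measurement, clashes and geometry QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ensemblefit as ef
from ensemblefit import fixtures as fx
from ensemblefit.errors import GeometryError, InputError, UndefinedDihedralError
from ensemblefit.geometry import (
    angle_from_coords,
    dihedral_from_coords,
    solve_ring_state,
    wrap_angle,
)


def independent_dihedral(p0, p1, p2, p3):
    """Oracle: textbook atan2 dihedral, coded independently of the package."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    c12 = np.cross(b1, b2)
    c23 = np.cross(b2, b3)
    x = np.dot(c12, c23)
    y = np.dot(np.cross(c12, c23), b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(y, x))


class TestDihedral:
    def test_trans_butane_is_180(self):
        t = fx.butane_template()
        c = ef.build_conformer(t, {"tor": 180.0})
        assert ef.measure_dihedral(c, "C1", "C2", "C3", "C4") == pytest.approx(180.0)

    def test_mirror_negates_dihedral(self):
        t = fx.butane_template()
        c = ef.build_conformer(t, {"tor": 63.0})
        mirrored = c.coordinates * np.array([1.0, 1.0, -1.0])
        m = ef.CartesianConformer(t, mirrored, {}, {})
        assert ef.measure_dihedral(m, "C1", "C2", "C3", "C4") == pytest.approx(-63.0)

    @given(st.lists(st.floats(-5, 5), min_size=12, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_atan2_oracle(self, flat):
        pts = np.array(flat).reshape(4, 3)
        b2 = pts[2] - pts[1]
        if np.linalg.norm(b2) < 1e-3:
            return
        try:
            got = float(dihedral_from_coords(*pts))
        except UndefinedDihedralError:
            return
        want = independent_dihedral(*pts)
        assert abs(wrap_angle(got - want)) < 1e-6

    def test_collinear_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]], float)
        t = fx.butane_template()
        c = ef.CartesianConformer(t, np.vstack([pts, pts[:2]]), {}, {})
        with pytest.raises(UndefinedDihedralError):
            ef.measure_dihedral(c, "C1", "C2", "C3", "C4")

    def test_distinct_atoms_required(self):
        t = fx.butane_template()
        c = ef.build_conformer(t, {"tor": 60.0})
        with pytest.raises(InputError):
            ef.measure_dihedral(c, "C1", "C2", "C2", "C4")


class TestBuildConformer:
    def test_cis_gives_minimal_end_distance(self):
        t = fx.butane_template()
        d = {
            tor: np.linalg.norm(
                ef.build_conformer(t, {"tor": tor}).coords_of("C1")
                - ef.build_conformer(t, {"tor": tor}).coords_of("C4")
            )
            for tor in range(-180, 181, 15)
        }
        assert min(d, key=d.get) == 0

    def test_streptomycin_round_trip_all_torsions(
        self, strepto_template, table_mean_torsions
    ):
        c = ef.build_conformer(strepto_template, table_mean_torsions)
        for name, quad in strepto_template.rotatable_bonds.items():
            got = ef.measure_dihedral(c, *quad)
            assert abs(wrap_angle(got - table_mean_torsions[name])) < 1e-3, name

    def test_round_trip_random_torsions(self, strepto_template, rng):
        for _ in range(5):
            tors = {
                name: float(rng.uniform(-180, 180))
                for name in strepto_template.rotatable_bonds
            }
            c = ef.build_conformer(strepto_template, tors)
            for name, quad in strepto_template.rotatable_bonds.items():
                got = ef.measure_dihedral(c, *quad)
                assert abs(wrap_angle(got - tors[name])) < 1e-3

    def test_input_accepts_0_360_convention(self, strepto_template, table_mean_torsions):
        shifted = {k: v % 360.0 for k, v in table_mean_torsions.items()}
        a = ef.build_conformer(strepto_template, table_mean_torsions)
        b = ef.build_conformer(strepto_template, shifted)
        assert np.allclose(a.coordinates, b.coordinates)

    def test_unknown_torsion_name_rejected(self, strepto_template, table_mean_torsions):
        with pytest.raises(InputError):
            ef.build_conformer(
                strepto_template, {**table_mean_torsions, "nope": 10.0}
            )
        with pytest.raises(InputError):
            ef.build_conformer(
                strepto_template, table_mean_torsions, puckers={"nope": "4C1"}
            )

    def test_missing_torsion_rejected(self, strepto_template):
        with pytest.raises(InputError):
            ef.build_conformer(strepto_template, {"phi12": 0.0})

    def test_bond_lengths_and_angles_fixed_regardless_of_torsions(
        self, strepto_template, rng
    ):
        for _ in range(3):
            tors = {
                name: float(rng.uniform(-180, 180))
                for name in strepto_template.rotatable_bonds
            }
            c = ef.build_conformer(strepto_template, tors)
            rep = ef.geometry_report(c)
            bonds = rep[rep.feature == "bond"]
            angles = rep[rep.feature == "angle"]
            assert (np.abs(bonds.observed - bonds.reference) < 1e-3).all()
            assert (np.abs(angles.observed - angles.reference) < 0.1).all()


class TestRigidBodyInvariance:
    def test_rotation_translation_leave_dihedrals_and_clashes(self, strepto_template,
                                                              table_mean_torsions, rng):
        c = ef.build_conformer(strepto_template, table_mean_torsions)
        # random rotation via QR
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = c.coordinates @ Q.T + np.array([5.0, -3.0, 11.0])
        c2 = ef.CartesianConformer(strepto_template, moved, {}, {})
        for name, quad in strepto_template.rotatable_bonds.items():
            assert ef.measure_dihedral(c2, *quad) == pytest.approx(
                ef.measure_dihedral(c, *quad), abs=1e-6
            )
        cl1 = ef.detect_clashes(c)
        cl2 = ef.detect_clashes(c2)
        assert [p for p, _ in cl1] == [p for p, _ in cl2]
        assert np.allclose([d for _, d in cl1], [d for _, d in cl2], atol=1e-6)


class TestClashes:
    def test_pair_below_threshold_flagged(self):
        t = fx.butane_template()
        # compress the torsion to bring C1 and C4 close: use raw coordinates
        c = ef.build_conformer(t, {"tor": 0.0})
        d14 = np.linalg.norm(c.coords_of("C1") - c.coords_of("C4"))
        hits = ef.detect_clashes(c, min_dist=d14 + 0.1)
        assert (("C1", "C4"), pytest.approx(d14)) in [
            (p, pytest.approx(d)) for p, d in hits
        ]

    def test_example_contact_below_2p4(self):
        t = fx.butane_template()
        coords = ef.build_conformer(t, {"tor": 60.0}).coordinates.copy()
        # place C4 exactly 2.3 A from C1
        coords[3] = coords[0] + np.array([2.3, 0, 0])
        c = ef.CartesianConformer(t, coords, {}, {})
        hits = ef.detect_clashes(c, min_dist=2.4)
        assert (("C1", "C4") in [p for p, _ in hits])

    def test_no_clashes_empty_list(self):
        t = fx.butane_template()
        c = ef.build_conformer(t, {"tor": 180.0})
        assert ef.detect_clashes(c, min_dist=0.5) == []

    def test_brute_force_oracle(self, strepto_template, table_mean_torsions):
        c = ef.build_conformer(strepto_template, table_mean_torsions)
        got = ef.detect_clashes(c, min_dist=3.0)
        # oracle: double loop over heavy atoms with BFS bond distances
        t = strepto_template
        gd = t.graph_distances(max_dist=2)
        expected = []
        names = t.atom_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if t.atoms[i].element == "H" or t.atoms[j].element == "H":
                    continue
                if gd[i, j] <= 2:
                    continue
                d = np.linalg.norm(c.coordinates[i] - c.coordinates[j])
                if d < 3.0:
                    expected.append(((names[i], names[j]), d))
        assert {p for p, _ in got} == {p for p, _ in expected}
        want = dict(expected)
        for p, d in got:
            assert d == pytest.approx(want[p], abs=1e-9)
        dists = [d for _, d in got]
        assert dists == sorted(dists)


class TestGeometryReport:
    def test_built_conformer_has_zero_z(self, strepto_template, table_mean_torsions):
        c = ef.build_conformer(strepto_template, table_mean_torsions)
        rep = ef.geometry_report(c)
        assert rep.z.max() < 0.05
        assert not rep.flagged.any()

    def test_exactly_three_spreads_not_flagged_strict(self):
        t = fx.butane_template()
        c = ef.build_conformer(t, {"tor": 180.0})
        coords = c.coordinates.copy()
        # displace H4 along its bond by exactly 3 bond spreads
        v = coords[5] - coords[3]
        coords[5] = coords[3] + v / np.linalg.norm(v) * (1.09 + 3 * t.bond_spread)
        c2 = ef.CartesianConformer(t, coords, {}, {})
        rep = ef.geometry_report(c2, z_threshold=3.0)
        row = rep[(rep.feature == "bond") & (rep.atoms == "C4-H4")].iloc[0]
        assert row.z == pytest.approx(3.0, abs=1e-6)
        assert not row.flagged

    def test_three_and_a_half_spreads_flagged(self):
        t = fx.butane_template()
        c = ef.build_conformer(t, {"tor": 180.0})
        coords = c.coordinates.copy()
        v = coords[5] - coords[3]
        coords[5] = coords[3] + v / np.linalg.norm(v) * (1.09 + 3.5 * t.bond_spread)
        c2 = ef.CartesianConformer(t, coords, {}, {})
        rep = ef.geometry_report(c2, z_threshold=3.0)
        row = rep[(rep.feature == "bond") & (rep.atoms == "C4-H4")].iloc[0]
        assert row.flagged


class TestRings:
    def test_ring_closure_within_tolerance(self, strepto_template, table_mean_torsions):
        for ring, spec in strepto_template.rings.items():
            for state in spec.states:
                c = ef.build_conformer(
                    strepto_template, table_mean_torsions, puckers={ring: state}
                )
                i0 = strepto_template.index(spec.path[0])
                i1 = strepto_template.index(spec.path[-1])
                closure = np.linalg.norm(c.coordinates[i0] - c.coordinates[i1])
                assert closure == pytest.approx(
                    spec.states[state].closure_length, abs=1e-3
                )

    def test_solver_rejects_impossible_ring(self):
        with pytest.raises(GeometryError):
            solve_ring_state(
                [1.5, 1.5, 1.5, 1.5, 20.0], [104] * 5, [35, -30, 10, 15, -30]
            )

    def test_pseudorotation_states_differ(self):
        t = fx.ribose_template()
        a = ef.build_conformer(t, {}, puckers={"ring": "P018"})
        b = ef.build_conformer(t, {}, puckers={"ring": "P198"})
        # H1-H2 dihedral flips with the pucker phase
        d1 = dihedral_from_coords(
            a.coords_of("H1"), a.coords_of("C1"), a.coords_of("C2"), a.coords_of("H2")
        )
        d2 = dihedral_from_coords(
            b.coords_of("H1"), b.coords_of("C1"), b.coords_of("C2"), b.coords_of("H2")
        )
        assert abs(wrap_angle(d1 - d2)) > 30


class TestTemplateIO:
    def test_json_round_trip_builds_identical_coordinates(
        self, strepto_template, table_mean_torsions, tmp_path
    ):
        p = tmp_path / "topology.json"
        strepto_template.save(p)
        t2 = ef.MoleculeTemplate.load(p)
        a = ef.build_conformer(strepto_template, table_mean_torsions)
        b = ef.build_conformer(t2, table_mean_torsions)
        assert np.allclose(a.coordinates, b.coordinates, atol=1e-12)

    def test_pdb_round_trip(self, strepto_template, table_mean_torsions, tmp_path):
        c1 = ef.build_conformer(strepto_template, table_mean_torsions)
        c2 = ef.build_conformer(
            strepto_template, {**table_mean_torsions, "phi12": 60.0}
        )
        coords = np.stack([c1.coordinates, c2.coordinates])
        path = tmp_path / "models.pdb"
        ef.write_pdb(path, strepto_template, coords)
        back = ef.read_pdb_coords(path, strepto_template)
        assert back.shape == coords.shape
        assert np.abs(back - coords).max() < 1e-3
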