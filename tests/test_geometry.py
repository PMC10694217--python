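"""Superposition, ring planes, cofactor rotation, and hydrogen bonds."""

import math

import numpy as np
import pytest

from frlpsi import geometry as geo
from frlpsi.geometry import (
    GeometryError,
    compare_hbond_quality,
    detect_hbonds,
    fit_ring_plane,
    measure_cofactor_rotation,
    superpose,
)
from frlpsi.structio import Atom, Chain, Cofactor, Residue, StructureModel
from frlpsi.synthetic_data import (
    GeometrySpec,
    _rotation_about_axis,
    generate_rotated_cofactor_pair,
)


def horn_quaternion_superpose(ref, mob):
    """Independent quaternion (Horn) absolute-orientation solution."""
    P = mob - mob.mean(axis=0)
    Q = ref - ref.mean(axis=0)
    S = P.T @ Q
    N = np.array(
        [
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ]
    )
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    moved = P @ R.T + ref.mean(axis=0)
    return float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))


class TestSuperpose:
    def test_identical_sets(self, rng):
        X = rng.normal(size=(10, 3))
        s = superpose(X, X)
        assert s.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(s.rotation, np.eye(3), atol=1e-10)

    def test_recovers_known_rotation(self, rng):
        X = rng.normal(size=(20, 3))
        R = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), 17.0)
        Y = X @ R.T + np.array([1.0, -2.0, 3.0])
        s = superpose(X, Y)
        assert s.rmsd == pytest.approx(0.0, abs=1e-9)
        angle = math.degrees(math.acos((np.trace(s.rotation) - 1) / 2))
        assert angle == pytest.approx(17.0, abs=1e-6)

    def test_determinant_plus_one(self, rng):
        X = rng.normal(size=(30, 3))
        Y = X.copy()
        Y[:, 0] *= -1  # mirrored: best proper rotation must not reflect
        s = superpose(X, Y)
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            X = rng.normal(size=(50, 3)) * 5
            R = _rotation_about_axis(rng.normal(size=3), float(rng.uniform(0, 180)))
            Y = X @ R.T + rng.normal(size=3) + rng.normal(scale=0.2, size=(50, 3))
            s = superpose(X, Y)
            assert s.rmsd == pytest.approx(horn_quaternion_superpose(X, Y), abs=1e-8)

    def test_too_few_or_collinear(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError, match="collinear"):
            superpose(line, line)


class TestFitRingPlane:
    def test_exact_xy_plane(self):
        pts = np.array([[1.0, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]])
        p = fit_ring_plane(pts)
        assert abs(p.unit_normal[2]) == pytest.approx(1.0, abs=1e-12)
        assert p.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_tilted_plane_angle(self):
        pts = np.array([[1.0, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0], [0.5, 0.5, 0]])
        R = _rotation_about_axis(np.array([1.0, 0, 0]), 30.0)
        p = fit_ring_plane(pts @ R.T)
        angle = math.degrees(math.acos(abs(p.unit_normal[2])))
        assert angle == pytest.approx(30.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self, rng):
        pts = rng.normal(size=(12, 3))
        pts[:, 2] *= 0.05  # noisy but planar
        p = fit_ring_plane(pts)
        C = np.cov((pts - pts.mean(axis=0)).T)
        vals, vecs = np.linalg.eigh(C)
        oracle_normal = vecs[:, 0]
        assert abs(abs(np.dot(p.unit_normal, oracle_normal)) - 1) < 1e-9

    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            fit_ring_plane(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))


class TestCofactorRotation:
    def test_structure_against_itself(self):
        ref, _, _ = generate_rotated_cofactor_pair(GeometrySpec(seed=0, scramble=False))
        m = measure_cofactor_rotation(ref, ref, ("X", 901))
        assert m.angle_deg == pytest.approx(0.0, abs=1e-9)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in m.per_ring_centroid_shift.values())

    @pytest.mark.parametrize("ring", list("ABCDE"))
    @pytest.mark.parametrize("angle", [1.0, 5.0, 20.0])
    def test_recovers_planted_rotation_and_pivot(self, ring, angle):
        ref, mob, truth = generate_rotated_cofactor_pair(
            GeometrySpec(seed=13, rotation_deg=angle, pivot_ring=ring)
        )
        m = measure_cofactor_rotation(ref, mob, ("X", 901))
        assert m.angle_deg == pytest.approx(angle, abs=0.1)
        assert m.pivot_ring == ring

    def test_symmetric_in_reference_and_mobile(self):
        ref, mob, _ = generate_rotated_cofactor_pair(GeometrySpec(seed=4, rotation_deg=7.0))
        a = measure_cofactor_rotation(ref, mob, ("X", 901)).angle_deg
        b = measure_cofactor_rotation(mob, ref, ("X", 901)).angle_deg
        assert abs(a - b) < 1e-6

    def test_rigid_motion_invariance(self, rng):
        ref, mob, _ = generate_rotated_cofactor_pair(GeometrySpec(seed=5, rotation_deg=5.0))
        m0 = measure_cofactor_rotation(ref, mob, ("X", 901))
        R = _rotation_about_axis(rng.normal(size=3), 73.0)
        t = np.array([3.0, -8.0, 12.0])
        for model in (ref, mob):
            for ch in model.chains:
                for res in ch.residues:
                    for a in res.atoms:
                        a.xyz = R @ a.xyz + t
            for cof in model.cofactors:
                for a in cof.atoms:
                    a.xyz = R @ a.xyz + t
        m1 = measure_cofactor_rotation(ref, mob, ("X", 901))
        assert m1.angle_deg == pytest.approx(m0.angle_deg, abs=1e-6)
        for ring in m0.per_ring_centroid_shift:
            assert m1.per_ring_centroid_shift[ring] == pytest.approx(
                m0.per_ring_centroid_shift[ring], abs=1e-6
            )

    def test_missing_cofactor_named(self):
        ref, mob, _ = generate_rotated_cofactor_pair(GeometrySpec(seed=6))
        with pytest.raises(GeometryError, match="synthetic_mobile.*Z:1"):
            measure_cofactor_rotation(ref, mob, ("X", 901), mobile_site=("Z", 1))


def _hbond_fixture():
    """A keto oxygen with its carbon antecedent and a donor nitrogen.

    The donor sits 2.9 A from the oxygen with an exact 120-degree
    antecedent-acceptor-donor angle.
    """
    c = np.array([0.0, 0.0, 0.0])
    o = np.array([1.23, 0.0, 0.0])
    ang = math.radians(120.0)
    d = o + 2.9 * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    res_o = Residue(1, "", "GLY", [Atom("C", "C", c), Atom("O", "O", o)])
    res_n = Residue(5, "", "GLY", [Atom("N", "N", d)])
    return StructureModel("hb", chains=[Chain("A", [res_o, res_n])], cofactors=[])


class TestHydrogenBonds:
    def test_beyond_cutoff_no_bond(self):
        st = _hbond_fixture()
        st.chains[0].residues[1].atoms[0].xyz = np.array([6.0, 0.0, 0.0])
        assert detect_hbonds(st, distance_cutoff=3.5) == []

    def test_constructed_optimal_geometry(self):
        st = _hbond_fixture()
        bonds = detect_hbonds(st)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.distance == pytest.approx(2.9, abs=1e-9)
        assert b.acceptor_angle_deg == pytest.approx(120.0, abs=1e-9)
        assert b.quality == pytest.approx(0.0, abs=1e-9)
        assert b.acceptor == ("A", 1, "O")
        assert b.donor == ("A", 5, "N")

    def test_covalent_and_13_pairs_excluded(self):
        # N-CA-C-O backbone of one residue: N..O is a 1-4 pair but N-CA
        # and 1-3 pairs are never hydrogen bonds
        res = Residue(
            1,
            "",
            "GLY",
            [
                Atom("N", "N", np.array([0.0, 0.0, 0.0])),
                Atom("CA", "C", np.array([1.45, 0.0, 0.0])),
                Atom("C", "C", np.array([2.2, 1.3, 0.0])),
                Atom("O", "O", np.array([1.6, 2.4, 0.0])),
            ],
        )
        st = StructureModel("x", chains=[Chain("A", [res])], cofactors=[])
        bonds = detect_hbonds(st)
        assert all({b.donor[2], b.acceptor[2]} != {"N", "CA"} for b in bonds)
        assert all({b.donor[2], b.acceptor[2]} != {"N", "C"} for b in bonds)

    def test_selection_restricts_output(self):
        st = _hbond_fixture()
        assert detect_hbonds(st, around=[("A", 1)])
        assert detect_hbonds(st, around=[("A", 99)]) == []


class TestCompareHbondQuality:
    def _bond(self, angle):
        from frlpsi.geometry import HydrogenBond

        return HydrogenBond(("A", 1, "N"), ("A", 2, "O"), 2.9, angle, abs(angle - 120))

    def test_identical_angles_tie(self):
        rows = compare_hbond_quality({"keto": self._bond(118.0)}, {"keto": self._bond(118.2)})
        assert rows[0]["closer"] == "equal"

    def test_closer_angle_wins(self):
        rows = compare_hbond_quality({"keto": self._bond(118.0)}, {"keto": self._bond(95.0)})
        assert rows[0]["closer"] == "a"

    def test_unpaired_reported(self):
        rows = compare_hbond_quality({"keto": self._bond(118.0)}, {})
        assert rows[0]["closer"] == "unpaired"
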