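"""Tensor orientation angles in the peptide-plane frame."""

import numpy as np
import pytest

from peptensor import structure_io
from peptensor.orientation import (
    DegenerateEigenvalueError,
    cst_orientation,
    in_plane_azimuth,
    off_plane_tilt,
    select_xi,
)
from peptensor.structure_io import PlaneFrame, backbone_sites, peptide_plane_frame
from peptensor.synthetic_data import BackboneSpec, make_backbone, make_tensor
from peptensor.tensor_core import eigensystem

from conftest import random_rotation


def _frame_from_vectors(u, v):
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    n = np.cross(u, v)
    return PlaneFrame(origin=np.zeros(3), u=u, v=v, n=n / np.linalg.norm(n))


class TestSelectXi:
    def test_diagonal(self):
        eig = eigensystem(np.diag([10.0, 50.0, 100.0]))
        xi1, xi2 = select_xi(eig)
        assert abs(xi1[0]) == pytest.approx(1.0)
        assert abs(xi2[1]) == pytest.approx(1.0)

    def test_permuted_construction(self):
        rng = np.random.default_rng(44)
        rot = random_rotation(rng)
        m = rot @ np.diag([50.0, 100.0, 10.0]) @ rot.T
        xi1, xi2 = select_xi(eigensystem(m))
        assert abs(np.dot(xi1, rot[:, 2])) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.dot(xi2, rot[:, 0])) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_smallest_raises(self):
        with pytest.raises(DegenerateEigenvalueError):
            select_xi(eigensystem(np.diag([10.0, 10.0, 100.0])))

    def test_largest_convention(self):
        eig = eigensystem(np.diag([10.0, 50.0, 100.0]))
        xi1, _ = select_xi(eig, convention="largest")
        assert abs(xi1[2]) == pytest.approx(1.0)


class TestCstOrientation:
    def test_aligned_case(self):
        fr = _frame_from_vectors([1, 0, 0], [0, 1, 0])
        # xi1 along u (smallest), xi2 along n
        vecs = np.column_stack([fr.u, fr.n, np.cross(fr.u, fr.n)])
        eig = eigensystem(vecs @ np.diag([10.0, 50, 100]) @ vecs.T)
        ang = cst_orientation(eig, fr)
        assert ang.alpha == pytest.approx(0.0, abs=1e-6)
        assert ang.beta == pytest.approx(0.0, abs=1e-6)
        assert ang.gamma == pytest.approx(0.0, abs=1e-6)

    def test_normal_case(self):
        fr = _frame_from_vectors([1, 0, 0], [0, 1, 0])
        vecs = np.column_stack([fr.n, fr.u, np.cross(fr.n, fr.u)])
        ang = cst_orientation(eigensystem(vecs @ np.diag([10.0, 50, 100]) @ vecs.T), fr)
        assert ang.alpha == pytest.approx(90.0)
        assert ang.beta == pytest.approx(90.0)

    def test_undefined_frame_returns_none(self):
        eig = eigensystem(np.diag([10.0, 50.0, 100.0]))
        assert cst_orientation(eig, None) is None

    def test_brute_force_oracle(self):
        """500 random eigenframes vs raw dot/cross-product evaluation."""
        rng = np.random.default_rng(500)
        fr = _frame_from_vectors(rng.normal(size=3), rng.normal(size=3))
        for _ in range(500):
            vecs = random_rotation(rng)
            eig = eigensystem(vecs @ np.diag([10.0, 50.0, 100.0]) @ vecs.T)
            got = cst_orientation(eig, fr)
            xi1, xi2 = vecs[:, 0], vecs[:, 1]
            n = np.cross(fr.u, fr.v)
            n = n / np.linalg.norm(n)
            beta = np.degrees(np.arccos(np.clip(abs(np.dot(xi1, fr.u)), 0, 1)))
            gamma = np.degrees(np.arccos(np.clip(abs(np.dot(xi2, n)), 0, 1)))
            proj = xi1 - np.dot(xi1, n) * n
            alpha = np.degrees(np.arctan2(abs(np.dot(xi1, n)),
                                          np.linalg.norm(proj)))
            assert got.beta == pytest.approx(beta, abs=1e-9)
            assert got.gamma == pytest.approx(gamma, abs=1e-9)
            assert got.alpha == pytest.approx(alpha, abs=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(61)
        st = make_backbone(BackboneSpec(residues=["ALA"] * 4))
        site = backbone_sites(st)[1]
        fr = peptide_plane_frame(site)
        t = make_tensor([10.0, 50.0, 100.0], frame=fr, angles=(4.0, 18.0, 30.0))
        a0 = cst_orientation(eigensystem(t), fr)
        rot, shift = random_rotation(rng), rng.normal(size=3) * 5
        for atom in st.atoms:
            atom.position = rot @ atom.position + shift
        fr1 = peptide_plane_frame(backbone_sites(st)[1])
        a1 = cst_orientation(eigensystem(rot @ t.matrix @ rot.T), fr1)
        assert a1.alpha == pytest.approx(a0.alpha, abs=1e-9)
        assert a1.beta == pytest.approx(a0.beta, abs=1e-9)
        assert a1.gamma == pytest.approx(a0.gamma, abs=1e-9)

    def test_eigenvector_sign_invariance(self):
        rng = np.random.default_rng(72)
        fr = _frame_from_vectors(rng.normal(size=3), rng.normal(size=3))
        vecs = random_rotation(rng)
        eig = eigensystem(vecs @ np.diag([10.0, 50.0, 100.0]) @ vecs.T)
        a0 = cst_orientation(eig, fr)
        for k in range(3):
            flipped = eig.vectors.copy()
            flipped[:, k] *= -1
            eig2 = type(eig)(values=eig.values, vectors=flipped, kind=eig.kind)
            a1 = cst_orientation(eig2, fr)
            assert (a1.alpha, a1.beta, a1.gamma) == pytest.approx(
                (a0.alpha, a0.beta, a0.gamma), abs=1e-12)

    def test_angles_in_range(self):
        rng = np.random.default_rng(83)
        fr = _frame_from_vectors(rng.normal(size=3), rng.normal(size=3))
        for _ in range(100):
            vecs = random_rotation(rng)
            eig = eigensystem(vecs @ np.diag([10.0, 50.0, 100.0]) @ vecs.T)
            a = cst_orientation(eig, fr)
            assert 0.0 <= a.alpha <= 90.0
            assert 0.0 <= a.beta <= 90.0
            assert 0.0 <= a.gamma <= 90.0

    def test_spherical_triangle_identity(self):
        """cos(beta) = cos(alpha) * cos(in-plane azimuth)."""
        rng = np.random.default_rng(94)
        fr = _frame_from_vectors(rng.normal(size=3), rng.normal(size=3))
        for _ in range(100):
            vecs = random_rotation(rng)
            eig = eigensystem(vecs @ np.diag([10.0, 50.0, 100.0]) @ vecs.T)
            a = cst_orientation(eig, fr)
            tau = in_plane_azimuth(eig, fr)
            assert np.cos(np.radians(a.beta)) == pytest.approx(
                np.cos(np.radians(a.alpha)) * np.cos(np.radians(tau)), abs=1e-9)


class TestOffPlaneTilt:
    def setup_method(self):
        self.p = (np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))

    def _eig_with_largest_along(self, direction, rng):
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        # complete to an orthonormal triple with d as the last column
        q, _ = np.linalg.qr(np.column_stack([d, rng.normal(size=(3, 2))]))
        vecs = np.column_stack([q[:, 1], q[:, 2], q[:, 0]])
        m = vecs @ np.diag([10.0, 50.0, 100.0]) @ vecs.T
        return eigensystem(m)

    def test_in_plane_vector(self):
        rng = np.random.default_rng(1)
        eig = self._eig_with_largest_along([1, 1, 0], rng)
        assert off_plane_tilt(eig, *self.p) == pytest.approx(0.0, abs=1e-9)

    def test_normal_vector(self):
        rng = np.random.default_rng(2)
        eig = self._eig_with_largest_along([0, 0, 1], rng)
        assert off_plane_tilt(eig, *self.p) == pytest.approx(90.0, abs=1e-9)

    def test_complementary_angle_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = rng.normal(size=3)
            eig = self._eig_with_largest_along(d, rng)
            got = off_plane_tilt(eig, *self.p)
            normal = np.array([0.0, 0.0, 1.0])
            to_normal = np.degrees(np.arccos(np.clip(
                abs(np.dot(d / np.linalg.norm(d), normal)), 0, 1)))
            assert got == pytest.approx(90.0 - to_normal, abs=1e-9)

    def test_collinear_plane_raises(self):
        eig = eigensystem(np.diag([10.0, 50.0, 100.0]))
        with pytest.raises(structure_io.GeometryError):
            off_plane_tilt(eig, np.zeros(3), np.array([1.0, 0, 0]),
                           np.array([2.0, 0, 0]))
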