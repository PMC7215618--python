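"""Structure parsing, backbone geometry and peptide-plane frames."""

import numpy as np
import pytest

from peptensor import datasets
from peptensor.structure_io import (
    GeometryError,
    PDBParseError,
    StructureError,
    backbone_sites,
    dihedral,
    nh_bond_length,
    parse_pdb,
    peptide_plane_frame,
    phi_psi,
    write_pdb,
)
from peptensor.synthetic_data import BackboneSpec, make_backbone

from conftest import random_rotation


class TestParsePDB:
    def test_minimal_glycine(self, glycine_pdb):
        st = parse_pdb(glycine_pdb)
        assert len(st.residues) == 1
        assert len(st.atoms) == 5
        assert st.residues[0].name == "GLY"
        np.testing.assert_allclose(st.residues[0].atom("CA").position,
                                   [1.458, 0.0, 0.0])

    def test_altloc_b_dropped(self, glycine_pdb):
        extra = ("ATOM      6  CB BGLY A   1       9.000   9.000   9.000"
                 "  1.00  0.00           C\n")
        st = parse_pdb(glycine_pdb.replace("END\n", extra + "END\n"))
        assert len(st.atoms) == 5
        assert st.residues[0].atom("CB") is None

    def test_malformed_record_names_line(self, glycine_pdb):
        bad = glycine_pdb.replace("1.458", "1.4x8")
        with pytest.raises(PDBParseError, match="line 3"):
            parse_pdb(bad)

    def test_empty_input(self):
        with pytest.raises(PDBParseError, match="no ATOM"):
            parse_pdb("REMARK nothing here\nEND\n")

    def test_write_parse_roundtrip(self, samarosporin_like_structure):
        st = samarosporin_like_structure
        st2 = parse_pdb(write_pdb(st))
        assert len(st2.atoms) == len(st.atoms)
        for a, b in zip(st.atoms, st2.atoms):
            assert a.name == b.name
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)


class TestBackboneSites:
    def test_peptaibol_residue_kinds(self, samarosporin_like_structure):
        sites = backbone_sites(samarosporin_like_structure)
        assert len(sites) == 15
        kinds = [s.kind for s in sites]
        assert kinds.count("canonical") == 5
        assert kinds.count("Aib") == 6
        assert kinds.count("Hyp") == 2
        assert kinds.count("Iva") == 1
        assert kinds.count("Fol") == 1

    def test_hydroxyproline_has_no_amide_h(self, samarosporin_like_structure):
        sites = backbone_sites(samarosporin_like_structure)
        no_h = [s.residue_index for s in sites if s.h is None]
        assert no_h == [10, 13]
        assert nh_bond_length(sites[9]) is None

    def test_chain_termini(self, glycine_pdb):
        pdb_2res = glycine_pdb  # single residue: both neighbours absent
        sites = backbone_sites(parse_pdb(pdb_2res))
        assert len(sites) == 1
        assert sites[0].prev_c is None and sites[0].next_n is None
        assert phi_psi(sites[0]) == (None, None)

    def test_missing_backbone_atom_raises(self, glycine_pdb):
        no_ca = "\n".join(l for l in glycine_pdb.splitlines()
                          if " CA " not in l) + "\n"
        with pytest.raises(StructureError, match="GLY1"):
            backbone_sites(parse_pdb(no_ca))

    def test_unknown_residue_kind_other(self, glycine_pdb, caplog):
        st = parse_pdb(glycine_pdb.replace("GLY", "XYZ"))
        with caplog.at_level("WARNING"):
            sites = backbone_sites(st)
        assert sites[0].kind == "other"

    def test_amide_h_nearest_fallback(self, glycine_pdb):
        # rename H to a nonstandard code; nearest hydrogen within 1.2 A wins
        st = parse_pdb(glycine_pdb.replace(" H   GLY", " HT1 GLY")
                       .replace("-0.500  -0.800   0.300", "-0.300  -0.900   0.200"))
        sites = backbone_sites(st)
        assert sites[0].h is not None and sites[0].h.name == "HT1"


def _dihedral_oracle(p1, p2, p3, p4):
    """Independent brute force: arccos of normal-plane angle, signed by
    the triple product of the normals with the central bond."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    c = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) > 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0)

    def test_planar_cis_is_0(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_points_raise(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_brute_force_oracle_agreement(self):
        rng = np.random.default_rng(20260930)
        checked = 0
        while checked < 1000:
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                got = dihedral(*pts)
            except GeometryError:
                continue
            want = _dihedral_oracle(*pts)
            diff = abs((got - want + 180.0) % 360.0 - 180.0)
            assert diff < 1e-9
            checked += 1

    @pytest.mark.parametrize("phi,psi", [(-57, -47), (-75, 145), (-150, 150)])
    def test_builder_roundtrip(self, phi, psi):
        st = make_backbone(BackboneSpec(residues=["GLY"] * 6, phi=phi, psi=psi))
        for site in backbone_sites(st)[1:-1]:
            got_phi, got_psi = phi_psi(site)
            assert got_phi == pytest.approx(phi, abs=0.01)
            assert got_psi == pytest.approx(psi, abs=0.01)

    def test_rigid_motion_invariance(self, helix_structure):
        rng = np.random.default_rng(11)
        rot, t = random_rotation(rng), rng.normal(size=3) * 10
        ref = [phi_psi(s) for s in backbone_sites(helix_structure)]
        for atom in helix_structure.atoms:
            atom.position = rot @ atom.position + t
        for (phi0, psi0), site in zip(ref, backbone_sites(helix_structure)):
            phi1, psi1 = phi_psi(site)
            if phi0 is not None:
                assert phi1 == pytest.approx(phi0, abs=1e-9)
            if psi0 is not None:
                assert psi1 == pytest.approx(psi0, abs=1e-9)


class TestNHBond:
    def test_tabulated_length(self):
        spec = BackboneSpec(residues=["ALA"] * 3, r_nh=1.0173)
        sites = backbone_sites(make_backbone(spec))
        assert nh_bond_length(sites[1]) == pytest.approx(101.73, abs=1e-9)

    def test_roundtrip_exact(self):
        spec = BackboneSpec(residues=["ALA"] * 3, r_nh=1.025)
        sites = backbone_sites(make_backbone(spec))
        assert nh_bond_length(sites[1]) == pytest.approx(102.5, abs=1e-6)

    def test_coincident_n_h_raises(self, glycine_pdb):
        st = parse_pdb(glycine_pdb.replace("-0.500  -0.800   0.300",
                                           " 0.000   0.000   0.000"))
        with pytest.raises(GeometryError):
            nh_bond_length(backbone_sites(st)[0])


class TestPlaneFrame:
    def test_axis_aligned(self, glycine_pdb):
        st = parse_pdb(glycine_pdb
                       .replace("-0.500  -0.800   0.300", " 1.000   0.000   0.000")
                       .replace("1.458   0.000   0.000", "0.000   1.000   0.000"))
        fr = peptide_plane_frame(backbone_sites(st)[0])
        np.testing.assert_allclose(fr.u, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.v, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.n, [0, 0, 1], atol=1e-12)

    def test_orthonormality(self, samarosporin_like_structure):
        for site in backbone_sites(samarosporin_like_structure):
            fr = peptide_plane_frame(site) if site.h else None
            if fr is None:
                continue
            assert abs(np.linalg.norm(fr.n) - 1) < 1e-10
            assert abs(np.dot(fr.n, fr.u)) < 1e-10
            assert abs(np.dot(fr.n, fr.v)) < 1e-10

    def test_rotation_equivariance(self, helix_structure):
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        site = backbone_sites(helix_structure)[2]
        fr0 = peptide_plane_frame(site)
        for atom in helix_structure.atoms:
            atom.position = rot @ atom.position
        fr1 = peptide_plane_frame(backbone_sites(helix_structure)[2])
        for a, b in ((fr0.u, fr1.u), (fr0.v, fr1.v), (fr0.n, fr1.n)):
            assert float(np.dot(rot @ a, b)) == pytest.approx(1.0, abs=1e-10)

    def test_hyp_frame_undefined(self, samarosporin_like_structure):
        sites = backbone_sites(samarosporin_like_structure)
        assert peptide_plane_frame(sites[9]) is None
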