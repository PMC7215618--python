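"""Peptide structure handling: PDB I/O, backbone sites, dihedrals, plane frames.

Coordinates are kept in ångström throughout; the amide bond length
``r_NH`` is reported in picometres because that is the unit the
solid-state NMR literature tabulates it in.

The local *peptide-plane frame* at an amide nitrogen is built from the
N→H and N→Cα bond vectors::

    u = unit(H  - N)        (along the amide bond)
    v = unit(Cα - N)
    n = unit(u × v)         (normal to the peptide plane)

u and v are generally not orthogonal; n is orthogonal to both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "BackboneSite",
    "PlaneFrame",
    "PDBParseError",
    "StructureError",
    "GeometryError",
    "parse_pdb",
    "write_pdb",
    "backbone_sites",
    "dihedral",
    "phi_psi",
    "nh_bond_length",
    "peptide_plane_frame",
    "DEFAULT_KIND_TABLE",
    "DEFAULT_HYDROGEN_NAMES",
]


class PDBParseError(ValueError):
    """A fixed-column PDB record could not be parsed."""


class StructureError(ValueError):
    """A residue is missing atoms required for backbone analysis."""


class GeometryError(ValueError):
    """Degenerate geometry (coincident or collinear points)."""


@dataclass(eq=False)
class Atom:
    name: str
    element: str
    residue_index: int
    residue_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.residue_index < 1:
            raise ValueError(f"atom {self.name}: residue_index must be >= 1")


@dataclass(eq=False)
class Residue:
    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(eq=False)
class Structure:
    """An ordered collection of residues; unit cell kept only as provenance."""

    residues: list[Residue]
    cell: tuple[float, ...] | None = None

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")


# Residue kinds relevant to peptaibols.  AIB = alpha-aminoisobutyric acid,
# IVA = D-isovaline, HYP = 4-hydroxyproline, FOL = phenylalaninol.
_STANDARD_20 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
DEFAULT_KIND_TABLE: Mapping[str, str] = {
    **{code: "canonical" for code in _STANDARD_20},
    "AIB": "Aib",
    "IVA": "Iva",
    "HYP": "Hyp",
    "FOL": "Fol",
}

# Residues whose backbone nitrogen carries no amide hydrogen.
_NO_AMIDE_H = {"PRO", "HYP"}

DEFAULT_HYDROGEN_NAMES: Sequence[str] = ("H", "HN", "H01")
_H_DISTANCE_CUTOFF = 1.2  # Å, fallback N-H search radius


@dataclass(eq=False)
class BackboneSite:
    """Backbone atom handles for one residue.

    ``h`` is None for proline-like residues (Pro, Hyp) and for residues
    where no amide hydrogen could be resolved; ``prev_c``/``next_n`` are
    None at the chain termini.
    """

    residue_index: int
    residue_name: str
    kind: str
    n: Atom
    ca: Atom
    c: Atom | None
    h: Atom | None
    prev_c: Atom | None
    next_n: Atom | None


@dataclass(eq=False)
class PlaneFrame:
    """Peptide-plane frame at an amide nitrogen (see module docstring)."""

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n: np.ndarray


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed, with a strict pre-scan for line-numbered errors)
# ---------------------------------------------------------------------------

def _prescan(text: str) -> int:
    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n_atom_records += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: bad coordinate field") from exc
    return n_atom_records


def parse_pdb(text: str) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Alternate locations other than blank/'A' are dropped; the element is
    taken from columns 77-78 when present, otherwise inferred from the
    atom name.  Residues are grouped by (chain, resSeq) in file order.
    """
    if _prescan(text) == 0:
        raise PDBParseError("no ATOM/HETATM records in input")
    st = gemmi.read_pdb_string(text)
    residues: list[Residue] = []
    for model in st:
        for chain in model:
            for res in chain:
                out = Residue(index=res.seqid.num, name=res.name.strip())
                for at in res:
                    if at.altloc not in ("\0", "", "A"):
                        continue
                    out.atoms.append(Atom(
                        name=at.name.strip(),
                        element=at.element.name,
                        residue_index=res.seqid.num,
                        residue_name=res.name.strip(),
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    ))
                if out.atoms:
                    residues.append(out)
        break  # first model only
    cell = None
    if st.cell and st.cell.a > 1.0:
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return Structure(residues=residues, cell=cell)


def _pdb_atom_name(name: str) -> str:
    # Names shorter than 4 characters start in column 14.
    return name.ljust(4) if len(name) == 4 else (" " + name).ljust(4)


def write_pdb(structure: Structure, chain: str = "A") -> str:
    """Serialize a :class:`Structure` to PDB text (%8.3f coordinates)."""
    lines: list[str] = []
    serial = 0
    for res in structure.residues:
        for a in res.atoms:
            serial += 1
            x, y, z = a.position
            lines.append(
                f"ATOM  {serial:5d} {_pdb_atom_name(a.name)} {res.name:>3s} "
                f"{chain}{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Backbone sites
# ---------------------------------------------------------------------------

def _resolve_amide_h(res: Residue, n_atom: Atom,
                     hydrogen_names: Sequence[str]) -> Atom | None:
    for name in hydrogen_names:
        a = res.atom(name)
        if a is not None:
            return a
    best, best_d = None, _H_DISTANCE_CUTOFF
    for a in res.atoms:
        if a.element != "H":
            continue
        d = float(np.linalg.norm(a.position - n_atom.position))
        if d < best_d:
            best, best_d = a, d
    return best


def backbone_sites(
    structure: Structure,
    kind_table: Mapping[str, str] | None = None,
    hydrogen_names: Sequence[str] = DEFAULT_HYDROGEN_NAMES,
) -> list[BackboneSite]:
    """One :class:`BackboneSite` per residue, in chain order.

    Residue kinds come from ``kind_table`` (default
    :data:`DEFAULT_KIND_TABLE`); unknown codes map to ``"other"`` with a
    warning.  Amide H is resolved by name preference, then by the nearest
    hydrogen within 1.2 Å of N; proline-like residues never carry one.
    """
    table = dict(DEFAULT_KIND_TABLE if kind_table is None else kind_table)
    sites: list[BackboneSite] = []
    residues = structure.residues
    for i, res in enumerate(residues):
        n_atom = res.atom("N")
        ca = res.atom("CA")
        if n_atom is None or ca is None:
            raise StructureError(
                f"residue {res.name}{res.index}: missing backbone N or CA")
        kind = table.get(res.name.upper())
        if kind is None:
            logger.warning("unknown residue code %r at %d: kind set to 'other'",
                           res.name, res.index)
            kind = "other"
        h = None
        if res.name.upper() not in _NO_AMIDE_H:
            h = _resolve_amide_h(res, n_atom, hydrogen_names)
        prev_c = residues[i - 1].atom("C") if i > 0 else None
        next_n = residues[i + 1].atom("N") if i + 1 < len(residues) else None
        sites.append(BackboneSite(
            residue_index=res.index, residue_name=res.name, kind=kind,
            n=n_atom, ca=ca, c=res.atom("C"), h=h,
            prev_c=prev_c, next_n=next_n,
        ))
    return sites


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_EPS = 1e-12


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign, range (-180, 180].

    trans is 180°, cis is 0°; looking down p2→p3, a clockwise rotation of
    the far bond is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    for a, b in ((p1, p2), (p2, p3), (p3, p4)):
        if np.linalg.norm(b - a) < _EPS:
            raise GeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise GeometryError("collinear consecutive points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def phi_psi(site: BackboneSite) -> tuple[float | None, float | None]:
    """Backbone dihedrals (φ, ψ) for a site; None where the chain ends.

    φ(i) = C(i−1)–N(i)–Cα(i)–C(i); ψ(i) = N(i)–Cα(i)–C(i)–N(i+1).
    """
    phi = psi = None
    if site.prev_c is not None and site.c is not None:
        phi = dihedral(site.prev_c.position, site.n.position,
                       site.ca.position, site.c.position)
    if site.next_n is not None and site.c is not None:
        psi = dihedral(site.n.position, site.ca.position,
                       site.c.position, site.next_n.position)
    return phi, psi


def nh_bond_length(site: BackboneSite) -> float | None:
    """Amide N-H distance in picometres; None when the site has no amide H."""
    if site.h is None:
        return None
    d = float(np.linalg.norm(site.h.position - site.n.position))
    if d < _EPS:
        raise GeometryError(
            f"residue {site.residue_name}{site.residue_index}: N and H coincide")
    return d * 100.0  # Å -> pm


def peptide_plane_frame(site: BackboneSite) -> PlaneFrame | None:
    """Peptide-plane frame (u, v, n) at a site; None when amide H is absent."""
    if site.h is None:
        return None
    origin = site.n.position
    u = site.h.position - origin
    v = site.ca.position - origin
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise GeometryError("degenerate N-H or N-CA bond vector")
    u, v = u / nu, v / nv
    cr = np.cross(u, v)
    ncr = np.linalg.norm(cr)
    if ncr < 1e-10:
        raise GeometryError("N-H and N-CA bond vectors are parallel")
    return PlaneFrame(origin=origin.copy(), u=u, v=v, n=cr / ncr)
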