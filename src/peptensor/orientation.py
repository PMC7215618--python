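"""Orientation of a ¹⁵N amide shielding tensor in the peptide-plane frame.

Three angles describe how the tensor sits on the peptide plane spanned
by the N→H (u) and N→Cα (v) bond vectors with normal n = u × v:

    α — out-of-plane tilt of ξ₁: the angle between ξ₁ and its orthogonal
        projection onto span(u, v);
    β — angle between ξ₁ and the N-H bond vector u;
    γ — angle between ξ₂ and the plane normal n.

ξ₁ is the eigenvector of the numerically smallest shielding eigenvalue
(the component that maps to the *largest* chemical shift — the one that
physically lies near the N-H bond); ξ₂ belongs to the middle eigenvalue.
Eigenvectors carry no intrinsic sign, so all angles are folded to
[0°, 90°].  For α-helical peptides α is typically below 5° and β in the
11-21° range, which is what oriented-sample techniques such as PISA-wheel
analysis consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import GeometryError, PlaneFrame
from .tensor_core import EigenSystem

__all__ = [
    "OrientationAngles",
    "DegenerateEigenvalueError",
    "select_xi",
    "cst_orientation",
    "in_plane_azimuth",
    "off_plane_tilt",
]

_DEGENERACY_TOL = 1e-8  # ppm


class DegenerateEigenvalueError(ValueError):
    """The eigenvalue selecting ξ₁ is degenerate; its direction is undefined."""


@dataclass(frozen=True)
class OrientationAngles:
    alpha: float  # degrees, [0, 90]
    beta: float
    gamma: float


def _acute_angle(a: np.ndarray, b: np.ndarray) -> float:
    c = abs(float(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return float(np.degrees(np.arccos(min(1.0, c))))


def select_xi(eig: EigenSystem, convention: str = "smallest",
              ) -> tuple[np.ndarray, np.ndarray]:
    """(ξ₁, ξ₂) from an ascending-ordered shielding eigensystem.

    ``convention="smallest"`` (default) binds ξ₁ to the numerically
    smallest shielding eigenvalue; ``"largest"`` to the numerically
    largest, for users who want the opposite reading.  ξ₂ is always the
    middle eigenvector.
    """
    v = np.asarray(eig.values, dtype=float)
    if convention == "smallest":
        i1 = 0
        gap = abs(v[1] - v[0])
    elif convention == "largest":
        i1 = 2
        gap = abs(v[2] - v[1])
    else:
        raise ValueError("convention must be 'smallest' or 'largest'")
    if gap < _DEGENERACY_TOL:
        raise DegenerateEigenvalueError(
            f"eigenvalues {v.tolist()} degenerate at the {convention} end "
            f"(gap {gap:.2e} ppm): xi_1 direction undefined")
    return eig.vector(i1), eig.vector(1)


def cst_orientation(eig: EigenSystem, frame: PlaneFrame | None,
                    convention: str = "smallest") -> OrientationAngles | None:
    """The {α, β, γ} triple of a tensor in a peptide-plane frame.

    Returns None when the frame is undefined (proline-like residues
    without an amide hydrogen).  If ξ₁ is exactly normal to the plane,
    α = 90° by continuity.
    """
    if frame is None:
        return None
    xi1, xi2 = select_xi(eig, convention=convention)
    beta = _acute_angle(xi1, frame.u)
    gamma = _acute_angle(xi2, frame.n)
    proj = xi1 - float(np.dot(xi1, frame.n)) * frame.n
    if np.linalg.norm(proj) < 1e-10:
        alpha = 90.0  # xi_1 along the normal: projection vanishes
    else:
        # angle to own projection == arcsin of the out-of-plane component,
        # which is numerically exact near 0 where arccos loses digits
        alpha = float(np.degrees(np.arcsin(min(1.0, abs(float(np.dot(xi1, frame.n)))))))
    return OrientationAngles(alpha=alpha, beta=beta, gamma=gamma)


def in_plane_azimuth(eig: EigenSystem, frame: PlaneFrame,
                     convention: str = "smallest") -> float:
    """Diagnostic: acute angle between ξ₁'s in-plane projection and u.

    This is the alternative "azimuth" reading of the out-of-plane tilt;
    it satisfies cos β = cos α · cos(azimuth).
    """
    xi1, _ = select_xi(eig, convention=convention)
    proj = xi1 - float(np.dot(xi1, frame.n)) * frame.n
    if np.linalg.norm(proj) < 1e-10:
        raise GeometryError("xi_1 is normal to the plane; azimuth undefined")
    return _acute_angle(proj, frame.u)


def off_plane_tilt(eig: EigenSystem, p1, p2, p3,
                   convention: str = "largest") -> float:
    """Tilt (degrees) of an eigenvector off the plane through three atoms.

    By default uses the eigenvector of the numerically largest shielding
    eigenvalue — the least-shielded component, the one reported to tilt
    more than 20° off the peptide plane at hydroxyproline sites.  For
    prolines an N, Cα, Cδ plane is a natural choice of the three atoms.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    normal = np.cross(p2 - p1, p3 - p1)
    if np.linalg.norm(normal) < 1e-10:
        raise GeometryError("plane atoms are collinear")
    vec = select_xi(eig, convention=convention)[0]
    s = abs(float(np.dot(vec, normal)) /
            (np.linalg.norm(vec) * np.linalg.norm(normal)))
    return float(np.degrees(np.arcsin(min(1.0, s))))
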