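"""Synthetic structures, tensors and calibration sets with known ground truth.

Every analysis stage in this package consumes the outputs of periodic
DFT computations (optimized geometries, GIPAW shielding tensors) that
are expensive and not redistributable.  The generators here emulate
those inputs with fully known ground truth so the whole pipeline is
testable end to end:

* :func:`make_backbone` builds an ideal peptide backbone from internal
  coordinates (NeRF chain construction) at prescribed {φ, ψ, ω} and
  bond lengths, placing the amide hydrogen in the C(i−1)–N–Cα plane
  along the external bisector;
* :func:`make_tensor` builds a shielding tensor with prescribed
  eigenvalues and eigenframe, either explicit or specified by target
  {α, β, γ} angles relative to a peptide-plane frame;
* :func:`make_calibration_pairs` draws shielding/shift pairs from a
  known affine law plus Gaussian noise;
* :func:`make_cohort` draws labelled ¹³Cα/¹⁵N shift parameters whose
  class means follow the three secondary-structure trends.

Generators take an explicit seed and create one private random
generator per call; no global random state is touched.  They do not
emulate DFT physics — tensors are not derived from geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationPair
from .structure_io import Atom, Residue, Structure
from .tensor_core import ShieldingTensor, ShiftParameters, symmetrize

__all__ = [
    "BackboneSpec",
    "BuildError",
    "DEFAULT_GEOMETRY",
    "make_backbone",
    "make_tensor",
    "make_calibration_pairs",
    "make_cohort",
    "DEFAULT_COHORT_MEANS",
]


class BuildError(ValueError):
    """Impossible internal-coordinate geometry."""


# Textbook backbone internal coordinates (lengths Å, angles degrees).
DEFAULT_GEOMETRY: Mapping[str, float] = {
    "d_n_ca": 1.458,
    "d_ca_c": 1.525,
    "d_c_n": 1.329,
    "d_n_h": 1.02,
    "ang_n_ca_c": 111.0,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
}

_NO_AMIDE_H = {"PRO", "HYP"}


@dataclass
class BackboneSpec:
    """Recipe for an ideal backbone.

    ``phi``/``psi``/``omega`` may be scalars (applied to every residue)
    or per-residue sequences; ω defaults to 180° (trans peptide bonds).
    ``r_nh`` is in Å.
    """

    residues: Sequence[str]
    phi: float | Sequence[float] = -57.0
    psi: float | Sequence[float] = -47.0
    omega: float | Sequence[float] = 180.0
    r_nh: float | Sequence[float] = 1.02
    geometry: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))

    def _per_residue(self, value) -> np.ndarray:
        n = len(self.residues)
        arr = np.broadcast_to(np.asarray(value, dtype=float), (n,)).copy()
        return arr


def _unit(v: np.ndarray) -> np.ndarray:
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise BuildError("degenerate zero-length bond vector")
    return v / nv


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    if not (1e-6 < angle_deg < 180.0 - 1e-6):
        raise BuildError(f"bond angle {angle_deg} deg is degenerate")
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = _unit(c - b)
    ab = b - a
    n = np.cross(ab, bc)
    if np.linalg.norm(n) < 1e-10:
        raise BuildError("collinear reference atoms for torsion placement")
    n = _unit(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               -np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_backbone(spec: BackboneSpec) -> Structure:
    """Build a backbone-only Structure (N, H, CA, C per residue).

    Measured dihedrals of the result equal the spec values (interior
    residues); proline-like residues (PRO, HYP) get no amide hydrogen.
    """
    names = [r.upper() for r in spec.residues]
    if len(names) < 2:
        raise BuildError("need at least two residues for defined dihedrals")
    g = dict(DEFAULT_GEOMETRY, **spec.geometry)
    phi = spec._per_residue(spec.phi)
    psi = spec._per_residue(spec.psi)
    omega = spec._per_residue(spec.omega)
    r_nh = spec._per_residue(spec.r_nh)

    n_pos: list[np.ndarray] = []
    ca_pos: list[np.ndarray] = []
    c_pos: list[np.ndarray] = []
    theta = np.radians(g["ang_n_ca_c"])
    n_pos.append(np.zeros(3))
    ca_pos.append(np.array([g["d_n_ca"], 0.0, 0.0]))
    c_pos.append(ca_pos[0] + g["d_ca_c"] * np.array([-np.cos(theta), np.sin(theta), 0.0]))
    for i in range(1, len(names)):
        n_i = _place(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                     g["d_c_n"], g["ang_ca_c_n"], psi[i - 1])
        ca_i = _place(ca_pos[i - 1], c_pos[i - 1], n_i,
                      g["d_n_ca"], g["ang_c_n_ca"], omega[i])
        c_i = _place(c_pos[i - 1], n_i, ca_i,
                     g["d_ca_c"], g["ang_n_ca_c"], phi[i])
        n_pos.append(n_i)
        ca_pos.append(ca_i)
        c_pos.append(c_i)

    residues: list[Residue] = []
    for i, name in enumerate(names):
        res = Residue(index=i + 1, name=name)
        res.atoms.append(Atom("N", "N", i + 1, name, n_pos[i]))
        if name not in _NO_AMIDE_H:
            # external bisector of the two heavy-atom bonds at N; the
            # N-terminal residue bisects its own N-CA / N-C directions
            ref = c_pos[i - 1] if i > 0 else c_pos[i]
            h_dir = -( _unit(ref - n_pos[i]) + _unit(ca_pos[i] - n_pos[i]) )
            res.atoms.append(Atom("H", "H", i + 1, name,
                                  n_pos[i] + r_nh[i] * _unit(h_dir)))
        res.atoms.append(Atom("CA", "C", i + 1, name, ca_pos[i]))
        res.atoms.append(Atom("C", "C", i + 1, name, c_pos[i]))
        residues.append(res)
    return Structure(residues=residues)


# ---------------------------------------------------------------------------
# Tensors
# ---------------------------------------------------------------------------

def _frame_from_angles(frame, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Orthonormal eigenvector triple realizing target {α, β, γ} in a frame.

    Geometry constrains β ≥ α and γ ≥ α (ξ₁ tilted α out of plane cannot
    be closer than α to the in-plane u; ξ₂ ⊥ ξ₁ cannot be closer than α
    to the normal).
    """
    for name, val in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not 0.0 <= val <= 90.0:
            raise ValueError(f"{name} must be in [0, 90] degrees")
    a, b_, c_ = np.radians([alpha, beta, gamma])
    if np.cos(a) < 1e-12:
        raise ValueError("alpha = 90 leaves the in-plane direction undefined")
    cos_tau = np.cos(b_) / np.cos(a)
    cos_phi = np.cos(c_) / np.cos(a)
    if cos_tau > 1 + 1e-9 or cos_phi > 1 + 1e-9:
        raise ValueError("infeasible angle triple: need beta >= alpha and gamma >= alpha")
    tau = np.arccos(np.clip(cos_tau, -1.0, 1.0))
    phi = np.arccos(np.clip(cos_phi, -1.0, 1.0))
    e1, e3 = frame.u, frame.n
    e2 = np.cross(e3, e1)
    xi1 = np.cos(a) * (np.cos(tau) * e1 + np.sin(tau) * e2) + np.sin(a) * e3
    p1 = e3 - float(np.dot(e3, xi1)) * xi1
    p1 = p1 / np.linalg.norm(p1)
    p2 = np.cross(xi1, p1)
    xi2 = np.cos(phi) * p1 + np.sin(phi) * p2
    xi3 = np.cross(xi1, xi2)
    return np.column_stack([xi1, xi2, xi3])


def make_tensor(
    eigenvalues: Sequence[float],
    vectors: np.ndarray | None = None,
    frame=None,
    angles: tuple[float, float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    kind: str = "shielding",
    site: str | int | None = None,
) -> ShieldingTensor:
    """Tensor with prescribed ascending eigenvalues and eigenframe.

    The eigenframe is the identity by default, an explicit orthonormal
    column triple via ``vectors``, or — given a peptide-plane ``frame``
    and target ``angles`` (α, β, γ in degrees) — a triple constructed so
    the orientation analysis recovers those angles exactly at zero
    noise.  ``noise_sd`` adds a symmetric Gaussian perturbation (ppm).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,):
        raise ValueError("expected three eigenvalues")
    if not (lam[0] <= lam[1] <= lam[2]):
        raise ValueError("eigenvalues must be ascending")
    if vectors is not None and angles is not None:
        raise ValueError("give either explicit vectors or target angles, not both")
    if angles is not None:
        if frame is None:
            raise ValueError("target angles require a peptide-plane frame")
        v = _frame_from_angles(frame, *angles)
    elif vectors is not None:
        v = np.asarray(vectors, dtype=float)
        if v.shape != (3, 3) or np.max(np.abs(v.T @ v - np.eye(3))) > 1e-10:
            raise ValueError("explicit eigenframe must be orthonormal 3x3")
    else:
        v = np.eye(3)
    m = v @ np.diag(lam) @ v.T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = m + symmetrize(rng.normal(0.0, noise_sd, (3, 3)))
    return ShieldingTensor(matrix=m, kind=kind, site=site)


# ---------------------------------------------------------------------------
# Calibration pairs
# ---------------------------------------------------------------------------

# Three synthetic "compounds" × three ¹⁵N amide shift components (ppm),
# spanning the typical amide tensor range.
_DEFAULT_DELTAS: tuple[tuple[float, float, float], ...] = (
    (38.0, 65.0, 214.0),
    (52.0, 80.0, 228.0),
    (45.0, 72.0, 221.0),
)


def make_calibration_pairs(
    a: float = -0.93574,
    b: float = 209.54,
    delta_values: Sequence[Sequence[float]] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[CalibrationPair]:
    """Shielding/shift pairs from σ = a·δ + b + N(0, noise_sd²).

    Default (a, b) mirror the reference ¹⁵N amide calibration; the
    default δ set emulates its benchmark of 3 compounds × 3 components.
    """
    triples = _DEFAULT_DELTAS if delta_values is None else delta_values
    rng = np.random.default_rng(seed)
    pairs: list[CalibrationPair] = []
    for k, triple in enumerate(triples, start=1):
        for rank, delta in enumerate(sorted(triple, reverse=True), start=1):
            sigma = a * delta + b + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            pairs.append(CalibrationPair(sigma=float(sigma), delta=float(delta),
                                         site=f"syn{k}", rank=rank))
    return pairs


# ---------------------------------------------------------------------------
# Secondary-structure cohort
# ---------------------------------------------------------------------------

# Class-conditional means emulating glycyl tensor statistics: ¹³Cα iso
# lower in α-helix; ¹³Cα span ordered PP II > α > β; ¹⁵N dev ordered
# β > PP II > α.  All ppm.
DEFAULT_COHORT_MEANS: Mapping[str, Mapping[str, float]] = {
    "beta_sheet": {"c13_iso": 44.6, "c13_span": 36.0, "n15_dev": 40.0},
    "pp2_helix": {"c13_iso": 45.4, "c13_span": 52.0, "n15_dev": 30.0},
    "alpha_r_helix": {"c13_iso": 41.0, "c13_span": 44.0, "n15_dev": 21.0},
}
_COHORT_SDS = {"c13_iso": 0.5, "c13_span": 1.5, "n15_dev": 2.0}


def make_cohort(
    n_per_class: int = 10,
    seed: int | None = None,
    means: Mapping[str, Mapping[str, float]] | None = None,
) -> list[tuple[str, ShiftParameters, ShiftParameters]]:
    """Labelled (¹³Cα, ¹⁵N) shift parameters for the three structure classes."""
    means = DEFAULT_COHORT_MEANS if means is None else means
    rng = np.random.default_rng(seed)
    cohort: list[tuple[str, ShiftParameters, ShiftParameters]] = []
    for label, mu in means.items():
        for _ in range(n_per_class):
            c_span = max(1.0, rng.normal(mu["c13_span"], _COHORT_SDS["c13_span"]))
            c13 = ShiftParameters(
                iso=float(rng.normal(mu["c13_iso"], _COHORT_SDS["c13_iso"])),
                span=float(c_span),
                dev=float(0.4 * c_span),
            )
            n_dev = max(1.0, rng.normal(mu["n15_dev"], _COHORT_SDS["n15_dev"]))
            n15 = ShiftParameters(
                iso=float(rng.normal(105.0, 3.0)),
                span=float(n_dev + rng.normal(170.0, 5.0)),
                dev=float(n_dev),
            )
            cohort.append((label, c13, n15))
    return cohort
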