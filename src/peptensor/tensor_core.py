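"""Chemical shielding/shift tensor eigen-analysis and derived parameters.

A nucleus's chemical shielding tensor (computed, σ, ppm) or chemical
shift tensor (experimental, δ, ppm) is a 3×3 matrix whose symmetric part
carries the observable information.  Eigenvalues are ordered ascending
throughout (δ11 ≤ δ22 ≤ δ33); the derived parameters are

    iso  = (δ11 + δ22 + δ33) / 3     isotropic value
    span = δ33 − δ11                 total width of the tensor
    dev  = δ22 − δ11                 deviation from axial symmetry

The "most shielded"/"least shielded" vocabulary is deliberately avoided
as an ordering key: for shieldings and shifts it points at opposite ends
of the numeric scale, so every cross-kind correspondence is handled
explicitly (see :mod:`peptensor.calibration`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShieldingTensor",
    "EigenSystem",
    "ShiftParameters",
    "symmetrize",
    "eigensystem",
    "shift_params",
    "shielding_iso",
    "read_magres",
    "write_magres",
    "read_tensor_csv",
    "write_tensor_csv",
]


@dataclass(eq=False)
class ShieldingTensor:
    """A raw 3×3 tensor in ppm with its site reference.

    kind is "shielding" (computed σ) or "shift" (experimental δ).
    """

    matrix: np.ndarray
    kind: str = "shielding"
    site: str | int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("tensor entries must be finite")
        if self.kind not in ("shielding", "shift"):
            raise ValueError("kind must be 'shielding' or 'shift'")


@dataclass(eq=False)
class EigenSystem:
    """Ascending eigenvalues with orthonormal eigenvectors (columns)."""

    values: np.ndarray
    vectors: np.ndarray
    kind: str = "shielding"

    def vector(self, rank: int) -> np.ndarray:
        """Eigenvector of the rank-th smallest eigenvalue (0-based)."""
        return self.vectors[:, rank]


@dataclass(frozen=True)
class ShiftParameters:
    iso: float
    span: float
    dev: float

    def __post_init__(self) -> None:
        if self.span < -1e-9 or self.dev < -1e-9 or self.dev > self.span + 1e-9:
            raise ValueError("require 0 <= dev <= span")


def symmetrize(matrix) -> np.ndarray:
    """(M + Mᵀ)/2 — the antisymmetric part does not affect eigenvalues."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    return (m + m.T) / 2.0


def eigensystem(tensor: ShieldingTensor | np.ndarray,
                kind: str = "shielding") -> EigenSystem:
    """Diagonalize the symmetric part; eigenvalues ascending."""
    if isinstance(tensor, ShieldingTensor):
        m, kind = tensor.matrix, tensor.kind
    else:
        m = np.asarray(tensor, dtype=float)
    values, vectors = np.linalg.eigh(symmetrize(m))
    return EigenSystem(values=values, vectors=vectors, kind=kind)


def shift_params(values: Sequence[float]) -> ShiftParameters:
    """Derived parameters from ascending shift eigenvalues."""
    v = np.asarray(values, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected exactly three eigenvalues")
    if not (v[0] <= v[1] + 1e-9 and v[1] <= v[2] + 1e-9):
        raise ValueError("eigenvalues must be in ascending order")
    return ShiftParameters(iso=float(v.mean()),
                           span=float(v[2] - v[0]),
                           dev=float(v[1] - v[0]))


def shielding_iso(values: Sequence[float]) -> float:
    """Isotropic shielding: arithmetic mean of the eigenvalues."""
    v = np.asarray(values, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected exactly three eigenvalues")
    return float(v.mean())


# ---------------------------------------------------------------------------
# magres (CCP-NC ab-initio v1.0) and CSV tensor I/O
# ---------------------------------------------------------------------------

def read_magres(text: str) -> list[tuple[str, int, np.ndarray]]:
    """Parse ``ms`` lines of a magres file.

    Returns (atom label, 1-based atom index, 3×3 ppm tensor) per entry;
    only the magnetic-shielding block is consumed, EFG and coupling
    blocks are ignored.
    """
    entries: list[tuple[str, int, np.ndarray]] = []
    in_magres = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("[magres]"):
            in_magres = True
            continue
        if line.startswith("[/magres]"):
            in_magres = False
            continue
        if not in_magres or not line.startswith("ms "):
            continue
        parts = line.split()
        if len(parts) != 12:
            raise ValueError(f"malformed ms line: {raw!r}")
        label, index = parts[1], int(parts[2])
        m = np.array([float(x) for x in parts[3:12]]).reshape(3, 3)
        entries.append((label, index, m))
    return entries


def write_magres(entries: Iterable[tuple[str, int, np.ndarray]]) -> str:
    lines = ["#$magres-abinitio-v1.0", "[magres]", "units ms ppm"]
    for label, index, m in entries:
        flat = " ".join(f"{x:.6f}" for x in np.asarray(m, float).ravel())
        lines.append(f"ms {label} {index} {flat}")
    lines.append("[/magres]")
    return "\n".join(lines) + "\n"


_CSV_COLS = ["residue_index", "atom_name",
             "m11", "m12", "m13", "m21", "m22", "m23", "m31", "m32", "m33"]


def read_tensor_csv(text: str) -> list[tuple[int, str, np.ndarray]]:
    """CSV fallback: residue_index, atom_name, m11..m33 (row-major, ppm)."""
    df = pd.read_csv(io.StringIO(text))
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"tensor CSV missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        m = row[_CSV_COLS[2:]].to_numpy(dtype=float).reshape(3, 3)
        out.append((int(row.residue_index), str(row.atom_name), m))
    return out


def write_tensor_csv(entries: Iterable[tuple[int, str, np.ndarray]]) -> str:
    rows = []
    for idx, name, m in entries:
        rows.append([idx, name, *np.asarray(m, float).ravel().tolist()])
    return pd.DataFrame(rows, columns=_CSV_COLS).to_csv(index=False)
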