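"""Per-site backbone reports and group statistics.

Assembles one record per backbone amide site — r_NH, {φ, ψ}, calibrated
shift components and isotropic value, peptide-plane orientation angles,
secondary-structure label — and summarizes groups of residues (e.g.
Aib versus canonical amino acids) by component means and β-angle
medians.

Component labelling: shift components are stored ascending
(smallest, mid, largest); some of the literature indexes them
descending (ε_11 ≥ ε_22 ≥ ε_33), so group differences are reported with
explicit ascending/descending tags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import structure_io
from ._rounding import round_half_up
from .calibration import Calibration, apply_calibration
from .orientation import cst_orientation
from .secondary_structure import DEFAULT_REGIONS, RamachandranRegion, classify
from .structure_io import Structure
from .tensor_core import ShieldingTensor, eigensystem

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "GroupStats",
    "MissingTensorError",
    "build_site_table",
    "component_group_diff",
    "beta_median",
    "group_stats",
    "records_to_dataframe",
]


class MissingTensorError(ValueError):
    """No shielding tensor was supplied for one or more backbone sites."""


@dataclass(eq=False)
class SiteRecord:
    """One backbone site's parameters (a table row).

    Undefined values (hydroxyproline angles/r_NH, terminal dihedrals)
    are None.  ``eps_components`` is ascending (smallest, mid, largest).
    """

    residue_index: int
    residue_label: str
    kind: str
    r_nh: float | None         # pm
    phi: float | None          # degrees
    psi: float | None
    eps_iso: float             # ppm
    eps_components: tuple[float, float, float]
    alpha: float | None        # degrees
    beta: float | None
    gamma: float | None
    ss_label: str | None


@dataclass(frozen=True)
class GroupStats:
    label: str
    component_means: tuple[float, float, float]  # ascending ranks, ppm
    beta_median: float | None                    # degrees
    n: int


def build_site_table(
    structure: Structure,
    tensors: Mapping[int, ShieldingTensor | np.ndarray],
    calibration: Calibration | tuple[float, float],
    regions: Sequence[RamachandranRegion] = DEFAULT_REGIONS,
) -> list[SiteRecord]:
    """Run the full per-site pipeline over a structure.

    ``tensors`` maps residue_index to the ¹⁵N amide shielding tensor of
    that site.  Each site gets its geometry (r_NH, φ, ψ, plane frame),
    calibrated shift components (sorted ascending), orientation angles
    and a Ramachandran label.  Sites without an amide hydrogen carry
    undefined r_NH and angles.
    """
    sites = structure_io.backbone_sites(structure)
    missing = [s.residue_index for s in sites if s.residue_index not in tensors]
    if missing:
        raise MissingTensorError(f"no shielding tensor for residues {missing}")
    records: list[SiteRecord] = []
    for site in sites:
        eig = eigensystem(tensors[site.residue_index])
        est = apply_calibration(np.sort(eig.values), calibration)
        comps = tuple(sorted(est.components))
        phi, psi = structure_io.phi_psi(site)
        frame = structure_io.peptide_plane_frame(site) if site.h else None
        angles = cst_orientation(eig, frame)
        if angles is None:
            logger.info("residue %s%d: no amide H, orientation undefined",
                        site.residue_name, site.residue_index)
        label = classify(phi, psi, regions) if phi is not None and psi is not None else None
        records.append(SiteRecord(
            residue_index=site.residue_index,
            residue_label=f"{site.residue_name.capitalize()}{site.residue_index}",
            kind=site.kind,
            r_nh=structure_io.nh_bond_length(site),
            phi=phi, psi=psi,
            eps_iso=est.eps_iso, eps_components=comps,
            alpha=angles.alpha if angles else None,
            beta=angles.beta if angles else None,
            gamma=angles.gamma if angles else None,
            ss_label=label,
        ))
    return records


def _select(records: Sequence[SiteRecord],
            subset: Sequence[int]) -> list[SiteRecord]:
    by_index = {r.residue_index: r for r in records}
    try:
        return [by_index[i] for i in subset]
    except KeyError as exc:
        raise ValueError(f"residue index {exc.args[0]} not in records") from exc


def component_group_diff(
    records: Sequence[SiteRecord],
    group_a: Sequence[int],
    group_b: Sequence[int],
    rounded: bool = True,
) -> dict[str, tuple[float, float, float]]:
    """Per-rank mean shift-component differences, group A minus group B.

    Returns the three differences under both labellings:
    ``"ascending"`` = (smallest, mid, largest) and ``"descending"`` the
    reverse.  With ``rounded`` (default) values are integers, half-up.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    a = np.array([r.eps_components for r in _select(records, group_a)])
    b = np.array([r.eps_components for r in _select(records, group_b)])
    diff = a.mean(axis=0) - b.mean(axis=0)
    if rounded:
        diff = np.array([round_half_up(d, 0) for d in diff])
    asc = tuple(float(d) for d in diff)
    return {"ascending": asc, "descending": asc[::-1]}


def beta_median(records: Sequence[SiteRecord],
                subset: Sequence[int], rounded: bool = True) -> float:
    """Median of the β orientation angle over a residue subset (degrees)."""
    chosen = _select(records, subset)
    undefined = [r.residue_label for r in chosen if r.beta is None]
    if undefined:
        raise ValueError(f"beta undefined for {undefined}")
    med = float(np.median([r.beta for r in chosen]))
    return round_half_up(med, 1) if rounded else med


def group_stats(records: Sequence[SiteRecord], label: str,
                subset: Sequence[int]) -> GroupStats:
    chosen = _select(records, subset)
    comp = np.array([r.eps_components for r in chosen]).mean(axis=0)
    betas = [r.beta for r in chosen if r.beta is not None]
    return GroupStats(
        label=label,
        component_means=tuple(float(c) for c in comp),
        beta_median=float(np.median(betas)) if betas else None,
        n=len(chosen),
    )


def records_to_dataframe(records: Sequence[SiteRecord]) -> pd.DataFrame:
    """Tabulate records in the standard column order, print precision."""
    rows = []
    for r in records:
        e1, e2, e3 = r.eps_components
        rows.append({
            "site": r.residue_label, "kind": r.kind,
            "r_NH_pm": None if r.r_nh is None else round_half_up(r.r_nh, 2),
            "phi": None if r.phi is None else round_half_up(r.phi, 1),
            "psi": None if r.psi is None else round_half_up(r.psi, 1),
            "eps_iso": round_half_up(r.eps_iso, 1),
            "eps_11": round_half_up(e1, 1),
            "eps_22": round_half_up(e2, 1),
            "eps_33": round_half_up(e3, 1),
            "alpha": None if r.alpha is None else round_half_up(r.alpha, 1),
            "beta": None if r.beta is None else round_half_up(r.beta, 1),
            "gamma": None if r.gamma is None else round_half_up(r.gamma, 1),
            "ss": r.ss_label,
        })
    return pd.DataFrame(rows)
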