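"""Reference-free shielding-to-shift calibration for ¹⁵N amide tensors.

Computed shielding eigenvalues {σ_ii} and experimental shift eigenvalues
{δ_ii} of the same sites are related affinely,

    {σ_ii} = a·{δ_ii} + b,

with a slope near −1: shielding and shift run in opposite directions, so
the smallest σ pairs with the largest δ.  The fitted (a, b) are then
applied directly to computed shieldings to estimate shifts,

    ε_ii = a·σ_ii + b,    ε^iso = (ε_11 + ε_22 + ε_33) / 3,

which avoids referencing against the computed shielding of any standard
compound.  Because a ≈ −1 the direct re-application is an excellent
approximate inverse of the fitted law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationPair",
    "Calibration",
    "EstimatedShift",
    "SingularFitError",
    "pair_components",
    "fit_calibration",
    "apply_calibration",
    "read_pairs_csv",
    "calibration_to_json",
    "calibration_from_json",
]


class SingularFitError(ValueError):
    """The regression design is singular (all predictors equal)."""


@dataclass(frozen=True)
class CalibrationPair:
    sigma: float  # computed shielding eigenvalue, ppm
    delta: float  # experimental shift eigenvalue, ppm
    site: str = ""
    rank: int = 0  # 1..3 within the site's ordered set


@dataclass(frozen=True)
class Calibration:
    a: float        # slope, dimensionless
    b: float        # intercept, ppm
    adj_r2: float
    resid_sd: float  # ppm, n-2 dof
    n: int


@dataclass(frozen=True)
class EstimatedShift:
    components: tuple[float, float, float]  # ε_ii, same order as input σ
    eps_iso: float


def pair_components(
    sigma_values: Sequence[float],
    delta_values: Sequence[float],
    site: str = "",
    association: str = "anti",
) -> list[CalibrationPair]:
    """Pair one site's three σ eigenvalues with its three δ eigenvalues.

    The default ``association="anti"`` pairs σ ascending with δ
    descending (smallest shielding ↔ largest shift), consistent with the
    negative slope of the calibration law; ``"direct"`` pairs
    ascending↔ascending.
    """
    s = np.sort(np.asarray(sigma_values, dtype=float))
    d = np.sort(np.asarray(delta_values, dtype=float))
    if s.shape != (3,) or d.shape != (3,):
        raise ValueError("expected three eigenvalues per set")
    if association == "anti":
        d = d[::-1]
    elif association != "direct":
        raise ValueError("association must be 'anti' or 'direct'")
    return [CalibrationPair(sigma=float(s[i]), delta=float(d[i]),
                            site=site, rank=i + 1) for i in range(3)]


def fit_calibration(pairs: Sequence[CalibrationPair]) -> Calibration:
    """Ordinary least squares of σ on δ: σ = a·δ + b.

    adj R² = 1 − (1 − R²)(n − 1)/(n − 2); residual SD uses n − 2 degrees
    of freedom (one predictor).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    delta = np.array([p.delta for p in pairs])
    sigma = np.array([p.sigma for p in pairs])
    if np.ptp(delta) < 1e-12:
        raise SingularFitError("all shift values identical; slope undefined")
    res = stats.linregress(delta, sigma)
    n = len(pairs)
    resid = sigma - (res.slope * delta + res.intercept)
    sse = float(resid @ resid)
    r2 = res.rvalue ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return Calibration(a=float(res.slope), b=float(res.intercept),
                       adj_r2=float(adj_r2),
                       resid_sd=float(np.sqrt(sse / (n - 2))), n=n)


def apply_calibration(sigma_values: Sequence[float],
                      calibration: Calibration | tuple[float, float],
                      ) -> EstimatedShift:
    """Estimated shift components ε_ii = a·σ_ii + b and their mean ε^iso."""
    if isinstance(calibration, Calibration):
        a, b = calibration.a, calibration.b
    else:
        a, b = calibration
    s = np.asarray(sigma_values, dtype=float)
    if s.shape != (3,):
        raise ValueError("expected three shielding eigenvalues")
    eps = a * s + b
    return EstimatedShift(components=tuple(float(x) for x in eps),
                          eps_iso=float(eps.mean()))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pairs_csv(text_or_path) -> list[CalibrationPair]:
    """CSV with columns site, sigma_1..sigma_3, delta_1..delta_3."""
    df = pd.read_csv(text_or_path)
    need = {"site", "sigma_1", "sigma_2", "sigma_3",
            "delta_1", "delta_2", "delta_3"}
    if not need <= set(df.columns):
        raise ValueError(f"pairs CSV missing columns: {sorted(need - set(df.columns))}")
    pairs: list[CalibrationPair] = []
    for _, row in df.iterrows():
        pairs.extend(pair_components(
            [row.sigma_1, row.sigma_2, row.sigma_3],
            [row.delta_1, row.delta_2, row.delta_3],
            site=str(row.site)))
    return pairs


def calibration_to_json(calib: Calibration) -> str:
    return json.dumps(asdict(calib), indent=2)


def calibration_from_json(text: str) -> Calibration:
    d = json.loads(text)
    return Calibration(a=d["a"], b=d["b"], adj_r2=d["adj_r2"],
                       resid_sd=d["resid_sd"], n=d["n"])
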