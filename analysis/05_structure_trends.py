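#!/usr/bin/env python
"""Secondary-structure trends on a synthetic glycyl cohort.

Draws a labelled cohort of ¹³Cα/¹⁵N shift parameters for the three
regular secondary structures (β-sheet, PP II helix, right-handed
α-helix) and evaluates the three diagnostic trends:

    1. ¹³Cα isotropic shift lower in α-helices than β/PP II;
    2. ¹³Cα span ordered PP II > α > β;
    3. ¹⁵N deviation from axial symmetry ordered β > PP II > α.
"""

import json
from pathlib import Path

from peptensor.secondary_structure import classify, trend_report
from peptensor.synthetic_data import make_cohort

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(n_per_class=10, seed=SEED)
    report = trend_report(cohort)
    print(f"cohort of {len(cohort)} synthetic glycyl sites (seed {SEED}):")
    print(f"  trend 1 (alpha iso lowest):        {report.iso_lower_in_alpha}")
    print(f"  trend 2 (span PP II > alpha > beta): {report.span_order_pp2_alpha_beta}")
    print(f"  trend 3 (dev beta > PP II > alpha):  {report.dev_order_beta_pp2_alpha}")

    centers = {"beta_sheet": (-150, 150), "pp2_helix": (-75, 145),
               "alpha_r_helix": (-57, -47)}
    labels = {name: classify(*phi_psi) for name, phi_psi in centers.items()}
    (OUT / "trends.json").write_text(json.dumps({
        "seed": SEED, "n_sites": len(cohort),
        "trends": dict(zip(report._fields, report)),
        "region_self_classification": labels}, indent=2))
    assert all(report), "trend cohort no longer satisfies the orderings"


if __name__ == "__main__":
    main()
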