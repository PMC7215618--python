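#!/usr/bin/env python
"""Generate the synthetic pipeline inputs with known ground truth.

Builds an ideal 15-residue peptaibol-like backbone (helical {φ, ψ},
hydroxyprolines without amide H) and one ¹⁵N amide shielding tensor per
site with prescribed eigenvalues and prescribed orientation relative to
each site's peptide plane.  Writes the PDB, the magres shielding file
and the ground-truth table that later stages are checked against.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from peptensor import datasets, structure_io, synthetic_data, tensor_core

SEED = 20200413
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = synthetic_data.BackboneSpec(
        residues=datasets.SAMAROSPORIN_SEQUENCE, phi=-60.0, psi=-35.0,
        r_nh=1.025)
    structure = synthetic_data.make_backbone(spec)
    (OUT / "peptide.pdb").write_text(structure_io.write_pdb(structure))

    rng = np.random.default_rng(SEED)
    entries, truth = [], []
    for site in structure_io.backbone_sites(structure):
        # Aib-like sites get higher-shift (lower-shielding) components,
        # mirroring the ~15 ppm isotropic offset seen in peptaibols
        offset = -15.0 if site.kind in ("Aib", "Iva") else 0.0
        lam = np.sort(rng.normal([-25.0 + offset, 135.0 + offset,
                                  160.0 + offset], 4.0))
        frame = structure_io.peptide_plane_frame(site) if site.h else None
        if frame is not None:
            angles = (float(rng.uniform(0, 5)), float(rng.uniform(11, 21)),
                      float(rng.uniform(6, 50)))
            tensor = synthetic_data.make_tensor(lam, frame=frame, angles=angles)
        else:
            angles = (None, None, None)
            tensor = synthetic_data.make_tensor(lam)
        entries.append(("N", site.residue_index, tensor.matrix))
        truth.append({"residue_index": site.residue_index,
                      "kind": site.kind,
                      "sigma_1": lam[0], "sigma_2": lam[1], "sigma_3": lam[2],
                      "alpha": angles[0], "beta": angles[1],
                      "gamma": angles[2]})
    (OUT / "shieldings.magres").write_text(tensor_core.write_magres(entries))
    pd.DataFrame(truth).to_csv(OUT / "ground_truth.csv", index=False)
    (OUT / "spec.json").write_text(json.dumps(
        {"phi": -60.0, "psi": -35.0, "r_nh_angstrom": 1.025, "seed": SEED},
        indent=2))
    print(f"wrote synthetic peptide ({len(truth)} residues) and shielding "
          f"tensors to {OUT}")


if __name__ == "__main__":
    main()
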