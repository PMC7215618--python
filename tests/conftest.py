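import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from peptensor import datasets, structure_io, synthetic_data


GLYCINE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  H   GLY A   1      -0.500  -0.800   0.300  1.00  0.00           H
ATOM      3  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      4  C   GLY A   1       2.004   1.420   0.000  1.00  0.00           C
ATOM      5  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def glycine_pdb() -> str:
    return GLYCINE_PDB


@pytest.fixture
def helix_structure():
    """Ideal right-handed helix, 6 residues at (phi, psi) = (-57, -47)."""
    spec = synthetic_data.BackboneSpec(residues=["ALA"] * 6)
    return synthetic_data.make_backbone(spec)


@pytest.fixture
def samarosporin_like_structure():
    """Synthetic 15-residue chain with the peptaibol residue kinds."""
    spec = synthetic_data.BackboneSpec(
        residues=datasets.SAMAROSPORIN_SEQUENCE, phi=-60.0, psi=-35.0)
    return synthetic_data.make_backbone(spec)


@pytest.fixture
def plane_frame(helix_structure):
    sites = structure_io.backbone_sites(helix_structure)
    return structure_io.peptide_plane_frame(sites[2])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=rng).as_matrix()
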