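import numpy as np
import pytest

from bundlesans import AtomicModel, ContrastModel, ScatteringCurve
from bundlesans.synthetic import sphere_intensity


@pytest.fixture
def contrast():
    return ContrastModel()


@pytest.fixture
def sphere_curve():
    """Noiseless uniform-sphere curve, radius 25.82 A (Rg = 20.0 A)."""
    radius = 25.82
    q = np.linspace(0.002, 0.35, 300)
    return ScatteringCurve(q=q, intensity=sphere_intensity(q, radius),
                           label="sphere"), radius


def toy_model(coords, element="C"):
    """Bare point-scatterer model (unknown residue: generic H bookkeeping)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return AtomicModel(
        element=np.array([element] * n), atom_name=np.array([element] * n),
        res_name=np.array(["UNK"] * n), res_seq=np.arange(n),
        chain_id=np.array(["A"] * n), coords=coords)


SYNTHETIC_PDB = """\
HEADER    SYNTHETIC TEST STRUCTURE
REMARK    three-residue fragment plus a heme iron and a water
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.762   6.818  -4.145  1.00  0.00           C
ATOM      4  O   ALA A   1       9.832   7.530  -4.523  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.793   4.623  -4.695  1.00  0.00           C
ATOM      6  N   GLY A   2      11.032   6.673  -2.852  1.00  0.00           N
ATOM      7  CA  GLY A   2      10.253   7.350  -1.820  1.00  0.00           C
ATOM      8  C   GLY A   2      10.987   8.575  -1.295  1.00  0.00           C
ATOM      9  O   GLY A   2      12.197   8.703  -1.471  1.00  0.00           O
ATOM     10  N   SER B   3      10.274   9.480  -0.634  1.00  0.00           N
ATOM     11  CA  SER B   3      10.861  10.707  -0.096  1.00  0.00           C
ATOM     12  OG  SER B   3      11.907  10.368   0.809  1.00  0.00
HETATM   13 FE   HEC A   4       8.500   9.000  -3.000  1.00  0.00          FE
HETATM   14  O   HOH A   5       5.000   5.000  -5.000  1.00  0.00           O
END
"""
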