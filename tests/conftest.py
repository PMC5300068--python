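import numpy as np
import pytest

from flexscat.synthetic import ToyDimerSpec, make_toy_dimer

TINY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.967   6.820  -5.066  1.00  0.00           C
ATOM      4  O   ALA A   1      13.304   7.533  -6.012  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.826   4.625  -4.699  1.00  0.00           C
ATOM      6  N   GLY A   2      13.725   6.641  -3.986  1.00  0.00           N
ATOM      7  CA  GLY A   2      15.015   7.311  -3.841  1.00  0.00           C
ATOM      8  C   GLY A   2      16.102   6.414  -4.414  1.00  0.00           C
ATOM      9  O   GLY A   2      15.841   5.228  -4.643  1.00  0.00           O
ATOM     10  N   SER B   5      17.321   6.942  -4.609  1.00  0.00           N
ATOM     11  CA  SER B   5      18.453   6.173  -5.128  1.00  0.00           C
ATOM     12  C   SER B   5      19.761   6.944  -4.957  1.00  0.00           C
ATOM     13  O   SER B   5      19.790   8.169  -5.091  1.00  0.00           O
ATOM     14  CB  SER B   5      18.232   5.845  -6.607  1.00  0.00           C
ATOM     15  OG  SER B   5      19.362   5.168  -7.138  1.00  0.00           O
TER
HETATM   16 CA    CA B 101      21.500   7.000  -5.500  1.00  0.00          CA
END
"""


@pytest.fixture()
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture(scope="session")
def masp3d_toy():
    """Default three-domain-per-arm toy dimer (straight arms)."""
    return make_toy_dimer(ToyDimerSpec())


@pytest.fixture(scope="session")
def bent_toy():
    return make_toy_dimer(ToyDimerSpec(bend_angle_deg=120.0))


def random_ball_points(n, radius, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        c = rng.uniform(-radius, radius, size=(2 * n, 3))
        pts.extend(c[np.sum(c**2, axis=1) <= radius**2])
    return np.array(pts[:n])
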