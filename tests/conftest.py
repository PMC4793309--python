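import numpy as np
import pytest

import pocketfish as pf
from pocketfish import synth

# hand-written 3-residue PDB with an acetylsalicylate HETATM group (13 heavy atoms)
PROTEIN_LINES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.200  -1.200   0.500  1.00  0.00           O
ATOM      5  N   GLY A   2       3.800   0.200   0.100  1.00  0.00           N
ATOM      6  CA  GLY A   2       5.100   0.600   0.300  1.00  0.00           C
ATOM      7  O   GLY A   2       6.000  -0.500   0.200  1.00  0.00           O
ATOM      8  N   SER A   3       7.500   1.000   0.500  1.00  0.00           N
ATOM      9  CA  SER A   3       8.900   1.200   0.700  1.00  0.00           C
ATOM     10  OG  SER A   3       9.500   2.500   0.900  1.00  0.00           O
"""

LIGAND_LINES = """\
HETATM   11  C1  AIN A 101       1.390   0.000   4.000  1.00  0.00           C
HETATM   12  C2  AIN A 101       0.695   1.204   4.000  1.00  0.00           C
HETATM   13  C3  AIN A 101      -0.695   1.204   4.000  1.00  0.00           C
HETATM   14  C4  AIN A 101      -1.390   0.000   4.000  1.00  0.00           C
HETATM   15  C5  AIN A 101      -0.695  -1.204   4.000  1.00  0.00           C
HETATM   16  C6  AIN A 101       0.695  -1.204   4.000  1.00  0.00           C
HETATM   17  C7  AIN A 101       2.890   0.000   4.000  1.00  0.00           C
HETATM   18  O1  AIN A 101       3.490   1.070   4.000  1.00  0.00           O
HETATM   19  O2  AIN A 101       3.490  -1.070   4.000  1.00  0.00           O
HETATM   20  O3  AIN A 101       1.410   2.440   4.000  1.00  0.00           O
HETATM   21  C8  AIN A 101       1.910   3.310   4.800  1.00  0.00           C
HETATM   22  O4  AIN A 101       3.010   3.310   5.300  1.00  0.00           O
HETATM   23  C9  AIN A 101       0.910   4.410   5.000  1.00  0.00           C
"""


@pytest.fixture
def protein_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(PROTEIN_LINES + "TER\nEND\n")
    return p


@pytest.fixture
def complex_pdb(tmp_path):
    p = tmp_path / "toy_complex.pdb"
    p.write_text(PROTEIN_LINES + "TER\n" + LIGAND_LINES + "END\n")
    return p


@pytest.fixture(scope="session")
def query_complex():
    return pf.make_query_complex(3, struct_id="QRY0")


@pytest.fixture(scope="session")
def query_site(query_complex):
    return pf.extract_site(query_complex, query_complex.ligands[0])


@pytest.fixture(scope="session")
def query_ligand(query_complex):
    return query_complex.ligands[0]


@pytest.fixture(scope="session")
def pocket_direction(query_complex, query_site):
    lig = query_complex.ligands[0]
    return lig.heavy_coords().mean(axis=0) - query_site.rep_coords.mean(axis=0)


@pytest.fixture(scope="session")
def benchmark(query_site, query_ligand, pocket_direction):
    """The core planted-pocket benchmark: 10 planted (sigma 0.3 Å, 1 BLOSUM62
    substitution) among 100 decoys, with a null calibrated on disjoint decoys."""
    spec = synth.PlantSpec(noise_sigma=0.3, n_substitutions=1, seed=42)
    db, truth = synth.make_benchmark(
        query_site, n_planted=10, n_decoys=100, spec=spec,
        pocket_direction=pocket_direction, ligand_coords=query_ligand.heavy_coords(),
    )
    null_db = synth.make_decoy_db(25, 777)
    null = pf.calibrate_null(query_site, null_db, n_samples=20_000, seed=99)
    return db, truth, null


@pytest.fixture(scope="session")
def benchmark_hits(query_site, benchmark):
    db, truth, null = benchmark
    return pf.search(query_site, db, null, pf.SearchConfig())


def random_rigid_transform(rng):
    """Random proper rotation + translation (QR-based, seeded)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    return q, t


def apply_rigid_to_structure(structure, rotation, translation):
    import copy

    s = copy.deepcopy(structure)
    for res in list(s.residues) + list(s.ligands):
        for a in res.atoms:
            a.coord = rotation @ a.coord + translation
    return s
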