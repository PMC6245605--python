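"""Shared fixtures: tiny hand-written PDB texts and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from shapeclust.synthetic import FamilySpec, generate_dataset

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.345   7.364  -4.803  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       8.000   8.000   8.000  1.00  0.00           C
ENDMDL
END
"""

HYDROGEN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  HA  ALA A   1       1.500   1.000   0.000  1.00  0.00           H
ATOM      4  C   ALA A   1       2.200   1.300   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       3.400   1.300   0.500  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA AALA A   2       3.000   0.000   0.000  0.50  0.00           C
ATOM      4  CA BALA A   2       4.000   0.000   0.000  0.50  0.00           C
END
"""


@pytest.fixture
def pdb_file(tmp_path):
    def _write(text, name="model.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def two_family_models():
    """Two families of three 40-residue models each, with ground truth."""
    specs = [
        FamilySpec("A", 3, template_length=40, seed=0),
        FamilySpec("B", 3, template_length=40, seed=1),
    ]
    return generate_dataset(specs, global_seed=3)


@pytest.fixture(scope="session")
def plane_cloud():
    """A 10x10 grid on z = 0 (clearly planar neighborhoods)."""
    from shapeclust.pdb_io import PointCloud

    xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
    pts = np.stack([xs.ravel(), ys.ravel(), np.zeros(100)], axis=1)
    return PointCloud(points=pts)


@pytest.fixture(scope="session")
def sphere_cloud():
    """500 quasi-uniform points on a sphere of radius 5, with exact normals."""
    from shapeclust.pdb_io import PointCloud

    rng = np.random.default_rng(7)
    v = rng.normal(size=(500, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return PointCloud(points=5.0 * v, normals=v.copy())
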