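"""Shared fixtures: hand-written PDB snippets and session-scoped synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

import helixsurf as hs
from helixsurf.synthetic import make_groove_complex, make_rough_blob

ALA_FRAGMENT_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.885  -5.032  1.00  0.00           C
TER
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   LEU A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  LEU A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  CB  LEU A   2       5.500   2.600   0.000  1.00  0.00           C
TER
ATOM      8  N   TRP B   5      10.000  10.000  10.000  1.00  0.00           N
ATOM      9  CA  TRP B   5      11.400  10.000  10.000  1.00  0.00           C
ATOM     10  CB  TRP B   5      12.000  11.400  10.000  1.00  0.00           C
TER
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.450   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.500   0.100   0.000  0.40  0.00           C
ATOM      4  CB  SER A   1       2.000   1.400   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def ala_pdb_text() -> str:
    return ALA_FRAGMENT_PDB


@pytest.fixture
def two_chain_pdb_text() -> str:
    return TWO_CHAIN_PDB


@pytest.fixture
def altloc_pdb_text() -> str:
    return ALTLOC_PDB


@pytest.fixture(scope="session")
def groove():
    """Default synthetic groove complex with its ground truth."""
    receptor, peptide, truth = make_groove_complex(seed=0)
    return receptor, peptide, truth


@pytest.fixture(scope="session")
def groove_report(groove, tmp_path_factory):
    """End-to-end pipeline report on the groove complex, written via PDB."""
    receptor, peptide, truth = groove
    outdir = tmp_path_factory.mktemp("groove")
    combined = hs.Structure(
        receptor.atoms + peptide.atoms, source_id="groove", model_index=1
    )
    path = outdir / "groove.pdb"
    hs.write_pdb(combined, path)
    report = hs.analyze_complex(str(path), peptide_chain="P")
    return report, truth


@pytest.fixture(scope="session")
def blob_dimensions():
    """Fitted fractal dimension per roughness level 0..3 (fixed seed)."""
    dims = []
    for level in range(4):
        blob, _ = make_rough_blob(bump_levels=level, seed=1)
        series = hs.area_series(blob, n_points=960)
        dims.append(hs.fit_dimension(series).dimension)
    return np.asarray(dims)
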