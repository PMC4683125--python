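"""Shared fixtures: hand-written minimal structures and synthetic corpora."""

from __future__ import annotations

import textwrap

import pytest

from nabench.binding_annotation import AnnotationConfig, annotate
from nabench.sasa import SasaParams
from nabench.synthetic_data import SyntheticSpec, generate_complex

# One alanine (5 atoms, chain A) next to one adenosine fragment
# (10 atoms, chain B).  Hand-written; coordinates are arbitrary but place
# the nucleotide within contact range of the residue.
MINIMAL_PDB = textwrap.dedent("""\
    ATOM      1  N   ALA A   1       0.000   1.458   0.000  1.00  0.00           N
    ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
    ATOM      3  C   ALA A   1       1.420  -0.550   0.000  1.00  0.00           C
    ATOM      4  O   ALA A   1       2.100  -0.300  -1.000  1.00  0.00           O
    ATOM      5  CB  ALA A   1      -0.800  -0.500   1.200  1.00  0.00           C
    TER       6      ALA A   1
    ATOM      7  P     A B   1       5.000   0.000   0.000  1.00  0.00           P
    ATOM      8  OP1   A B   1       5.800   1.200   0.300  1.00  0.00           O
    ATOM      9  O5'   A B   1       5.500  -1.300   0.600  1.00  0.00           O
    ATOM     10  C5'   A B   1       6.700  -1.900   1.100  1.00  0.00           C
    ATOM     11  C4'   A B   1       6.500  -3.400   1.300  1.00  0.00           C
    ATOM     12  O4'   A B   1       6.000  -4.000   0.100  1.00  0.00           O
    ATOM     13  C3'   A B   1       5.500  -3.800   2.400  1.00  0.00           C
    ATOM     14  C2'   A B   1       5.600  -5.300   2.400  1.00  0.00           C
    ATOM     15  C1'   A B   1       5.900  -5.400   0.900  1.00  0.00           C
    ATOM     16  N9    A B   1       7.000  -6.300   0.600  1.00  0.00           N
    END
""")

# The same content in mmCIF syntax (field-by-field equivalent).
MINIMAL_CIF = textwrap.dedent("""\
    data_mini
    loop_
    _atom_site.group_PDB
    _atom_site.id
    _atom_site.type_symbol
    _atom_site.label_atom_id
    _atom_site.label_alt_id
    _atom_site.label_comp_id
    _atom_site.label_asym_id
    _atom_site.label_entity_id
    _atom_site.label_seq_id
    _atom_site.pdbx_PDB_ins_code
    _atom_site.Cartn_x
    _atom_site.Cartn_y
    _atom_site.Cartn_z
    _atom_site.occupancy
    _atom_site.B_iso_or_equiv
    _atom_site.auth_seq_id
    _atom_site.auth_asym_id
    _atom_site.pdbx_PDB_model_num
    ATOM 1 N N . ALA A 1 1 ? 0.000 1.458 0.000 1.00 0.00 1 A 1
    ATOM 2 C CA . ALA A 1 1 ? 0.000 0.000 0.000 1.00 0.00 1 A 1
    ATOM 3 C C . ALA A 1 1 ? 1.420 -0.550 0.000 1.00 0.00 1 A 1
    ATOM 4 O O . ALA A 1 1 ? 2.100 -0.300 -1.000 1.00 0.00 1 A 1
    ATOM 5 C CB . ALA A 1 1 ? -0.800 -0.500 1.200 1.00 0.00 1 A 1
    ATOM 6 P P . A B 2 1 ? 5.000 0.000 0.000 1.00 0.00 1 B 1
    ATOM 7 O OP1 . A B 2 1 ? 5.800 1.200 0.300 1.00 0.00 1 B 1
    ATOM 8 O "O5'" . A B 2 1 ? 5.500 -1.300 0.600 1.00 0.00 1 B 1
    ATOM 9 C "C5'" . A B 2 1 ? 6.700 -1.900 1.100 1.00 0.00 1 B 1
    ATOM 10 C "C4'" . A B 2 1 ? 6.500 -3.400 1.300 1.00 0.00 1 B 1
    ATOM 11 O "O4'" . A B 2 1 ? 6.000 -4.000 0.100 1.00 0.00 1 B 1
    ATOM 12 C "C3'" . A B 2 1 ? 5.500 -3.800 2.400 1.00 0.00 1 B 1
    ATOM 13 C "C2'" . A B 2 1 ? 5.600 -5.300 2.400 1.00 0.00 1 B 1
    ATOM 14 C "C1'" . A B 2 1 ? 5.900 -5.400 0.900 1.00 0.00 1 B 1
    ATOM 15 N N9 . A B 2 1 ? 7.000 -6.300 0.600 1.00 0.00 1 B 1
""")

WATERS_ONLY_PDB = textwrap.dedent("""\
    HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
    HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
    END
""")


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def minimal_cif(tmp_path):
    p = tmp_path / "mini.cif"
    p.write_text(MINIMAL_CIF)
    return p


@pytest.fixture
def waters_only_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATERS_ONLY_PDB)
    return p


# Fast SASA parameters for tests where quadrature accuracy is not under test.
FAST_SASA = SasaParams(n_sphere_points=240)


@pytest.fixture(scope="session")
def small_spec():
    """A small but curation-passing synthetic corpus specification."""
    return SyntheticSpec(seed=7, n_proteins=3, chain_length=40)


@pytest.fixture(scope="session")
def small_complex(small_spec):
    """(structure, truth) for one small ladder complex."""
    return generate_complex(small_spec, 0)


@pytest.fixture(scope="session")
def small_annotations(small_complex):
    structure, _ = small_complex
    return annotate(structure, AnnotationConfig(), FAST_SASA)
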