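import pytest

from gatesite.family_alignment import read_msa, read_numbering
from gatesite.residue_triage import read_annotations, read_fixture
from gatesite.synthetic_data import write_paper_fixture


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Worked-example fixture files written once per session."""
    outdir = tmp_path_factory.mktemp("worked_example")
    return write_paper_fixture(outdir)


@pytest.fixture(scope="session")
def worked_example(fixture_paths):
    """Parsed worked-example inputs: per-residue table, annotations, family."""
    return {
        "fixture": read_fixture(fixture_paths["fixture"]),
        "annotations": read_annotations(fixture_paths["annotations"]),
        "family": read_msa(
            fixture_paths["msa"], read_numbering(fixture_paths["numbering"])
        ),
        "target": "MERTK",
    }


def write_pdb(path, text):
    path.write_text(text)
    return path


MINIMAL_PDB = """\
ATOM      1  N   GLY A   1       5.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       6.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       7.000   0.000   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       8.000   0.000   0.000  1.00  0.00           O
HETATM    5  C1  LIG B   9       0.000   0.000   0.000  1.00  0.00           C
END
"""
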