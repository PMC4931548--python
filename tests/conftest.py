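import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dasi.bin_io import Candidate, CIDSpectrum, UnknownFeatures
from dasi.chemgraph import Formula, parse_structure
from dasi.config import FilterWindows


SMILES_FIXTURES = {
    "methane": "C",
    "ethane": "CC",
    "ethanol": "CCO",
    "propanol": "CCCO",
    "butane": "CCCC",
    "isobutane": "CC(C)C",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "cyclohexadiene": "C1=CC=CCC1",
    "glycine": "NCC(=O)O",
    "pyridine": "c1ccncc1",
    "ethyl_acetate": "CCOC(C)=O",
    "tetrafluoromethane": "FC(F)(F)F",
}


@pytest.fixture(scope="session")
def mols():
    return {name: parse_structure(smi) for name, smi in SMILES_FIXTURES.items()}


@pytest.fixture
def windows():
    return FilterWindows()


@pytest.fixture
def simple_unknown():
    """A hand-built unknown with a two-peak spectrum."""
    return UnknownFeatures(
        id="u0", mimw=Formula.from_string("C4H8O2").mass,
        formula=Formula.from_string("C4H8O2"),
        ri_ref=200.0, ecom50_ref=5.0, drift_ref=10.0,
        spectrum=CIDSpectrum(((60.0206, 50.0), (74.0362, 100.0))),
    )


def make_candidate(cid, smiles, ri=200.0, ecom50=5.0, drift=10.0, bio=1.0):
    return Candidate(id=cid, structure=parse_structure(smiles),
                     ri_pred=ri, ecom50_pred=ecom50, drift_pred=drift,
                     bio_score=bio)


@pytest.fixture
def make_cand():
    return make_candidate
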