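import pytest

from glycoextract import MolecularGraph, analyze


def graph(smiles: str) -> MolecularGraph:
    return MolecularGraph.from_smiles(smiles)


@pytest.fixture(scope="session")
def analyzed_fixtures():
    """Pipeline results for every bundled fixture, computed once."""
    from glycoextract import fixtures

    out = {}
    for name in fixtures.SET_NAMES:
        for entry in fixtures.fixture_set(name):
            out[entry.id] = (entry, analyze(graph(entry.smiles)))
    return out
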