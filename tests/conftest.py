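import logging

import pytest

from glyccs import fixtures

logging.getLogger("glyccs").setLevel(logging.ERROR)


def _session_molecule(request, key, smiles, seed):
    store = getattr(request.session, "_mol_store", None)
    if store is None:
        store = {}
        request.session._mol_store = store
    if key not in store:
        store[key] = fixtures.from_smiles(smiles, seed=seed, label=key)
    return store[key].copy()  # molecules are mutable: hand out copies


@pytest.fixture
def glucose(request):
    return _session_molecule(request, "glucose", fixtures.SMILES["glucose"], 3)


@pytest.fixture
def melezitose(request):
    return _session_molecule(request, "melezitose", fixtures.SMILES["melezitose"], 5)


@pytest.fixture
def cellobiose(request):
    return _session_molecule(request, "cellobiose", fixtures.SMILES["cellobiose"], 5)


@pytest.fixture
def butane(request):
    return _session_molecule(request, "butane", "CCCC", 1)


@pytest.fixture
def ethane(request):
    return _session_molecule(request, "ethane", "CC", 1)
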