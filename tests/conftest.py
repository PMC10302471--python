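import pytest
from hypothesis import settings
from rdkit import Chem

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from polyforge import BuildConfig
from polyforge import fixtures as fx


@pytest.fixture(scope="session")
def catalog():
    return fx.catalog()


@pytest.fixture
def furan(catalog):
    return catalog["furan"]


@pytest.fixture
def thiophene(catalog):
    return catalog["thiophene"]


@pytest.fixture
def benzene(catalog):
    return catalog["benzene"]


@pytest.fixture
def fast_cfg():
    """Topology-only config: no relaxation, deterministic."""
    return BuildConfig(ff_iterations=0, seed=7)


def canon(smiles_or_graph) -> str:
    """Canonical SMILES with hydrogens collapsed, for graph-identity checks."""
    if isinstance(smiles_or_graph, str):
        return Chem.CanonSmiles(smiles_or_graph)
    mol = Chem.RemoveHs(smiles_or_graph.to_rdkit())
    return Chem.MolToSmiles(mol)


def count_substructure(graph, smarts: str) -> int:
    mol = graph.to_rdkit()
    query = Chem.MolFromSmarts(smarts)
    return len(mol.GetSubstructMatches(query, uniquify=True))
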