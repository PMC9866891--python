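import numpy as np
import pytest
from rdkit import Chem

from pfascreen.descriptors import descriptor_table
from pfascreen.modeling import dataset_from_table
from pfascreen.synthetic import (
    SyntheticConfig,
    benchmark_structures,
    decoy_structures,
    simulate_scores,
)


@pytest.fixture(scope="session")
def benchmark_table():
    """Descriptor table of the fixed 43-compound synthetic structure set."""
    table, rejects = descriptor_table(benchmark_structures(), include_pool=True)
    assert rejects.empty
    return table


@pytest.fixture(scope="session")
def benchmark(benchmark_table):
    """Labeled synthetic benchmark under the default generating model."""
    cfg = SyntheticConfig(seed=11)
    ds = dataset_from_table(benchmark_table)
    ds.y = simulate_scores(benchmark_table, cfg)
    return ds


@pytest.fixture(scope="session")
def molecule_smiles():
    """A diverse pool of >100 parsable structures: the fixed benchmark
    series, named reference compounds and random decoys."""
    from pfascreen.synthetic import NAMED_PFAS

    smiles = [s for _, s in benchmark_structures()]
    smiles += list(NAMED_PFAS.values())
    smiles += decoy_structures(60, seed=5)
    return smiles


def shuffled_smiles(smi: str, seed: int) -> str:
    """Rewrite a SMILES with a random atom numbering (same molecule)."""
    mol = Chem.MolFromSmiles(smi)
    rng = np.random.default_rng(seed)
    perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
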