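import numpy as np
import pytest
from hypothesis import settings

from chanvar.structure import Residue, StructureModel

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_model(entries) -> StructureModel:
    """Build a StructureModel from (chain, pos, name, {atom: xyz}) tuples."""
    residues = {}
    for chain, pos, name, atoms in entries:
        residues[(chain, pos)] = Residue(
            chain=chain, position=pos, name=name,
            atoms={k: np.asarray(v, float) for k, v in atoms.items()})
    return StructureModel(residues=residues)


@pytest.fixture
def model_factory():
    return make_model
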