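import numpy as np
import pytest

from structqa import synthetic
from structqa.structure_io import Residue, StructureModel


@pytest.fixture
def helix_model() -> StructureModel:
    return synthetic.make_chain(20, topology="helix", seed=42)


@pytest.fixture
def walk_model() -> StructureModel:
    return synthetic.make_chain(30, topology="random_walk", seed=7)


@pytest.fixture
def two_entity_complex() -> StructureModel:
    model, _ = synthetic.make_complex(3, ("1", "1", "2"), seed=3)
    return model


def simple_model(plddts, chain_id="A", entity_id="1", spacing=3.8):
    """Linear chain with the given per-residue confidences."""
    residues = [
        Residue(
            chain_id=chain_id,
            entity_id=entity_id,
            seq_index=i + 1,
            aa_code="A",
            ca_coord=np.array([i * spacing, 0.0, 0.0]),
            cb_coord=np.array([i * spacing, 1.53, 0.0]),
            plddt=float(p),
        )
        for i, p in enumerate(plddts)
    ]
    return StructureModel(residues=residues)
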