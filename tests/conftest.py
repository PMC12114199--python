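import numpy as np
import pytest
from rdkit import Chem

from pharmscreen.chem_io import Molecule, generate_conformers
from pharmscreen.matching import MatchParams
from pharmscreen.model import (
    ModelFeature,
    ModelOrigin,
    PharmacophoreModel,
    load_exemplar_models,
)
from pharmscreen.perception import perceive_features


@pytest.fixture(scope="session")
def exemplar_collection():
    return load_exemplar_models()


@pytest.fixture(scope="session")
def jak1_sb1(exemplar_collection):
    return exemplar_collection.get("jak1_sb1")


def embed(smiles: str, name: str, n_conf: int = 1, seed: int = 7) -> Molecule:
    mol = Molecule(name, Chem.MolFromSmiles(smiles))
    return generate_conformers(mol, n_conf, seed=seed)


@pytest.fixture(scope="session")
def benzene():
    return embed("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def phenol():
    return embed("Oc1ccccc1", "phenol")


def self_model(molecule: Molecule, conformer: int = 0, radius: float = 1.5,
               model_id: str = "self", xvols=()) -> PharmacophoreModel:
    """A model built verbatim from a ligand's own perceived features."""
    fs = perceive_features(molecule, conformer)
    return PharmacophoreModel(
        id=model_id,
        target="other",
        origin=ModelOrigin("ligand_based", training_ids=(molecule.id,)),
        features=[
            ModelFeature(
                f.kind, f.position, radius, f.direction,
                34.0 if f.direction is not None else None,
            )
            for f in fs.features
        ],
        xvols=list(xvols),
    )


@pytest.fixture(scope="session")
def default_params():
    return MatchParams()
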