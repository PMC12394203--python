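import numpy as np
import pytest

from cdr3scope.regions import imgt_cdr3_positions
from cdr3scope.repertoire import AnnotatedVHH, Repertoire
from cdr3scope.synthetic import (
    FR4_POSITIONS,
    FR4_TEMPLATE,
    SCAFFOLD,
    RepertoireRecipe,
    StructureRecipe,
    generate_repertoire,
    generate_structures,
)


def make_vhh(id: str, cdr3: str, count: int = 10, species: str = "alpaca",
             germline: str = "", scaffold_overrides: dict[int, str] | None = None) -> AnnotatedVHH:
    """A structurally valid VHH built on the standard scaffold with a custom CDR3."""
    overrides = scaffold_overrides or {}
    numbering = [(pos, "", overrides.get(pos, res)) for pos, res in SCAFFOLD]
    numbering += [(pos, icode, res) for (pos, icode), res in zip(imgt_cdr3_positions(len(cdr3)), cdr3)]
    numbering += [(pos, "", res) for pos, res in zip(FR4_POSITIONS, FR4_TEMPLATE)]
    sequence = "".join(res for _, _, res in numbering)
    return AnnotatedVHH(id=id, species=species, sequence=sequence,
                        numbering=tuple(numbering), count=count, germline=germline)


@pytest.fixture(scope="session")
def small_repertoire() -> Repertoire:
    rep, _ = generate_repertoire(RepertoireRecipe(n=600, seed=42))
    return rep


@pytest.fixture(scope="session")
def structure_set():
    models, sidecar = generate_structures(StructureRecipe(n=60, seed=7))
    return models, sidecar


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
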