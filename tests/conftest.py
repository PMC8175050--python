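import numpy as np
import pytest

from hetphylo.alphabets import AA, DNA
from hetphylo.models import (
    GammaASRV,
    MixtureComposition,
    ProfileSet,
    SingleComposition,
    SubstitutionModel,
    uniform_exchangeabilities,
)
from hetphylo.msa import Alignment
from hetphylo.trees import parse_newick


@pytest.fixture
def dna_alignment():
    return Alignment(
        ["t1", "t2", "t3", "t4"],
        np.array([list("ACGTACGTAC"), list("ACGTACGTAA"),
                  list("ACGAACGTAC"), list("ACTTACGTAC")]),
        DNA,
    )


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((t1:0.1,t2:0.2):0.05,(t3:0.15,t4:0.3):0.05);")


@pytest.fixture
def jc_gamma():
    from hetphylo.models import jc69

    return jc69(GammaASRV(0.5, 4))


def random_model(rng, alphabet, mode="single", asrv=None):
    """Random valid model for property-style checks."""
    c = alphabet.size
    R = np.triu(rng.uniform(0.3, 2.0, (c, c)), 1)
    R = R + R.T
    if mode == "single":
        comp = SingleComposition(rng.dirichlet(np.ones(c)))
    elif mode == "mixture":
        K = int(rng.integers(2, 4))
        comp = MixtureComposition(
            ProfileSet(rng.dirichlet(np.ones(c), K)), rng.dirichlet(np.ones(K))
        )
    else:
        raise ValueError(mode)
    return SubstitutionModel(alphabet, R, comp, asrv)
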