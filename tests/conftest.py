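import numpy as np
import pytest

from cryotrace import (
    DensityMap,
    SyntheticSpec,
    gen_toy_structure,
    simulate_density,
)
from cryotrace.candidates import CandidateSet, CaCandidate
from cryotrace.constants import AA_INDEX
from cryotrace.labels import make_label_masks
from cryotrace.structure import Chain, Residue, Structure


@pytest.fixture(scope="session")
def toy_spec():
    return SyntheticSpec(n_residues=40, seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def toy_structure(toy_spec):
    return gen_toy_structure(toy_spec)


@pytest.fixture(scope="session")
def toy_map(toy_structure, toy_spec):
    return simulate_density(toy_structure, toy_spec)


@pytest.fixture(scope="session")
def toy_masks(toy_structure, toy_map):
    return make_label_masks(toy_structure, toy_map)


def make_structure(coords, sequence, chain_id="A"):
    """Cα-only structure from coordinates and a sequence string."""
    chain = Chain(chain_id=chain_id)
    for i, (xyz, aa) in enumerate(zip(coords, sequence)):
        chain.residues.append(
            Residue(aa=aa, seq_index=i + 1, atoms={"CA": np.asarray(xyz, dtype=float)})
        )
    return Structure(chains=[chain])


def candidates_from_structure(structure, one_hot=0.95):
    """CandidateSet with near-one-hot amino probabilities at true Cα sites."""
    cs = CandidateSet()
    for _, res in structure.iter_residues():
        aa = np.full(20, (1 - one_hot) / 19.0)
        if res.aa in AA_INDEX:
            aa[AA_INDEX[res.aa]] = one_hot
        else:
            aa[:] = 1.0 / 20
        cs.candidates.append(
            CaCandidate(
                coord=np.array(res.ca, dtype=float),
                ca_prob=0.9,
                backbone_score=0.9,
                aa_probs=aa / aa.sum(),
            )
        )
    return cs


@pytest.fixture
def make_ca_structure():
    return make_structure


@pytest.fixture
def make_candidates():
    return candidates_from_structure
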