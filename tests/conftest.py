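import numpy as np
import pytest

from ensemblekit import ConformerEnsemble, concatenate
from ensemblekit.synthetic_data import (
    HairpinSpec,
    make_extended_ensemble,
    make_hairpin_ensemble,
)


@pytest.fixture
def hairpin18():
    """Noiseless idealized 18-residue hairpin, turn at the chain midpoint."""
    return make_hairpin_ensemble(HairpinSpec(n_res=18, apex=9, strand_sep=4.8))


@pytest.fixture
def left_hairpin18():
    """Left-registered hairpin: apex shifted toward the N-terminus."""
    return make_hairpin_ensemble(HairpinSpec(n_res=18, apex=7, strand_sep=4.8))


@pytest.fixture
def extended18():
    return make_extended_ensemble(18)


@pytest.fixture
def mixed_ensemble():
    """70% noisy hairpin + 30% noisy extended frames, well separated."""
    hp = make_hairpin_ensemble(
        HairpinSpec(n_res=18, apex=9, noise_sd=0.3, n_frames=70, seed=11))
    ext = make_extended_ensemble(18, noise_sd=0.3, n_frames=30, seed=12)
    return concatenate(hp, ext)


def random_ensemble(n_frames, n_res, seed=0, scale=5.0):
    """Unstructured random-coordinate ensemble for oracle comparisons."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    coords = rng.normal(0, scale, size=(n_frames, n_res, 3))
    atoms = pd.DataFrame({"res_id": np.arange(1, n_res + 1),
                          "res_name": ["GLY"] * n_res,
                          "atom_name": ["CA"] * n_res})
    return ConformerEnsemble(coords, atoms)
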