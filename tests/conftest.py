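import numpy as np
import pandas as pd
import pytest

from enzypred.io_model import DescriptorMatrix, ReactionSet
from enzypred.synthetic import preset_params, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20180613)


@pytest.fixture(scope="session")
def separated_dataset():
    """A clean clustered dataset: 10 enzymes x 5 substrates, 50 descriptors."""
    return simulate_dataset(preset_params("separated", seed=11))


@pytest.fixture
def tiny_matrix():
    """3 substrates, 2 descriptors, hand-sized."""
    return DescriptorMatrix(
        pd.DataFrame(
            [[0.0, 1.0], [0.1, 1.1], [5.0, -3.0]],
            index=["a", "b", "c"],
            columns=["d1", "d2"],
        )
    )


@pytest.fixture
def tiny_reactions():
    """E1 catalyzes a and b; E2 catalyzes c."""
    return ReactionSet.from_pairs([("E1", "a"), ("E1", "b"), ("E2", "c")])


@pytest.fixture
def reaction_csv(tmp_path):
    path = tmp_path / "reactions.csv"
    path.write_text(
        "enzyme_id,substrate_id,source\n"
        "E1,a,hmdb\nE1,b,hmdb\nE1,a,brenda\nE2,c,\nE2,a,\n"
    )
    return path


@pytest.fixture
def descriptor_csv(tmp_path):
    path = tmp_path / "descriptors.csv"
    path.write_text(
        "Name,XLogP,nsOH,MW\n"
        "a,1.5,2,46.07\n"
        "b,,3,60.10\n"
        "c,0.2,not_a_number,18.02\n"
    )
    return path
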