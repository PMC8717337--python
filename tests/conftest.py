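import numpy as np
import pandas as pd
import pytest

from soilphylo import CommunityMatrix, read_newick
from soilphylo.synthetic import generate

TOY5 = "((A:1,B:1):1,(C:1,(D:0.5,E:0.5):0.5):1);"


@pytest.fixture(scope="session")
def toy5():
    """Five-tip tree with hand-enumerable path lengths."""
    return read_newick(TOY5)[0]


@pytest.fixture(scope="session")
def toy5_dist(toy5):
    from soilphylo import cophenetic
    return cophenetic(toy5)


@pytest.fixture(scope="session")
def small_dataset():
    """Neutral synthetic dataset reused by pipeline-level tests."""
    return generate("neutral", seed=7, n_trees=5)


@pytest.fixture()
def tiny_community():
    return CommunityMatrix(
        sites=("s1", "s2", "s3"),
        taxa=("A", "B", "C", "D", "E"),
        values=np.array([
            [1, 1, 1, 0, 0],
            [1, 0, 0, 1, 1],
            [0, 0, 1, 1, 1],
        ]),
    )


@pytest.fixture()
def tiny_env():
    return pd.DataFrame({
        "site": ["s1", "s2", "s3"],
        "base_cation": [7.5, 0.2, 0.4],
        "formation": pd.Categorical(
            ["Solimoes", "Ica", "Terrace"],
            categories=["Solimoes", "Ica", "Terrace"]),
    }).set_index("site", drop=False)
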