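import numpy as np
import pytest

from echonet.bicm import BipartiteGraph, fit_bicm
from echonet.io import Dataset, PostRecord
from echonet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def small_dataset() -> Dataset:
    """Hand-built mini dataset: 2 verified creators, 3 unverified users."""
    posts = [
        PostRecord("p1", "v1", True),
        PostRecord("p2", "v2", True),
        PostRecord("p3", "u1", False, retweeted_author_id="v1"),
        PostRecord("p4", "u1", False, retweeted_author_id="v1"),
        PostRecord("p5", "u2", False, retweeted_author_id="v1"),
        PostRecord("p6", "u2", False, retweeted_author_id="v2"),
        PostRecord("p7", "u3", False, retweeted_author_id="v2"),
        PostRecord("p8", "u1", False, urls=("https://example.com/a", "https://bad.net/x")),
        PostRecord("p9", "u2", False, urls=("https://example.com/a",)),
    ]
    return Dataset(posts=posts)


@pytest.fixture
def graph_3x3() -> BipartiteGraph:
    B = np.array([[1, 1, 0], [1, 0, 0], [0, 0, 1]])
    return BipartiteGraph(list("ABC"), list("xyz"), B)


@pytest.fixture
def model_3x3(graph_3x3):
    return fit_bicm(graph_3x3, tol=1e-10)


@pytest.fixture(scope="session")
def planted():
    """One strong-effect synthetic dataset plus its ground truth."""
    cfg = SyntheticConfig(seed=11)
    return generate_dataset(cfg)


def random_bipartite(rng: np.random.Generator, n_top: int, n_bottom: int, density: float) -> BipartiteGraph:
    B = (rng.random((n_top, n_bottom)) < density).astype(int)
    return BipartiteGraph(list(range(n_top)), [f"b{j}" for j in range(n_bottom)], B)
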