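import copy

import numpy as np
import pytest
from hypothesis import settings

from corovasc import (VentricleAnatomy, load_morphometry, scale_to_human)
from corovasc.morphometry import _DEFAULT_DICT, MorphometryTable
from corovasc.topology import Tree

settings.register_profile("suite", derandomize=True, max_examples=40,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_table():
    return scale_to_human(load_morphometry("default"))


@pytest.fixture(scope="session")
def small_table():
    """A light connectivity variant producing ~200-terminal trees quickly."""
    d = copy.deepcopy(_DEFAULT_DICT)
    d["connectivity"] = {
        "7": {"6": 2.5},
        "8": {"7": 2.2, "6": 0.3},
        "9": {"8": 2.2, "7": 0.3},
        "10": {"9": 2.2, "8": 0.3},
        "11": {"10": 2.2, "9": 0.5, "8": 0.5, "7": 0.5, "6": 0.5},
    }
    for row in d["orders"]:
        row["segments_per_element"] = min(row["segments_per_element"], 2.0)
    d["orders"][-1]["segments_per_element"] = 16.0
    return scale_to_human(MorphometryTable.from_dict(d))


@pytest.fixture(scope="session")
def anatomy():
    return VentricleAnatomy()


def make_random_tree(rng: np.random.Generator, n: int = 50) -> Tree:
    """Random binary-ish tree for solver property tests (any orders)."""
    parent = [-1]
    child_count = {0: 0}
    for i in range(1, n):
        candidates = [s for s, c in child_count.items() if c < 2]
        p = int(rng.choice(candidates))
        parent.append(p)
        child_count[p] += 1
        child_count[i] = 0
    length = rng.uniform(0.5, 5.0, size=n)
    radius = rng.uniform(0.1, 1.5, size=n)
    order = np.full(n, 6)
    return Tree("RAND", parent, order, length, radius,
                np.arange(n), 3.6e-3, trunk_segments=[0])


@pytest.fixture
def random_tree_factory():
    return make_random_tree
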