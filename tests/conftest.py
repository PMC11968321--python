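import numpy as np
import pandas as pd
import pytest

from fedshield.client import connect
from fedshield.node import DataView, Node, SiteDataset, UserAccount, hash_token
from fedshield.settings import default_registry, default_settings


@pytest.fixture
def settings():
    return default_settings()


@pytest.fixture
def registry():
    return default_registry()


def make_node(
    frame: pd.DataFrame,
    site: str = "s1",
    settings=None,
    permitted=None,
    types=None,
    custodian_token: str = "cust",
    node_seed: int = 7,
) -> Node:
    """One-dataset node with a single analyst account (user 'a', token 't')."""
    permitted = frozenset(permitted if permitted is not None else frame.columns)
    account = UserAccount("a", hash_token("t"), views=(DataView("D", permitted),))
    return Node(
        site=site,
        datasets=[SiteDataset("D", frame, dict(types or {}))],
        accounts=[account],
        settings=settings,
        custodian_token=custodian_token,
        node_seed=node_seed,
    )


def small_frame(n: int = 10, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(50, 10, n).round(2),
            "bmi": rng.normal(27, 4, n).round(2),
            "group": rng.choice(["a", "b"], n),
        }
    )


@pytest.fixture
def node():
    return make_node(small_frame())


@pytest.fixture
def session(node):
    return node.login("a", "t")


def connect_single(node):
    return connect([node], [{"site": node.site, "user": "a", "token": "t"}])
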