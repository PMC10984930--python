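import numpy as np
import pandas as pd
import pytest

from anrs import HybridSchema, HybridTable


@pytest.fixture
def toy_table() -> HybridTable:
    """Six records, two classes, one straddler (row 2 sits between clusters)."""
    schema = HybridSchema(
        attributes=(("v", "numeric"), ("tag", "categorical")),
        decision="cls",
    )
    df = pd.DataFrame(
        {
            "v": [0.0, 0.1, 0.5, 1.0, 1.1, 0.9],
            "tag": ["aa", "aa", "ab", "bb", "bb", "bb"],
            "cls": ["p", "p", "p", "n", "n", "n"],
        }
    )
    return HybridTable(schema, df)


def random_hybrid_table(rng: np.random.Generator, n: int, n_num: int = 2, n_cat: int = 2,
                        n_classes: int = 2) -> HybridTable:
    """Small random labeled table for oracle-equivalence tests."""
    attrs = tuple([(f"x{j}", "numeric") for j in range(n_num)]) + tuple(
        [(f"s{j}", "categorical") for j in range(n_cat)]
    )
    schema = HybridSchema(attributes=attrs, decision="y")
    tokens = ["ab", "abc", "xyz", "x", "abd"]
    cols = {f"x{j}": rng.normal(size=n) for j in range(n_num)}
    for j in range(n_cat):
        cols[f"s{j}"] = [tokens[i] for i in rng.integers(0, len(tokens), size=n)]
    cols["y"] = [f"c{i}" for i in rng.integers(0, n_classes, size=n)]
    return HybridTable(schema, pd.DataFrame(cols))
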