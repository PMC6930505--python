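import numpy as np
import pytest

from ckdrules import TransactionSet


@pytest.fixture
def toy_db() -> TransactionSet:
    """Five-transaction database with hand-countable supports:
    supp(a)=.8 supp(b)=.8 supp(c)=.4 supp(ab)=.6 supp(ac)=.4 supp(abc)=.2."""
    return TransactionSet(
        [{"a", "b"}, {"a", "b", "c"}, {"a", "c"}, {"b"}, {"a", "b"}]
    )


def random_transaction_set(
    seed: int, max_items: int = 12, max_n: int = 200
) -> TransactionSet:
    """A random small instance for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    n_items = int(rng.integers(3, max_items + 1))
    n = int(rng.integers(10, max_n + 1))
    items = [f"i{j}" for j in range(n_items)]
    p = rng.uniform(0.1, 0.6, size=n_items)
    mat = rng.random((n, n_items)) < p
    txs = [frozenset(items[j] for j in np.flatnonzero(row)) for row in mat]
    return TransactionSet(txs, catalog=items)
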