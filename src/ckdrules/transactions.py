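"""Transaction database container shared by the survey and literature miners.

A *transaction* is one respondent's set of positively-annotated survey items
(or, in the literature stage, the term pair of one semantic predication).
The container keeps transactions as frozensets over a fixed item catalog and
caches a vertical (item -> transaction-id set) index, which is what the
Apriori miner intersects to count support.
"""

from __future__ import annotations

from collections.abc import Iterable
from typing import FrozenSet


class TransactionSet:
    """An ordered collection of item-code sets over a catalog.

    Parameters
    ----------
    transactions:
        Iterable of item-code collections; duplicates within one
        transaction are collapsed (a set has no multiplicity).
    catalog:
        The item universe. If omitted it is the union of all items seen.
        Every item of every transaction must belong to the catalog.
    """

    __slots__ = ("catalog", "transactions", "_tidsets")

    def __init__(
        self,
        transactions: Iterable[Iterable[str]],
        catalog: Iterable[str] | None = None,
    ) -> None:
        txs = tuple(frozenset(t) for t in transactions)
        if catalog is None:
            cat: FrozenSet[str] = frozenset().union(*txs) if txs else frozenset()
        else:
            cat = frozenset(catalog)
            for i, t in enumerate(txs):
                extra = t - cat
                if extra:
                    raise ValueError(
                        f"transaction {i} contains items outside the catalog: "
                        f"{sorted(extra)}"
                    )
        self.catalog: FrozenSet[str] = cat
        self.transactions: tuple[FrozenSet[str], ...] = txs
        self._tidsets: dict[str, frozenset[int]] | None = None

    @property
    def n(self) -> int:
        """Number of transactions (the |T| denominator of the support)."""
        return len(self.transactions)

    def tidsets(self) -> dict[str, frozenset[int]]:
        """Vertical index: item code -> ids of transactions containing it."""
        if self._tidsets is None:
            idx: dict[str, set[int]] = {item: set() for item in self.catalog}
            for tid, t in enumerate(self.transactions):
                for item in t:
                    idx[item].add(tid)
            self._tidsets = {k: frozenset(v) for k, v in idx.items()}
        return self._tidsets

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransactionSet):
            return NotImplemented
        return self.catalog == other.catalog and self.transactions == other.transactions

    def __repr__(self) -> str:
        return f"TransactionSet(n={self.n}, |catalog|={len(self.catalog)})"
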