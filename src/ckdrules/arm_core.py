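"""Apriori frequent-itemset mining and association-rule statistics.

The three interestingness measures for a rule ``m => n`` over a transaction
database *T* of size *N* are

* support    = |{t in T : m ∪ n ⊆ t}| / N
* confidence = support(m ∪ n) / support(m)
* lift       = confidence / support(n)

Lift 1 marks statistical independence of antecedent and consequent; values
above 1 indicate positive dependence. All three are derived on demand from
exact transaction counts, so threshold comparisons at ``min_support`` never
hinge on float rounding of a stored fraction.

``apriori_mine`` is the level-wise miner (candidate join + subset pruning,
support counted by intersecting per-item transaction-id sets);
``brute_force_oracle`` enumerates every candidate itemset directly and exists
purely as an independent correctness check on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, Iterable, Mapping, Sequence

from .transactions import TransactionSet

__all__ = [
    "Itemset",
    "AssociationRule",
    "MiningParams",
    "support_of",
    "rule_metrics",
    "apriori_mine",
    "generate_rules",
    "brute_force_oracle",
    "rules_to_frame",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which the statistics are undefined (e.g. N=0)."""


class UndefinedMetricError(ValueError):
    """Raised when a rule metric would be 0/0 — never silently NaN."""


@dataclass(frozen=True, order=True)
class Itemset:
    """A k-itemset with its exact support count.

    ``items`` is kept canonically sorted so collections of itemsets have a
    deterministic order and a well-defined equality.
    """

    items: tuple[str, ...]
    count: int
    n: int

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("itemset must be non-empty")
        if tuple(sorted(set(self.items))) != self.items:
            raise ValueError("items must be sorted and duplicate-free")
        if not 0 <= self.count <= self.n:
            raise ValueError("count must lie in [0, n]")

    @property
    def support(self) -> float:
        return self.count / self.n

    @property
    def k(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class AssociationRule:
    """The rule antecedent => consequent with support/confidence/lift.

    Metrics are stored as computed from exact counts; ``count`` is the
    number of transactions containing antecedent ∪ consequent.
    """

    antecedent: tuple[str, ...]
    consequent: tuple[str, ...]
    support: float
    confidence: float
    lift: float
    count: int

    def __post_init__(self) -> None:
        if not self.consequent:
            raise ValueError("consequent must be non-empty")
        if set(self.antecedent) & set(self.consequent):
            raise ValueError("antecedent and consequent must be disjoint")

    @property
    def items(self) -> FrozenSet[str]:
        return frozenset(self.antecedent) | frozenset(self.consequent)

    def rule_str(self) -> str:
        """Render as ``{a,b} => {c}`` (the conventional rule notation)."""
        lhs = ",".join(self.antecedent)
        rhs = ",".join(self.consequent)
        return f"{{{lhs}}} => {{{rhs}}}"


@dataclass(frozen=True)
class MiningParams:
    """Thresholds for the miner: minSup, minConf and a maximum itemset size."""

    min_support: float
    min_confidence: float = 0.0
    max_len: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.min_support <= 1.0:
            raise ValueError("min_support must be in (0, 1]")
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must be in [0, 1]")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")


def _min_count(min_support: float, n: int) -> int:
    # smallest integer count with count/n >= min_support, guarded against
    # float representation of e.g. 0.1 * n
    return max(1, math.ceil(min_support * n - 1e-9))


def support_of(items: Iterable[str], t: TransactionSet) -> tuple[float, int]:
    """Exact support (fraction, count) of an itemset in ``t``.

    The empty itemset has support 1 by convention (it is contained in every
    transaction).
    """
    if t.n == 0:
        raise DegenerateInputError("support is undefined on an empty TransactionSet")
    items = frozenset(items)
    missing = items - t.catalog
    if missing:
        raise KeyError(f"items not in catalog: {sorted(missing)}")
    if not items:
        return 1.0, t.n
    tidsets = t.tidsets()
    tids: frozenset[int] | set[int] = tidsets[min(items, key=lambda i: len(tidsets[i]))]
    for item in items:
        tids = tids & tidsets[item]
        if not tids:
            return 0.0, 0
    return len(tids) / t.n, len(tids)


def rule_metrics(
    m: Iterable[str], n: Iterable[str], t: TransactionSet
) -> AssociationRule:
    """Compute support, confidence and lift for the rule ``m => n``."""
    m, n = frozenset(m), frozenset(n)
    if not n:
        raise ValueError("consequent must be non-empty")
    if m & n:
        raise ValueError("antecedent and consequent must be disjoint")
    _, c_m = support_of(m, t)
    _, c_n = support_of(n, t)
    if c_m == 0:
        raise UndefinedMetricError("confidence undefined: antecedent never occurs")
    if c_n == 0:
        raise UndefinedMetricError("lift undefined: consequent never occurs")
    _, c_mn = support_of(m | n, t)
    confidence = c_mn / c_m
    return AssociationRule(
        antecedent=tuple(sorted(m)),
        consequent=tuple(sorted(n)),
        support=c_mn / t.n,
        confidence=confidence,
        lift=c_mn * t.n / (c_m * c_n),
        count=c_mn,
    )


def apriori_mine(t: TransactionSet, params: MiningParams) -> list[Itemset]:
    """Level-wise Apriori search for all frequent itemsets.

    Exploits anti-monotonicity: a (k)-candidate is generated by joining two
    frequent (k-1)-itemsets sharing their first k-2 items and is pruned
    unless every (k-1)-subset is frequent. Support is counted by
    intersecting the transaction-id sets of the two join parents.

    Returns every itemset of size <= ``params.max_len`` with support >=
    ``params.min_support`` (inclusive threshold), canonically ordered by
    (size, items).
    """
    if t.n == 0:
        raise DegenerateInputError("cannot mine an empty TransactionSet")
    minc = _min_count(params.min_support, t.n)

    tidsets = t.tidsets()
    level: dict[tuple[str, ...], frozenset[int]] = {
        (item,): tids for item, tids in tidsets.items() if len(tids) >= minc
    }
    out: list[Itemset] = [
        Itemset(items=key, count=len(tids), n=t.n) for key, tids in level.items()
    ]

    k = 2
    while level and k <= params.max_len:
        frequent_prev = set(level)
        keys = sorted(level)
        nxt: dict[tuple[str, ...], frozenset[int]] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if a[:-1] != b[:-1]:
                    break  # sorted keys: once prefixes diverge, no more joins
                cand = a + (b[-1],)
                # subset pruning: every (k-1)-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1 :] not in frequent_prev
                    for j in range(len(cand) - 2)
                ):
                    continue
                tids = level[a] & level[b]
                if len(tids) >= minc:
                    nxt[cand] = tids
        out.extend(Itemset(items=key, count=len(tids), n=t.n) for key, tids in nxt.items())
        level = nxt
        k += 1

    out.sort(key=lambda s: (s.k, s.items))
    return out


def generate_rules(
    frequent: Sequence[Itemset],
    t: TransactionSet,
    params: MiningParams,
    max_consequent_len: int = 1,
) -> list[AssociationRule]:
    """Construct rules from the closed collection of frequent itemsets.

    For each frequent itemset of size >= 2 every partition into a non-empty
    antecedent and a consequent of size <= ``max_consequent_len`` is scored;
    rules with confidence >= ``params.min_confidence`` are kept. Single-item
    consequents (the default) match the usual Apriori rule-induction
    convention. Supports are looked up in ``frequent``, which must be closed
    under taking subsets (as ``apriori_mine`` output is).
    """
    counts: dict[FrozenSet[str], int] = {
        frozenset(s.items): s.count for s in frequent
    }
    rules: list[AssociationRule] = []
    for s in frequent:
        if s.k < 2:
            continue
        items = frozenset(s.items)
        for size in range(1, min(max_consequent_len, s.k - 1) + 1):
            for cons in combinations(s.items, size):
                cons_fs = frozenset(cons)
                ante_fs = items - cons_fs
                c_ante = counts.get(ante_fs)
                c_cons = counts.get(cons_fs)
                if c_ante is None or c_cons is None:
                    raise ValueError(
                        f"frequent collection is not closed: missing subset of "
                        f"{s.items}"
                    )
                confidence = s.count / c_ante
                if confidence < params.min_confidence:
                    continue
                rules.append(
                    AssociationRule(
                        antecedent=tuple(sorted(ante_fs)),
                        consequent=tuple(sorted(cons_fs)),
                        support=s.count / t.n,
                        confidence=confidence,
                        lift=s.count * t.n / (c_ante * c_cons),
                        count=s.count,
                    )
                )
    rules.sort(key=lambda r: (r.antecedent, r.consequent))
    return rules


def brute_force_oracle(
    t: TransactionSet, min_support: float, max_len: int = 10
) -> list[Itemset]:
    """Exhaustively enumerate frequent itemsets; test oracle only.

    Counts support by scanning every transaction for every candidate subset
    of the catalog — deliberately sharing no code with ``apriori_mine``.
    Guarded to catalogs of at most 16 items.
    """
    if t.n == 0:
        raise DegenerateInputError("cannot mine an empty TransactionSet")
    if len(t.catalog) > 16:
        raise ValueError("brute-force oracle limited to catalogs of <= 16 items")
    minc = _min_count(min_support, t.n)
    out: list[Itemset] = []
    catalog = sorted(t.catalog)
    for k in range(1, min(max_len, len(catalog)) + 1):
        for cand in combinations(catalog, k):
            cset = set(cand)
            count = sum(1 for tx in t.transactions if cset <= tx)
            if count >= minc:
                out.append(Itemset(items=cand, count=count, n=t.n))
    out.sort(key=lambda s: (s.k, s.items))
    return out


def rules_to_frame(rules: Sequence[AssociationRule]):
    """Rules as a pandas DataFrame in the export column layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rule": [r.rule_str() for r in rules],
            "antecedent": [",".join(r.antecedent) for r in rules],
            "consequent": [",".join(r.consequent) for r in rules],
            "support": [r.support for r in rules],
            "confidence": [r.confidence for r in rules],
            "lift": [r.lift for r in rules],
            "count": [r.count for r in rules],
        }
    )
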