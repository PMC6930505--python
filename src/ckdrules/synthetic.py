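"""Synthetic survey cohorts and predication stores with planted structure.

The survey generator draws an otherwise-independent binary item field and
plants antecedent -> consequent dependencies as conditional Bernoulli draws,
so every planted rule has closed-form expected metrics:

    P(X)       = prod of the antecedent items' marginals
    support    = P(X) * P(Y|X)
    confidence = P(Y|X)
    P(Y)       = P(X) P(Y|X) + (1 - P(X)) P(Y|not X)
    lift       = P(Y|X) / P(Y)

The predication generator plants term pairs with fixed repeat counts in a
background of otherwise-unique pairs, which makes the pairwise lift of a
planted pair exactly n * c(A,B) / (c(A) * c(B)) computable by hand.

Both generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .litmine import PredicationRecord
from .transactions import TransactionSet

__all__ = [
    "PlantedDependency",
    "SyntheticSurveySpec",
    "SyntheticPredicationSpec",
    "expected_rule_metrics",
    "generate_survey",
    "generate_predications",
    "default_survey_spec",
    "default_predication_spec",
]


@dataclass(frozen=True)
class PlantedDependency:
    """One planted rule X => Y: P(Y | all of X present) vs P(Y | otherwise)."""

    antecedent: tuple[str, ...]
    consequent: str
    p_given: float
    p_not_given: float

    def __post_init__(self) -> None:
        if self.consequent in self.antecedent:
            raise ValueError("consequent must not be a member of its antecedent")
        for p in (self.p_given, self.p_not_given):
            if not 0.0 <= p <= 1.0:
                raise ValueError("conditional probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSurveySpec:
    """Item marginals, planted dependencies and cohort size.

    ``marginals`` covers the independent items; consequents of planted
    dependencies take their distribution from the dependency, not from a
    marginal. Antecedent items must be independent (i.e. not themselves a
    consequent) so the closed-form expectations hold.
    """

    marginals: Mapping[str, float]
    planted: tuple[PlantedDependency, ...] = ()
    n: int = 20_000

    def __post_init__(self) -> None:
        for item, p in self.marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal of {item!r} must be in [0, 1]")
        consequents = [d.consequent for d in self.planted]
        if len(set(consequents)) != len(consequents):
            raise ValueError("each item may be the consequent of at most one dependency")
        for d in self.planted:
            for a in d.antecedent:
                if a in consequents:
                    raise ValueError(
                        f"antecedent item {a!r} is itself a planted consequent; "
                        "closed-form expectations would not hold"
                    )
                if a not in self.marginals:
                    raise ValueError(f"antecedent item {a!r} has no marginal")
            if d.consequent in self.marginals:
                raise ValueError(
                    f"consequent {d.consequent!r} must not also have a marginal"
                )
        if self.n < 1:
            raise ValueError("cohort size must be positive")

    @property
    def catalog(self) -> list[str]:
        return sorted(list(self.marginals) + [d.consequent for d in self.planted])


def expected_rule_metrics(
    spec: SyntheticSurveySpec, antecedent: Sequence[str], consequent: str
) -> tuple[float, float, float]:
    """Closed-form (support, confidence, lift) of a planted rule."""
    dep = next(
        (
            d
            for d in spec.planted
            if d.consequent == consequent and set(d.antecedent) == set(antecedent)
        ),
        None,
    )
    if dep is None:
        raise ValueError(
            f"rule {tuple(antecedent)} => {consequent!r} does not match a planted dependency"
        )
    p_x = math.prod(spec.marginals[a] for a in dep.antecedent)
    p_y = p_x * dep.p_given + (1.0 - p_x) * dep.p_not_given
    support = p_x * dep.p_given
    confidence = dep.p_given
    if p_y == 0.0:
        raise ValueError("consequent has probability 0; lift undefined")
    return support, confidence, confidence / p_y


def generate_survey(spec: SyntheticSurveySpec, seed: int) -> TransactionSet:
    """Sample a cohort of binary transactions; bit-reproducible under seed."""
    rng = np.random.default_rng(seed)
    items = sorted(spec.marginals)
    cols = {item: rng.random(spec.n) < spec.marginals[item] for item in items}
    for dep in spec.planted:
        x_all = np.ones(spec.n, dtype=bool)
        for a in dep.antecedent:
            x_all &= cols[a]
        p = np.where(x_all, dep.p_given, dep.p_not_given)
        cols[dep.consequent] = rng.random(spec.n) < p

    catalog = sorted(cols)
    mat = np.column_stack([cols[c] for c in catalog])
    transactions = [
        frozenset(catalog[j] for j in np.flatnonzero(row)) for row in mat
    ]
    return TransactionSet(transactions, catalog=catalog)


def default_survey_spec(n: int = 20_000) -> SyntheticSurveySpec:
    """The default 14-item fixture with planted lifts ~{2.105, 1.5, 1.0}.

    Three single-antecedent dependencies exercise both selection stages:
    a strong rule (lift 2.105) that should survive the two-stage selection,
    a moderate one (lift 1.5), and an independent pair (lift exactly 1)
    that should not. Background marginals sit in 0.35-0.5 so item pairs
    clear a 0.1 support lower bound and give the selection a realistic
    rule population to average over.
    """
    marginals = {
        "x1": 0.30,
        "x2": 0.40,
        "x3": 0.50,
        "bg1": 0.50,
        "bg2": 0.45,
        "bg3": 0.45,
        "bg4": 0.40,
        "bg5": 0.40,
        "bg6": 0.35,
        "bg7": 0.35,
        "bg8": 0.50,
    }
    planted = (
        # support 0.24, confidence 0.8, lift 0.8/0.38 = 2.105...
        PlantedDependency(("x1",), "y1", p_given=0.80, p_not_given=0.20),
        # P(Y) = 0.4*0.63 + 0.6*0.28 = 0.42, lift = 0.63/0.42 = 1.5 exactly
        PlantedDependency(("x2",), "y2", p_given=0.63, p_not_given=0.28),
        # independent: lift exactly 1
        PlantedDependency(("x3",), "y3", p_given=0.50, p_not_given=0.50),
    )
    return SyntheticSurveySpec(marginals=marginals, planted=planted, n=n)


# -- predication store -------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPredicationSpec:
    """Planted co-occurring term pairs in a sparse background of pairs.

    ``planted`` maps (subject, object) -> repeat count (>= 2, so planted
    pairs clear a count-2 threshold). The background fills the store up to
    ``n`` records: "unique" mints two fresh terms per record (every
    background term occurs exactly once, giving closed-form lifts for the
    planted pairs), "uniform" samples pairs uniformly from
    ``background_vocab``. ``semtypes`` assigns a semantic type per term;
    unlisted terms default to ``default_semtype``.
    """

    planted: Mapping[tuple[str, str], int]
    n: int
    semtypes: Mapping[str, str] = field(default_factory=dict)
    default_semtype: str = "fndg"
    background: Literal["unique", "uniform"] = "unique"
    background_vocab: tuple[str, ...] = ()
    negated_fraction: float = 0.0
    predicate: str = "ASSOCIATED_WITH"

    def __post_init__(self) -> None:
        total_planted = sum(self.planted.values())
        for pair, c in self.planted.items():
            if c < 2:
                raise ValueError(f"planted pair {pair} needs a repeat count >= 2")
        if total_planted > self.n:
            raise ValueError("planted records exceed the requested store size")
        if not 0.0 <= self.negated_fraction <= 1.0:
            raise ValueError("negated_fraction must be in [0, 1]")
        if self.background == "uniform" and len(self.background_vocab) < 2:
            raise ValueError("uniform background needs a vocabulary of >= 2 terms")


def generate_predications(
    spec: SyntheticPredicationSpec, seed: int
) -> list[PredicationRecord]:
    """Emit the planted pairs their stated number of times plus background."""
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    for (s, o), c in spec.planted.items():
        rows.extend([(s, o)] * c)
    n_bg = spec.n - len(rows)
    if spec.background == "unique":
        rows.extend((f"bgterm{i}a", f"bgterm{i}b") for i in range(n_bg))
    else:
        vocab = list(spec.background_vocab)
        for _ in range(n_bg):
            i, j = rng.choice(len(vocab), size=2, replace=False)
            rows.append((vocab[i], vocab[j]))

    negated = rng.random(spec.n) < spec.negated_fraction
    records = []
    for i, (s, o) in enumerate(rows):
        pred = f"NEG_{spec.predicate}" if negated[i] else spec.predicate
        records.append(
            PredicationRecord(
                subject=s,
                subject_semtype=spec.semtypes.get(s, spec.default_semtype),
                predicate=pred,
                object=o,
                object_semtype=spec.semtypes.get(o, spec.default_semtype),
                citation_id=f"PMID{i:07d}",
            )
        )
    return records


def default_predication_spec(n: int = 60) -> SyntheticPredicationSpec:
    """A 60-record store with three planted pairs among unique background.

    With unique background terms a pair planted k times has c(A) = c(B) =
    c(A,B) = k, so its pairwise lift is n*k/(k*k) = n/k: at n = 60 the
    planted repeat counts {3, 4, 5} give lifts {20, 15, 12}. Planting
    several pairs at distinct lifts keeps the mean-lift selection stage
    non-degenerate (under a strict mean threshold a lone rule can never
    exceed its own mean), and the top pair's count-3 / confidence-1 /
    lift-20 metrics are checkable by hand.
    """
    return SyntheticPredicationSpec(
        planted={
            ("Iron deficiency", "Anemia"): 3,
            ("Sedentary lifestyle", "Obesity"): 4,
            ("Malnutrition", "Atherosclerosis"): 5,
        },
        n=n,
        semtypes={
            "Iron deficiency": "fndg",
            "Anemia": "dsyn",
            "Sedentary lifestyle": "inbe",
            "Obesity": "dsyn",
            "Malnutrition": "fndg",
            "Atherosclerosis": "dsyn",
        },
    )
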