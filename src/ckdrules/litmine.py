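"""Literature-enrichment mining over semantic predications.

Semantic predications are subject-predicate-object triples extracted from
PubMed titles and abstracts (SemMedDB style), with each argument a UMLS
concept carrying a semantic-type code. The stage extracts the subgraph
adjacent to a set of seed disease concepts, filters terms by a semantic-type
whitelist and a generic-term blacklist, collapses each surviving triple to
the unordered term pair {subject, object} (the predicate's meaning is
deliberately ignored; negated NEG_* predications are kept by default since
the literature reports both signs for the same pair), and mines pairwise
rules with a minimum-occurrence count. Because a pair store is extremely
sparse, absolute support thresholds are corpus-size-dependent; thresholds
are therefore derived from ``min_count`` (a rule must be attested at least
twice by default). Selection keeps rules with lift > 1, then rules above
the mean lift of those, and finally rules touching at least one term of a
lifestyle-focused semantic type.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .arm_core import (
    AssociationRule,
    DegenerateInputError,
    MiningParams,
    apriori_mine,
    generate_rules,
)
from .rule_selection import SelectionReport
from .transactions import TransactionSet

__all__ = [
    "PredicationRecord",
    "SemanticFilterConfig",
    "load_predications",
    "filter_predications",
    "predications_to_transactions",
    "mine_pair_rules",
    "lifestyle_filter",
    "load_semantic_filter",
    "default_semantic_filter",
]

NEG_PREFIX = "NEG_"

PREDICATION_COLUMNS = (
    "subject",
    "subject_semtype",
    "predicate",
    "object",
    "object_semtype",
    "citation_id",
)


@dataclass(frozen=True)
class PredicationRecord:
    """One subject-predicate-object triple with semantic types."""

    subject: str
    subject_semtype: str
    predicate: str
    object: str
    object_semtype: str
    citation_id: str = ""

    def __post_init__(self) -> None:
        if not self.subject or not self.object:
            raise ValueError("subject and object must be non-empty")

    @property
    def negated(self) -> bool:
        return self.predicate.upper().startswith(NEG_PREFIX)


@dataclass(frozen=True)
class SemanticFilterConfig:
    """Whitelist/blacklist/focus semantic-type configuration.

    ``focus_semtypes`` (the lifestyle types, e.g. daily or recreational
    activity `dora`, food `food`, hazardous or poisonous substance `hops`,
    individual behavior `inbe`, mental or behavioral dysfunction `mobd`,
    finding `fndg`) must be a subset of the whitelist.
    """

    semtype_whitelist: frozenset[str]
    term_blacklist: frozenset[str] = frozenset()
    focus_semtypes: frozenset[str] = frozenset()
    keep_negated: bool = True

    def __post_init__(self) -> None:
        if not self.semtype_whitelist:
            raise ValueError("semtype whitelist must be non-empty")
        if not self.focus_semtypes <= self.semtype_whitelist:
            raise ValueError("focus_semtypes must be a subset of the whitelist")


def load_predications(path: str | Path) -> list[PredicationRecord]:
    """Read a predication CSV with the six standard columns."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PREDICATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"predication file missing columns: {missing}")
    return [
        PredicationRecord(
            subject=row.subject,
            subject_semtype=row.subject_semtype,
            predicate=row.predicate,
            object=row.object,
            object_semtype=row.object_semtype,
            citation_id=row.citation_id,
        )
        for row in df.itertuples()
    ]


def write_predications_csv(records: Sequence[PredicationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PREDICATION_COLUMNS)
        for r in records:
            w.writerow([r.subject, r.subject_semtype, r.predicate, r.object,
                        r.object_semtype, r.citation_id])


def filter_predications(
    records: Iterable[PredicationRecord],
    cfg: SemanticFilterConfig,
    seed_terms: Iterable[str] = (),
) -> list[PredicationRecord]:
    """Restrict to the disease subgraph and semantically admissible terms.

    Filter order (deterministic): (1) seed adjacency — keep records whose
    subject or object is a seed term (skipped when no seeds are given);
    (2) semantic-type whitelist on both arguments; (3) generic-term
    blacklist on both arguments; (4) drop negated records unless
    ``keep_negated``. Never increases the record count.
    """
    seeds = set(seed_terms)
    out = []
    for r in records:
        if seeds and r.subject not in seeds and r.object not in seeds:
            continue
        if r.subject_semtype not in cfg.semtype_whitelist:
            continue
        if r.object_semtype not in cfg.semtype_whitelist:
            continue
        if r.subject in cfg.term_blacklist or r.object in cfg.term_blacklist:
            continue
        if r.negated and not cfg.keep_negated:
            continue
        out.append(r)
    return out


def predications_to_transactions(records: Iterable[PredicationRecord]) -> TransactionSet:
    """Each triple becomes the two-item transaction {subject, object}.

    Self-loops (subject == object) are dropped; duplicate pairs are kept —
    repetition across citations is exactly what the count threshold uses.
    """
    pairs = [
        (r.subject, r.object) for r in records if r.subject != r.object
    ]
    return TransactionSet([{s, o} for s, o in pairs])


def mine_pair_rules(
    t: TransactionSet, min_count: int = 2
) -> tuple[list[AssociationRule], SelectionReport]:
    """Mine single-term pairwise rules attested at least ``min_count`` times.

    The support threshold is derived as ``min_count / n`` so the semantics
    are stable across corpus sizes. Selection keeps rules with lift > 1,
    then those above the mean lift of that set; the report records the
    derived lower bound and both stage counts.
    """
    if t.n == 0:
        raise DegenerateInputError("cannot mine an empty predication store")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    min_support = min_count / t.n
    params = MiningParams(min_support=min_support, min_confidence=0.0, max_len=2)
    frequent = apriori_mine(t, params)
    rules = generate_rules(frequent, t, params)
    rules = [r for r in rules if len(r.antecedent) == 1 and len(r.consequent) == 1]

    stage1 = [r for r in rules if r.lift > 1]
    if stage1:
        mean_lift = sum(r.lift for r in stage1) / len(stage1)
        final = [r for r in stage1 if r.lift > mean_lift]
    else:
        mean_lift, final = None, []
    report = SelectionReport(
        support_lower_bound=min_support,
        mean_support=None,
        n_input=len(rules),
        n_after_stage1=len(stage1),
        mean_lift=mean_lift,
        n_final=len(final),
    )
    return final, report


def lifestyle_filter(
    rules: Iterable[AssociationRule],
    cfg: SemanticFilterConfig,
    term_semtypes: Mapping[str, str],
) -> tuple[list[AssociationRule], list[str]]:
    """Keep rules with at least one term of a focus (lifestyle) semantic type.

    Also returns the deduplicated, sorted keyword list of focus-type terms
    appearing in the input rules. An unmapped term is an error naming it.
    """
    kept = []
    keywords: set[str] = set()
    for r in rules:
        focus_terms = []
        for term in r.items:
            if term not in term_semtypes:
                raise KeyError(f"term {term!r} has no semantic-type mapping")
            if term_semtypes[term] in cfg.focus_semtypes:
                focus_terms.append(term)
        if focus_terms:
            kept.append(r)
            keywords.update(focus_terms)
    return kept, sorted(keywords)


def load_semantic_filter(path: str | Path) -> SemanticFilterConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SemanticFilterConfig(
        semtype_whitelist=frozenset(doc["semtype_whitelist"]),
        term_blacklist=frozenset(doc.get("term_blacklist", [])),
        focus_semtypes=frozenset(doc.get("focus_semtypes", [])),
        keep_negated=bool(doc.get("keep_negated", True)),
    )


def default_semantic_filter() -> SemanticFilterConfig:
    """Bundled filter config seeded with the standard focus types and
    well-known generic terms; users extend it for a full corpus."""
    from importlib.resources import files

    return load_semantic_filter(files("ckdrules.data") / "semantic_filter.yaml")
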