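"""Two-stage adaptive rule selection and comorbidity-focused ranking.

Mining a dense survey cohort at a low support bound yields thousands of
rules; rather than fixing absolute cut-offs, selection adapts to the rule
population itself:

* stage 1 keeps rules whose support exceeds the mean support of all mined
  rules and whose lift exceeds 1;
* stage 2 keeps, from the stage-1 survivors, rules whose lift exceeds the
  mean lift of those survivors.

Both comparisons are strict by default ("larger than" semantics), with an
inclusive variant behind a flag. The report records every threshold that
was actually applied so a run can be audited.

``subset_by_keywords`` and ``top_k_by_lift`` then pull out the rules that
mention a given comorbidity (on either side of the implication) and rank
them by lift with a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Sequence

from .arm_core import AssociationRule

__all__ = [
    "SelectionReport",
    "CohortKeywordSpec",
    "two_stage_select",
    "subset_by_keywords",
    "top_k_by_lift",
]


@dataclass(frozen=True)
class SelectionReport:
    """Thresholds and counts produced by a two-stage selection run.

    ``mean_support`` is None when stage 1 did not use a support-mean
    threshold (the literature miner gates stage 1 on lift > 1 alone).
    """

    support_lower_bound: float | None
    mean_support: float | None
    n_input: int
    n_after_stage1: int
    mean_lift: float | None
    n_final: int

    def to_dict(self) -> dict:
        return {
            "support_lower_bound": self.support_lower_bound,
            "mean_support": self.mean_support,
            "n_input": self.n_input,
            "n_after_stage1": self.n_after_stage1,
            "mean_lift": self.mean_lift,
            "n_final": self.n_final,
        }


@dataclass(frozen=True)
class CohortKeywordSpec:
    """A comorbid condition and the variable codes that flag it."""

    condition: str
    keywords: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"condition {self.condition!r} needs at least one keyword")


def two_stage_select(
    rules: Sequence[AssociationRule],
    *,
    inclusive: bool = False,
    lift_gate_before_support_mean: bool = False,
    support_lower_bound: float | None = None,
) -> tuple[list[AssociationRule], SelectionReport]:
    """Apply the adaptive mean-support / mean-lift selection.

    Parameters
    ----------
    rules:
        All mined rules (already past any mining support lower bound).
    inclusive:
        Use >= instead of the default strict > at both mean thresholds.
    lift_gate_before_support_mean:
        If True, the stage-1 support mean is computed only over rules with
        lift > 1 rather than over all input rules. The two orderings differ
        only in which population defines the support mean; the default
        computes it over all input rules.
    support_lower_bound:
        Recorded in the report for auditability (the bound applied upstream
        at mining time); not re-applied here.

    Returns the selected rules (input order preserved) and a report of the
    thresholds and counts. An empty stage-1 set yields an empty selection,
    not an error.
    """
    if not rules:
        raise ValueError("two_stage_select requires a non-empty rule collection")

    def above(x: float, thr: float) -> bool:
        return x >= thr if inclusive else x > thr

    pool = [r for r in rules if r.lift > 1] if lift_gate_before_support_mean else rules
    if not pool:
        report = SelectionReport(support_lower_bound, None, len(rules), 0, None, 0)
        return [], report
    mean_support = fmean(r.support for r in pool)

    stage1 = [r for r in rules if above(r.support, mean_support) and r.lift > 1]
    if not stage1:
        report = SelectionReport(
            support_lower_bound, mean_support, len(rules), 0, None, 0
        )
        return [], report

    mean_lift = fmean(r.lift for r in stage1)
    final = [r for r in stage1 if above(r.lift, mean_lift)]
    report = SelectionReport(
        support_lower_bound=support_lower_bound,
        mean_support=mean_support,
        n_input=len(rules),
        n_after_stage1=len(stage1),
        mean_lift=mean_lift,
        n_final=len(final),
    )
    return final, report


def subset_by_keywords(
    rules: Iterable[AssociationRule], spec: CohortKeywordSpec
) -> list[AssociationRule]:
    """Rules mentioning any keyword on either side of the implication."""
    kw = set(spec.keywords)
    return [r for r in rules if kw & r.items]


def top_k_by_lift(rules: Iterable[AssociationRule], k: int = 10) -> list[AssociationRule]:
    """Top-k rules by lift with a deterministic tie-break.

    Ordering is (lift descending, count descending, rule string ascending),
    so the result is a pure function of the rule multiset regardless of
    input order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(rules, key=lambda r: (-r.lift, -r.count, r.rule_str()))
    return ranked[:k]
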