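"""Spearman correlation of risk-factor indicators against conditions.

Builds a 0/1 indicator matrix over the cohort — risk-factor variables,
condition variables, and derived conjunction columns such as disease
co-occurrence (e.g. CKD together with cardiovascular disease) — and computes
Spearman rank correlations with average-rank tie handling for every
(factor, condition) pair. For binary columns Spearman rho coincides with
the Pearson correlation of the 0/1 values (the phi coefficient). Constant
columns make the correlation undefined; such pairs are reported explicitly
rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transactions import TransactionSet

__all__ = [
    "CorrelationResult",
    "build_indicator_matrix",
    "spearman_matrix",
    "conjunction_name",
]


def conjunction_name(a: str, b: str) -> str:
    return f"{a}&{b}"


def build_indicator_matrix(
    t: TransactionSet,
    factor_codes: Sequence[str],
    condition_codes: Sequence[str],
    conjunctions: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Binary indicator DataFrame: factors, conditions, then conjunctions.

    An entry is 1 iff the code is in the respondent's transaction; a
    conjunction column is the elementwise AND of its two parent condition
    columns.
    """
    codes = list(factor_codes) + [c for c in condition_codes if c not in factor_codes]
    unknown = [c for c in codes if c not in t.catalog]
    if unknown:
        raise KeyError(f"codes not in catalog: {unknown}")
    cond_set = set(condition_codes)
    for a, b in conjunctions:
        if a not in cond_set or b not in cond_set:
            raise KeyError(f"conjunction parents ({a!r}, {b!r}) must be condition codes")

    data = {
        c: np.fromiter((int(c in tx) for tx in t.transactions), dtype=np.int8, count=t.n)
        for c in codes
    }
    df = pd.DataFrame(data)
    for a, b in conjunctions:
        df[conjunction_name(a, b)] = df[a] & df[b]
    if df.columns.duplicated().any():
        raise ValueError("duplicate column names in indicator matrix")
    return df


@dataclass
class CorrelationResult:
    """Factor x condition grids of Spearman rho and p, plus undefined pairs."""

    rho: pd.DataFrame
    p: pd.DataFrame
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.rho.index:
            for c in self.rho.columns:
                rows.append((f, c, self.rho.at[f, c], self.p.at[f, c]))
        return pd.DataFrame(rows, columns=["factor", "condition", "rho", "p"])

    def heatmap(self, ax=None):
        """Convenience rendering of the rho grid (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(
                figsize=(1 + 0.5 * len(self.rho.columns), 1 + 0.35 * len(self.rho))
            )
        im = ax.imshow(self.rho.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(self.rho.columns)), self.rho.columns, rotation=90)
        ax.set_yticks(range(len(self.rho)), self.rho.index)
        ax.figure.colorbar(im, ax=ax, label="Spearman rho")
        return ax


def spearman_matrix(
    m: pd.DataFrame, factors: Sequence[str], conditions: Sequence[str]
) -> CorrelationResult:
    """Spearman rho (average-rank ties) for every factor x condition pair.

    Requires at least 3 rows. A pair involving a constant column gets an
    explicit NaN entry and is listed in ``undefined``; NaN never leaks from
    one pair into another.
    """
    if len(m) < 3:
        raise ValueError("need at least 3 observations for a rank correlation")
    missing = [c for c in list(factors) + list(conditions) if c not in m.columns]
    if missing:
        raise KeyError(f"columns not in indicator matrix: {missing}")

    rho = pd.DataFrame(index=list(factors), columns=list(conditions), dtype=float)
    pval = pd.DataFrame(index=list(factors), columns=list(conditions), dtype=float)
    undefined: list[tuple[str, str]] = []
    constant = {c for c in m.columns if m[c].nunique() <= 1}
    for f in factors:
        for c in conditions:
            if f in constant or c in constant:
                rho.at[f, c] = np.nan
                pval.at[f, c] = np.nan
                undefined.append((f, c))
                continue
            res = stats.spearmanr(m[f], m[c])
            rho.at[f, c] = res.statistic
            pval.at[f, c] = res.pvalue
    return CorrelationResult(rho=rho, p=pval, undefined=undefined)
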