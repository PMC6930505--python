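"""Survey table reading and binary transaction encoding.

BRFSS-style survey tables arrive as CSV (column headers = variable codes)
or SAS Transport (XPT). Each selected variable carries an annotation rule
mapping raw response codes to 1 (condition/behavior present), 0 (absent:
"no", "don't know", "refused"), or missing. A respondent's transaction is
the set of variable codes annotated 1; respondents with missing data on any
selected variable are excluded outright so absence of an item always means
"answered no", never "not asked".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
import yaml

from .transactions import TransactionSet

__all__ = [
    "VariableSpec",
    "RawSurveyTable",
    "ExclusionLog",
    "read_survey_table",
    "encode_transactions",
    "select_cohort",
    "load_variable_specs",
    "default_variable_specs",
    "write_transactions_csv",
    "read_transactions_csv",
]


class SurveyFormatError(ValueError):
    """Malformed survey file (e.g. duplicate column codes)."""


class ResponseCodeError(ValueError):
    """A raw response code not covered by its variable's annotation rule."""


@dataclass(frozen=True)
class VariableSpec:
    """Annotation rule for one survey variable.

    ``positive_values`` are annotated 1, ``negative_values`` 0, and
    ``missing_values`` mark absent data; the three sets must be disjoint.
    Raw codes are compared as strings (raw survey codes are never coerced).
    """

    code: str
    label: str = ""
    positive_values: frozenset[str] = frozenset({"1"})
    negative_values: frozenset[str] = frozenset({"2", "7", "9"})
    missing_values: frozenset[str] = frozenset({""})

    def __post_init__(self) -> None:
        p, n, m = self.positive_values, self.negative_values, self.missing_values
        if p & n or p & m or n & m:
            raise ValueError(
                f"variable {self.code!r}: positive/negative/missing value sets overlap"
            )

    def annotate(self, raw: str) -> int | None:
        """1 / 0 / None for a raw response; raises on an uncovered code."""
        if raw in self.positive_values:
            return 1
        if raw in self.negative_values:
            return 0
        if raw in self.missing_values:
            return None
        raise ResponseCodeError(
            f"variable {self.code!r}: response code {raw!r} is not covered by "
            "the positive/negative/missing sets"
        )


class RawSurveyTable:
    """Raw survey rows with response codes preserved verbatim as strings."""

    def __init__(self, df: pd.DataFrame) -> None:
        dupes = df.columns[df.columns.duplicated()].tolist()
        if dupes:
            raise SurveyFormatError(f"duplicate variable codes: {sorted(set(dupes))}")
        self.df = df.astype(str)

    @property
    def catalog(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ExclusionLog:
    """Records dropped for missing data, with the variable that triggered it."""

    excluded: list[tuple[object, str]] = field(default_factory=list)

    @property
    def excluded_record_ids(self) -> list[object]:
        return [rid for rid, _ in self.excluded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["record_id", "missing_variable"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_survey_table(
    path: str | Path, format: Literal["csv", "sas-transport"] = "csv"
) -> RawSurveyTable:
    """Read a survey table, preserving raw response codes verbatim.

    CSV headers are variable codes; a repeated header is a format error.
    SAS Transport files are read via pandas and their values rendered as
    strings (numeric codes lose any trailing ``.0``).
    """
    path = Path(path)
    if format == "csv":
        with open(path, newline="") as fh:
            header = next(csv.reader(fh), None)
        if header is None:
            return RawSurveyTable(pd.DataFrame())
        seen, dupes = set(), []
        for col in header:
            if col in seen:
                dupes.append(col)
            seen.add(col)
        if dupes:
            raise SurveyFormatError(f"duplicate variable codes: {sorted(set(dupes))}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif format == "sas-transport":
        df = pd.read_sas(path, format="xport")
        df = df.map(_render_sas_value)
    else:
        raise ValueError(f"unknown format {format!r}")
    return RawSurveyTable(df)


def _render_sas_value(v: object) -> str:
    if v is None or (isinstance(v, float) and v != v):  # NaN
        return ""
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, float) and v == int(v):
        return str(int(v))
    return str(v)


def encode_transactions(
    raw: RawSurveyTable,
    specs: Sequence[VariableSpec],
    missing_policy: Literal["exclude-record", "skip-variable"] = "exclude-record",
) -> tuple[TransactionSet, ExclusionLog]:
    """Binary-encode the survey into transactions plus an exclusion log.

    A retained record becomes the set of spec codes whose response is in
    ``positive_values``. Under the default complete-case policy, a record
    missing on *any* spec-covered variable is excluded entirely;
    ``skip-variable`` instead drops only the missing item from that record.
    Retained transactions plus exclusions always partition the input rows.
    """
    codes = [s.code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate codes in variable specs")
    absent = [c for c in codes if c not in raw.df.columns]
    if absent:
        raise KeyError(f"spec codes missing from survey table: {absent}")

    spec_by_code = {s.code: s for s in specs}
    transactions: list[frozenset[str]] = []
    log = ExclusionLog()
    columns = {c: raw.df[c].tolist() for c in codes}
    index = raw.df.index.tolist()
    for i, rid in enumerate(index):
        items = []
        missing_on: str | None = None
        for c in codes:
            ann = spec_by_code[c].annotate(columns[c][i])
            if ann is None:
                missing_on = c
                if missing_policy == "exclude-record":
                    break
            elif ann == 1:
                items.append(c)
        if missing_policy == "exclude-record" and missing_on is not None:
            log.excluded.append((rid, missing_on))
        else:
            transactions.append(frozenset(items))
    return TransactionSet(transactions, catalog=codes), log


def select_cohort(
    raw: RawSurveyTable, condition_code: str, specs: Sequence[VariableSpec]
) -> RawSurveyTable:
    """Rows whose condition variable is positively annotated, order preserved."""
    spec = next((s for s in specs if s.code == condition_code), None)
    if spec is None:
        raise KeyError(f"no variable spec for condition code {condition_code!r}")
    if condition_code not in raw.df.columns:
        raise KeyError(f"condition code {condition_code!r} not in survey table")
    mask = raw.df[condition_code].isin(spec.positive_values)
    return RawSurveyTable(raw.df[mask])


# -- variable-spec config ----------------------------------------------------

def load_variable_specs(path: str | Path) -> list[VariableSpec]:
    """Load variable specs from YAML: a list of {code, label, positive, negative, missing}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["variables"] if isinstance(doc, dict) else doc
    specs = []
    for e in entries:
        specs.append(
            VariableSpec(
                code=e["code"],
                label=e.get("label", ""),
                positive_values=frozenset(str(v) for v in e.get("positive", ["1"])),
                negative_values=frozenset(str(v) for v in e.get("negative", ["2", "7", "9"])),
                missing_values=frozenset(str(v) for v in e.get("missing", [""])),
            )
        )
    codes = [s.code for s in specs]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate variable codes in spec file")
    return specs


def default_variable_specs() -> list[VariableSpec]:
    """The bundled variable specs (condition + comorbidity + behavior codes)."""
    from importlib.resources import files

    return load_variable_specs(files("ckdrules.data") / "variable_specs.yaml")


# -- transaction CSV round-trip ----------------------------------------------

def write_transactions_csv(t: TransactionSet, path: str | Path) -> None:
    """One row per respondent: record index and comma-joined sorted items."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record", "items"])
        for i, tx in enumerate(t.transactions):
            w.writerow([i, ",".join(sorted(tx))])


def read_transactions_csv(path: str | Path, catalog: Iterable[str] | None = None) -> TransactionSet:
    with open(path, newline="") as fh:
        r = csv.reader(fh)
        header = next(r)
        if header[:2] != ["record", "items"]:
            raise SurveyFormatError("expected header: record,items")
        txs = [[s for s in row[1].split(",") if s] for row in r]
    return TransactionSet(txs, catalog=catalog)
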