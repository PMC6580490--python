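"""CSV formats: rule tables in, effects tables out.

Rule-mining packages print one row per rule with at least lift, support and
confidence columns; column names differ per package, so the reader takes a
column map rather than assuming a dialect.  Rows that violate the
index-triple constraints are collected into a rejects report with reasons —
never silently dropped — because a confidence above 1 or a support above
confidence usually signals a mis-mapped column.

The effects writer emits one row per rule with the indices, prevalences,
converted RR/OR, and (when known) the reconstructed or observed cell
counts.  Stored values are full precision and round-trip through the
reader; ``display_dp`` is a presentation-only rounding for eyeballing
against published two-decimal tables.  Infinite estimates are rendered as
``Inf``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import LiftRRError
from .miner import Rule
from .tables import ContingencyTable, EffectEstimates, IndexSet

__all__ = [
    "RuleRow",
    "RejectedRow",
    "EffectRecord",
    "read_rule_table",
    "write_effects_table",
    "significant_digits",
]

#: canonical column names of a rule table; a column map renames file columns
#: onto these.
CANONICAL_COLUMNS = ("lift", "support", "confidence")
OPTIONAL_COLUMNS = ("n", "rule_id")


@dataclass(frozen=True)
class RuleRow:
    """One successfully parsed rule-table row."""

    rule_id: str
    indices: IndexSet
    #: fewest significant digits among the three parsed index strings;
    #: three or fewer means converted estimates will carry rounding drift
    min_sig_digits: int


@dataclass(frozen=True)
class RejectedRow:
    """One rule-table row that failed validation, with the reason."""

    rule_id: str
    row_number: int
    reason: str


@dataclass(frozen=True)
class EffectRecord:
    """One output row of an effects table."""

    rule_id: str
    indices: IndexSet
    effects: EffectEstimates
    antecedents: Optional[tuple[str, ...]] = None
    table: Optional[ContingencyTable] = None
    p_value: Optional[float] = None

    @classmethod
    def from_rule(cls, rule: Rule, rule_id: Optional[str] = None) -> "EffectRecord":
        return cls(
            rule_id=rule_id if rule_id is not None else " & ".join(rule.antecedents),
            indices=rule.indices,
            effects=rule.effects,
            antecedents=rule.antecedents,
            table=rule.table,
            p_value=rule.p_value,
        )


_SIG_RE = re.compile(r"^\s*[+-]?0*(\d*)\.?(\d*?)0*(?:[eE][+-]?\d+)?\s*$")


def significant_digits(text: str) -> int:
    """Count significant digits in a decimal string (e.g. ``"1.22"`` -> 3).

    Leading zeros never count; trailing zeros after the decimal point do
    count (they were printed deliberately).  Returns a large number for
    strings that are not plain decimals, so the caller's low-precision
    warning stays quiet.
    """
    m = re.match(r"^\s*[+-]?(\d*)\.?(\d*)(?:[eE][+-]?\d+)?\s*$", text)
    if not m or (not m.group(1) and not m.group(2)):
        return 99
    digits = (m.group(1) + m.group(2)).lstrip("0")
    return len(digits) if digits else 1


def read_rule_table(
    path,
    column_map: Optional[dict[str, str]] = None,
    n_total: Optional[int] = None,
) -> tuple[list[RuleRow], list[RejectedRow]]:
    """Read a rule-mining output CSV into validated index triples.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Mapping from canonical names (``lift``, ``support``, ``confidence``,
        optionally ``n`` and ``rule_id``) to the file's column names, for
        files using another package's dialect; canonical names present in
        the file are picked up without a map.
    n_total
        Cohort size applied to every row when the file has no ``n`` column;
        a per-row ``n`` column wins over this.

    Returns
    -------
    (rows, rejects)
        Parsed rows, and a reject report (row number, reason) for every row
        whose numbers were unparseable or violated the index constraints.

    Raises
    ------
    LiftRRError
        If the file is empty or a mapped column is missing entirely.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise LiftRRError(f"rule table {path} is empty") from None
    if df.empty:
        raise LiftRRError(f"rule table {path} has a header but no rows")

    colmap = {name: name for name in CANONICAL_COLUMNS + OPTIONAL_COLUMNS}
    if column_map:
        unknown = set(column_map) - set(colmap)
        if unknown:
            raise LiftRRError(
                f"column map refers to unknown canonical names: {sorted(unknown)}"
            )
        colmap.update(column_map)
    missing = [colmap[name] for name in CANONICAL_COLUMNS if colmap[name] not in df.columns]
    if missing:
        raise LiftRRError(f"rule table {path} is missing columns: {missing}")

    has_n = colmap["n"] in df.columns
    has_id = colmap["rule_id"] in df.columns
    rows: list[RuleRow] = []
    rejects: list[RejectedRow] = []
    for i, rec in enumerate(df.to_dict("records")):
        rule_id = str(rec[colmap["rule_id"]]) if has_id else f"rule_{i + 1}"
        try:
            raw = {name: str(rec[colmap[name]]) for name in CANONICAL_COLUMNS}
            values = {}
            for name, text in raw.items():
                try:
                    values[name] = float(text)
                except ValueError:
                    raise LiftRRError(f"column {name!r}: unparseable number {text!r}")
            if has_n and not _is_missing(rec[colmap["n"]]):
                n_row: Optional[int] = int(float(rec[colmap["n"]]))
            else:
                n_row = n_total
            idx = IndexSet(
                support=values["support"],
                confidence=values["confidence"],
                lift=values["lift"],
                n_total=n_row,
            )
        except LiftRRError as exc:
            rejects.append(RejectedRow(rule_id=rule_id, row_number=i + 1, reason=str(exc)))
            continue
        sig = min(significant_digits(text) for text in raw.values())
        rows.append(RuleRow(rule_id=rule_id, indices=idx, min_sig_digits=sig))
    return rows, rejects


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


def _fmt(value: Optional[float], dp: Optional[int]) -> str:
    if value is None:
        return ""
    if math.isinf(value):
        return "Inf"
    if dp is not None:
        return f"{value:.{dp}f}"
    return repr(float(value))


def write_effects_table(
    records: Sequence[Union[EffectRecord, Rule]],
    path,
    display_dp: Optional[int] = None,
) -> pd.DataFrame:
    """Write an effects table CSV; returns the frame that was written.

    Columns: ``rule_id, antecedents, n, a, b, c, d, support, confidence,
    lift, p_exposure, p_outcome, rr, or, p_value``; count and p-value
    columns are blank when unknown.  ``display_dp`` rounds the real-valued
    columns for display; omit it for full-precision values that round-trip
    through :func:`read_rule_table`.

    Raises
    ------
    LiftRRError
        On an empty record list.
    """
    if not records:
        raise LiftRRError("refusing to write an empty effects table")
    out = []
    for rec in records:
        if isinstance(rec, Rule):
            rec = EffectRecord.from_rule(rec)
        t = rec.table
        row = {
            "rule_id": rec.rule_id,
            "antecedents": " & ".join(rec.antecedents) if rec.antecedents else "",
            "n": rec.indices.n_total if rec.indices.n_total is not None else "",
            "a": t.a if t else "",
            "b": t.b if t else "",
            "c": t.c if t else "",
            "d": t.d if t else "",
            "support": _fmt(float(rec.indices.support), display_dp),
            "confidence": _fmt(float(rec.indices.confidence), display_dp),
            "lift": _fmt(float(rec.indices.lift), display_dp),
            "p_exposure": _fmt(rec.effects.p_exposure, display_dp),
            "p_outcome": _fmt(rec.effects.p_outcome, display_dp),
            "rr": _fmt(rec.effects.rr, display_dp),
            "or": _fmt(rec.effects.or_, display_dp),
            "p_value": _fmt(rec.p_value, None) if rec.p_value is not None else "",
        }
        out.append(row)
    frame = pd.DataFrame(out)
    frame.to_csv(path, index=False)
    return frame
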