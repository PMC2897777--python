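"""Aggregation of two-vector expression/solubility outcomes.

Per-target per-vector statuses (soluble / insoluble / no_expression /
no_clone / not_screened) are tabulated by domain of life and vector, a
combined per-target column takes the best outcome across the two vectors
(soluble > insoluble > no_expression > no_clone), and percentage rows use
the full target count as denominator with integer rounding half away from
zero.  A pipeline "funnel" reports stage-to-stage efficiencies
(e.g. selected -> amplified -> cloned -> expressed -> soluble).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .sequence_model import TargetGene

__all__ = [
    "ScreeningRecord",
    "SummaryTable",
    "STATUS_PRECEDENCE",
    "VECTOR_NAMES",
    "combine_vectors",
    "integer_percent",
    "tabulate",
    "funnel",
    "read_screening_tsv",
    "write_screening_tsv",
]

VECTOR_NAMES = ("pFO4", "pGEX-4T-1")
#: best-outcome precedence for the combined column
STATUS_PRECEDENCE = ("soluble", "insoluble", "no_expression", "no_clone")
STATUSES = STATUS_PRECEDENCE + ("not_screened",)


@dataclass(frozen=True)
class ScreeningRecord:
    target_id: str
    vector: str
    status: str

    def __post_init__(self) -> None:
        if self.vector not in VECTOR_NAMES:
            raise ValueError(f"unknown vector {self.vector!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def combine_vectors(records: list[ScreeningRecord]) -> str:
    """Best outcome for one target across its two vector records.

    soluble in either vector wins; else insoluble; else no_expression when a
    clone existed but nothing was expressed; else no_clone.
    """
    if not records:
        raise ValueError("no records for target")
    statuses = {r.status for r in records}
    for status in STATUS_PRECEDENCE[:3]:
        if status in statuses:
            return status
    return "no_clone"


def integer_percent(count: int, total: int) -> int:
    """round(100 * count / total) with halves rounded away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0:
        return -integer_percent(-count, total)
    return (200 * count + total) // (2 * total)


@dataclass
class SummaryTable:
    """Count and percentage tables plus per-target combined statuses.

    ``counts``: rows = statuses, columns = (domain, vector) plus
    ("Total", vector) and ("Total", "combined").  ``percentages``: the
    soluble and soluble+insoluble rows over the same columns, denominator =
    total target count.
    """

    counts: pd.DataFrame
    percentages: pd.DataFrame
    combined: dict[str, str]
    total_targets: int


def tabulate(records: list[ScreeningRecord], targets: list[TargetGene]) -> SummaryTable:
    """Stratify screening records by domain of life and vector.

    Every record's target must be in ``targets``; targets without a record
    for a vector count as not_screened there.
    """
    domain_of = {t.id: t.domain_of_life for t in targets}
    for r in records:
        if r.target_id not in domain_of:
            raise ValueError(f"screening record for unknown target {r.target_id!r}")

    by_target: dict[str, dict[str, str]] = {t.id: {} for t in targets}
    for r in records:
        if r.vector in by_target[r.target_id]:
            raise ValueError(f"duplicate record for ({r.target_id}, {r.vector})")
        by_target[r.target_id][r.vector] = r.status

    total = len(targets)
    domains = [d for d in ("eukarya", "bacteria", "archaea", "virus")
               if any(t.domain_of_life == d for t in targets)]

    columns = [(d, v) for d in domains for v in VECTOR_NAMES]
    columns += [("Total", v) for v in VECTOR_NAMES] + [("Total", "combined")]
    counts = pd.DataFrame(
        0, index=list(STATUSES),
        columns=pd.MultiIndex.from_tuples(columns, names=["domain", "vector"]),
    )

    combined: dict[str, str] = {}
    for tid, vec_statuses in by_target.items():
        d = domain_of[tid]
        recs = []
        for v in VECTOR_NAMES:
            status = vec_statuses.get(v, "not_screened")
            counts.loc[status, (d, v)] += 1
            counts.loc[status, ("Total", v)] += 1
            recs.append(ScreeningRecord(tid, v, status))
        c = combine_vectors(recs)
        combined[tid] = c
        counts.loc[c, ("Total", "combined")] += 1

    soluble = counts.loc["soluble"]
    sol_insol = counts.loc["soluble"] + counts.loc["insoluble"]
    percentages = pd.DataFrame(
        {
            col: {
                "percentage of soluble proteins": integer_percent(int(soluble[col]), total),
                "percentage of soluble + insoluble proteins": integer_percent(int(sol_insol[col]), total),
            }
            for col in counts.columns
        }
    )
    percentages.columns = counts.columns
    return SummaryTable(counts=counts, percentages=percentages, combined=combined,
                        total_targets=total)


def funnel(stage_counts: dict[str, int]) -> pd.DataFrame:
    """Stage counts with integer stage-to-stage efficiencies.

    For each consecutive stage pair the later count is expressed as an
    integer percent of the earlier.  Counts are expected non-increasing;
    a violation warns but does not fail.
    """
    if not stage_counts:
        raise ValueError("empty stage mapping")
    stages = list(stage_counts.items())
    rows = []
    prev = None
    for name, count in stages:
        if prev is not None and count > prev[1]:
            warnings.warn(f"funnel stage {name!r} ({count}) exceeds {prev[0]!r} ({prev[1]})",
                          stacklevel=2)
        rows.append(
            {
                "stage": name,
                "count": count,
                "percent_of_previous": integer_percent(count, prev[1]) if prev else None,
            }
        )
        prev = (name, count)
    return pd.DataFrame(rows)


def read_screening_tsv(path) -> list[ScreeningRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [ScreeningRecord(r.target_id, r.vector, r.status) for r in df.itertuples()]


def write_screening_tsv(records: list[ScreeningRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
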