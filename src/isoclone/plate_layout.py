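"""96-well cloning-plate and 24-well expression-plate bookkeeping.

Targets are filled row-major (A1, A2, ... A12, B1, ...), optionally grouped
by cloning strategy so that wells sharing a digestion mix are contiguous;
a new plate is opened when the current one is full.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PlateAssignment", "PLATE_FORMATS", "well_labels", "assign_wells", "picklist", "render_plate_map"]

#: rows x columns per supported format
PLATE_FORMATS = {96: ("ABCDEFGH", 12), 24: ("ABCD", 6)}


def well_labels(plate_format: int) -> list[str]:
    """Row-major well labels for a plate format (A1 ... H12 for 96)."""
    rows, ncol = PLATE_FORMATS[plate_format]
    return [f"{r}{c}" for r in rows for c in range(1, ncol + 1)]


@dataclass(frozen=True)
class PlateAssignment:
    plate_id: str
    well: str
    target_id: str
    group_key: str = ""


def assign_wells(
    target_ids: list[str],
    plate_format: int = 96,
    group_by_strategy: bool = True,
    strategies: dict[str, str] | None = None,
    plate_prefix: str = "plate",
) -> list[PlateAssignment]:
    """Array targets into plates, deterministically for a given input order.

    With grouping on, targets are sorted by (strategy label, input order) so
    each enzyme-pair group occupies contiguous wells; without grouping the
    input order is kept.
    """
    if not target_ids:
        raise ValueError("no targets to array")
    strategies = strategies or {}
    order = list(enumerate(target_ids))
    if group_by_strategy:
        order.sort(key=lambda it: (strategies.get(it[1], ""), it[0]))

    labels = well_labels(plate_format)
    assignments = []
    for n, (_, tid) in enumerate(order):
        plate, idx = divmod(n, len(labels))
        assignments.append(
            PlateAssignment(
                plate_id=f"{plate_prefix}_{plate + 1}",
                well=labels[idx],
                target_id=tid,
                group_key=strategies.get(tid, ""),
            )
        )
    return assignments


def picklist(assignments: list[PlateAssignment]):
    """Picklist DataFrame sorted by plate then row-major well."""
    import pandas as pd

    if any(a.well not in well_labels(96) + well_labels(24) for a in assignments):
        raise ValueError("invalid well label in assignments")

    def well_key(well: str) -> tuple[str, int]:
        return (well[0], int(well[1:]))

    rows = sorted(assignments, key=lambda a: (a.plate_id, well_key(a.well)))
    return pd.DataFrame(
        [
            {"plate": a.plate_id, "well": a.well, "target": a.target_id, "group": a.group_key}
            for a in rows
        ]
    )


def render_plate_map(assignments: list[PlateAssignment], plate_id: str, plate_format: int = 96) -> str:
    """Plain-text grid rendering of one plate."""
    rows, ncol = PLATE_FORMATS[plate_format]
    by_well = {a.well: a.target_id for a in assignments if a.plate_id == plate_id}
    width = max([len(v) for v in by_well.values()] + [4]) + 1
    lines = [plate_id, "   " + "".join(f"{c:<{width}}" for c in range(1, ncol + 1))]
    for r in rows:
        lines.append(
            f"{r}  " + "".join(f"{by_well.get(f'{r}{c}', '.'):<{width}}" for c in range(1, ncol + 1))
        )
    return "\n".join(lines)
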