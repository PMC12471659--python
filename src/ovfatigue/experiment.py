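"""Packaged chewing-simulation outcome record and specimen-table I/O.

The in vitro record: 72 occlusal veneers (two ceramics × three thicknesses
× 12 specimens) fatigued at 49 N / 1.6 Hz for 1.2 million cycles with
5–55 °C thermocycling. Six of the twelve 0.5 mm zirconia veneers (group
Z-0.5) developed flexural radial cracks at the cycle counts below; every
other specimen survived the protocol and is right-censored at 1.2 × 10⁶
cycles. Radial cracking is the failure event; wear facets are not, and no
specimen fractured completely or debonded.

Cycle counts are attributed to sequential specimen IDs in ascending order;
only the multiset of six counts is authoritative, not the mapping to
physical specimens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .params import FatigueProtocol

__all__ = [
    "Z05_FAILURE_CYCLES",
    "CSV_COLUMNS",
    "OUTCOME_FAILED",
    "OUTCOME_INTACT",
    "GroupSummary",
    "load_packaged_experiment",
    "read_specimen_csv",
    "write_specimen_csv",
    "validate_specimen_table",
    "summarize_group",
    "summarize_all_groups",
]

#: Cycle counts at radial-crack detection for the six failed Z-0.5 specimens.
Z05_FAILURE_CYCLES: tuple[int, ...] = (95_107, 95_296, 381_053, 630_042, 656_903, 840_513)

CSV_COLUMNS = ["specimen_id", "group_id", "material", "thickness_mm", "outcome", "cycles"]
OUTCOME_FAILED = "radial_crack"
OUTCOME_INTACT = "intact"
_VALID_OUTCOMES = frozenset({OUTCOME_FAILED, OUTCOME_INTACT})

_GROUPS = [
    ("LD", "lithium_disilicate", 0.5),
    ("LD", "lithium_disilicate", 1.0),
    ("LD", "lithium_disilicate", 1.5),
    ("Z", "zirconia_5y", 0.5),
    ("Z", "zirconia_5y", 1.0),
    ("Z", "zirconia_5y", 1.5),
]
_SPECIMENS_PER_GROUP = 12


@dataclass(frozen=True)
class GroupSummary:
    group_id: str
    n_specimens: int
    n_failed: int
    failure_fraction: float
    min_cycles: int
    max_cycles: int
    geometric_mean_cycles: float | None  # over failed specimens; None if none failed


def load_packaged_experiment(
    protocol: FatigueProtocol | None = None,
) -> pd.DataFrame:
    """The full 72-specimen outcome table as a DataFrame in the canonical
    CSV schema (one row per specimen)."""
    protocol = protocol or FatigueProtocol()
    rows = []
    for code, material, thickness in _GROUPS:
        group_id = f"{code}-{thickness:.1f}"
        failures = list(Z05_FAILURE_CYCLES) if group_id == "Z-0.5" else []
        for i in range(1, _SPECIMENS_PER_GROUP + 1):
            if i <= len(failures):
                outcome, cycles = OUTCOME_FAILED, failures[i - 1]
            else:
                outcome, cycles = OUTCOME_INTACT, protocol.total_cycles
            rows.append(
                {
                    "specimen_id": f"{group_id}-{i:02d}",
                    "group_id": group_id,
                    "material": material,
                    "thickness_mm": thickness,
                    "outcome": outcome,
                    "cycles": cycles,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def validate_specimen_table(
    table: pd.DataFrame, protocol: FatigueProtocol | None = None
) -> None:
    """Check schema and censoring invariants; raise ValueError naming the
    offending CSV line (header = line 1) on the first violation."""
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for idx, row in table.iterrows():
        line = int(idx) + 2  # type: ignore[arg-type]
        if row["outcome"] not in _VALID_OUTCOMES:
            raise ValueError(
                f"line {line}: unknown outcome {row['outcome']!r} "
                f"(expected one of {sorted(_VALID_OUTCOMES)})"
            )
        cycles = row["cycles"]
        if not (isinstance(cycles, (int, float)) and float(cycles).is_integer() and cycles > 0):
            raise ValueError(f"line {line}: cycles must be a positive integer, got {cycles!r}")
        if not row["thickness_mm"] > 0:
            raise ValueError(f"line {line}: thickness_mm must be > 0")
        if protocol is not None:
            if row["outcome"] == OUTCOME_INTACT and cycles != protocol.total_cycles:
                raise ValueError(
                    f"line {line}: intact specimen must be censored at "
                    f"{protocol.total_cycles} cycles, got {int(cycles)}"
                )
            if row["outcome"] == OUTCOME_FAILED and cycles > protocol.total_cycles:
                raise ValueError(
                    f"line {line}: failure at {int(cycles)} cycles exceeds the "
                    f"protocol length {protocol.total_cycles}"
                )


def read_specimen_csv(
    path, protocol: FatigueProtocol | None = None
) -> pd.DataFrame:
    """Read a specimen table; validates schema and (if a protocol is given)
    censoring invariants. An empty file with a header is an empty table."""
    table = pd.read_csv(path, dtype={"specimen_id": str, "group_id": str, "material": str})
    if not table.empty:
        table["cycles"] = table["cycles"].astype("int64")
    validate_specimen_table(table, protocol)
    return table[CSV_COLUMNS] if not table.empty else table.reindex(columns=CSV_COLUMNS)


def write_specimen_csv(table: pd.DataFrame, path) -> None:
    """Write in the canonical schema; write ∘ read is the identity."""
    table[CSV_COLUMNS].to_csv(path, index=False)


def summarize_group(
    table: pd.DataFrame,
    group_id: str,
    protocol: FatigueProtocol | None = None,
) -> GroupSummary:
    """Descriptive summary of one group: failure fraction and the cycle-count
    range, plus the geometric mean cycles-to-failure of the failed specimens
    (the natural location statistic for lifetimes spread over decades)."""
    grp = table[table["group_id"] == group_id]
    if grp.empty:
        known = ", ".join(sorted(table["group_id"].unique()))
        raise KeyError(f"unknown group {group_id!r}; table contains: {known}")
    failed = grp[grp["outcome"] == OUTCOME_FAILED]
    n, k = len(grp), len(failed)
    geo = (
        float(math.exp(failed["cycles"].map(math.log).mean())) if k else None
    )
    return GroupSummary(
        group_id=group_id,
        n_specimens=n,
        n_failed=k,
        failure_fraction=k / n,
        min_cycles=int(grp["cycles"].min()),
        max_cycles=int(grp["cycles"].max()),
        geometric_mean_cycles=geo,
    )


def summarize_all_groups(
    table: pd.DataFrame, protocol: FatigueProtocol | None = None
) -> list[GroupSummary]:
    return [
        summarize_group(table, g, protocol) for g in sorted(table["group_id"].unique())
    ]
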