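"""Pool presence table: per-coordinate read counts across all pools,
read-count thresholding and line classification.

One table line per unique insertion coordinate records how many reads carried
each pool barcode.  Thresholding a line at t drops pool coordinates with
fewer than t reads; what survives determines how the line maps back to the
collection:

* one coordinate on every axis           -> a single well (unambiguous)
* multiple coordinates on exactly one axis -> multiple wells, all real
* multiple coordinates on two or more axes -> ambiguous (needs the
  read-count-ratio model to pick the real address combinations)
* three axes populated, fourth only below threshold -> salvageable by the
  fill-in rule
* anything less                           -> unmappable at this threshold
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .layout import AXES, Axis


class LineClass(enum.Enum):
    UNAMBIGUOUS_SINGLE = "unambiguous_single"
    UNAMBIGUOUS_MULTIPLE = "unambiguous_multiple"
    AMBIGUOUS_MULTI = "ambiguous_multi"
    INCOMPLETE_3AXIS = "incomplete_3axis"
    UNMAPPABLE = "unmappable"


#: Classes that map to at least one collection address at a given threshold.
MAPPABLE_CLASSES = frozenset(
    {
        LineClass.UNAMBIGUOUS_SINGLE,
        LineClass.UNAMBIGUOUS_MULTIPLE,
        LineClass.AMBIGUOUS_MULTI,
        LineClass.INCOMPLETE_3AXIS,
    }
)


@dataclass
class PoolPresenceLine:
    """Read counts for one insertion coordinate, keyed by axis and pool index."""

    replicon: str
    position: int
    counts: dict[Axis, dict[int, int]] = field(default_factory=dict)

    def add(self, axis: Axis, pool_index: int, reads: int) -> None:
        if reads < 1:
            raise ValueError("read counts must be >= 1")
        axis_counts = self.counts.setdefault(axis, {})
        axis_counts[pool_index] = axis_counts.get(pool_index, 0) + reads

    def total_reads(self) -> int:
        return sum(c for per_axis in self.counts.values() for c in per_axis.values())

    def above_threshold(self, t: int) -> dict[Axis, dict[int, int]]:
        return {
            axis: {i: c for i, c in per_axis.items() if c >= t}
            for axis, per_axis in self.counts.items()
            if any(c >= t for c in per_axis.values())
        }

    @property
    def coordinate(self) -> tuple[str, int]:
        return (self.replicon, self.position)


def build_table(records: pd.DataFrame | Iterable[tuple]) -> list[PoolPresenceLine]:
    """Assemble presence lines from (replicon, position, axis, pool_index, reads).

    Accepts the tidy frame produced by demultiplexing or an iterable of
    5-tuples; repeated records for the same coordinate and pool are summed.
    Lines come back sorted by coordinate.
    """
    if isinstance(records, pd.DataFrame):
        rows = records[["replicon", "position", "axis", "pool_index", "reads"]].itertuples(
            index=False
        )
    else:
        rows = iter(records)
    lines: dict[tuple[str, int], PoolPresenceLine] = {}
    for replicon, position, axis, pool_index, reads in rows:
        key = (str(replicon), int(position))
        line = lines.get(key)
        if line is None:
            line = lines[key] = PoolPresenceLine(key[0], key[1])
        line.add(Axis(str(axis)), int(pool_index), int(reads))
    return [lines[k] for k in sorted(lines)]


def classify_line(
    line: PoolPresenceLine, threshold: int
) -> tuple[LineClass, dict[Axis, dict[int, int]]]:
    """Threshold a line and classify how it maps to the collection.

    Returns the class and the surviving (above-threshold) counts per axis.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    surviving = line.above_threshold(threshold)
    populated = [a for a in AXES if surviving.get(a)]
    if len(populated) == 4:
        multi_axes = sum(1 for a in AXES if len(surviving[a]) > 1)
        if multi_axes == 0:
            return LineClass.UNAMBIGUOUS_SINGLE, surviving
        if multi_axes == 1:
            return LineClass.UNAMBIGUOUS_MULTIPLE, surviving
        return LineClass.AMBIGUOUS_MULTI, surviving
    if len(populated) == 3:
        missing = next(a for a in AXES if a not in populated)
        if line.counts.get(missing):  # sub-threshold data exists on the 4th axis
            return LineClass.INCOMPLETE_3AXIS, surviving
    return LineClass.UNMAPPABLE, surviving


@dataclass(frozen=True)
class ThresholdScan:
    """Per-threshold mapping census plus the automatically chosen threshold."""

    report: pd.DataFrame  # t, n_single, n_any_mapped, n_unmapped
    chosen_t: int

    def write_tsv(self, path: str | Path) -> None:
        self.report.to_csv(path, sep="\t", index=False)


def threshold_scan(
    table: Sequence[PoolPresenceLine], t_range: Iterable[int] = range(1, 31)
) -> ThresholdScan:
    """Scan the read-count threshold and pick the one maximising single maps.

    For every t the report counts lines that map to a single address, lines
    that map in any way, and lines that do not map.  The chosen threshold is
    the argmax of the single-address count with ties broken toward smaller t;
    the full report is returned so a user can override the choice after
    inspection.
    """
    table = list(table)
    if not table:
        raise ValueError("empty pool presence table")
    rows = []
    for t in t_range:
        n_single = n_mapped = 0
        for line in table:
            cls, _ = classify_line(line, t)
            if cls is LineClass.UNAMBIGUOUS_SINGLE:
                n_single += 1
            if cls in MAPPABLE_CLASSES:
                n_mapped += 1
        rows.append(
            {
                "t": t,
                "n_single": n_single,
                "n_any_mapped": n_mapped,
                "n_unmapped": len(table) - n_mapped,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        raise ValueError("empty threshold range")
    best = report.sort_values(["n_single", "t"], ascending=[False, True]).iloc[0]
    return ThresholdScan(report=report, chosen_t=int(best["t"]))


def table_to_frame(table: Sequence[PoolPresenceLine]) -> pd.DataFrame:
    rows = [
        (line.replicon, line.position, axis.value, pool_index, reads)
        for line in table
        for axis in AXES
        for pool_index, reads in sorted(line.counts.get(axis, {}).items())
    ]
    return pd.DataFrame(rows, columns=["replicon", "position", "axis", "pool_index", "reads"])


def write_table(table: Sequence[PoolPresenceLine], path: str | Path) -> None:
    table_to_frame(table).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> list[PoolPresenceLine]:
    return build_table(pd.read_csv(path, sep="\t"))
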