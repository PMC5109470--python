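"""Four-axis combinatorial pooling geometry.

An arrayed mutant collection lives in 96-well (or other rectangular) plates.
Each plate is assigned a position on a virtual plate grid, so that every well
has four coordinates: its row and column within the plate, and the plate-row
(PR) and plate-column (PC) of its plate on the grid.  One sample pool exists
per coordinate value on each axis; a well's culture is dispatched to exactly
four pools, whose joint identity encodes the well uniquely.  With the default
geometry (8 x 12 wells, 20 x 21 plate grid) this gives

    8 row + 12 column + 20 plate-row + 21 plate-column = 61 pools

for up to 420 plates, while the number of pooling operations grows only
linearly with the plate count (4 per plate).
"""

from __future__ import annotations

import enum
import math
import re
import string
from dataclasses import dataclass, field
from typing import Iterator, Mapping


class Axis(enum.Enum):
    """The four pooling axes."""

    ROW = "row"
    COL = "col"
    PR = "pr"
    PC = "pc"

    def __lt__(self, other: "Axis") -> bool:
        order = list(Axis)
        return order.index(self) < order.index(other)


#: Canonical ordering used everywhere counts or ratios are tabulated.
AXES: tuple[Axis, Axis, Axis, Axis] = (Axis.ROW, Axis.COL, Axis.PR, Axis.PC)


class PhantomPlateError(ValueError):
    """A plate-grid position beyond the declared number of plates."""


@dataclass(frozen=True)
class GridLayout:
    """Physical geometry of an arrayed collection and its pooling grid.

    Parameters
    ----------
    n_rows, n_cols:
        Wells per plate along each axis (default 8 x 12 = 96-well plates).
    n_plate_rows, n_plate_cols:
        Dimensions of the virtual grid onto which plates are placed.
    n_plates:
        Number of plates actually present; must fit on the grid.  Plates are
        assigned to grid positions row-major, 1-based.
    control_wells_per_plate:
        Sterile control wells per plate; they receive no culture.  Their
        positions default to the last wells of each plate in row-major order.
    """

    n_rows: int = 8
    n_cols: int = 12
    n_plate_rows: int = 20
    n_plate_cols: int = 21
    n_plates: int = 417
    control_wells_per_plate: int = 2

    def __post_init__(self) -> None:
        for name in ("n_rows", "n_cols", "n_plate_rows", "n_plate_cols", "n_plates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_plates > self.n_plate_rows * self.n_plate_cols:
            raise ValueError(
                f"n_plates={self.n_plates} exceeds plate grid capacity "
                f"{self.n_plate_rows * self.n_plate_cols}"
            )
        if self.control_wells_per_plate < 0:
            raise ValueError("control_wells_per_plate must be >= 0")
        if self.control_wells_per_plate >= self.n_rows * self.n_cols:
            raise ValueError("control wells would fill the whole plate")
        if self.n_rows > 26:
            raise ValueError("row labels only support up to 26 rows (A..Z)")

    @property
    def wells_per_plate(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def usable_wells_per_plate(self) -> int:
        return self.wells_per_plate - self.control_wells_per_plate

    @property
    def pool_count(self) -> int:
        return self.n_rows + self.n_cols + self.n_plate_rows + self.n_plate_cols

    def axis_size(self, axis: Axis) -> int:
        return {
            Axis.ROW: self.n_rows,
            Axis.COL: self.n_cols,
            Axis.PR: self.n_plate_rows,
            Axis.PC: self.n_plate_cols,
        }[axis]

    def plates_in_plate_row(self, plate_row: int) -> int:
        """Number of real plates occupying a plate-row of the grid."""
        if not 1 <= plate_row <= self.n_plate_rows:
            raise ValueError(f"plate_row {plate_row} out of range")
        first = (plate_row - 1) * self.n_plate_cols + 1
        if first > self.n_plates:
            return 0
        return min(self.n_plates, first + self.n_plate_cols - 1) - first + 1

    def plates_in_plate_col(self, plate_col: int) -> int:
        if not 1 <= plate_col <= self.n_plate_cols:
            raise ValueError(f"plate_col {plate_col} out of range")
        n_full_rows, rem = divmod(self.n_plates, self.n_plate_cols)
        return n_full_rows + (1 if plate_col <= rem else 0)

    def control_positions(self) -> tuple[tuple[int, int], ...]:
        """(row, col) positions of control wells, last wells in row-major order."""
        out = []
        for k in range(self.control_wells_per_plate):
            idx = self.wells_per_plate - 1 - k  # 0-based row-major index
            out.append((idx // self.n_cols + 1, idx % self.n_cols + 1))
        return tuple(sorted(out))

    def iter_wells(self, include_controls: bool = False) -> Iterator["WellAddress"]:
        """All wells, plate-major then row-major within the plate."""
        controls = set(self.control_positions())
        for plate in range(1, self.n_plates + 1):
            for row in range(1, self.n_rows + 1):
                for col in range(1, self.n_cols + 1):
                    if not include_controls and (row, col) in controls:
                        continue
                    yield WellAddress(plate, row, col)


def row_letter(row: int) -> str:
    if not 1 <= row <= 26:
        raise ValueError(f"row index {row} outside A..Z range")
    return string.ascii_uppercase[row - 1]


def row_index(letter: str) -> int:
    letter = letter.strip().upper()
    if len(letter) != 1 or letter not in string.ascii_uppercase:
        raise ValueError(f"bad row label {letter!r}")
    return string.ascii_uppercase.index(letter) + 1


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well: plate number plus in-plate row/column (all 1-based)."""

    plate: int
    row: int
    col: int

    def validate(self, layout: GridLayout) -> "WellAddress":
        if not 1 <= self.plate <= layout.n_plates:
            raise ValueError(f"plate {self.plate} outside 1..{layout.n_plates}")
        if not 1 <= self.row <= layout.n_rows:
            raise ValueError(f"row {self.row} outside 1..{layout.n_rows}")
        if not 1 <= self.col <= layout.n_cols:
            raise ValueError(f"col {self.col} outside 1..{layout.n_cols}")
        return self

    @property
    def label(self) -> str:
        """Render as e.g. ``P394_H06``."""
        return f"P{self.plate}_{row_letter(self.row)}{self.col:02d}"

    @classmethod
    def from_label(cls, label: str) -> "WellAddress":
        m = re.fullmatch(r"P(\d+)_([A-Z])(\d+)", label.strip())
        if m is None:
            raise ValueError(f"cannot parse well label {label!r}")
        return cls(int(m.group(1)), row_index(m.group(2)), int(m.group(3)))


@dataclass(frozen=True, order=True)
class PoolId:
    """One address pool: an axis, a 1-based index, and optionally its barcode."""

    axis: Axis
    index: int
    barcode: str | None = field(default=None, compare=False)

    @property
    def name(self) -> str:
        if self.axis is Axis.ROW:
            return f"row_{row_letter(self.index)}"
        return f"{self.axis.value}_{self.index}"


def plate_grid_position(plate: int, layout: GridLayout) -> tuple[int, int]:
    """Plate-grid (plate_row, plate_col) of a plate number, row-major 1-based.

    Plate 1 sits at (1, 1); plate numbers increase along plate-rows, so with a
    20 x 21 grid plate 394 = 18 * 21 + 16 sits at (19, 16).
    """
    capacity = layout.n_plate_rows * layout.n_plate_cols
    if not 1 <= plate <= capacity:
        raise ValueError(f"plate {plate} outside grid capacity 1..{capacity}")
    plate_row = math.ceil(plate / layout.n_plate_cols)
    plate_col = plate - (plate_row - 1) * layout.n_plate_cols
    return plate_row, plate_col


def plate_from_grid_position(plate_row: int, plate_col: int, layout: GridLayout) -> int:
    """Inverse of :func:`plate_grid_position`; rejects phantom plates."""
    if not 1 <= plate_row <= layout.n_plate_rows:
        raise ValueError(f"plate_row {plate_row} outside 1..{layout.n_plate_rows}")
    if not 1 <= plate_col <= layout.n_plate_cols:
        raise ValueError(f"plate_col {plate_col} outside 1..{layout.n_plate_cols}")
    plate = (plate_row - 1) * layout.n_plate_cols + plate_col
    if plate > layout.n_plates:
        raise PhantomPlateError(
            f"grid position ({plate_row}, {plate_col}) is plate {plate}, "
            f"but only {layout.n_plates} plates exist"
        )
    return plate


def pools_for_well(addr: WellAddress, layout: GridLayout) -> tuple[PoolId, ...]:
    """The four pools (one per axis) that receive aliquots of this well."""
    addr.validate(layout)
    pr, pc = plate_grid_position(addr.plate, layout)
    return (
        PoolId(Axis.ROW, addr.row),
        PoolId(Axis.COL, addr.col),
        PoolId(Axis.PR, pr),
        PoolId(Axis.PC, pc),
    )


def well_for_pools(coords: Mapping[Axis, int], layout: GridLayout) -> WellAddress:
    """The unique well encoded by one pool coordinate per axis.

    Raises
    ------
    PhantomPlateError
        If the PR/PC pair points at a grid position holding no real plate.
    """
    missing = [a for a in AXES if a not in coords]
    if missing:
        raise ValueError(f"missing coordinates for axes {missing}")
    plate = plate_from_grid_position(coords[Axis.PR], coords[Axis.PC], layout)
    return WellAddress(plate, coords[Axis.ROW], coords[Axis.COL]).validate(layout)


def pooling_operation_count(layout: GridLayout) -> int:
    """Multichannel dispatch operations needed to pool the collection (4/plate)."""
    return 4 * layout.n_plates


def wells_in_pool(axis: Axis, index: int, layout: GridLayout) -> int:
    """Number of wells whose aliquots feed a given pool.

    Control wells are counted here (the analytic template model treats all
    plate positions alike); the stochastic read simulator works from actual
    well occupancy instead.
    """
    if not 1 <= index <= layout.axis_size(axis):
        raise ValueError(f"pool index {index} outside axis {axis}")
    if axis is Axis.ROW:
        return layout.n_cols * layout.n_plates
    if axis is Axis.COL:
        return layout.n_rows * layout.n_plates
    if axis is Axis.PR:
        return layout.wells_per_plate * layout.plates_in_plate_row(index)
    return layout.wells_per_plate * layout.plates_in_plate_col(index)


def expected_template_ratio(axis_a: Axis, axis_b: Axis, layout: GridLayout) -> float:
    """Expected axis_a : axis_b per-mutant template (hence read-count) ratio.

    Each well contributes one equal aliquot to each of its four pools, and the
    amplicon reactions are templated with equal DNA mass per pool, so a
    mutant's template fraction in a pool is 1 / (wells feeding that pool).
    The expected ratio is averaged over every well in the collection; e.g. a
    column pool holds 8 wells per plate versus 12 for a row pool, so the
    column:row ratio is 12/8 = 1.5.
    """
    if axis_a is axis_b:
        return 1.0
    total = 0.0
    n = 0
    for plate in range(1, layout.n_plates + 1):
        pr, pc = plate_grid_position(plate, layout)
        index = {Axis.ROW: 1, Axis.COL: 1, Axis.PR: pr, Axis.PC: pc}
        ratio = wells_in_pool(axis_b, index[axis_b], layout) / wells_in_pool(
            axis_a, index[axis_a], layout
        )
        total += ratio * layout.wells_per_plate
        n += layout.wells_per_plate
    return total / n
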