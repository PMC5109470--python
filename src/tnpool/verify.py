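"""Orthogonal verification of a condensed collection.

After re-array/colony purification the condensed collection is re-pooled on
its own four-axis grid and re-sequenced.  Verification deliberately avoids
the probabilistic solver: it asks only whether each well's *predicted*
coordinate appears in all four of the well's pools (set intersection of the
per-pool coordinate sets), which is an independent check of the original
location calls, the re-array and the colony picking.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import Axis, GridLayout, WellAddress, pools_for_well


class VerifyStatus(enum.Enum):
    CORRECT = "CORRECT"                  # a predicted coordinate is present
    DESIRED_PRESENT = "DESIRED_PRESENT"  # the desired coordinate itself is present
    ABSENT = "ABSENT"


PoolSets = dict[tuple[Axis, int], dict[str, np.ndarray]]


def pool_coordinate_sets(records: pd.DataFrame, threshold: int = 1) -> PoolSets:
    """Thresholded coordinate membership per pool.

    ``records`` is a tidy count frame (replicon, position, axis, pool_index,
    reads); coordinates with fewer than ``threshold`` reads in a pool are not
    members of that pool.  Arrays come back sorted for tolerant lookup.
    """
    sets: PoolSets = {}
    kept = records[records["reads"] >= threshold]
    for (axis, pool_index, replicon), grp in kept.groupby(
        ["axis", "pool_index", "replicon"], sort=True
    ):
        key = (Axis(str(axis)), int(pool_index))
        sets.setdefault(key, {})[str(replicon)] = np.sort(
            grp["position"].to_numpy(dtype=np.int64)
        )
    return sets


def _in_set(
    sets: PoolSets, key: tuple[Axis, int], replicon: str, position: int, tol: int
) -> bool:
    arr = sets.get(key, {}).get(replicon)
    if arr is None or len(arr) == 0:
        return False
    i = np.searchsorted(arr, position)
    for j in (i - 1, i):
        if 0 <= j < len(arr) and abs(int(arr[j]) - position) <= tol:
            return True
    return False


@dataclass(frozen=True)
class VerificationRecord:
    well: WellAddress
    predicted: tuple[tuple[str, int], ...]
    desired: tuple[str, int] | None
    found: tuple[tuple[str, int], ...]  # predicted coordinates present in all 4 pools
    status: VerifyStatus
    tolerance_bp: int


def verify_well(
    well: WellAddress,
    predictions: Sequence[tuple[str, int]],
    sets: PoolSets,
    layout: GridLayout,
    desired: tuple[str, int] | None = None,
    tolerance_bp: int = 2,
) -> VerificationRecord:
    """Check a well's predicted coordinates against its four pools.

    A coordinate counts as present if each of the well's four pools holds a
    coordinate within ``tolerance_bp`` of it (absorbing junction-calling
    off-by-ones).  Status is DESIRED_PRESENT when the desired coordinate is
    found, CORRECT when any prediction is, ABSENT otherwise.
    """
    pools = pools_for_well(well, layout)
    found = []
    for replicon, position in predictions:
        if all(
            _in_set(sets, (p.axis, p.index), replicon, position, tolerance_bp)
            for p in pools
        ):
            found.append((replicon, int(position)))
    desired_found = desired is not None and any(
        rep == desired[0] and abs(pos - desired[1]) <= tolerance_bp for rep, pos in found
    )
    if desired_found:
        status = VerifyStatus.DESIRED_PRESENT
    elif found:
        status = VerifyStatus.CORRECT
    else:
        status = VerifyStatus.ABSENT
    return VerificationRecord(
        well=well,
        predicted=tuple((r, int(p)) for r, p in predictions),
        desired=desired,
        found=tuple(found),
        status=status,
        tolerance_bp=tolerance_bp,
    )


@dataclass
class VerificationReport:
    records: list[VerificationRecord]

    @property
    def summary(self) -> dict[str, int]:
        n_desired = sum(1 for r in self.records if r.status is VerifyStatus.DESIRED_PRESENT)
        n_correct = n_desired + sum(
            1 for r in self.records if r.status is VerifyStatus.CORRECT
        )
        return {
            "n_wells": len(self.records),
            "n_correct": n_correct,  # desired implies correct
            "n_desired": n_desired,
            "n_absent": sum(1 for r in self.records if r.status is VerifyStatus.ABSENT),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": [r.well.label for r in self.records],
                "status": [r.status.value for r in self.records],
                "n_predicted": [len(r.predicted) for r in self.records],
                "n_found": [len(r.found) for r in self.records],
                "tolerance_bp": [r.tolerance_bp for r in self.records],
            }
        )

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary, fh, indent=2, sort_keys=True)


def verify_collection(
    predictions: Mapping[WellAddress, Sequence[tuple[str, int]]],
    records: pd.DataFrame,
    layout: GridLayout,
    threshold: int = 1,
    desired: Mapping[WellAddress, tuple[str, int]] | None = None,
    tolerance_bp: int = 2,
) -> VerificationReport:
    """Verify every predicted well of a condensed collection."""
    sets = pool_coordinate_sets(records, threshold)
    desired = desired or {}
    recs = [
        verify_well(
            well,
            preds,
            sets,
            layout,
            desired=desired.get(well),
            tolerance_bp=tolerance_bp,
        )
        for well, preds in sorted(predictions.items())
    ]
    return VerificationReport(records=recs)


SANGER_CLASSES = ("exact", "<=1bp", "<=5bp", "mismatch")


def compare_sanger(
    predicted: tuple[str, int], observed: tuple[str, int]
) -> tuple[int | None, str]:
    """Compare a predicted junction against a Sanger-measured one.

    Returns (|delta| in bp, class), where class is ``exact`` (0 bp),
    ``<=1bp``, ``<=5bp`` or ``mismatch`` (different replicon or > 5 bp; the
    distance is None across replicons).
    """
    if predicted[0] != observed[0]:
        return None, "mismatch"
    delta = abs(int(predicted[1]) - int(observed[1]))
    if delta == 0:
        return delta, "exact"
    if delta <= 1:
        return delta, "<=1bp"
    if delta <= 5:
        return delta, "<=5bp"
    return delta, "mismatch"
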