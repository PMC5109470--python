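"""Selection of one representative mutant per disrupted gene.

An oversampled collection usually holds several mutants per gene; the
condensation step picks, for each gene, the mutant that best trades off two
factors: the chance that a colony struck from the source well is actually the
desired clone (1/m for a well with m located co-occupants) and the chance
that the insertion disrupts gene function, taken to fall off linearly with
the fractional distance d of the insertion from the translation start.  The
default score is their product,

    S(m, d) = (1/m) * (1 - d)

so an early insertion in a crowded well can lose to a later insertion in a
clean well.  Representatives from singly occupied wells are re-arrayed
directly; those from shared wells are colony purified, picking enough
colonies to reach a target probability of catching the desired clone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

from .layout import GridLayout, WellAddress

ACTION_REARRAY = "REARRAY"
ACTION_COLONY_PURIFY = "COLONY_PURIFY"


def fractional_distance(position: int, gene_start: int, gene_end: int, strand: str) -> float:
    """Fractional distance of an insertion from the gene's translation start.

    Coordinates are 1-based inclusive; d = 0 at the start codon and
    approaches 1 at the distal end.  For minus-strand genes the translation
    start is the genomic ``gene_end``.
    """
    if not gene_start <= position <= gene_end:
        raise ValueError(
            f"position {position} outside gene span {gene_start}..{gene_end}"
        )
    length = gene_end - gene_start + 1
    offset = (gene_end - position) if strand == "-" else (position - gene_start)
    return offset / length


def candidate_score(m: int, d: float) -> float:
    """Joint pick-and-disrupt likelihood S = (1/m) * (1 - d)."""
    if m < 1:
        raise ValueError("occupancy m must be >= 1")
    if not 0.0 <= d <= 1.0:
        raise ValueError("fractional distance d must be in [0, 1]")
    return (1.0 / m) * (1.0 - d)


def colonies_to_pick(m: int, p_target: float = 0.85, lo: int = 2, hi: int = 10) -> int:
    """Colonies to streak from an m-occupant well for a p_target hit chance.

    Solves 1 - (1 - 1/m)^n >= p_target for n and clamps to [lo, hi].
    """
    if m < 2:
        raise ValueError("colony purification applies to wells with m >= 2")
    if not 0.0 < p_target < 1.0:
        n = lo
    else:
        n = math.ceil(math.log(1.0 - p_target) / math.log(1.0 - 1.0 / m))
    return int(min(max(n, lo), hi))


@dataclass
class CondensationPlan:
    """Chosen representative per locus, with re-array/purification actions."""

    plan: pd.DataFrame
    destination_layout: GridLayout

    def write_tsv(self, path: str | Path) -> None:
        self.plan.to_csv(path, sep="\t", index=False)

    @property
    def n_rearray(self) -> int:
        return int((self.plan["action"] == ACTION_REARRAY).sum())

    @property
    def n_colony_purify(self) -> int:
        return int((self.plan["action"] == ACTION_COLONY_PURIFY).sum())


def well_occupancy(catalogue: pd.DataFrame) -> pd.Series:
    """Located co-occupant count per source well (address label -> m).

    Only mutants the solver located are visible, so m is a lower bound on
    true occupancy.
    """
    return catalogue.groupby("address").size()


def _destinations(layout: GridLayout, n: int) -> list[WellAddress]:
    wells = []
    for i, w in enumerate(layout.iter_wells()):
        if i >= n:
            break
        wells.append(w)
    if len(wells) < n:
        raise ValueError(f"destination layout holds {len(wells)} wells; need {n}")
    return wells


def pick_representatives(
    catalogue: pd.DataFrame,
    features: pd.DataFrame,
    destination_layout: GridLayout | None = None,
    p_target: float = 0.85,
    scorer: Callable[[int, float], float] = candidate_score,
) -> CondensationPlan:
    """Choose the best-scoring mutant per disrupted locus and plan its move.

    ``catalogue`` is an annotated solver catalogue (needs locus_tag,
    fractional_position, address columns).  For each locus the candidate with
    the highest score S(m, d) wins; ties break toward smaller d, then earlier
    plate/row/col.  Singly occupied sources are re-arrayed; shared sources
    are colony purified with a computed colony count.  Destinations are laid
    out plate-major in the destination layout.
    """
    cat = catalogue[catalogue["locus_tag"].astype(str) != ""].copy()
    cat = cat.dropna(subset=["fractional_position"])
    if cat.empty:
        raise ValueError("catalogue contains no gene-disrupting entries")
    occ = well_occupancy(catalogue)
    cat["m"] = cat["address"].map(occ).astype(int)
    cat["d"] = cat["fractional_position"].astype(float)
    cat["S"] = [scorer(int(m), float(d)) for m, d in zip(cat["m"], cat["d"])]
    cat = cat.sort_values(
        ["locus_tag", "S", "d", "plate", "row", "col"],
        ascending=[True, False, True, True, True, True],
    )
    chosen = cat.groupby("locus_tag", as_index=False).first()
    chosen = chosen.sort_values("locus_tag").reset_index(drop=True)

    n = len(chosen)
    if destination_layout is None:
        import math as _math

        plates_needed = max(1, _math.ceil(n / (96 - 2)))
        side = max(1, _math.ceil(_math.sqrt(plates_needed)))
        destination_layout = GridLayout(
            n_plate_rows=side,
            n_plate_cols=_math.ceil(plates_needed / side),
            n_plates=plates_needed,
        )
    dests = _destinations(destination_layout, n)
    rows = []
    for dest, rec in zip(dests, chosen.itertuples(index=False)):
        m = int(rec.m)
        action = ACTION_REARRAY if m == 1 else ACTION_COLONY_PURIFY
        rows.append(
            {
                "locus_tag": rec.locus_tag,
                "replicon": rec.replicon,
                "position": int(rec.position),
                "source_well": rec.address,
                "occupancy_m": m,
                "fractional_position": float(rec.d),
                "score": float(rec.S),
                "action": action,
                "colonies_to_pick": 1 if m == 1 else colonies_to_pick(m, p_target),
                "destination_well": dest.label,
            }
        )
    plan = pd.DataFrame(rows)
    if plan["destination_well"].duplicated().any():
        raise AssertionError("destination wells must be unique")
    return CondensationPlan(plan=plan, destination_layout=destination_layout)
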