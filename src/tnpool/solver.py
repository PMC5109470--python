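"""Probabilistic address solving.

Within one sequencing run, a given mutant's template fraction — and hence its
expected read count — differs between its four pools only by fixed dilution
factors, so the six pairwise read-count ratios (row/col, row/PR, row/PC,
col/PR, col/PC, PR/PC) of a genuinely co-located coordinate set cluster
around characteristic values.  The solver fits a Voigt profile (Gaussian (x)
Lorentzian convolution) to the histogram of each log-ratio over all
unambiguously single-mapping lines, normalises each fit into a probability
density, and scores every candidate address of an ambiguous line by the
product of the six densities evaluated at its log read-count ratios.  The
top-scoring addresses — at most as many as the largest number of coordinates
in any single axis — are accepted.

Two post-processing rules complete the catalogue: lines with only three axes
above threshold borrow the highest sub-threshold coordinate on the fourth
axis, and runs of consecutive genomic coordinates that map to the same wells
are collapsed to a consensus coordinate (the A of an AT/TA dinucleotide in
the run if present, otherwise a read-weighted median).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import curve_fit
from scipy.special import voigt_profile

from .layout import (
    AXES,
    Axis,
    GridLayout,
    PhantomPlateError,
    WellAddress,
    well_for_pools,
)
from .presence import LineClass, PoolPresenceLine, classify_line

#: The six axis pairs, in canonical order.
AXIS_PAIRS: tuple[tuple[Axis, Axis], ...] = (
    (Axis.ROW, Axis.COL),
    (Axis.ROW, Axis.PR),
    (Axis.ROW, Axis.PC),
    (Axis.COL, Axis.PR),
    (Axis.COL, Axis.PC),
    (Axis.PR, Axis.PC),
)

DENSITY_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Ratio model
# ---------------------------------------------------------------------------


def ratio_histograms(
    single_lines: Iterable[PoolPresenceLine],
    threshold: int = 1,
) -> dict[tuple[Axis, Axis], np.ndarray]:
    """ln(read-count ratio) samples per axis pair from single-mapping lines.

    Each line must have exactly one above-threshold coordinate per axis (its
    surviving counts are used); a line with counts (24, 60, 93, 124) on
    (row, col, PR, PC) contributes ln(24/60), ln(24/93), ln(24/124),
    ln(60/93), ln(60/124) and ln(93/124).
    """
    samples: dict[tuple[Axis, Axis], list[float]] = {pair: [] for pair in AXIS_PAIRS}
    for line in single_lines:
        cls, surviving = classify_line(line, threshold)
        if cls is not LineClass.UNAMBIGUOUS_SINGLE:
            continue
        counts = {axis: next(iter(surviving[axis].values())) for axis in AXES}
        for a, b in AXIS_PAIRS:
            samples[(a, b)].append(math.log(counts[a] / counts[b]))
    return {pair: np.asarray(vals) for pair, vals in samples.items()}


@dataclass(frozen=True)
class VoigtFit:
    """A Voigt profile fitted to a log-ratio histogram.

    ``amplitude`` scales the profile to the histogram counts (reported for
    diagnostics); the probability density drops it, since the Voigt profile
    itself integrates to one.  ``support`` records the fitted data range;
    densities outside it floor at DENSITY_FLOOR.
    """

    amplitude: float
    center: float
    sigma: float
    gamma: float
    support: tuple[float, float]
    n_samples: int
    bin_width: float
    residual: float
    stderr: tuple[float, float, float, float] = (np.nan,) * 4
    gaussian_fallback: bool = False

    def density(self, x: float | np.ndarray) -> float | np.ndarray:
        """Normalised probability density at log-ratio x."""
        x = np.asarray(x, dtype=float)
        val = voigt_profile(x - self.center, max(self.sigma, 1e-12), self.gamma)
        lo, hi = self.support
        val = np.where((x < lo) | (x > hi), DENSITY_FLOOR, np.maximum(val, DENSITY_FLOOR))
        return float(val) if val.ndim == 0 else val


def _histogram(values: np.ndarray, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = np.quantile(values, [0.005, 0.995])
    if hi - lo < bin_width * 5:
        lo, hi = values.min(), values.max()
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    heights, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, heights.astype(float)


def fit_voigt(values: np.ndarray, bin_width: float = 0.1) -> VoigtFit:
    """Least-squares Voigt fit to the histogram of log-ratio samples.

    Initialised at (median, IQR/1.349, IQR/10), which is robust whether the
    data are Gaussian-like or heavy-tailed.  Falls back to a pure Gaussian
    (gamma = 0) if the Voigt fit fails to converge.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("too few samples to fit a ratio distribution")
    centers, heights = _histogram(values, bin_width)
    if (heights > 0).sum() < 5:
        raise ValueError(
            "degenerate histogram (fewer than 5 occupied bins); "
            "ratio fitting needs stochastic, not deterministic, data"
        )
    q25, med, q75 = np.quantile(values, [0.25, 0.5, 0.75])
    iqr = max(q75 - q25, bin_width)
    amp0 = heights.max() * iqr
    p0 = [amp0, med, iqr / 1.349, iqr / 10.0]
    bounds = ([0.0, centers.min(), 1e-9, 0.0], [np.inf, centers.max(), np.inf, np.inf])

    def model(x, amp, center, sigma, gamma):
        return amp * voigt_profile(x - center, sigma, gamma)

    support = (float(values.min()), float(values.max()))
    try:
        popt, pcov = curve_fit(model, centers, heights, p0=p0, bounds=bounds, maxfev=20000)
        resid = float(np.sqrt(np.mean((model(centers, *popt) - heights) ** 2)))
        stderr = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(pcov), 0.0)))
        return VoigtFit(
            amplitude=float(popt[0]),
            center=float(popt[1]),
            sigma=float(popt[2]),
            gamma=float(popt[3]),
            support=support,
            n_samples=len(values),
            bin_width=bin_width,
            residual=resid,
            stderr=stderr,  # type: ignore[arg-type]
        )
    except RuntimeError:
        def gauss(x, amp, center, sigma):
            return amp * voigt_profile(x - center, sigma, 0.0)

        popt, pcov = curve_fit(
            gauss, centers, heights, p0=p0[:3],
            bounds=([0.0, centers.min(), 1e-9], [np.inf, centers.max(), np.inf]),
            maxfev=20000,
        )
        resid = float(np.sqrt(np.mean((gauss(centers, *popt) - heights) ** 2)))
        err = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        return VoigtFit(
            amplitude=float(popt[0]),
            center=float(popt[1]),
            sigma=float(popt[2]),
            gamma=0.0,
            support=support,
            n_samples=len(values),
            bin_width=bin_width,
            residual=resid,
            stderr=(float(err[0]), float(err[1]), float(err[2]), np.nan),
            gaussian_fallback=True,
        )


@dataclass(frozen=True)
class RatioModel:
    """Six fitted log-ratio probability densities, one per axis pair."""

    fits: Mapping[tuple[Axis, Axis], VoigtFit]
    min_fit_lines: int = 200

    @classmethod
    def fit(
        cls,
        table: Sequence[PoolPresenceLine],
        threshold: int,
        bin_width: float = 0.1,
        min_fit_lines: int = 200,
    ) -> "RatioModel":
        """Fit the model from the single-mapping lines of a presence table."""
        hists = ratio_histograms(table, threshold)
        n = min(len(v) for v in hists.values())
        if n < min_fit_lines:
            raise ValueError(
                f"only {n} single-address lines available; need >= {min_fit_lines} "
                "to fit the ratio model"
            )
        fits = {pair: fit_voigt(vals, bin_width) for pair, vals in hists.items()}
        return cls(fits=fits, min_fit_lines=min_fit_lines)

    def density(self, pair: tuple[Axis, Axis], ratio_value: float) -> float:
        """Probability density of an (untransformed) read-count ratio."""
        if ratio_value <= 0:
            raise ValueError("ratio must be positive")
        return float(self.fits[pair].density(math.log(ratio_value)))

    def integral(self, pair: tuple[Axis, Axis]) -> float:
        """Numeric check that a fitted density integrates to one."""
        fit = self.fits[pair]
        val, _ = quad(
            lambda x: voigt_profile(x - fit.center, max(fit.sigma, 1e-12), fit.gamma),
            -np.inf,
            np.inf,
        )
        return float(val)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), fit in self.fits.items():
            rows.append(
                {
                    "pair": f"{a.value}/{b.value}",
                    "amplitude": fit.amplitude,
                    "center": fit.center,
                    "sigma": fit.sigma,
                    "gamma": fit.gamma,
                    "support_lo": fit.support[0],
                    "support_hi": fit.support[1],
                    "n_samples": fit.n_samples,
                    "residual": fit.residual,
                    "gaussian_fallback": fit.gaussian_fallback,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def ratio_density(model: RatioModel, pair: tuple[Axis, Axis], ratio_value: float) -> float:
    return model.density(pair, ratio_value)


# ---------------------------------------------------------------------------
# Candidate enumeration and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AddressCall:
    """One proposed well for a coordinate, with its score and provenance."""

    address: WellAddress
    score: float
    rank: int
    line_class: LineClass
    fill_in: bool = False
    counts: tuple[int, int, int, int] = (0, 0, 0, 0)  # row, col, pr, pc reads

    @property
    def total_reads(self) -> int:
        return sum(self.counts)


def enumerate_candidates(
    surviving: Mapping[Axis, Mapping[int, int]], layout: GridLayout
) -> list[dict[Axis, tuple[int, int]]]:
    """Cartesian product of surviving coordinates, one per axis.

    Each candidate maps axis -> (pool index, read count).  Combinations whose
    PR/PC pair addresses a grid position with no real plate (phantom plates)
    are discarded.
    """
    if any(not surviving.get(a) for a in AXES):
        return []
    out = []
    per_axis = [sorted(surviving[a].items()) for a in AXES]
    for combo in itertools.product(*per_axis):
        cand = dict(zip(AXES, combo))
        try:
            well_for_pools({a: idx for a, (idx, _) in cand.items()}, layout)
        except PhantomPlateError:
            continue
        out.append(cand)
    return out


def score_candidates(
    surviving: Mapping[Axis, Mapping[int, int]],
    candidates: Sequence[Mapping[Axis, tuple[int, int]]],
    model: RatioModel,
    layout: GridLayout,
    line_class: LineClass = LineClass.AMBIGUOUS_MULTI,
    fill_in: bool = False,
) -> list[AddressCall]:
    """Rank candidate addresses by the product of the six ratio densities.

    At most m calls are returned, where m is the largest number of surviving
    coordinates in any single axis (the most parsimonious multiplicity
    consistent with the line).  Ties break by total read count, then by
    address ordering, so ranking is deterministic.
    """
    if not candidates:
        return []
    m = max(len(surviving[a]) for a in AXES)
    scored = []
    for cand in candidates:
        counts = {a: cand[a][1] for a in AXES}
        score = 1.0
        for a, b in AXIS_PAIRS:
            score *= model.density((a, b), counts[a] / counts[b])
        addr = well_for_pools({a: cand[a][0] for a in AXES}, layout)
        scored.append((score, sum(counts.values()), addr, cand))
    scored.sort(key=lambda rec: (-rec[0], -rec[1], rec[2]))
    calls = []
    for rank, (score, _, addr, cand) in enumerate(scored[:m], start=1):
        calls.append(
            AddressCall(
                address=addr,
                score=score,
                rank=rank,
                line_class=line_class,
                fill_in=fill_in,
                counts=tuple(cand[a][1] for a in AXES),  # type: ignore[arg-type]
            )
        )
    return calls


def fill_fourth_axis(
    line: PoolPresenceLine, threshold: int
) -> dict[Axis, dict[int, int]] | None:
    """Complete a three-axis line using its best sub-threshold coordinate.

    Requires exactly three axes above threshold and at least one (necessarily
    sub-threshold) count on the fourth; the highest-count fourth-axis
    coordinate is inserted (ties break toward the smaller pool index).
    Returns the completed surviving counts, or None if the line does not
    qualify.
    """
    surviving = line.above_threshold(threshold)
    populated = [a for a in AXES if surviving.get(a)]
    if len(populated) != 3:
        return None
    missing = next(a for a in AXES if a not in populated)
    below = line.counts.get(missing, {})
    if not below:
        return None
    best_index = max(sorted(below), key=lambda i: below[i])
    completed = {a: dict(surviving[a]) for a in populated}
    completed[missing] = {best_index: below[best_index]}
    return completed


# ---------------------------------------------------------------------------
# Consecutive-coordinate consensus
# ---------------------------------------------------------------------------


def _consensus_coordinate(
    positions: Sequence[int], reads: Sequence[int], genome_seq: str
) -> int:
    """Consensus for a run of consecutive junction coordinates.

    If the run's span contains an AT or TA dinucleotide, the position of the
    A is the consensus; otherwise the read-weighted median position is used.
    """
    lo, hi = min(positions), max(positions)
    for p in range(lo, hi):
        dinuc = genome_seq[p - 1 : p + 1].upper()
        if dinuc == "AT":
            return p
        if dinuc == "TA":
            return p + 1
    order = np.argsort(positions)
    pos = np.asarray(positions)[order]
    w = np.asarray(reads, dtype=float)[order]
    cum = np.cumsum(w)
    return int(pos[np.searchsorted(cum, cum[-1] / 2.0)])


def merge_consecutive(
    entries: pd.DataFrame,
    genome: Mapping[str, str],
    max_gap: int = 1,
) -> pd.DataFrame:
    """Collapse runs of near-adjacent coordinates mapping to identical wells.

    ``entries`` must carry columns replicon, position, address_set (a
    frozenset or sorted tuple of well labels) and reads.  Coordinates on the
    same replicon with the same address set, spaced by at most ``max_gap``,
    are merged into one row at the consensus coordinate with summed reads.
    """
    required = {"replicon", "position", "address_set", "reads"}
    if not required <= set(entries.columns):
        raise ValueError(f"entries must have columns {sorted(required)}")
    out_rows = []
    df = entries.copy()
    df["_aset"] = df["address_set"].map(
        lambda s: tuple(sorted(s)) if not isinstance(s, tuple) else s
    )
    for (replicon, aset), grp in df.groupby(["replicon", "_aset"], sort=True):
        grp = grp.sort_values("position")
        run_pos: list[int] = []
        run_reads: list[int] = []

        def flush() -> None:
            if not run_pos:
                return
            if len(run_pos) == 1:
                consensus = run_pos[0]
            else:
                consensus = _consensus_coordinate(run_pos, run_reads, genome[replicon])
            out_rows.append(
                {
                    "replicon": replicon,
                    "position": consensus,
                    "address_set": aset,
                    "reads": int(sum(run_reads)),
                    "n_merged": len(run_pos),
                }
            )

        for row in grp.itertuples(index=False):
            if run_pos and row.position - run_pos[-1] > max_gap:
                flush()
                run_pos, run_reads = [], []
            run_pos.append(int(row.position))
            run_reads.append(int(row.reads))
        flush()
    out = pd.DataFrame(out_rows, columns=["replicon", "position", "address_set", "reads", "n_merged"])
    return out.sort_values(["replicon", "position"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# End-to-end solving
# ---------------------------------------------------------------------------


@dataclass
class SolveResult:
    """Catalogue of located mutants plus per-class accounting."""

    catalogue: pd.DataFrame
    class_counts: dict[str, int]

    def write_tsv(self, path: str | Path) -> None:
        self.catalogue.to_csv(path, sep="\t", index=False)


def solve_table(
    table: Sequence[PoolPresenceLine],
    threshold: int,
    layout: GridLayout,
    model: RatioModel | None = None,
) -> SolveResult:
    """Resolve every presence-table line to collection addresses.

    Single and one-axis-multiple lines are solved by direct coordinate
    combination; ambiguous lines need the fitted ratio model (without one
    they are recorded as unresolved); three-axis lines first borrow their
    best sub-threshold fourth-axis coordinate and are then solved like the
    rest.  The catalogue has one row per (coordinate, address call), ordered
    by coordinate then rank, and is deterministic given its inputs.
    """
    rows = []
    class_counts: dict[str, int] = {c.value: 0 for c in LineClass}
    for line in table:
        cls, surviving = classify_line(line, threshold)
        fill_in = False
        if cls is LineClass.INCOMPLETE_3AXIS:
            completed = fill_fourth_axis(line, threshold)
            if completed is None:  # pragma: no cover - classify guarantees data
                cls = LineClass.UNMAPPABLE
            else:
                surviving = completed
                fill_in = True
        class_counts[cls.value] += 1
        if cls is LineClass.UNMAPPABLE:
            continue
        candidates = enumerate_candidates(surviving, layout)
        if not candidates:
            class_counts[cls.value] -= 1
            class_counts[LineClass.UNMAPPABLE.value] += 1
            continue
        if cls is LineClass.UNAMBIGUOUS_SINGLE and not fill_in:
            calls = score_candidates(
                surviving, candidates, model, layout, cls, fill_in
            ) if model else [
                AddressCall(
                    address=well_for_pools({a: candidates[0][a][0] for a in AXES}, layout),
                    score=1.0,
                    rank=1,
                    line_class=cls,
                    counts=tuple(candidates[0][a][1] for a in AXES),  # type: ignore[arg-type]
                )
            ]
        elif cls is LineClass.UNAMBIGUOUS_MULTIPLE or (
            cls is LineClass.INCOMPLETE_3AXIS
            and sum(len(surviving[a]) > 1 for a in AXES) <= 1
        ):
            # every combination is real: multiplicity lives on a single axis
            calls = [
                AddressCall(
                    address=well_for_pools({a: cand[a][0] for a in AXES}, layout),
                    score=1.0,
                    rank=r,
                    line_class=cls,
                    fill_in=fill_in,
                    counts=tuple(cand[a][1] for a in AXES),  # type: ignore[arg-type]
                )
                for r, cand in enumerate(candidates, start=1)
            ]
        else:
            if model is None:
                continue
            calls = score_candidates(surviving, candidates, model, layout, cls, fill_in)
        for call in calls:
            rows.append(
                {
                    "replicon": line.replicon,
                    "position": line.position,
                    "plate": call.address.plate,
                    "row": call.address.row,
                    "col": call.address.col,
                    "address": call.address.label,
                    "line_class": call.line_class.value,
                    "rank": call.rank,
                    "score": call.score,
                    "fill_in": call.fill_in,
                    "reads_row": call.counts[0],
                    "reads_col": call.counts[1],
                    "reads_pr": call.counts[2],
                    "reads_pc": call.counts[3],
                    "reads_total": call.total_reads,
                }
            )
    catalogue = pd.DataFrame(
        rows,
        columns=[
            "replicon", "position", "plate", "row", "col", "address",
            "line_class", "rank", "score", "fill_in",
            "reads_row", "reads_col", "reads_pr", "reads_pc", "reads_total",
        ],
    )
    catalogue = catalogue.sort_values(["replicon", "position", "rank"]).reset_index(drop=True)
    return SolveResult(catalogue=catalogue, class_counts=class_counts)


def annotate_catalogue(catalogue: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Attach locus tags and fractional gene positions to a catalogue.

    Coordinates outside any gene get an empty locus and NaN fraction.  The
    fractional distance is strand-aware: 0 at the translation start, close to
    1 at the far end of the coding region.
    """
    from .condense import fractional_distance

    out = catalogue.copy()
    locus = []
    frac = []
    for row in out.itertuples(index=False):
        sub = features[
            (features["replicon"] == row.replicon)
            & (features["start"] <= row.position)
            & (features["end"] >= row.position)
        ]
        if len(sub) == 0:
            locus.append("")
            frac.append(np.nan)
            continue
        if len(sub) > 1:  # overlap: nearest upstream translation start wins
            dists = [
                (row.position - g.start) if g.strand == "+" else (g.end - row.position)
                for g in sub.itertuples(index=False)
            ]
            g = sub.iloc[int(np.argmin(dists))]
        else:
            g = sub.iloc[0]
        locus.append(g["locus_tag"])
        frac.append(
            fractional_distance(int(row.position), int(g["start"]), int(g["end"]), str(g["strand"]))
        )
    out["locus_tag"] = locus
    out["fractional_position"] = frac
    return out
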