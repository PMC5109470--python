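import math

import numpy as np
import pandas as pd
import pytest

from tnpool.layout import AXES, Axis, GridLayout, WellAddress, pools_for_well
from tnpool.presence import PoolPresenceLine
from tnpool.solver import (
    AXIS_PAIRS,
    DENSITY_FLOOR,
    RatioModel,
    enumerate_candidates,
    fill_fourth_axis,
    fit_voigt,
    merge_consecutive,
    ratio_histograms,
    score_candidates,
    solve_table,
)
from tests.test_presence import SINGLE_COUNTS, make_line


def synthetic_ratio_model(rng, n_lines=2000, sigma_pool=0.35, base=None):
    """Fit a RatioModel from synthetic single-address lines.

    Counts follow the generative model the solver assumes: per-line abundance
    lambda (log-normal), per-axis base counts scaled by pool size, independent
    per-(line, axis) log-normal noise, Poisson sampling.
    """
    base = base or {Axis.ROW: 100.0, Axis.COL: 150.0, Axis.PR: 65.0, Axis.PC: 100.0}
    lines = []
    for i in range(n_lines):
        lam = rng.lognormal(0.0, 1.0)
        line = PoolPresenceLine("chr1", i + 1)
        for axis in AXES:
            mean = base[axis] * lam * rng.lognormal(0.0, sigma_pool)
            line.add(axis, 1, max(1, int(rng.poisson(mean))))
        lines.append(line)
    return RatioModel.fit(lines, threshold=1), base


class TestRatioHistograms:
    def test_six_ratios_of_the_worked_example(self):
        hists = ratio_histograms([make_line(SINGLE_COUNTS)], threshold=5)
        expected = {
            (Axis.ROW, Axis.COL): math.log(24 / 60),
            (Axis.ROW, Axis.PR): math.log(24 / 93),
            (Axis.ROW, Axis.PC): math.log(24 / 124),
            (Axis.COL, Axis.PR): math.log(60 / 93),
            (Axis.COL, Axis.PC): math.log(60 / 124),
            (Axis.PR, Axis.PC): math.log(93 / 124),
        }
        for pair, value in expected.items():
            assert hists[pair].tolist() == [pytest.approx(value)]

    def test_equal_counts_give_zero_log_ratios(self):
        line = make_line({a: {1: 42} for a in AXES})
        hists = ratio_histograms([line])
        assert all(v.tolist() == [0.0] for v in hists.values())

    def test_mass_equals_line_count_per_pair(self):
        lines = [make_line(SINGLE_COUNTS, position=i) for i in range(1, 8)]
        hists = ratio_histograms(lines, threshold=5)
        assert all(len(v) == 7 for v in hists.values())

    def test_non_single_lines_excluded(self):
        ambiguous = make_line(
            {Axis.ROW: {1: 9, 2: 9}, Axis.COL: {1: 9, 2: 9},
             Axis.PR: {1: 9}, Axis.PC: {1: 9}}
        )
        hists = ratio_histograms([ambiguous])
        assert all(len(v) == 0 for v in hists.values())


class TestVoigtFit:
    def test_gaussian_samples_recovered(self, rng):
        mu, sigma = 0.4, 0.5
        values = rng.normal(mu, sigma, size=100_000)
        fit = fit_voigt(values, bin_width=0.05)
        assert abs(fit.center - mu) < 3 * max(fit.stderr[1], sigma / math.sqrt(len(values)))
        assert fit.gamma < 3 * (fit.stderr[3] if np.isfinite(fit.stderr[3]) else 0) + 0.02
        assert abs(fit.sigma - sigma) < 0.05

    def test_lorentzian_samples_recovered(self, rng):
        x0, gamma = -0.2, 0.3
        values = x0 + gamma * rng.standard_cauchy(size=100_000)
        fit = fit_voigt(values, bin_width=0.05)
        assert abs(fit.center - x0) < 3 * fit.stderr[1] + 0.02
        assert abs(fit.gamma - gamma) < 3 * (fit.stderr[3] if np.isfinite(fit.stderr[3]) else 0.02) + 0.03
        assert fit.sigma < 0.1

    def test_symmetric_data_center_near_median(self, rng):
        values = rng.normal(1.0, 0.3, size=50_000)
        fit = fit_voigt(values, bin_width=0.05)
        assert abs(fit.center - np.median(values)) < 0.02

    def test_degenerate_histogram_raises(self):
        with pytest.raises(ValueError, match="deterministic"):
            fit_voigt(np.zeros(1000))


@pytest.fixture(scope="module")
def fitted_model():
    rng = np.random.default_rng(77)
    model, _ = synthetic_ratio_model(rng)
    return model


class TestRatioDensity:
    @pytest.fixture()
    def model(self, fitted_model):
        return fitted_model

    def test_density_integrates_to_one(self, model):
        for pair in AXIS_PAIRS:
            assert model.integral(pair) == pytest.approx(1.0, abs=1e-6)

    def test_maximum_at_center_and_symmetry(self, model):
        fit = model.fits[(Axis.ROW, Axis.COL)]
        at_center = fit.density(fit.center)
        assert at_center >= fit.density(fit.center + 0.3)
        assert fit.density(fit.center + 0.2) == pytest.approx(
            fit.density(fit.center - 0.2), rel=1e-9
        )

    def test_floor_outside_support(self, model):
        assert model.density((Axis.ROW, Axis.COL), 1e9) == DENSITY_FLOOR
        with pytest.raises(ValueError):
            model.density((Axis.ROW, Axis.COL), -1.0)

    def test_too_few_lines_rejected(self):
        lines = [make_line(SINGLE_COUNTS, position=i) for i in range(1, 20)]
        with pytest.raises(ValueError, match="single-address lines"):
            RatioModel.fit(lines, threshold=1, min_fit_lines=200)


class TestEnumerateCandidates:
    def _surviving(self, sizes):
        return {
            axis: {i + 1: 50 - 10 * i for i in range(n)}
            for axis, n in zip(AXES, sizes)
        }

    @pytest.mark.parametrize("sizes,expected", [((2, 2, 2, 2), 16), ((1, 1, 1, 1), 1),
                                                ((3, 1, 1, 1), 3)])
    def test_cartesian_product_size(self, small_layout, sizes, expected):
        cands = enumerate_candidates(self._surviving(sizes), small_layout)
        assert len(cands) == expected

    def test_phantom_plates_pruned(self):
        layout = GridLayout(n_rows=8, n_cols=12, n_plate_rows=2, n_plate_cols=3, n_plates=5)
        surviving = {
            Axis.ROW: {1: 50},
            Axis.COL: {1: 50},
            Axis.PR: {1: 50, 2: 40},
            Axis.PC: {2: 50, 3: 40},
        }
        cands = enumerate_candidates(surviving, layout)
        # grid position (2,3) would be plate 6 which does not exist
        assert len(cands) == 3
        assert all((c[Axis.PR][0], c[Axis.PC][0]) != (2, 3) for c in cands)

    def test_empty_axis_gives_no_candidates(self, small_layout):
        surviving = self._surviving((2, 2, 2, 2))
        surviving[Axis.PC] = {}
        assert enumerate_candidates(surviving, small_layout) == []


class TestScoreCandidates:
    def test_top_m_rule_returns_two_calls_for_sixteen_combinations(self, small_layout):
        rng = np.random.default_rng(5)
        model, _ = synthetic_ratio_model(rng)
        surviving = {
            Axis.ROW: {1: 200, 2: 20},
            Axis.COL: {1: 300, 2: 30},
            Axis.PR: {1: 130, 2: 13},
            Axis.PC: {1: 200, 2: 20},
        }
        cands = enumerate_candidates(surviving, small_layout)
        assert len(cands) == 16
        calls = score_candidates(surviving, cands, model, small_layout)
        assert len(calls) == 2
        assert [c.rank for c in calls] == [1, 2]

    def test_high_low_pair_ranks_first_and_second(self, small_layout):
        # a planted ambiguous line: one high-abundance and one low-abundance
        # clone in unrelated wells; the pure high and pure low combinations
        # must outrank the twelve mixed ones
        rng = np.random.default_rng(6)
        model, base = synthetic_ratio_model(rng)
        lam_high, lam_low = 8.0, 1.0
        hits = 0
        n_rep = 500
        wells = (WellAddress(1, 1, 1), WellAddress(5, 4, 8))
        pools = [
            {p.axis: p.index for p in pools_for_well(w, small_layout)} for w in wells
        ]
        for _ in range(n_rep):
            surviving = {axis: {} for axis in AXES}
            for lam, pool_idx in zip((lam_high, lam_low), pools):
                for axis in AXES:
                    mean = base[axis] * lam * rng.lognormal(0.0, 0.35)
                    surviving[axis][pool_idx[axis]] = max(1, int(rng.poisson(mean)))
            calls = score_candidates(
                surviving, enumerate_candidates(surviving, small_layout),
                model, small_layout,
            )
            if {c.address for c in calls} == set(wells):
                hits += 1
        assert hits / n_rep >= 0.95

    def test_deterministic_tie_break(self, small_layout):
        rng = np.random.default_rng(7)
        model, _ = synthetic_ratio_model(rng)
        surviving = {
            Axis.ROW: {1: 50, 2: 50},
            Axis.COL: {1: 50},
            Axis.PR: {1: 50},
            Axis.PC: {1: 50},
        }
        calls = score_candidates(
            surviving, enumerate_candidates(surviving, small_layout), model, small_layout
        )
        again = score_candidates(
            surviving, enumerate_candidates(surviving, small_layout), model, small_layout
        )
        assert [c.address for c in calls] == [c.address for c in again]
        # equal scores and counts: lexicographic address order decides
        assert calls[0].address < calls[1].address


class TestFillFourthAxis:
    def test_highest_subthreshold_coordinate_taken(self):
        counts = dict(SINGLE_COUNTS)
        counts[Axis.PC] = {16: 3, 2: 1}
        completed = fill_fourth_axis(make_line(counts), threshold=5)
        assert completed[Axis.PC] == {16: 3}

    def test_empty_fourth_axis_stays_unmappable(self):
        counts = {a: v for a, v in SINGLE_COUNTS.items() if a is not Axis.PC}
        assert fill_fourth_axis(make_line(counts), threshold=5) is None

    def test_tie_prefers_smaller_pool_index(self):
        counts = dict(SINGLE_COUNTS)
        counts[Axis.PC] = {7: 2, 3: 2}
        completed = fill_fourth_axis(make_line(counts), threshold=5)
        assert completed[Axis.PC] == {3: 2}


class TestMergeConsecutive:
    def _entries(self, rows):
        return pd.DataFrame(rows, columns=["replicon", "position", "address_set", "reads"])

    def test_at_dinucleotide_rule(self):
        genome = {"chr1": "G" * 999 + "AT" + "G" * 999}
        entries = self._entries(
            [("chr1", 1000, ("P1_A01",), 10), ("chr1", 1001, ("P1_A01",), 4)]
        )
        merged = merge_consecutive(entries, genome)
        assert merged["position"].tolist() == [1000]  # the A of the AT
        assert merged["reads"].tolist() == [14]

    def test_ta_dinucleotide_takes_the_a(self):
        genome = {"chr1": "G" * 999 + "TA" + "G" * 999}
        entries = self._entries(
            [("chr1", 1000, ("P1_A01",), 10), ("chr1", 1001, ("P1_A01",), 4)]
        )
        merged = merge_consecutive(entries, genome)
        assert merged["position"].tolist() == [1001]

    def test_read_weighted_median_without_site(self):
        genome = {"chr1": "G" * 2000}
        entries = self._entries(
            [("chr1", 1000, ("P1_A01",), 5), ("chr1", 1001, ("P1_A01",), 1),
             ("chr1", 1002, ("P1_A01",), 5)]
        )
        merged = merge_consecutive(entries, genome)
        assert merged["position"].tolist() == [1001]
        assert merged["n_merged"].tolist() == [3]

    def test_singleton_and_gap_split(self):
        genome = {"chr1": "G" * 2000}
        entries = self._entries(
            [("chr1", 100, ("P1_A01",), 5), ("chr1", 500, ("P1_A01",), 5),
             ("chr1", 501, ("P2_B02",), 5)]
        )
        merged = merge_consecutive(entries, genome)
        assert len(merged) == 3  # gap > 1 and differing addresses keep runs apart


class TestSolveTable:
    def test_deterministic_given_inputs(self, det_pipeline):
        layout = det_pipeline["layout"]
        a = solve_table(det_pipeline["table"], 1, layout, None).catalogue
        b = solve_table(det_pipeline["table"], 1, layout, None).catalogue
        assert a.equals(b)

    def test_class_counts_partition_table(self, det_pipeline):
        res = solve_table(det_pipeline["table"], 1, det_pipeline["layout"], None)
        assert sum(res.class_counts.values()) == len(det_pipeline["table"])
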