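import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diazosip.single_cell import (
    CellGeometry,
    RoiMeasurement,
    accumulate_planes,
    biovolume,
    carbon_content,
    cell_rate,
    convergence_check,
    fish_effect_compare,
    isotope_fraction,
    nitrogen_content,
    passes_qc,
    process_rois,
    ratio_poisson_error,
    roi_geometry,
    rois_from_table,
)


def roi(minor, major, cell_id="c1", population="popA"):
    return RoiMeasurement(
        cell_id=cell_id,
        population=population,
        planes={"15N": np.asarray(minor), "14N": np.asarray(major)},
    )


class TestRoiMeasurement:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative integers"):
            roi([10, -1], [100, 100])

    def test_rejects_unequal_plane_lists(self):
        with pytest.raises(ValueError, match="equal length"):
            roi([10], [100, 100])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            roi([], [])


class TestAccumulatePlanes:
    def test_addition(self):
        totals = accumulate_planes(roi([10, 12], [1000, 1100]))
        assert totals == {"15N": 22, "14N": 2100}

    def test_single_plane_is_itself(self):
        assert accumulate_planes(roi([5], [500])) == {"15N": 5, "14N": 500}

    def test_fifty_identical_planes(self):
        totals = accumulate_planes(roi([2] * 50, [200] * 50))
        assert totals == {"15N": 100, "14N": 10000}


class TestIsotopeFraction:
    def test_zero_minor(self):
        assert isotope_fraction(0, 1000) == 0.0

    def test_zero_major(self):
        assert isotope_fraction(1000, 0) == 1.0

    def test_near_natural_abundance(self):
        assert isotope_fraction(37, 10063) == pytest.approx(0.003663366, rel=1e-6)

    def test_zero_total_flagged_missing(self):
        assert math.isnan(isotope_fraction(0, 0))

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 1000), st.integers(1, 100000)), min_size=2, max_size=20
        ),
        n_chunks=st.integers(1, 5),
    )
    def test_plane_partition_invariance(self, counts, n_chunks):
        # fraction on accumulated counts == count-weighted mean over any chunking
        minor = np.array([c[0] for c in counts])
        major = np.array([c[1] for c in counts])
        total_frac = isotope_fraction(minor.sum(), major.sum())
        chunks = np.array_split(np.arange(len(counts)), n_chunks)
        m_sum = sum(minor[ix].sum() for ix in chunks if ix.size)
        mj_sum = sum(major[ix].sum() for ix in chunks if ix.size)
        assert isotope_fraction(m_sum, mj_sum) == pytest.approx(total_frac, rel=1e-12)


class TestPoissonError:
    def test_formula_fail_case(self):
        err = ratio_poisson_error(100, 10000)
        assert err == pytest.approx(0.100499, rel=1e-5)
        assert not passes_qc(100, 10000)

    def test_formula_pass_case(self):
        err = ratio_poisson_error(1e6, 1e8)
        assert err == pytest.approx(math.sqrt(1e-6 + 1e-8), rel=1e-9)
        assert passes_qc(1e6, 1e8)

    def test_minor_dominated_asymptote(self):
        err = ratio_poisson_error(1e12, 10000)
        assert err == pytest.approx(math.sqrt(1 / 10000), rel=1e-3)

    def test_zero_minor_fails_qc(self):
        assert math.isinf(ratio_poisson_error(0, 1000))
        assert not passes_qc(0, 1000)

    def test_threshold_is_strict(self):
        # error exactly 0.05: 1/800 + 1/800 = 0.0025
        assert ratio_poisson_error(800, 800) == pytest.approx(0.05, rel=1e-12)
        assert not passes_qc(800, 800)

    def test_qc_calibration_under_poisson_sampling(self):
        # ROIs simulated at 4% true ratio error essentially always pass,
        # at 6% essentially always fail (estimator SD is ~2-3% relative)
        rng = np.random.default_rng(5)
        f = 0.01
        for target, expect_pass in ((0.04, True), (0.06, False)):
            total = (1 / f + 1 / (1 - f)) / target**2
            passed = [
                passes_qc(rng.poisson(f * total), rng.poisson((1 - f) * total))
                for _ in range(300)
            ]
            frac = np.mean(passed)
            assert (frac >= 0.95) if expect_pass else (frac <= 0.05)


class TestGeometryAndContents:
    def test_sphere_special_case(self):
        assert biovolume(CellGeometry(2.0, 2.0)) == pytest.approx(4.18879, rel=1e-5)

    def test_prolate_formula(self):
        assert biovolume(CellGeometry(2.0, 4.0)) == pytest.approx(8.37758, rel=1e-5)

    def test_cubic_scaling(self):
        bv1 = biovolume(CellGeometry(1.5, 3.0))
        bv2 = biovolume(CellGeometry(3.0, 6.0))
        assert bv2 == pytest.approx(8 * bv1)

    def test_invalid_geometry(self):
        with pytest.raises(ValueError):
            CellGeometry(0.0, 1.0)
        with pytest.raises(ValueError):
            CellGeometry(3.0, 2.0)

    def test_roi_geometry_orders_axes(self):
        g = roi_geometry(4.0, 2.0)
        assert (g.width, g.length, g.source) == (2.0, 4.0, "roi")

    def test_carbon_content_zero_biovolume(self):
        assert carbon_content(0.0) == 0.0

    def test_carbon_content_unit_biovolume(self):
        assert carbon_content(1.0) == pytest.approx(0.433 * 1000 / 12, rel=1e-12)

    def test_carbon_content_power_law(self):
        assert carbon_content(100.0) == pytest.approx(1920.02, rel=1e-4)

    def test_carbon_content_increasing_and_concave(self):
        bv = np.linspace(0.5, 200, 50)
        c = np.array([carbon_content(v) for v in bv])
        assert np.all(np.diff(c) > 0)
        # concave power (exponent < 1): per-biovolume content decreases
        assert np.all(np.diff(c / bv) < 0)

    def test_nitrogen_content(self):
        assert nitrogen_content(8.6, 8.6) == 1.0
        assert nitrogen_content(0.0, 8.6) == 0.0
        assert nitrogen_content(36.083, 8.6) == pytest.approx(4.1957, rel=1e-4)
        with pytest.raises(ValueError):
            nitrogen_content(1.0, 0.0)


class TestCellRate:
    def test_zero_excess(self):
        assert cell_rate(0.0, 29.6, 10.0, 1.0) == 0.0

    def test_full_label_equilibration_upper_bound(self):
        assert cell_rate(29.6, 29.6, 10.0, 2.0) == pytest.approx(5.0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cell_rate(1.0, 0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            cell_rate(1.0, 29.6, 10.0, 0.0)
        with pytest.raises(ValueError):
            cell_rate(1.0, 29.6, 0.0, 1.0)


class TestConvergence:
    def test_identical_fractions_adequate_at_two(self):
        _, _, n = convergence_check([0.01] * 10)
        assert n == 2

    def test_alternating_extremes_never_converge(self):
        _, _, n = convergence_check([0.0, 1.0] * 5, threshold=0.05)
        assert n is None

    def test_single_cell_flagged_insufficient(self):
        _, _, n = convergence_check([0.01])
        assert n is None

    def test_noisy_population_converges_before_full_sample(self):
        rng = np.random.default_rng(1)
        fracs = rng.normal(0.01, 0.003, size=50)  # CV 30%
        _, _, n = convergence_check(fracs, threshold=0.05)
        assert n is not None and n < 50


class TestFishEffectCompare:
    def test_identical_groups(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0.01, 0.001, size=20)
        res = fish_effect_compare(vals, vals)
        assert res.sufficient
        assert res.pvalue > 0.9
        assert res.median_a == res.median_b

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.01, 0.001, size=15)
        b = rng.normal(0.015, 0.001, size=15)  # shift = 5 SD
        res = fish_effect_compare(a, b)
        assert res.pvalue < 0.01

    def test_small_group_flagged(self):
        res = fish_effect_compare([0.1, 0.2], [0.1, 0.2, 0.3])
        assert not res.sufficient
        assert math.isnan(res.pvalue)


class TestProcessRois:
    @staticmethod
    def _table(fraction_n=0.01, fraction_c=0.02, counts=20000, planes=10, cell_id="c1"):
        rows = []
        for sp, f in (("15N", fraction_n), ("14N", 1 - fraction_n),
                      ("13C", fraction_c), ("12C", 1 - fraction_c)):
            for p in range(planes):
                rows.append({"cell_id": cell_id, "population": "popA", "plane_index": p,
                             "species": sp, "counts": int(round(f * counts))})
        return pd.DataFrame(rows)

    def test_deterministic_counts_recover_fraction(self):
        table = self._table()
        geom = pd.DataFrame([{"cell_id": "c1", "population": "popA",
                              "width_um": 2.0, "length_um": 4.0}])
        out = process_rois(table, geom, at_excess_15n_medium=29.6,
                          at_excess_13c_medium=6.9, time_d=1.0)
        row = out.iloc[0]
        assert row.fraction_15N == pytest.approx(0.01, rel=1e-9)
        assert row.passed_qc
        # independent hand-chain: excess -> rate through contents
        bv = math.pi / 6 * 4 * 4
        c_cell = 0.433 * bv**0.863 * 1000 / 12
        n_cell = c_cell / 8.6
        expected = (1.0 - 0.3663) / 29.6 * n_cell / 1.0
        assert row.rate_N_fmol_d == pytest.approx(expected, rel=1e-9)

    def test_inactive_cell_has_near_zero_rate(self):
        # a cell at natural abundance: excess clips to ~0 and so does the rate
        table = self._table(fraction_n=0.003663, fraction_c=0.0111)
        geom = pd.DataFrame([{"cell_id": "c1", "population": "popA",
                              "width_um": 2.0, "length_um": 4.0}])
        out = process_rois(table, geom, at_excess_15n_medium=29.6,
                          at_excess_13c_medium=6.9, time_d=1.0)
        row = out.iloc[0]
        assert row.rate_N_fmol_d == pytest.approx(0.0, abs=1e-3)
        assert not row.significantly_enriched_15N

    def test_population_median_geometry_fallback(self):
        table = self._table(cell_id="c9")
        widths = [1.0, 2.0, 3.0]
        geom = pd.DataFrame(
            [{"population": "popA", "width_um": w, "length_um": 2 * w} for w in widths]
        )
        out = process_rois(table, geom, at_excess_15n_medium=29.6,
                          at_excess_13c_medium=6.9, time_d=1.0)
        assert out.iloc[0].biovolume_um3 == pytest.approx(math.pi / 6 * 4 * 4)

    def test_rois_from_table_round_trip(self):
        table = self._table(planes=3)
        rois = rois_from_table(table)
        assert len(rois) == 1
        assert rois[0].n_planes == 3
        assert set(rois[0].planes) == {"15N", "14N", "13C", "12C"}
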