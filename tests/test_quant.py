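from math import pi

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from aqp_profiler.quant import (CtTable, PfResult, SwellingSeries, compute_pf,
                                expression_matrix, fold_change_ddct,
                                pf_group_comparison, relative_expression_dct,
                                sphere_geometry)
from aqp_profiler.synthetic import make_ct_table, make_swelling_series


def ct_table(rows, reference="actin"):
    return CtTable(pd.DataFrame(rows, columns=["gene", "sample", "bio_rep",
                                               "tech_rep", "ct"]), reference)


def simple_table(gene_ct, ref_ct, sample="leaf"):
    rows = [("actin", sample, 1, 1, ref_ct), ("aqp", sample, 1, 1, gene_ct)]
    return ct_table(rows)


class TestDct:
    def test_equal_ct_gives_unity(self):
        assert relative_expression_dct(simple_table(20, 20), "aqp", "leaf") == 1.0

    def test_one_cycle_below_reference_doubles(self):
        assert relative_expression_dct(simple_table(19, 20), "aqp", "leaf") == 2.0

    def test_missing_reference_is_error(self):
        table = simple_table(19, 20)
        with pytest.raises(KeyError):
            relative_expression_dct(table, "aqp", "root")

    @given(st.floats(min_value=-5, max_value=5))
    def test_invariant_under_constant_ct_shift(self, shift):
        base = simple_table(18.0, 21.0)
        shifted = simple_table(18.0 + shift, 21.0 + shift)
        assert relative_expression_dct(shifted, "aqp", "leaf") == pytest.approx(
            relative_expression_dct(base, "aqp", "leaf"))

    def test_technical_replicates_averaged_within_biological(self):
        rows = [("actin", "leaf", 1, 1, 20), ("actin", "leaf", 1, 2, 20),
                ("actin", "leaf", 2, 1, 20),
                ("aqp", "leaf", 1, 1, 18), ("aqp", "leaf", 1, 2, 20),
                ("aqp", "leaf", 2, 1, 21)]
        # bio means: (19, 21) -> grand mean 20
        assert relative_expression_dct(ct_table(rows), "aqp", "leaf") == 1.0


class TestDdct:
    def _two_sample(self, treated_gene_ct):
        rows = [("actin", "control", 1, 1, 20.0), ("aqp", "control", 1, 1, 22.0),
                ("actin", "treated", 1, 1, 20.0),
                ("aqp", "treated", 1, 1, treated_gene_ct)]
        return ct_table(rows)

    def test_treated_equals_control_gives_unity(self):
        assert fold_change_ddct(self._two_sample(22.0), "aqp", "treated",
                                "control") == 1.0

    def test_two_cycle_drop_gives_fourfold(self):
        assert fold_change_ddct(self._two_sample(20.0), "aqp", "treated",
                                "control") == 4.0

    def test_log_fold_antisymmetric_under_sample_swap(self):
        table = self._two_sample(19.5)
        fwd = fold_change_ddct(table, "aqp", "treated", "control")
        rev = fold_change_ddct(table, "aqp", "control", "treated")
        assert np.log2(fwd) == pytest.approx(-np.log2(rev))

    @given(st.floats(min_value=-5, max_value=5))
    def test_invariant_under_per_sample_ct_shift(self, shift):
        base = self._two_sample(20.0)
        shifted = base.data.copy()
        shifted.loc[shifted["sample"] == "treated", "ct"] += shift
        assert fold_change_ddct(CtTable(shifted, "actin"), "aqp", "treated",
                                "control") == pytest.approx(4.0)


class TestMatrix:
    def test_single_cell(self):
        m = expression_matrix(simple_table(19, 20), "dct")
        assert m.shape == (1, 1)
        assert m.loc["aqp", "leaf"] == 2.0

    def test_ddct_all_equal_is_zero_after_log2(self):
        rows = [("actin", s, 1, 1, 20.0) for s in ("control", "salt")] + \
               [("aqp", s, 1, 1, 23.0) for s in ("control", "salt")]
        m = expression_matrix(ct_table(rows), "ddct", control_sample="control",
                              log2=True)
        assert np.allclose(m.values, 0.0)

    def test_cells_match_scalar_operations(self):
        table = make_ct_table({"g1": {"c": 1.0, "t": 3.0},
                               "g2": {"c": 1.0, "t": 0.25}}, noise_sd=0.3, seed=4)
        m = expression_matrix(table, "ddct", control_sample="c")
        for gene in ("g1", "g2"):
            assert m.loc[gene, "t"] == pytest.approx(
                fold_change_ddct(table, gene, "t", "c"))

    def test_missing_cells_stay_nan(self):
        rows = [("actin", "a", 1, 1, 20.0), ("actin", "b", 1, 1, 20.0),
                ("g1", "a", 1, 1, 19.0)]
        m = expression_matrix(ct_table(rows), "dct")
        assert np.isnan(m.loc["g1", "b"])
        assert m.loc["g1", "a"] == 2.0


class TestSphere:
    def test_unit_sphere(self):
        v, s = sphere_geometry(pi)
        assert v == pytest.approx(4 * pi / 3)
        assert s == pytest.approx(4 * pi)

    @given(st.floats(min_value=1e-6, max_value=1e4))
    def test_volume_surface_ratio_is_radius_over_three(self, area):
        v, s = sphere_geometry(area)
        r = (area / pi) ** 0.5
        assert v / s == pytest.approx(r / 3)

    def test_doubling_area_scales_volume_by_two_to_three_halves(self):
        v1, _ = sphere_geometry(2.0)
        v2, _ = sphere_geometry(4.0)
        assert v2 / v1 == pytest.approx(2 ** 1.5)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            sphere_geometry(0.0)


def linear_series(b_per_min, area0=0.01, n=21, osm_in=2e-4, osm_out=0.4e-4):
    """Series whose relative volume is exactly 1 + b*t (t in minutes)."""
    times = np.linspace(0, 10, n)
    v0, _ = sphere_geometry(area0)
    volumes = v0 * (1 + b_per_min * times)
    radii = (volumes * 3 / (4 * pi)) ** (1 / 3)
    return SwellingSeries(oocyte_id="o", times=tuple(times),
                          areas=tuple(pi * radii ** 2),
                          osm_in=osm_in, osm_out=osm_out)


class TestComputePf:
    def test_exactly_linear_series_closed_form(self):
        b = 0.006  # per minute
        series = linear_series(b)
        res = compute_pf(series, method="linear")
        assert res.slope == pytest.approx(b / 60.0, rel=1e-9)
        v0, s0 = sphere_geometry(series.areas[0])
        expected = v0 * (b / 60) / (s0 * 18.0 * (series.osm_in - series.osm_out))
        assert res.pf == pytest.approx(expected, rel=1e-9)

    def test_zero_slope_gives_zero_pf(self):
        series = linear_series(0.0)
        assert compute_pf(series).pf == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pf_true", [1e-3, 5e-3])
    def test_round_trip_recovers_planted_pf(self, pf_true):
        series = make_swelling_series(pf_true, dt_s=0.25)
        res = compute_pf(series)
        assert res.pf == pytest.approx(pf_true, rel=0.02)

    def test_dimensional_consistency_under_unit_rescaling(self):
        series = make_swelling_series(2e-3)
        c = 2.0
        # lengths x c: areas x c^2, V0/S0 x c; keeping Vw fixed, the product
        # Vw * dOsm must scale by c for the reported number to be unchanged
        scaled = SwellingSeries(oocyte_id="o",
                                times=series.times,
                                areas=tuple(a * c ** 2 for a in series.areas),
                                osm_in=series.osm_in * c,
                                osm_out=series.osm_out * c)
        assert compute_pf(scaled).pf == pytest.approx(compute_pf(series).pf,
                                                      rel=1e-9)

    def test_zero_gradient_is_error(self):
        series = linear_series(0.001)
        bad = SwellingSeries(oocyte_id="o", times=series.times,
                             areas=series.areas, osm_in=1e-4, osm_out=1e-4)
        with pytest.raises(ValueError, match="gradient"):
            compute_pf(bad)

    def test_too_few_points_is_error(self):
        s = SwellingSeries(oocyte_id="o", times=(0.0, 5.0), areas=(1.0, 1.1),
                           osm_in=2e-4, osm_out=1e-4)
        with pytest.raises(ValueError, match="three"):
            compute_pf(s)


def _pf_result(pf, oid, group):
    return PfResult(oocyte_id=oid, pf=pf, v0=1.0, s0=1.0, slope=0.0, group=group)


class TestGroupComparison:
    def test_identical_groups_fold_one_p_near_one(self):
        groups = {"water": [_pf_result(1e-3, f"w{i}", "water") for i in range(4)],
                  "aqp": [_pf_result(1e-3, f"a{i}", "aqp") for i in range(4)]}
        # tiny jitter so the within-group variance is nonzero
        groups["water"][0] = _pf_result(1.0001e-3, "w0", "water")
        groups["aqp"][0] = _pf_result(1.0001e-3, "a0", "aqp")
        cmp = pf_group_comparison(groups)
        assert cmp.fold_changes["aqp"] == pytest.approx(1.0, rel=1e-3)
        assert cmp.anova_p > 0.9

    def test_f_statistic_matches_hand_computation(self):
        groups = {"water": [_pf_result(v, f"w{i}", "water")
                            for i, v in enumerate([1.0, 2.0, 3.0])],
                  "aqp": [_pf_result(v, f"a{i}", "aqp")
                          for i, v in enumerate([4.0, 5.0, 6.0])]}
        cmp = pf_group_comparison(groups)
        # grand mean 3.5; SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5, df 1
        # SSW = 2 + 2 = 4, df 4 -> F = 13.5 / 1 = 13.5
        assert cmp.f_statistic == pytest.approx(13.5)

    def test_planted_twofold_difference_detected(self):
        groups = {"water": [], "aqp": []}
        for i in range(6):
            w = make_swelling_series(1e-3, noise_sd=0.002, seed=10 + i,
                                     oocyte_id=f"w{i}", group="water")
            a = make_swelling_series(2e-3, noise_sd=0.002, seed=50 + i,
                                     oocyte_id=f"a{i}", group="aqp")
            groups["water"].append(compute_pf(w))
            groups["aqp"].append(compute_pf(a))
        cmp = pf_group_comparison(groups)
        assert cmp.fold_changes["aqp"] == pytest.approx(2.0, rel=0.15)
        assert cmp.anova_p < 0.05
        assert cmp.lsd_p[("aqp", "water")] < 0.05

    def test_small_group_rejected(self):
        groups = {"water": [_pf_result(1.0, "w0", "water")],
                  "aqp": [_pf_result(1.0, "a0", "aqp"),
                          _pf_result(1.1, "a1", "aqp")]}
        with pytest.raises(ValueError, match="fewer than two"):
            pf_group_comparison(groups)
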