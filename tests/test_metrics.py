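"""Item geometry, amount estimators, weighted tests, Holm correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from woodpool.metrics import (
    compare_managed_unmanaged,
    item_surface_areas,
    item_volume,
    landscape_weighted_mean,
    landscape_weights,
    line_intersect_density,
    line_intersect_volume,
    plot_density_estimate,
    sequential_bonferroni,
    stand_amounts,
    weighted_mean_se,
    weighted_t_test,
)


class TestItemGeometry:
    def test_cylinder_volume(self):
        assert item_volume(20, 2) == pytest.approx(0.06283, abs=1e-5)
        assert item_volume(10, 0.4) == pytest.approx(0.003142, abs=1e-6)

    def test_volume_vanishes_with_diameter(self):
        assert item_volume(1e-6, 2) < 1e-12

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            item_volume(0, 1)
        with pytest.raises(ValueError):
            item_surface_areas(10, -1, 0.5)

    def test_surface_split(self):
        bark, barkfree = item_surface_areas(20, 2, 0.5)
        assert bark == pytest.approx(0.6283, abs=1e-4)
        assert barkfree == pytest.approx(0.6283, abs=1e-4)
        bark, barkfree = item_surface_areas(20, 2, 1.0)
        assert barkfree == 0.0

    def test_bark_area_linear_in_diameter(self):
        # lateral area scales linearly with d: 30 cm vs 5 cm -> 6:1
        a30, _ = item_surface_areas(30, 3, 1.0)
        a5, _ = item_surface_areas(5, 3, 1.0)
        assert a30 / a5 == pytest.approx(6.0)


class TestPlotAndTransectEstimates:
    def test_plot_density_arithmetic(self):
        assert plot_density_estimate([0.01] * 3, 0.1) == pytest.approx(0.3)
        assert plot_density_estimate([], 0.1) == 0.0
        with pytest.raises(ValueError):
            plot_density_estimate([1.0], 0.0)

    def test_line_intersect_single_crossing(self):
        # Van Wagner estimator, one 10 cm crossing on a 100 m transect
        assert line_intersect_volume([10.0], 100.0) == pytest.approx(1.2337, abs=1e-4)
        assert line_intersect_volume([], 100.0) == 0.0
        with pytest.raises(ValueError):
            line_intersect_volume([10.0], 0.0)

    def test_attribute_estimator_reduces_to_volume(self):
        d = np.array([12.0, 25.0, 18.0])
        ln = np.array([3.0, 7.0, 5.0])
        vols = item_volume(d, ln)
        assert line_intersect_density(vols, ln, 400.0) == pytest.approx(
            line_intersect_volume(d, 400.0), rel=1e-12
        )

    def test_stand_totals_additive_over_tree_species(self, landscape):
        stands, items = landscape
        for measure in ("volume_m3", "bark_area_m2"):
            total = stand_amounts(items, stands, measure)
            per_sp = stand_amounts(items, stands, measure, by_tree_species=True)
            merged = (
                per_sp.groupby(["stand_id", "dw_type"])["amount_per_ha"].sum()
                .rename("sum_sp").reset_index()
                .merge(total, on=["stand_id", "dw_type"])
            )
            assert np.allclose(merged["sum_sp"], merged["amount_per_ha"], rtol=1e-9)


class TestLandscapeWeighting:
    def test_single_type_reduces_to_ordinary_mean(self):
        x = np.array([1.0, 4.0, 7.0])
        mean, _ = weighted_mean_se(x, np.full(3, 0.2))
        assert mean == pytest.approx(x.mean())

    def test_area_weighted_convex_combination(self):
        stands = pd.DataFrame(
            {"stand_id": ["a", "b"], "stand_type": ["young", "old"]}
        )
        w = landscape_weights(stands, {"young": 75.0, "old": 25.0})
        mean, _ = weighted_mean_se([4.0, 8.0], [w["a"], w["b"]])
        assert mean == pytest.approx(5.0)

    def test_equal_areas_unequal_counts_average_type_means(self):
        # algebra: weight (A/2)/n_k makes the overall mean the mean of
        # per-type means regardless of how many stands each type has
        stands = pd.DataFrame(
            {
                "stand_id": ["a", "b", "c"],
                "stand_type": ["young", "young", "old"],
            }
        )
        w = landscape_weights(stands, {"young": 50.0, "old": 50.0})
        mean, _ = weighted_mean_se([2.0, 4.0, 10.0], w[["a", "b", "c"]])
        assert mean == pytest.approx(((2 + 4) / 2 + 10) / 2)


class TestWeightedTTest:
    def test_unit_weights_reduce_to_welch(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2, 9)
        res = weighted_t_test(a, np.ones(12), b, np.ones(9))
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        assert res.df == pytest.approx(ref.df, rel=1e-12)

    def test_identical_groups_give_t_zero(self):
        x = [1.0, 2.0, 3.0]
        res = weighted_t_test(x, [1, 1, 1], x, [1, 1, 1])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_bruteforce_formula_transcription(self):
        """Independent step-by-step recomputation of the weighted Welch
        statistic on an unequal-weight fixture."""
        xa = [3.0, 5.0, 9.0, 4.0]
        wa = [0.5, 2.0, 1.0, 0.5]
        xb = [8.0, 12.0, 10.0]
        wb = [1.0, 3.0, 2.0]

        def moments(x, w):
            x, w = np.array(x), np.array(w)
            w = w * len(x) / w.sum()
            m = (w * x).sum() / len(x)
            v = (w * (x - m) ** 2).sum() / (len(x) - 1)
            return len(x), m, v

        na, ma, va = moments(xa, wa)
        nb, mb, vb = moments(xb, wb)
        t = (ma - mb) / np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p = 2 * stats.t.sf(abs(t), df)
        res = weighted_t_test(xa, wa, xb, wb)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_degenerate_group_is_flagged(self):
        res = weighted_t_test([1.0, 1.0], [1, 1], [1.0, 2.0], [1, 1])
        assert res.degenerate
        assert np.isnan(res.p)


class TestSequentialBonferroni:
    def test_holm_hand_example(self):
        out = sequential_bonferroni([0.01, 0.03, 0.04], alpha=0.05)
        assert list(out["reject"]) == [True, False, False]
        assert np.allclose(out["threshold"], [0.05 / 3, 0.05 / 2, 0.05])

    def test_all_ones_none_rejected(self):
        assert not sequential_bonferroni([1.0, 1.0, 1.0]).reject.any()

    def test_single_test_plain_alpha(self):
        assert sequential_bonferroni([0.049], alpha=0.05)["reject"].iloc[0]
        assert not sequential_bonferroni([0.051], alpha=0.05)["reject"].iloc[0]

    @settings(deadline=None, max_examples=40)
    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        alpha=st.floats(0.001, 0.2),
    )
    def test_holm_subset_of_unadjusted_and_monotone(self, ps, alpha):
        out = sequential_bonferroni(ps, alpha)
        # Holm rejections are a subset of the unadjusted-alpha rejections
        assert (out.loc[out["reject"], "p"] <= alpha).all()
        # monotone in alpha
        wider = sequential_bonferroni(ps, min(1.0, alpha * 2))
        assert (wider["reject"] | ~out["reject"]).all()


def test_managed_unmanaged_table(landscape, sim_config):
    stands, items = landscape
    out = compare_managed_unmanaged(
        items, stands, sim_config.landscape_area_by_type
    )
    assert set(out["dw_type"]) == {"FWD", "stump", "log", "snag"}
    assert len(out) == 16  # 4 overall + 12 per-tree-species tests
    ok = out["p"].dropna()
    assert ((ok >= 0) & (ok <= 1)).all()
    # direction encoded by the generator: more stumps in managed stands,
    # more snags in unmanaged stands
    overall = out[out["tree_species"] == "all"].set_index("dw_type")
    assert overall.loc["stump", "mean_managed"] > overall.loc["stump", "mean_unmanaged"]
    assert overall.loc["snag", "mean_unmanaged"] > overall.loc["snag", "mean_managed"]


def test_old_managed_stands_filtered(landscape, sim_config):
    stands, items = landscape
    out = compare_managed_unmanaged(
        items, stands, sim_config.landscape_area_by_type, max_managed_age=30.0
    )
    # with the age cut at 30 only clearcuts and young stands remain managed;
    # the result table is still complete
    assert len(out) == 16


def test_landscape_weighted_mean_table(landscape, sim_config):
    stands, items = landscape
    est = stand_amounts(items, stands, "volume_m3")
    means = landscape_weighted_mean(est, stands, sim_config.landscape_area_by_type)
    assert set(means["mclass"]) == {"managed", "unmanaged"}
    assert (means["se"] >= 0).all()
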