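"""Densities, subsample standardization, quality scores, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from woodpool.config import DW_TYPES
from woodpool.quality import (
    dunn_posthoc,
    kruskal_wallis,
    occurrence_counts,
    quality_analysis,
    quality_score,
    species_density,
    standardize_subsamples,
)
from woodpool.synthetic import ObservationTable


def _items(rows):
    df = pd.DataFrame(
        rows,
        columns=["item_id", "dw_type", "tree_species", "diameter_cm",
                 "length_m", "bark_fraction"],
    )
    df["stand_id"] = "s1"
    df["stand_type"] = "old"
    return df


@pytest.fixture()
def five_items():
    return _items(
        [[f"i{k}", "log", "pine", 20.0, 2.0, 0.5] for k in range(5)]
    )


class TestSpeciesDensity:
    def test_fungi_fraction_of_items(self, five_items):
        obs = pd.DataFrame({"species": ["f"] * 2, "item_id": ["i0", "i3"]})
        dens = species_density(ObservationTable("fungi", obs), five_items)
        assert dens["f"] == pytest.approx(0.4)

    def test_lichen_cover_per_area(self, five_items):
        # one item surveyed: bark-free area = pi*0.2*2*0.5 m^2; force the
        # denominator to 1 m^2 by scaling cover on two items to sum 50 cm^2
        items = _items([["i0", "log", "pine", 20.0, 2.0, 0.0]])
        area_cm2 = np.pi * 0.2 * 2.0 * 1e4
        obs = pd.DataFrame(
            {"species": ["l"], "item_id": ["i0"], "cover_cm2": [0.005 * area_cm2]}
        )
        dens = species_density(ObservationTable("lichens", obs), items)
        assert dens["l"] == pytest.approx(0.005)

    def test_beetles_per_bark_area(self, five_items):
        samples = pd.DataFrame(
            {"sample_id": ["b0", "b1"], "item_id": ["i0", "i1"],
             "bark_area_m2": [1.5, 1.5]}
        )
        obs = pd.DataFrame(
            {"species": ["c", "c"], "sample_id": ["b0", "b1"],
             "item_id": ["i0", "i1"], "count": [10, 2]}
        )
        dens = species_density(
            ObservationTable("beetles", obs, samples), five_items
        )
        assert dens["c"] == pytest.approx(4.0)

    def test_zero_effort_rejected(self, five_items):
        obs = pd.DataFrame({"species": ["f"], "item_id": ["i0"]})
        with pytest.raises(ValueError):
            species_density(ObservationTable("fungi", obs), five_items, unit_ids=[])


def _mixed_items(n_per_type=8):
    rows = []
    dims = {"FWD": (5.0, 1.0), "stump": (25.0, 0.4), "log": (20.0, 3.0),
            "snag": (20.0, 4.0)}
    k = 0
    for dw in DW_TYPES:
        d, ln = dims[dw]
        for _ in range(n_per_type):
            rows.append([f"i{k}", dw, "pine", d, ln, 0.5])
            k += 1
    return _items(rows)


class TestStandardizeSubsamples:
    def test_single_substrate_species_row(self):
        items = _mixed_items()
        stump_ids = items.loc[items["dw_type"] == "stump", "item_id"]
        obs = pd.DataFrame(
            {"species": "s_only", "item_id": stump_ids.iloc[:6]}
        )
        rdm = standardize_subsamples(
            ObservationTable("fungi", obs), items, seed=0
        )
        # row order is (FWD, stump, log, snag)
        assert np.allclose(
            rdm.matrix.loc["s_only", ["FWD", "stump", "log", "snag"]],
            [0.0, 1.0, 0.0, 0.0],
        )

    def test_equal_effort_reduces_to_direct_ratios(self):
        # identical item counts per substrate: the fungal subsample is the
        # full sample, so relative densities equal direct density ratios
        items = _mixed_items(6)
        ids = {dw: items.loc[items["dw_type"] == dw, "item_id"] for dw in DW_TYPES}
        obs = pd.concat(
            [
                pd.DataFrame({"species": "x", "item_id": ids["log"].iloc[:6]}),
                pd.DataFrame({"species": "x", "item_id": ids["snag"].iloc[:3]}),
            ]
        )
        rdm = standardize_subsamples(
            ObservationTable("fungi", obs), items, seed=1
        )
        row = rdm.matrix.loc["x"]
        assert row["log"] == pytest.approx(2 / 3)
        assert row["snag"] == pytest.approx(1 / 3)

    def test_rows_sum_to_one_and_filter_applied(self, communities, landscape):
        _, items = landscape
        for taxon, table in communities.items():
            rdm = standardize_subsamples(table, items, seed=3)
            assert np.allclose(rdm.matrix.sum(axis=1), 1.0, atol=1e-9)
            assert (rdm.occurrences >= 5).all()

    def test_determinism_under_seed(self, communities, landscape):
        _, items = landscape
        table = communities["lichens"]
        a = standardize_subsamples(table, items, seed=7)
        b = standardize_subsamples(table, items, seed=7)
        pd.testing.assert_frame_equal(a.matrix, b.matrix)

    def test_missing_substrate_reported(self):
        items = _items([["i0", "log", "pine", 20.0, 2.0, 0.5]])
        obs = pd.DataFrame({"species": ["f"] * 5, "item_id": ["i0"] * 5})
        with pytest.raises(ValueError, match="FWD"):
            standardize_subsamples(ObservationTable("fungi", obs), items)

    def test_subsample_mean_variance_shrinks(self, communities, landscape):
        """More subsamples -> the averaged densities stabilize (variance of
        the subsample mean shrinks roughly like 1/k on fixed data)."""
        _, items = landscape
        table = communities["beetles"]

        def spread(n_sub, reps=6):
            mats = [
                standardize_subsamples(
                    table, items, n_subsamples=n_sub, seed=100 + r
                ).matrix
                for r in range(reps)
            ]
            stacked = np.stack([m.to_numpy() for m in mats])
            return stacked.std(axis=0).mean()

        assert spread(12) < spread(2)


class TestQualityScore:
    def test_single_specialist(self):
        mat = pd.DataFrame([[0, 0, 0, 1.0]], columns=list(DW_TYPES), index=["s"])
        assert quality_score(mat).tolist() == [0, 0, 0, 1.0]

    def test_generalists_split_evenly(self):
        mat = pd.DataFrame(
            np.full((6, 4), 0.25), columns=list(DW_TYPES)
        )
        assert np.allclose(quality_score(mat), 1.5)

    def test_fixture_column_sums(self):
        mat = pd.DataFrame(
            [[0.5, 0.5, 0.0, 0.0], [0.1, 0.2, 0.3, 0.4], [0.0, 0.0, 1.0, 0.0]],
            columns=list(DW_TYPES),
        )
        assert np.allclose(quality_score(mat), [0.6, 0.7, 1.3, 0.4])
        assert quality_score(mat).sum() == pytest.approx(3.0)


class TestRankTests:
    def test_kruskal_hand_fixture(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert df == 2
        assert p == pytest.approx(0.0273, abs=5e-4)

    def test_identical_groups_h_zero(self):
        h, _, p = kruskal_wallis([[2, 2], [2, 2], [2, 2]])
        assert h == 0.0
        assert p == 1.0

    def test_tie_correction_matches_bruteforce(self, rng):
        groups = [rng.integers(0, 4, size=9).astype(float) for _ in range(3)]
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):
            flat[0] += 1.0
        ranks = stats.rankdata(flat)
        n = len(flat)
        bounds = np.cumsum([0] + [len(g) for g in groups])
        h = 12.0 / (n * (n + 1)) * sum(
            len(g) * (ranks[bounds[i]:bounds[i + 1]].mean() - (n + 1) / 2) ** 2
            for i, g in enumerate(groups)
        )
        _, counts = np.unique(flat, return_counts=True)
        h /= 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        got_h, _, _ = kruskal_wallis(groups)
        assert got_h == pytest.approx(h, rel=1e-12)

    def test_dunn_hand_fixture(self):
        out = dunn_posthoc([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        row = out[(out["group_a"] == "g0") & (out["group_b"] == "g2")].iloc[0]
        assert abs(row["z"]) == pytest.approx(2.683, abs=1e-3)
        assert row["p"] == pytest.approx(0.0073, abs=2e-4)

    def test_dunn_identical_groups(self):
        out = dunn_posthoc([[1.0, 1.0], [1.0, 1.0]])
        assert out["z"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_dunn_sign_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 5)
        z_ab = dunn_posthoc([a, b])["z"].iloc[0]
        z_ba = dunn_posthoc([b, a])["z"].iloc[0]
        assert z_ab == pytest.approx(-z_ba, rel=1e-12)

    def test_invalid_group_counts(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0]])


def test_quality_analysis_end_to_end(communities, landscape):
    _, items = landscape
    res = quality_analysis(communities["fungi"], items, seed=5)
    total = res["quality"].sum()
    assert total == pytest.approx(len(res["relative_densities"].matrix))
    assert len(res["dunn"]) == 6
    assert 0 <= res["kruskal"]["p"] <= 1


def test_occurrence_counts_on_items_not_records():
    obs = pd.DataFrame(
        {"species": ["b", "b"], "sample_id": ["s1", "s2"],
         "item_id": ["i1", "i1"], "count": [3, 0]}
    )
    table = ObservationTable("beetles", obs, samples=None)
    assert occurrence_counts(table)["b"] == 1
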