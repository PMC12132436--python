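import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nichestat.spatial_stats import (
    DENSE,
    OTHER,
    SPARSE,
    DistanceDistribution,
    classify_density,
    cross_type_distances,
    density_expression_test,
    ks_compare,
    neighborhood_counts,
)

from conftest import build_dataset


def calls_frame(ds, labels):
    return pd.DataFrame({"cell_id": ds.cell_ids, "call": labels})


def ecdf_max_gap(a, b):
    """Literal KS D: max |ECDF_a - ECDF_b| over all observed points."""
    pts = np.concatenate([a, b])
    gaps = [
        abs((a <= t).mean() - (b <= t).mean()) for t in pts
    ]
    return max(gaps)


class TestCrossTypeDistances:
    def test_three_four_five_triangle(self):
        ds = build_dataset(np.zeros((1, 2), int), coords=[[0, 0], [3, 4]])
        dists = cross_type_distances(ds, calls_frame(ds, ["A", "B"]), "A", "B")
        assert dists[0].distances.tolist() == [5.0]

    def test_all_pairs_match_double_loop(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, size=(5, 2))
        ds = build_dataset(np.zeros((1, 5), int), coords=coords)
        labels = ["A", "A", "A", "B", "B"]
        dists = cross_type_distances(ds, calls_frame(ds, labels), "A", "B")
        brute = sorted(
            np.hypot(*(coords[i] - coords[j]))
            for i in range(3)
            for j in range(3, 5)
        )
        assert len(dists[0].distances) == 6
        np.testing.assert_allclose(dists[0].distances, brute, rtol=1e-12)

    def test_cross_sample_pairs_never_formed(self):
        ds = build_dataset(
            np.zeros((1, 2), int),
            coords=[[0, 0], [1, 0]],
            sample_ids=["s1", "s2"],
        )
        with pytest.warns(UserWarning, match="empty"):
            dists = cross_type_distances(ds, calls_frame(ds, ["A", "B"]), "A", "B")
        assert dists[0].empty

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 50, size=(6, 2))
        labels = ["A", "B", "A", "B", "A", "B"]
        d1 = cross_type_distances(
            build_dataset(np.zeros((1, 6), int), coords=coords),
            calls_frame(build_dataset(np.zeros((1, 6), int)), labels),
            "A", "B",
        )[0].distances
        d2 = cross_type_distances(
            build_dataset(np.zeros((1, 6), int), coords=coords + [123.4, -56.7]),
            calls_frame(build_dataset(np.zeros((1, 6), int)), labels),
            "A", "B",
        )[0].distances
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_same_type_pair_rejected(self):
        ds = build_dataset(np.zeros((1, 1), int))
        with pytest.raises(ValueError):
            cross_type_distances(ds, calls_frame(ds, ["A"]), "A", "A")


class TestKSCompare:
    def _dist(self, values):
        return DistanceDistribution(("A", "B"), "x", np.asarray(values, float))

    def test_identical_samples_D_zero_p_one(self):
        res = ks_compare(self._dist([1, 2, 3]), self._dist([1, 2, 3]))
        assert res.D == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports_D_one(self):
        res = ks_compare(self._dist([1, 2, 3]), self._dist([4, 5, 6]))
        assert res.D == 1.0

    def test_interleaved_matches_ecdf_oracle(self):
        a, b = np.array([1.0, 3, 5, 7]), np.array([2.0, 4, 6])
        res = ks_compare(self._dist(a), self._dist(b))
        assert res.D == pytest.approx(ecdf_max_gap(a, b), abs=1e-12)

    def test_empty_side_named(self):
        with pytest.raises(ValueError, match="second"):
            ks_compare(self._dist([1.0]), self._dist([]))


class TestNeighborhoodCounts:
    def test_single_cell_has_no_neighbors(self):
        ds = build_dataset(np.zeros((1, 1), int), coords=[[5, 5]])
        assert neighborhood_counts(ds)["n"].tolist() == [0]

    def test_collinear_boundary_inclusive(self):
        ds = build_dataset(
            np.zeros((1, 3), int), coords=[[0, 0], [50, 0], [100, 0]]
        )
        assert neighborhood_counts(ds, radius_um=100)["n"].tolist() == [2, 2, 2]

    def test_counts_are_per_sample(self):
        ds = build_dataset(
            np.zeros((1, 2), int),
            coords=[[0, 0], [1, 0]],
            sample_ids=["s1", "s2"],
        )
        assert neighborhood_counts(ds)["n"].tolist() == [0, 0]

    def test_symmetric_consistency(self, small_sim):
        ds, _ = small_sim
        prof = neighborhood_counts(ds, radius_um=80)
        coords = ds.cells[["x_um", "y_um"]].to_numpy()
        samples = ds.cells["sample_id"].to_numpy()
        rng = np.random.default_rng(0)
        for i in rng.choice(ds.n_cells, 25, replace=False):
            same = samples == samples[i]
            d = np.hypot(*(coords[same] - coords[i]).T)
            assert prof["n"].iloc[i] == int((d <= 80).sum()) - 1


class TestClassifyDensity:
    @pytest.mark.parametrize(
        "n,expected",
        [(0, OTHER), (1, SPARSE), (2, OTHER), (4, OTHER), (5, DENSE), (9, DENSE)],
    )
    def test_density_rule(self, n, expected):
        prof = pd.DataFrame({"cell_id": ["c"], "sample_id": ["s"], "n": [n]})
        assert classify_density(prof)["density_class"].iloc[0] == expected


def _density_fixture(seed, slope=0.5, sigma=0.2, n_cells=120):
    """Cells on a grid-ish layout with one gene's norm = slope*n + noise."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 600, size=(n_cells, 2))
    ds = build_dataset(np.ones((3, n_cells), int), coords=coords)
    prof = classify_density(neighborhood_counts(ds, radius_um=100))
    n = prof["n"].to_numpy(float)
    norm = np.vstack(
        [
            slope * n + rng.normal(0, sigma, n_cells),
            rng.normal(2, 1, n_cells),
            np.zeros(n_cells),
        ]
    )
    from scipy import sparse

    ds.norm = sparse.csc_matrix(norm)
    calls = calls_frame(ds, ["npc"] * n_cells)
    return ds, calls, prof


class TestDensityExpressionTest:
    def test_planted_slope_recovered_with_ci(self):
        ds, calls, prof = _density_fixture(seed=11)
        res = density_expression_test(ds, calls, prof, "npc").set_index("gene")
        assert res.loc["g0", "linear_ci_low"] <= 0.5 <= res.loc["g0", "linear_ci_high"]
        assert res.loc["g0", "linear_p"] < 1e-6

    def test_constant_gene_flagged_not_tested(self):
        ds, calls, prof = _density_fixture(seed=2)
        res = density_expression_test(ds, calls, prof, "npc").set_index("gene")
        assert res.loc["g2", "linear_flag"] == "zero_variance"
        assert np.isnan(res.loc["g2", "linear_p"])

    def test_linear_arm_matches_statsmodels(self):
        import statsmodels.api as sm

        ds, calls, prof = _density_fixture(seed=4)
        res = density_expression_test(ds, calls, prof, "npc").set_index("gene")
        n = prof["n"].to_numpy(float)
        y = np.asarray(ds.norm[1].todense()).ravel()
        fit = sm.OLS(y, sm.add_constant(n)).fit()
        assert res.loc["g1", "linear_slope"] == pytest.approx(fit.params[1], rel=1e-10)
        assert res.loc["g1", "linear_p"] == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_q_never_below_p(self):
        ds, calls, prof = _density_fixture(seed=6)
        res = density_expression_test(ds, calls, prof, "npc")
        ok = res["linear_p"].notna()
        assert (res.loc[ok, "q_linear"] >= res.loc[ok, "linear_p"] - 1e-15).all()

    def test_unnormalized_dataset_rejected(self):
        ds = build_dataset(np.ones((2, 5), int))
        prof = classify_density(neighborhood_counts(ds))
        with pytest.raises(ValueError, match="normalized"):
            density_expression_test(ds, calls_frame(ds, ["npc"] * 5), prof, "npc")
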