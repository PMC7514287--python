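"""Cohort table building, correlations, clustering, rank tests, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sigentropy.records import Cohort, SubjectRecord
from sigentropy.sampen import EntropyGrid, EntropyValue, MatchCounts
from sigentropy.stats import (
    Selector,
    build_cohort_table,
    compute_grid_map,
    correlate_metadata,
    group_summary,
    mann_whitney_test,
    relative_increase,
    style_cluster,
)

from conftest import make_signature


def toy_grid(subject_id, instance, values, m_range=(3,), r_range=(0.1,), n=100):
    """EntropyGrid with prescribed values per channel (None = undefined)."""
    entries = {}
    for ch, val in values.items():
        for m in m_range:
            for r in r_range:
                if val is None:
                    entries[(ch, m, round(r, 6))] = EntropyValue(None, False, MatchCounts(0, 5))
                else:
                    entries[(ch, m, round(r, 6))] = EntropyValue(val, True, MatchCounts(3, 5))
    return EntropyGrid(
        subject_id=subject_id,
        instance=instance,
        m_range=tuple(m_range),
        r_range=tuple(round(r, 6) for r in r_range),
        channels=tuple(values),
        entries=entries,
        n_samples=n,
    )


def toy_cohort_and_grids(se_values):
    """Cohort of len(se_values) subjects; se_values[i] = (group, v1, v2)
    giving the p-channel entropy of the two signatures."""
    subjects, grids = [], {}
    for i, (group, v1, v2) in enumerate(se_values):
        sid = f"S{i:02d}"
        sigs = [make_signature(sid, 1, seed=i), make_signature(sid, 2, seed=100 + i)]
        mmse = 25 if group == "AD" else 29
        subjects.append(
            SubjectRecord(sid, group, 70.0 + i, "F", mmse, "R", "mixed", sigs)
        )
        grids[(sid, 1)] = toy_grid(sid, 1, {"p": v1})
        grids[(sid, 2)] = toy_grid(sid, 2, {"p": v2})
    return Cohort(subjects), grids


class TestBuildCohortTable:
    def test_person_average_of_two_defined(self):
        cohort, grids = toy_cohort_and_grids([("AD", 0.2, 0.4), ("HC", 0.5, 0.7)])
        table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        assert table["SE_p"].tolist() == pytest.approx([0.3, 0.6])
        assert table.shape[0] == 2

    def test_single_defined_value_is_kept(self):
        cohort, grids = toy_cohort_and_grids([("AD", None, 0.4)])
        table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        assert table["SE_p"].iloc[0] == pytest.approx(0.4)
        assert np.isnan(table["SE1_p"].iloc[0])

    def test_both_undefined_is_nan(self):
        cohort, grids = toy_cohort_and_grids([("AD", None, None)])
        table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        assert np.isnan(table["SE_p"].iloc[0])

    def test_missing_grid_raises(self):
        cohort, grids = toy_cohort_and_grids([("AD", 0.2, 0.4)])
        del grids[("S00", 2)]
        with pytest.raises(KeyError):
            build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))

    def test_selector_outside_ranges_raises(self):
        cohort, grids = toy_cohort_and_grids([("AD", 0.2, 0.4)])
        with pytest.raises(ValueError, match="outside computed ranges"):
            build_cohort_table(cohort, grids, Selector("fixed", 5, 0.3), channels=("p",))

    def test_grid_average_equals_mean_of_cells(self, small_cohort):
        grids = compute_grid_map(
            small_cohort, channels=("p",), m_range=(1, 2, 3), r_range=(0.1, 0.2, 0.3)
        )
        table = build_cohort_table(
            small_cohort, grids, Selector("grid_average", None, None), channels=("p",)
        )
        subj = small_cohort.subjects[0]
        grid = grids[(subj.subject_id, 1)]
        direct = np.mean(
            [
                grid.value("p", m, r).value
                for m in (1, 2, 3)
                for r in (0.1, 0.2, 0.3)
                if grid.value("p", m, r).defined
            ]
        )
        assert table["SE1_p"].iloc[0] == pytest.approx(direct, abs=1e-12)


class TestCorrelateMetadata:
    def test_affine_covariate_gives_unity(self):
        cohort, grids = toy_cohort_and_grids(
            [("AD", v, v) for v in (0.1, 0.2, 0.3, 0.4)]
        )
        table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        table["mmse"] = (10 * table["SE_p"] + 3).round(6)
        assert correlate_metadata(table, "p", "mmse") == pytest.approx(1.0)

    def test_matches_covariance_formula(self, default_cohort):
        grids = compute_grid_map(default_cohort, channels=("p",), m_range=(3,), r_range=(0.1,))
        table = build_cohort_table(default_cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        rho = correlate_metadata(table, "p", "mmse")
        x = table["SE_p"].to_numpy()
        y = table["mmse"].to_numpy(dtype=float)
        direct = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert rho == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        cohort, grids = toy_cohort_and_grids([("AD", 0.2, 0.2)] * 3)
        table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        table["mmse"] = 25
        with pytest.raises(ValueError, match="zero variance"):
            correlate_metadata(table, "p", "mmse")

    def test_unknown_covariate_rejected(self):
        cohort, grids = toy_cohort_and_grids([("AD", 0.2, 0.4)] * 3)
        table = build_cohort_table(cohort, grids, Selector("fixed", 3, 0.1), channels=("p",))
        with pytest.raises(ValueError):
            correlate_metadata(table, "p", "sex")


def cluster_table(points, styles=None):
    n = len(points)
    styles = styles or ["mixed"] * n
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "style": styles,
            "SE_x": [p[0] for p in points],
            "SE_y": [p[1] for p in points],
        }
    )


class TestStyleCluster:
    def test_recovers_planted_blobs(self, rng):
        centers = [(0.1, 0.15), (0.5, 0.5), (1.0, 1.2)]
        points, truth = [], []
        for label, c in enumerate(centers):
            for _ in range(10):
                points.append((c[0] + 0.01 * rng.standard_normal(), c[1] + 0.01 * rng.standard_normal()))
                truth.append(label)
        result = style_cluster(cluster_table(points), k=3, seed=0)
        # relabeled cluster 0 has the highest SE_x -> matches planted label 2
        remap = {0: 2, 1: 1, 2: 0}
        predicted = [remap[c] for c in result.assignments.to_numpy()]
        assert predicted == truth

    def test_k_one_centroid_is_grand_mean(self):
        points = [(0.1, 0.2), (0.3, 0.4), (0.5, 0.9)]
        result = style_cluster(cluster_table(points), k=1, seed=0)
        np.testing.assert_allclose(result.centroids[0], np.mean(points, axis=0), atol=1e-12)

    def test_duplication_stability(self, rng):
        points = [(0.1, 0.1), (0.12, 0.13), (0.5, 0.5), (0.52, 0.51), (1.0, 1.0), (1.02, 0.98)]
        base = style_cluster(cluster_table(points), k=3, seed=1)
        doubled = style_cluster(cluster_table(points + points), k=3, seed=1)
        n = len(points)
        assert doubled.assignments.to_numpy()[:n].tolist() == base.assignments.to_numpy().tolist()
        assert doubled.assignments.to_numpy()[n:].tolist() == base.assignments.to_numpy().tolist()

    def test_final_assignment_is_fixed_point(self, rng):
        points = [(rng.uniform(0, 1), rng.uniform(0, 1)) for _ in range(30)]
        result = style_cluster(cluster_table(points), k=3, seed=2)
        pts = np.array(points)
        dists = ((pts[:, None, :] - result.centroids[None, :, :]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(np.argmin(dists, axis=1), result.assignments.to_numpy())

    def test_centroids_ordered_by_decreasing_first_channel(self):
        points = [(0.1, 0.1), (0.11, 0.1), (0.5, 0.5), (0.52, 0.5), (0.9, 1.0), (0.93, 1.0)]
        result = style_cluster(cluster_table(points), k=3, seed=0)
        assert np.all(np.diff(result.centroids[:, 0]) < 0)

    def test_fewer_points_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer distinct points"):
            style_cluster(cluster_table([(0.1, 0.1), (0.1, 0.1)]), k=3)


class TestMannWhitney:
    @staticmethod
    def make_table(ad_vals, hc_vals):
        rows = []
        for i, v in enumerate(ad_vals):
            rows.append({"subject_id": f"A{i}", "group": "AD", "SE_p": v})
        for i, v in enumerate(hc_vals):
            rows.append({"subject_id": f"H{i}", "group": "HC", "SE_p": v})
        return pd.DataFrame(rows)

    def test_complete_separation_exact_p(self):
        table = self.make_table([0.1, 0.2, 0.3, 0.4, 0.5], [1.1, 1.2, 1.3, 1.4, 1.5])
        res = mann_whitney_test(table, "p", method="exact")
        assert res.statistic in (0.0, 25.0)
        assert res.p_value == pytest.approx(2 / 252, rel=1e-9)  # 0.0079

    def test_matches_exact_enumeration_small_n(self, rng):
        """Exact p equals full enumeration of group assignments (n = 4 + 4)."""
        pooled = rng.normal(size=8)
        table = self.make_table(pooled[:4], pooled[4:])
        res = mann_whitney_test(table, "p", method="exact")

        def u_stat(ad, hc):
            return sum((a > h) + 0.5 * (a == h) for a in ad for h in hc)

        u_obs = u_stat(pooled[:4], pooled[4:])
        us = [
            u_stat(pooled[list(comb)], pooled[[i for i in range(8) if i not in comb]])
            for comb in itertools.combinations(range(8), 4)
        ]
        lo, hi = min(u_obs, 16 - u_obs), max(u_obs, 16 - u_obs)
        p_exact = sum(u <= lo or u >= hi for u in us) / len(us)
        assert res.p_value == pytest.approx(p_exact, rel=1e-9)

    def test_u_bounds_invariant(self, rng):
        table = self.make_table(rng.normal(size=10), rng.normal(size=12))
        res = mann_whitney_test(table, "p")
        assert 0 <= res.statistic <= 10 * 12
        assert 0 <= res.p_value <= 1

    def test_all_undefined_group_rejected(self):
        table = self.make_table([np.nan, np.nan], [0.5, 0.6])
        with pytest.raises(ValueError, match="no defined values"):
            mann_whitney_test(table, "p")


class TestRelativeIncrease:
    def test_direct_arithmetic(self):
        table = TestMannWhitney.make_table([0.4, 0.4], [0.6, 0.6])
        assert relative_increase(table, "p") == pytest.approx(50.0)

    def test_equal_means_zero(self):
        table = TestMannWhitney.make_table([0.5, 0.5], [0.5, 0.5])
        assert relative_increase(table, "p") == pytest.approx(0.0)

    def test_nonpositive_ad_mean_rejected(self):
        table = TestMannWhitney.make_table([0.0, 0.0], [0.5, 0.5])
        with pytest.raises(ValueError, match="AD group mean"):
            relative_increase(table, "p")


class TestGroupSummary:
    def test_two_subject_single_cell_means(self):
        cohort, grids = toy_cohort_and_grids([("AD", 0.2, 0.4), ("HC", 0.5, 0.7)])
        summary = group_summary(grids, cohort, channels=("p",))
        ad = summary[(summary["group"] == "AD")].iloc[0]
        hc = summary[(summary["group"] == "HC")].iloc[0]
        assert ad["mean"] == pytest.approx(0.3)
        assert hc["mean"] == pytest.approx(0.6)
        assert ad["n"] == 1 and hc["n"] == 1

    def test_undefined_counted_not_averaged(self):
        cohort, grids = toy_cohort_and_grids([("AD", None, None), ("AD", 0.2, 0.2)])
        summary = group_summary(grids, cohort, channels=("p",))
        ad = summary[summary["group"] == "AD"].iloc[0]
        assert ad["n_undefined"] == 1
        assert ad["mean"] == pytest.approx(0.2)

    def test_subject_order_invariance(self):
        values = [("AD", 0.2, 0.4), ("HC", 0.5, 0.7), ("HC", 0.1, 0.9)]
        cohort1, grids1 = toy_cohort_and_grids(values)
        cohort2 = Cohort(list(reversed(cohort1.subjects)))
        s1 = group_summary(grids1, cohort1, channels=("p",))
        s2 = group_summary(grids1, cohort2, channels=("p",))
        pd.testing.assert_frame_equal(s1, s2)
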