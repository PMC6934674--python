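"""Monthly-matched subsampling, estimated networks, Spearman validation and
randomization tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from socioscan.association import hwi, joint_counts
from socioscan.metrics import MetricTable
from socioscan.resampling import (
    SubsamplePlan,
    estimated_network,
    metric_differences,
    monthly_matched_subsamples,
    plan_from_road,
    randomization_test,
    spearman_validate,
)
from socioscan.scan_data import tally_sightings
from conftest import make_scans


def month_scans(month, n, context, individual="A", start_id=0):
    return [
        (start_id + k, f"{month}-0{1 + k % 9}", "morning", individual, context, "rest", set())
        for k in range(n)
    ]


class TestSubsampling:
    def test_quota_matches_road_monthly_pattern(self, tiny_roster):
        rows = month_scans("2016-10", 42, "road", start_id=0)
        rows += month_scans("2016-10", 60, "forest", start_id=100)
        rows += month_scans("2016-11", 5, "road", start_id=200)
        rows += month_scans("2016-11", 30, "forest", start_id=300)
        scans = make_scans(rows)
        plan = plan_from_road(scans, n_samples=10, seed=0)
        assert plan.per_month_quota == {"2016-10": 42, "2016-11": 5}
        samples = monthly_matched_subsamples(scans, plan)
        assert len(samples) == 10
        forest = scans[scans["context"] == "forest"]
        october = set(forest[forest["date"].map(lambda d: d.month) == 10]["scan_id"])
        for s in samples:
            assert len(s & october) == 42
            assert len(s) == 47

    def test_quota_exceeding_availability_names_month(self, tiny_roster):
        scans = make_scans(month_scans("2016-10", 3, "forest"))
        plan = SubsamplePlan(per_month_quota={"2016-10": 5}, n_samples=2)
        with pytest.raises(ValueError, match="2016-10.*quota 5"):
            monthly_matched_subsamples(scans, plan)

    def test_quota_equal_to_pool_is_degenerate(self):
        scans = make_scans(month_scans("2016-10", 8, "forest"))
        plan = SubsamplePlan(per_month_quota={"2016-10": 8}, n_samples=4)
        samples = monthly_matched_subsamples(scans, plan)
        full = set(scans["scan_id"])
        assert all(s == full for s in samples)

    def test_zero_quota_month_absent(self):
        rows = month_scans("2016-10", 5, "forest") + month_scans("2016-11", 5, "forest", start_id=50)
        plan = SubsamplePlan(per_month_quota={"2016-10": 2, "2016-11": 0}, n_samples=3)
        samples = monthly_matched_subsamples(make_scans(rows), plan)
        november = {50 + k for k in range(5)}
        assert all(not (s & november) for s in samples)

    def test_reproducible_and_row_order_invariant(self):
        rows = month_scans("2016-10", 20, "forest")
        scans = make_scans(rows)
        shuffled = scans.sample(frac=1.0, random_state=1).reset_index(drop=True)
        plan = SubsamplePlan(per_month_quota={"2016-10": 7}, n_samples=5, seed=11)
        assert monthly_matched_subsamples(scans, plan) == monthly_matched_subsamples(shuffled, plan)


class TestEstimatedNetwork:
    def test_degenerate_quota_reproduces_comprehensive_network(self, sim_analysis):
        scans, interactions, roster = sim_analysis
        forest = scans[scans["context"] == "forest"]
        months = forest["date"].map(lambda d: f"{d.year:04d}-{d.month:02d}")
        quota = forest.groupby(months)["scan_id"].nunique().to_dict()
        plan = SubsamplePlan(per_month_quota=quota, n_samples=3, seed=0)
        samples = monthly_matched_subsamples(scans, plan)
        est = estimated_network(samples, scans, roster, "proximity")
        comp = hwi(
            joint_counts(scans, "forest", "proximity", roster),
            tally_sightings(scans, "forest", roster),
        )
        np.testing.assert_allclose(est.hwi, comp.hwi, atol=1e-12)

    def test_estimated_matches_per_sample_recount(self, sim_analysis):
        # fast masked recount must equal the plain per-sample HWI pipeline
        scans, interactions, roster = sim_analysis
        plan = plan_from_road(scans, n_samples=3, seed=5)
        samples = monthly_matched_subsamples(scans, plan)
        est = estimated_network(samples, scans, roster, "proximity")
        acc = np.zeros_like(est.hwi)
        for sample in samples:
            sub = scans[(scans["context"] != "road") & scans["scan_id"].isin(sample)]
            acc += hwi(
                joint_counts(sub, "forest", "proximity", roster),
                tally_sightings(sub, "forest", roster),
            ).hwi
        np.testing.assert_allclose(est.hwi, acc / len(samples), atol=1e-12)

    def test_mean_of_two_samples(self, sim_analysis):
        scans, _, roster = sim_analysis
        plan = plan_from_road(scans, n_samples=2, seed=9)
        s1, s2 = monthly_matched_subsamples(scans, plan)
        est = estimated_network([s1, s2], scans, roster, "proximity")
        e1 = estimated_network([s1], scans, roster, "proximity")
        e2 = estimated_network([s2], scans, roster, "proximity")
        np.testing.assert_allclose(est.hwi, (e1.hwi + e2.hwi) / 2, atol=1e-14)

    def test_requires_samples(self, sim_analysis):
        scans, _, roster = sim_analysis
        with pytest.raises(ValueError, match="at least one"):
            estimated_network([], scans, roster, "proximity")


class TestSpearmanValidate:
    def test_identical_vectors(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
        rho, p = spearman_validate(a, a)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("ABCD"))
        rho, _ = spearman_validate(a, b)
        assert rho == pytest.approx(-1.0)

    def test_small_sample_p_matches_full_enumeration(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=5), index=list("ABCDE"))
        b = pd.Series(rng.normal(size=5), index=list("ABCDE"))
        rho, p = spearman_validate(a, b)
        # oracle: enumerate all 120 rank pairings directly
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        obs = stats.spearmanr(a, b).statistic
        count = 0
        total = 0
        for perm in itertools.permutations(rb):
            r = stats.spearmanr(ra, perm).statistic
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        assert total == 120
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_constant_vector_flagged(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("ABC"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("ABC"))
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_validate(a, b)
        assert math.isnan(rho)


class TestMetricDifferences:
    def table(self, values):
        df = pd.DataFrame({"weighted_degree": values}, index=list("ABC"))
        for col in ("betweenness", "closeness", "eigenvector"):
            df[col] = 0.0
        return MetricTable(tag="t", density=1.0, table=df)

    def test_identical_tables_give_zero(self):
        t = self.table([1.0, 2.0, 3.0])
        assert (metric_differences(t, t, "weighted_degree") == 0).all()

    def test_sign_convention_positive_means_road(self):
        road = self.table([1.1, 2.1, 3.1])
        forest = self.table([1.0, 2.0, 3.0])
        d = metric_differences(road, forest, "weighted_degree")
        np.testing.assert_allclose(d, 0.1)

    def test_node_mismatch_is_error(self):
        road = self.table([1.0, 2.0, 3.0])
        forest = self.table([1.0, 2.0, 3.0])
        forest.table.index = list("ABD")
        with pytest.raises(ValueError, match="different individuals"):
            metric_differences(road, forest, "weighted_degree")


class TestRandomizationTest:
    def test_exhaustive_sign_flip_all_positive_five(self):
        r = randomization_test(np.ones(5), mode="sign_flip", exhaustive=True)
        # only the all-plus and all-minus assignments reach |mean| = 1
        assert r.p_value == pytest.approx(2 / 32)
        assert r.direction == "greater along road"

    def test_exhaustive_sign_flip_twelve_positive(self):
        r = randomization_test(np.ones(12) * 0.5, mode="sign_flip", exhaustive=True)
        assert r.p_value == pytest.approx(2 / 4096)

    def test_symmetric_pair_gives_p_one(self):
        r = randomization_test(np.array([1.0, -1.0]), mode="sign_flip", exhaustive=True)
        assert r.p_value == pytest.approx(1.0)

    def test_monte_carlo_converges_to_exact(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.4, 1.0, size=10)
        exact = randomization_test(d, mode="sign_flip", exhaustive=True).p_value
        mc = randomization_test(d, n_resamples=10_000, mode="sign_flip", seed=2).p_value
        se = math.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) <= 3 * se + 1e-4

    def test_centered_bootstrap_mode_runs_and_is_seeded(self):
        d = np.array([0.5, 0.7, 0.2, 0.9, 0.4])
        r1 = randomization_test(d, n_resamples=2000, mode="centered_bootstrap", seed=3)
        r2 = randomization_test(d, n_resamples=2000, mode="centered_bootstrap", seed=3)
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning, match="all differences are zero"):
            r = randomization_test(np.zeros(5))
        assert r.p_value == 1.0

    def test_too_few_differences(self):
        with pytest.raises(ValueError, match="at least two"):
            randomization_test(np.array([1.0]))

    def test_null_rejection_rate_calibrated(self):
        # symmetric-null differences: rejection at 0.05 stays near 0.05
        rng = np.random.default_rng(17)
        n_rep, rejections = 500, 0
        for _ in range(n_rep):
            d = rng.normal(0.0, 1.0, size=12)
            p = randomization_test(d, n_resamples=499, mode="sign_flip", seed=int(rng.integers(2**31))).p_value
            rejections += p <= 0.05
        rate = rejections / n_rep
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se
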