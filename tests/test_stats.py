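"""FDR adjustment, effect sizes, regional tests, permutation machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fdnet import (
    CohortFDMatrix,
    SimulationSpec,
    bh_fdr,
    cohens_d,
    permutation_network_test,
    regional_fd_tests,
    simulate_two_groups,
)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_stepped_example(self):
        # min over j>=i of p_j * m / j
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(bh_fdr(np.ones(10)), 1.0)

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan], []])
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    def test_agrees_with_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_fdr(p), q_ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p_and_monotone(self, p):
        q = bh_fdr(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCohensD:
    def test_identical_samples_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([0.0, 0.0], [1.0, 1.0])

    def test_large_sample_recovery(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.5, 1.0, 100_000)
        b = rng.normal(0.0, 1.0, 100_000)
        assert cohens_d(a, b) == pytest.approx(0.5, abs=0.02)

    def test_sign_follows_mean_difference(self):
        rng = np.random.default_rng(4)
        lo, hi = rng.normal(0, 1, 50), rng.normal(1, 1, 50)
        assert cohens_d(lo, hi) < 0 < cohens_d(hi, lo)


class TestRegionalTests:
    def test_cohort_against_itself_is_null(self, region_table, rng):
        values = 2.2 + 0.03 * rng.standard_normal((10, 68))
        a = CohortFDMatrix(values=values, group_label="a", region_table=region_table)
        b = CohortFDMatrix(values=values.copy(), group_label="b", region_table=region_table)
        res = regional_fd_tests(a, b)
        assert np.allclose(res.table["t"], 0.0)
        assert np.allclose(res.table["effect_size"], 0.0)
        assert np.all(res.table["q"] == 1.0)
        assert len(res.significant()) == 0

    def test_planted_shift_detected_in_table(self):
        spec = SimulationSpec(n_subjects=60, effect_regions=(10,), effect_d=1.5, seed=2)
        a, b = simulate_two_groups(spec)
        res = regional_fd_tests(a, b)
        row = res.table.set_index("region_id").loc[10]
        assert row["t"] > 0  # group A (control) higher
        assert row["effect_size"] > 0
        assert row["q"] < 0.05

    def test_q_is_bh_of_p(self, region_table, rng):
        spec = SimulationSpec(n_subjects=20, seed=8)
        a, b = simulate_two_groups(spec)
        res = regional_fd_tests(a, b)
        assert np.allclose(res.table["q"], bh_fdr(res.table["p"].to_numpy()))

    def test_too_few_subjects_rejected(self, region_table):
        a = CohortFDMatrix(values=np.full((1, 68), 2.2), region_table=region_table)
        b = CohortFDMatrix(values=np.full((5, 68), 2.2), region_table=region_table)
        with pytest.raises(ValueError, match="2 subjects"):
            regional_fd_tests(a, b)

    def test_welch_option_runs(self):
        spec = SimulationSpec(n_subjects=12, seed=3)
        a, b = simulate_two_groups(spec)
        res = regional_fd_tests(a, b, equal_var=False)
        assert np.all((res.table["p"] >= 0) & (res.table["p"] <= 1))


@pytest.fixture(scope="module")
def cohorts():
    return simulate_two_groups(SimulationSpec(n_subjects=15, seed=6, effect_d=0.0))


class TestPermutationTest:

    def test_deterministic_given_seed(self, cohorts):
        a, b = cohorts
        r1 = permutation_network_test(a, b, n_perm=30, subsample=8, seed=4)
        r2 = permutation_network_test(a, b, n_perm=30, subsample=8, seed=4)
        for m in r1.null:
            assert np.array_equal(r1.null[m], r2.null[m])
        assert r1.p == r2.p and r1.q == r2.q

    def test_null_length_and_critical_value(self, cohorts):
        a, b = cohorts
        r = permutation_network_test(a, b, n_perm=40, subsample=8, seed=1)
        for m, dist in r.null.items():
            assert len(dist) == 40
        # the critical value is the empirical 95th percentile of the stored null
        q = r.observed_diff["modularity_q"]
        direction = 1.0 if q >= 0 else -1.0
        expected = direction * np.percentile(direction * r.null["modularity_q"], 95)
        assert r.critical["modularity_q"] == pytest.approx(expected)

    def test_label_swap_leaves_null_comparable(self, cohorts):
        """Exchangeable construction: swapping cohorts only flips/perturbs the null."""
        a, b = cohorts
        r_ab = permutation_network_test(a, b, n_perm=120, subsample=8, seed=11)
        r_ba = permutation_network_test(b, a, n_perm=120, subsample=8, seed=12)
        for m in ("modularity_q", "mean_participation"):
            sd_ab, sd_ba = r_ab.null[m].std(), r_ba.null[m].std()
            assert 0.5 < sd_ab / sd_ba < 2.0
            assert abs(r_ab.null[m].mean() - r_ba.null[m].mean()) < 3 * sd_ab

    def test_subsample_larger_than_cohort_rejected(self, cohorts):
        a, b = cohorts
        with pytest.raises(ValueError, match="subsample"):
            permutation_network_test(a, b, n_perm=5, subsample=20, seed=0)

    def test_bad_n_perm_rejected(self, cohorts):
        a, b = cohorts
        with pytest.raises(ValueError, match="n_perm"):
            permutation_network_test(a, b, n_perm=0, subsample=5, seed=0)

    def test_calibrated_in_exchangeable_regime(self):
        """When cohort size equals the subsample, the pool-and-resplit null is
        exact, and the data-adaptive one-tailed rule rejects at ~2x nominal
        (both tails of the symmetric null).  Rejection rate should be well
        away from 0 and from 1 — this isolates the permutation machinery from
        the subsample-vs-full-group scale mismatch of the emulated design.
        """
        rejections = 0
        for rep in range(60):
            a, b = simulate_two_groups(
                SimulationSpec(n_subjects=10, effect_d=0.0, seed=40000 + rep)
            )
            r = permutation_network_test(a, b, n_perm=100, subsample=10, seed=rep)
            if r.p["modularity_q"] <= 0.05:
                rejections += 1
        assert 1 <= rejections <= 15  # ~0.10 expected, loose binomial band

    def test_strong_group_difference_declared_significant(self):
        """Much weaker covariance in group B drives Q and weight differences."""
        spec = SimulationSpec(n_subjects=30, rho_within=0.7, seed=14, effect_d=0.0)
        weak = spec.replace(rho_within=0.15, rho_between=0.05, seed=15)
        from fdnet import simulate_cohort

        a = simulate_cohort(spec, "strong")
        b = simulate_cohort(weak, "weak")
        r = permutation_network_test(a, b, n_perm=150, subsample=10, seed=5)
        assert r.p["modularity_q"] < 0.05
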