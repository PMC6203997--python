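import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dyadkit.dyad_data import (
    ConfigurationError,
    DataError,
    DegenerateComparisonError,
    DyadTable,
    InsufficientDataError,
    ScaleDefinition,
    SummaryMoments,
    cronbach_alpha,
    moments_to_covariance,
    paired_t_from_summary,
    read_dyad_table,
    score_scale,
    summarize_dyads,
)
from dyadkit.synthetic import GeneratorSpec, simulate_dyads


def exact_sample(cov, n, rng):
    """Draw a sample whose *sample* covariance equals ``cov`` exactly.

    Raw normal draws are centred and whitened empirically before being
    coloured by the target Cholesky factor, so sample moments are exact
    rather than approximate — handy for closed-form oracles.
    """
    k = cov.shape[0]
    z = rng.standard_normal((n, k))
    z -= z.mean(axis=0)
    w = np.linalg.cholesky(np.cov(z, rowvar=False, ddof=1))
    z = np.linalg.solve(w, z.T).T  # exact identity sample covariance
    return z @ np.linalg.cholesky(cov).T


class TestScaleScoring:
    @pytest.mark.parametrize(
        "scale, items, expected",
        [
            (ScaleDefinition("EMS", 10, 1, 5), [5] * 10, 50),
            (ScaleDefinition("HADS-A", 7, 0, 3), [0] * 7, 0),
            (ScaleDefinition("one-rev", 1, 1, 5, frozenset({1})), [2], 4),
        ],
    )
    def test_examples(self, scale, items, expected):
        assert score_scale(items, scale) == expected

    def test_total_within_declared_range(self):
        scale = ScaleDefinition("s", 10, 1, 5, frozenset({2, 5}))
        rng = np.random.default_rng(0)
        items = rng.integers(1, 6, size=(200, 10))
        totals = score_scale(items, scale)
        lo, hi = scale.score_range
        assert totals.min() >= lo and totals.max() <= hi

    def test_out_of_range_names_item(self):
        scale = ScaleDefinition("s", 3, 1, 5)
        with pytest.raises(DataError, match="item 2"):
            score_scale([3, 9, 1], scale)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        base=st.lists(st.integers(1, 5), min_size=4, max_size=4),
        item=st.integers(0, 3),
    )
    def test_monotone_in_item_keying(self, base, item):
        """Raising a positive item raises the total; a reverse item lowers it."""
        plain = ScaleDefinition("p", 4, 1, 5)
        reverse = ScaleDefinition("r", 4, 1, 5, frozenset({item + 1}))
        bumped = list(base)
        if bumped[item] == 5:
            return
        bumped[item] += 1
        assert score_scale(bumped, plain) > score_scale(base, plain)
        assert score_scale(bumped, reverse) < score_scale(base, reverse)

    def test_invalid_reverse_index(self):
        with pytest.raises(ConfigurationError):
            ScaleDefinition("s", 3, 1, 5, frozenset({4}))


class TestCronbachAlpha:
    def test_compound_symmetry_closed_form(self):
        # equal variances and equal pairwise correlation r:
        # alpha = k*r / (1 + (k-1)*r), exactly, when sample moments match
        rng = np.random.default_rng(42)
        for k, r in [(3, 0.4), (5, 0.2), (10, 0.7)]:
            cov = np.full((k, k), r) + np.eye(k) * (1 - r)
            data = exact_sample(cov, 100, rng)
            expected = k * r / (1 + (k - 1) * r)
            assert cronbach_alpha(data) == pytest.approx(expected, abs=1e-10)

    def test_exact_copies_give_one(self):
        x = np.random.default_rng(1).standard_normal(50)
        assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((10000, 2))
        assert abs(cronbach_alpha(data)) < 0.1

    def test_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            data = rng.standard_normal((30, 4)) @ rng.standard_normal((4, 4))
            assert cronbach_alpha(data) <= 1.0

    @pytest.mark.parametrize(
        "bad", [np.ones((10, 1)), np.zeros((10, 3)), np.ones((2, 3))]
    )
    def test_undefined_cases(self, bad):
        with pytest.raises(DataError):
            cronbach_alpha(bad)


class TestDyadTableIO:
    def test_read_maps_columns(self, tmp_path):
        p = tmp_path / "dyads.csv"
        p.write_text(
            "id,ms_m,ms_w,anx_m,anx_w\n1,40,38,5,9\n2,35,33,8,11\n3,44,47,2,4\n"
        )
        cfg = {
            "dyad_id": "id",
            "roles": ["man", "woman"],
            "variables": {
                "satisfaction": {"man": "ms_m", "woman": "ms_w"},
                "anxiety": {"man": "anx_m", "woman": "anx_w"},
            },
        }
        table = read_dyad_table(p, cfg)
        assert table.n_dyads == 3
        assert table.data["satisfaction_woman"].tolist() == [38, 33, 47]
        assert not table.incomplete_mask().any()

    def test_missing_role_column_names_pair(self, tmp_path):
        p = tmp_path / "dyads.csv"
        p.write_text("id,ms_m\n1,40\n")
        cfg = {
            "dyad_id": "id",
            "roles": ["man", "woman"],
            "variables": {"satisfaction": {"man": "ms_m"}},
        }
        with pytest.raises(ConfigurationError, match="'satisfaction'.*'woman'"):
            read_dyad_table(p, cfg)

    def test_duplicate_dyad_id(self, tmp_path):
        p = tmp_path / "dyads.csv"
        p.write_text("id,a_m,a_w\n1,1,2\n1,3,4\n")
        cfg = {
            "dyad_id": "id",
            "roles": ["man", "woman"],
            "variables": {"a": {"man": "a_m", "woman": "a_w"}},
        }
        with pytest.raises(DataError, match="duplicate"):
            read_dyad_table(p, cfg)

    def test_synthetic_round_trip(self, tmp_path):
        spec = GeneratorSpec("apim", n=25, seed=5)
        table = simulate_dyads(spec)
        p = tmp_path / "sim.csv"
        table.write(p)
        cfg = {
            "dyad_id": "dyad_id",
            "roles": ["man", "woman"],
            "variables": {
                v: {r: f"{v}_{r}" for r in ("man", "woman")}
                for v in ("anxiety", "satisfaction")
            },
        }
        back = read_dyad_table(p, cfg)
        for col in table.analysis_columns:
            np.testing.assert_allclose(back.data[col], table.data[col], rtol=1e-12)


class TestSummarize:
    def test_recovers_generator_truth(self):
        spec = GeneratorSpec("apim", n=50_000, seed=99)
        table = simulate_dyads(spec)
        from dyadkit.synthetic import implied_population_covariance

        pop = implied_population_covariance(spec)
        m = summarize_dyads(table)
        m = m.reorder(pop.columns)
        n = m.n
        true_sd = np.sqrt(np.diag(pop.to_numpy()))
        true_corr = pop.to_numpy() / np.outer(true_sd, true_sd)
        # 3 Monte-Carlo standard errors on each moment
        assert np.all(np.abs(m.means - 0.0) <= 3 * true_sd / np.sqrt(n))
        assert np.all(np.abs(m.sds - true_sd) <= 3 * true_sd / np.sqrt(2 * n))
        iu = np.triu_indices(4, k=1)
        se_r = (1 - true_corr[iu] ** 2) / np.sqrt(n)
        assert np.all(np.abs(m.correlations[iu] - true_corr[iu]) <= 3 * se_r)

    def test_duplicated_variable_correlates_perfectly(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(20)
        table = DyadTable.from_scores(
            np.column_stack([x, x]), ["v"], ["man", "woman"]
        )
        m = summarize_dyads(table)
        assert m.correlations[0, 1] == pytest.approx(1.0)

    def test_four_column_structure(self, moments):
        assert moments.correlations.shape == (4, 4)
        iu = np.triu_indices(4, k=1)
        assert len(moments.correlations[iu]) == 6

    def test_too_few_complete_dyads(self):
        table = DyadTable.from_scores(
            np.array([[1.0, 2.0], [3.0, np.nan], [np.nan, 4.0], [1.0, 1.0]]),
            ["v"],
            ["man", "woman"],
        )
        with pytest.raises(InsufficientDataError):
            summarize_dyads(table)


class TestPairedT:
    def test_zero_when_means_equal(self):
        t = paired_t_from_summary(5.0, 5.0, 1.0, 1.2, 0.3, 30)
        assert t.statistic == 0.0 and t.pvalue == pytest.approx(1.0)

    def test_uncorrelated_matches_raw_data_oracle(self):
        # with r12 = 0 the summary formula must agree with a paired t test
        # on raw data carrying those exact moments
        rng = np.random.default_rng(8)
        cov = np.diag([1.44, 2.89])
        data = exact_sample(cov, 60, rng)
        data += np.array([3.0, 2.4]) - data.mean(axis=0)
        t_raw = stats.ttest_rel(data[:, 0], data[:, 1])
        t_sum = paired_t_from_summary(3.0, 2.4, 1.2, 1.7, 0.0, 60)
        assert t_sum.statistic == pytest.approx(t_raw.statistic, rel=1e-10)
        assert t_sum.pvalue == pytest.approx(t_raw.pvalue, rel=1e-10)

    def test_degenerate_difference(self):
        with pytest.raises(DegenerateComparisonError):
            paired_t_from_summary(1.0, 2.0, 1.0, 1.0, 1.0, 10)


class TestMomentsToCovariance:
    def test_fixture_values(self, moments):
        cov, means = moments_to_covariance(moments)
        # variance of men's marital satisfaction = 6.56^2
        assert cov[0, 0] == pytest.approx(43.0336)
        # covariance of men's satisfaction with men's anxiety
        assert cov[0, 1] == pytest.approx(-0.336 * 6.56 * 4.30)
        assert means[0] == pytest.approx(39.31)

    def test_perfect_correlation_equal_sds(self):
        m = SummaryMoments(
            n=10,
            names=("a", "b"),
            means=[0, 0],
            sds=[2.0, 2.0],
            correlations=[[1.0, 1.0], [1.0, 1.0]],
        )
        cov, _ = moments_to_covariance(m)
        assert cov[0, 1] == pytest.approx(4.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_restandardization_recovers_correlations(self, seed):
        rng = np.random.default_rng(seed)
        k = 4
        raw = rng.standard_normal((k + 2, k))
        corr = np.corrcoef(raw, rowvar=False)
        sds = rng.uniform(0.5, 8.0, k)
        m = SummaryMoments(10, tuple("abcd"), np.zeros(k), sds, corr)
        cov, _ = moments_to_covariance(m)
        d = np.sqrt(np.diag(cov))
        np.testing.assert_allclose(cov / np.outer(d, d), corr, atol=1e-12)

    def test_non_psd_rejected_then_repaired(self):
        corr = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        m = SummaryMoments(10, ("a", "b", "c"), np.zeros(3), np.ones(3), corr)
        with pytest.raises(DataError, match="repair"):
            moments_to_covariance(m)
        cov, _ = moments_to_covariance(m, repair=True)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10


class TestSummaryMomentsValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(DataError):
            SummaryMoments(
                5, ("a", "b"), [0, 0], [1, 1], [[1.0, 0.2], [0.3, 1.0]]
            )

    def test_nonunit_diagonal_rejected(self):
        with pytest.raises(DataError):
            SummaryMoments(5, ("a", "b"), [0, 0], [1, 1], [[1.1, 0], [0, 1.0]])

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(DataError):
            SummaryMoments(5, ("a", "b"), [0, 0], [1, 0], np.eye(2))
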