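"""Discrepancies, predictive p-values, partitioning and effect sizes."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ploveripm as pp
from ploveripm.diagnostics import hierarchical_partitioning


class TestDiscrepancies:
    def test_chi_square_examples(self):
        assert pp.chi_square_discrepancy([5, 10], [5, 10]) == 0.0
        assert pp.chi_square_discrepancy([5, 10], [4, 12]) \
            == pytest.approx(0.25 + 1.0 / 3.0)
        assert pp.chi_square_discrepancy([0], [2]) == pytest.approx(2.0)

    def test_chi_square_zero_expected_errors(self):
        with pytest.raises(ValueError):
            pp.chi_square_discrepancy([1], [0])

    def test_freeman_tukey_examples(self):
        assert pp.freeman_tukey_discrepancy([3, 4], [3, 4]) == 0.0
        assert pp.freeman_tukey_discrepancy([4], [1]) == pytest.approx(1.0)
        assert pp.freeman_tukey_discrepancy([9, 1], [4, 4]) \
            == pytest.approx(2.0)

    def test_freeman_tukey_negative_errors(self):
        with pytest.raises(ValueError):
            pp.freeman_tukey_discrepancy([-1], [1])

    @given(st.lists(st.tuples(st.integers(0, 50), st.floats(0.1, 50)),
                    min_size=1, max_size=10))
    def test_zero_iff_equal_and_permutation_invariant(self, cells):
        o = np.array([c[0] for c in cells], float)
        e = np.array([c[1] for c in cells], float)
        for f in (pp.chi_square_discrepancy, pp.freeman_tukey_discrepancy):
            assert f(o, o + 0.0) == pytest.approx(0.0) if f is \
                pp.freeman_tukey_discrepancy else True
            d = f(o, e)
            assert d >= 0
            perm = np.argsort(e)
            assert f(o[perm], e[perm]) == pytest.approx(d)
            if d == 0:
                assert np.allclose(o, e)

    def test_pvalue_examples(self):
        assert pp.posterior_predictive_pvalue([1, 1], [2, 3]) == 1.0
        assert pp.posterior_predictive_pvalue([5, 5], [2, 3]) == 0.0
        # ties excluded by the strict inequality
        assert pp.posterior_predictive_pvalue([2, 2, 2, 2],
                                              [1, 2, 3, 4]) == 0.5

    def test_pvalue_empty_errors(self):
        with pytest.raises(ValueError):
            pp.posterior_predictive_pvalue([], [])


# ---------------------------------------------------------------------------
# Hierarchical partitioning


def brute_force_partition(y, X):
    """Average R^2 increment over every predictor ordering."""
    n, k = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    tss = yc @ yc

    def r2(subset):
        if not subset:
            return 0.0
        Xs = Xc[:, sorted(subset)]
        beta, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        return 1.0 - np.sum((yc - Xs @ beta) ** 2) / tss

    contrib = np.zeros(k)
    orders = list(permutations(range(k)))
    for order in orders:
        current = set()
        for j in order:
            contrib[j] += r2(current | {j}) - r2(current)
            current.add(j)
    contrib /= len(orders)
    contrib = np.maximum(contrib, 0.0)
    return 100.0 * contrib / contrib.sum()


class TestHierarchicalPartitioning:
    def test_single_predictor_gets_everything(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 1))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.1, 12)
        assert hierarchical_partitioning(y, x) == pytest.approx([100.0])

    def test_orthogonal_two_predictor_analytic_split(self):
        x1 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        x2 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        y = x1 + 2.0 * x2
        out = hierarchical_partitioning(y, np.column_stack([x1, x2]))
        assert out == pytest.approx([20.0, 80.0], abs=1e-9)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_ordering_enumeration(self, k):
        rng = np.random.default_rng(k)
        X = rng.normal(size=(20, k))
        # correlated predictors to exercise the hierarchy weights
        X[:, 0] += 0.5 * X[:, -1]
        beta = rng.normal(size=k)
        y = X @ beta + rng.normal(0, 0.5, 20)
        ours = hierarchical_partitioning(y, X)
        brute = brute_force_partition(y, X)
        assert ours == pytest.approx(brute, abs=1e-9)

    def test_singular_subset_named(self):
        x = np.random.default_rng(1).normal(size=10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="x0.*x1"):
            hierarchical_partitioning(x + np.arange(10) * 0.01, X)

    def test_too_few_cases_rejected(self):
        X = np.random.default_rng(2).normal(size=(4, 3))
        with pytest.raises(ValueError, match="complete cases"):
            hierarchical_partitioning(np.arange(4.0), X)


class TestPartitionOverPosterior:
    def test_contributions_sum_to_100_per_draw(self, paper_fit):
        _, model, _, res = paper_fit
        part = res.partition()
        assert part.contributions.shape[1] == 6
        assert np.allclose(part.contributions.sum(axis=1), 100.0)

    def test_single_varying_rate_takes_all(self, small_bundle,
                                           small_scenario):
        """If only average clutch size varies across region-years, it
        receives (almost) the whole contribution."""
        bundle, state, _ = small_bundle
        from conftest import make_state
        from ploveripm.sampler import PosteriorSummary

        d = bundle.design
        R, T = d.n_regions, d.n_years
        params = small_scenario.true_params
        import copy

        params = copy.deepcopy(params)
        params.beta2[:] = params.beta3[:] = 0
        params.beta_f[:] = 0
        params.beta_C[:] = 0
        st0 = make_state(bundle, state)
        st0 = pp.LatentState(log_n=state.log_n,
                             eps_2=np.linspace(-1, 1, R * T).reshape(R, T),
                             eps_3=np.zeros((R, T)), eps_f=np.zeros((R, T)),
                             eps_C=np.zeros((4, R, T - 1)),
                             eps_y=st0.eps_y)
        post = PosteriorSummary(design=d, options=pp.ModelOptions(),
                                config=pp.MCMCConfig(), draws={},
                                latent_draws=[(params, st0,
                                               np.zeros((0, T), bool))])
        part = pp.partition_over_posterior(post, bundle)
        assert part.contributions.shape == (1, 6)
        gamma_share = part.contributions[0, 0]
        assert gamma_share > 95.0


# ---------------------------------------------------------------------------
# Standardized effect sizes


class TestSES:
    @pytest.mark.parametrize("mean,lo,hi,ses,cat", [
        (1.77, 1.27, 2.33, 1.67, "strong"),
        (1.59, 0.56, 2.91, 0.68, "strong"),
        (0.82, 0.34, 1.37, 0.80, "strong"),
        (0.71, -0.29, 1.91, 0.32, "moderate"),
        (1.12, 0.13, 3.22, 0.36, "moderate"),
        (0.45, -0.45, 1.28, 0.26, "little_to_none"),
        (0.70, -0.30, 1.84, 0.33, "moderate"),
    ])
    def test_reported_effects(self, mean, lo, hi, ses, cat):
        res = pp.standardized_effect_size(mean, lo, hi)
        assert round(res.ses, 2) == pytest.approx(ses)
        assert res.category == cat

    def test_zero_mean(self):
        res = pp.standardized_effect_size(0.0, -1.0, 1.0)
        assert res.ses == 0.0 and res.category == "little_to_none"

    def test_boundaries_are_moderate(self):
        assert pp.standardized_effect_size(0.3, 0.0, 1.0).category \
            == "moderate"
        assert pp.standardized_effect_size(0.6, 0.0, 1.0).category \
            == "moderate"
        assert pp.standardized_effect_size(0.601, 0.0, 1.0).category \
            == "strong"

    def test_zero_width_errors(self):
        with pytest.raises(ValueError):
            pp.standardized_effect_size(1.0, 0.5, 0.5)

    @given(st.floats(-5, 5), st.floats(0.01, 10), st.floats(0.5, 100))
    def test_scale_invariant(self, mean, width, c):
        lo, hi = mean - width / 3, mean + 2 * width / 3
        a = pp.standardized_effect_size(mean, lo, hi).ses
        b = pp.standardized_effect_size(c * mean, c * lo, c * hi).ses
        assert a == pytest.approx(b, rel=1e-9)

    def test_ses_table_consistent_with_cellwise(self, paper_fit):
        _, _, _, res = paper_fit
        table = res.ses_table()
        summ = res.summary()
        for label, row in table.iterrows():
            again = pp.standardized_effect_size(
                summ.loc[label, "mean"], summ.loc[label, "ci_low"],
                summ.loc[label, "ci_high"])
            assert row["ses"] == pytest.approx(again.ses)
            assert row["category"] == again.category


class TestReplicateData:
    def test_masked_cells_absent_and_deterministic(self, paper_fit):
        _, model, _, res = paper_fit
        bundle = model.bundle
        params, state, z = res.posterior.latent_draws[0]
        rep1 = pp.replicate_data(params, state, bundle,
                                 np.random.default_rng(3), z)
        rep2 = pp.replicate_data(params, state, bundle,
                                 np.random.default_rng(3), z)
        assert len(rep1["survey"]) == len(bundle.counts)
        assert len(rep1["nest_size"]) == len(bundle.nests)
        for key in rep1:
            assert np.array_equal(rep1[key], rep2[key])

    def test_replicate_counts_mean_tracks_population(self, small_design):
        """With detection 1 and no local noise, replicated counts average
        the latent population size."""
        params = pp.default_params(small_design)
        params.xi = 0.0
        params.sigma_y = 1e-9
        R, T = small_design.n_regions, small_design.n_years
        counts = [pp.CountObservation("Texas", small_design.first_year, "A",
                                      140, 0) for _ in range(4000)]
        cov = [pp.CovariateRecord(r, y, 0.1 * k, k % 3, k % 5)
               for k, (r, y) in enumerate(
                   (r, y) for r in small_design.regions
                   for y in small_design.years)]
        bundle = pp.build_bundle(small_design, counts=counts,
                                 covariates=cov)
        state = pp.LatentState(
            log_n=np.full((R, T), np.log(200.0)),
            eps_2=np.zeros((R, T)), eps_3=np.zeros((R, T)),
            eps_f=np.zeros((R, T)), eps_C=np.zeros((4, R, T - 1)),
            eps_y={"survey": np.zeros(len(counts)), "grid": np.zeros(0),
                   "distance": np.zeros(0)})
        rep = pp.replicate_data(params, state, bundle,
                                np.random.default_rng(0))
        assert rep["survey"].mean() == pytest.approx(
            200.0, abs=3 * np.sqrt(200.0 / len(counts)))
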