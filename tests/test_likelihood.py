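"""Core model mathematics against hand-computed and enumerative oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm, poisson

import ploveripm as pp
from ploveripm.likelihood import (derive_demography, eps_groups, log_prior,
                                  phi_schedule_for, process_means)

from conftest import make_state


class TestExpectedNextPopulation:
    def test_no_recruitment_perfect_adults(self):
        assert pp.expected_next_population(100, 1, 1, 0.5, 0.5, 2.0, 0.0) \
            == pytest.approx(100.0)

    def test_full_replacement_plus_juveniles(self):
        assert pp.expected_next_population(100, 1, 1, 1, 1, 2.0, 1.0) \
            == pytest.approx(200.0)

    def test_hand_evaluated_mixture(self):
        # four-term skeleton evaluated directly by hand
        val = pp.expected_next_population(80, 0.78, 0.75, 0.07, 0.17,
                                          2.63, 0.37)
        hand = (80 * 0.5 * 0.78 + 80 * 0.5 * 0.75
                + 80 * 0.5 * 2.63 * 0.37 * 0.5 * 0.07
                + 80 * 0.5 * 2.63 * 0.37 * 0.5 * 0.17)
        assert val == pytest.approx(hand)
        assert val == pytest.approx(65.87, abs=0.01)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            pp.expected_next_population(0.0, 1, 1, 1, 1, 2, 0.5)


class TestClutchRegression:
    def test_zero_arguments_give_one(self):
        assert pp.clutch_theta(0.0, np.zeros(3), np.zeros(3), 0.0) \
            == pytest.approx(1.0)

    def test_intercept_only(self):
        assert pp.clutch_theta(0.5, np.zeros(3), np.zeros(3), 0.0) \
            == pytest.approx(np.exp(0.5))

    def test_single_slope(self):
        val = pp.clutch_theta(0.0, np.array([1.59, 0.0, 0.0]),
                              np.array([1.0, 0.0, 0.0]), 0.0)
        assert val == pytest.approx(np.exp(1.59))

    def test_overflow_guarded(self):
        assert np.isfinite(pp.clutch_theta(1e6, np.zeros(3), np.zeros(3),
                                           0.0))

    def test_probs_symmetric(self):
        assert pp.clutch_size_probs(1.0, 1.0) == pytest.approx([1 / 3] * 3)

    def test_probs_dominance_limit(self):
        omega = pp.clutch_size_probs(1e12, 1.0)
        assert omega[1] == pytest.approx(1.0, abs=1e-9)

    def test_probs_hand_normalisation(self):
        omega = pp.clutch_size_probs(np.exp(0.5), np.exp(1.0))
        assert omega == pytest.approx([0.1863, 0.3072, 0.5065], abs=2e-4)

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_probs_sum_to_one_and_gamma_in_range(self, t2, t3):
        omega = pp.clutch_size_probs(t2, t3)
        assert omega.sum() == pytest.approx(1.0)
        gamma = pp.average_clutch_size(omega)
        assert 1.0 <= gamma <= 3.0

    def test_average_clutch_edges(self):
        assert pp.average_clutch_size([1, 0, 0]) == pytest.approx(1.0)
        assert pp.average_clutch_size([0, 0, 1]) == pytest.approx(3.0)
        assert pp.average_clutch_size([0.1863, 0.3072, 0.5065]) \
            == pytest.approx(2.3202, abs=1e-3)

    def test_average_clutch_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            pp.average_clutch_size([0.5, 0.2, 0.2])


class TestLogisticLink:
    def test_zero_predictor_half(self):
        assert pp.inv_logit_regression(0, np.zeros(3), np.zeros(3), 0) \
            == pytest.approx(0.5)

    def test_printed_slope_example(self):
        val = pp.inv_logit_regression(-1.0, np.array([1.77, 0, 0]),
                                      np.array([1.0, 0, 0]), 0.0)
        assert val == pytest.approx(1.0 / (1.0 + np.exp(-0.77)), abs=1e-4)
        assert val == pytest.approx(0.6835, abs=1e-4)

    def test_saturation_no_underflow(self):
        assert pp.inv_logit_regression(-50, np.zeros(3), np.zeros(3), 0) \
            == pytest.approx(0.0, abs=1e-15)


class TestDetection:
    def test_edges(self):
        assert pp.detection_at_distance(0.5, 0.0) == 1.0
        assert pp.detection_at_distance(0.0, 100.0) == 1.0

    def test_median_distance_value(self):
        assert pp.detection_at_distance(0.020, 30.0) \
            == pytest.approx(np.exp(-0.6), abs=1e-12)
        assert pp.detection_at_distance(0.020, 30.0) \
            == pytest.approx(0.5488, abs=1e-4)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            pp.detection_at_distance(-0.1, 5.0)
        with pytest.raises(ValueError):
            pp.detection_at_distance(0.1, -5.0)

    @given(st.floats(0, 0.3), st.floats(0, 0.3), st.floats(0, 75),
           st.floats(0, 75))
    def test_monotone_in_xi_and_distance(self, x1, x2, d1, d2):
        lo_x, hi_x = sorted((x1, x2))
        lo_d, hi_d = sorted((d1, d2))
        assert pp.detection_at_distance(hi_x, lo_d) \
            <= pp.detection_at_distance(lo_x, lo_d)
        assert pp.detection_at_distance(lo_x, hi_d) \
            <= pp.detection_at_distance(lo_x, lo_d)


class TestCountLoglik:
    def test_zero_count(self):
        rate = 100 * 0.5
        assert pp.count_loglik(0, 100, 0.0, 0.5) == pytest.approx(-rate)

    def test_against_scipy_pmf(self):
        val = pp.count_loglik(55, 100, 0.0, 0.5488)
        assert val == pytest.approx(poisson.logpmf(55, 54.88), abs=1e-12)
        assert val == pytest.approx(-2.92, abs=0.01)
        assert pp.count_loglik(3, 7.0, 0.0, 1.0) == pytest.approx(
            poisson.logpmf(3, 7.0), abs=1e-12)

    def test_grid_divisor(self):
        assert pp.count_loglik(2, 668.0, 0.0, 1.0, divisor=668) \
            == pytest.approx(poisson.logpmf(2, 1.0), abs=1e-12)

    def test_zero_rate_guard(self):
        assert pp.count_loglik(0, 1.0, 0.0, 0.0) == 0.0
        assert pp.count_loglik(3, 1.0, 0.0, 0.0) == -np.inf


class TestProcessDensity:
    def test_at_mean(self):
        assert pp.population_process_logdensity(100, 100, 1.0) \
            == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)))

    def test_log_ratio_symmetry(self):
        a = pp.population_process_logdensity(110, 100, 0.2)
        b = pp.population_process_logdensity(100, 110, 0.2)
        assert a == pytest.approx(b)
        assert a == pytest.approx(norm.logpdf(np.log(1.1), 0, 0.2))

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            pp.population_process_logdensity(-1, 100, 0.2)


# ---------------------------------------------------------------------------
# CJS likelihood


def brute_force_cjs(det, f, phi, p_star):
    """Enumerate alive/dead paths: sum over the last occasion alive."""
    T = len(det)
    total = 0.0
    last_det = max(t for t in range(T) if det[t])
    for last_alive in range(last_det, T):
        prob = 1.0
        for s in range(f, last_alive):
            prob *= phi[s]
        if last_alive < T - 1:
            prob *= 1.0 - phi[last_alive]
        for t in range(f + 1, last_alive + 1):
            prob *= p_star if det[t] else 1.0 - p_star
        if any(det[t] for t in range(last_alive + 1, T)):
            prob = 0.0
        total += prob
    return np.log(total)


def _history(det, start=2000):
    f = next(t for t, d in enumerate(det) if d)
    return pp.EncounterHistory("b", "AF", "Texas", start + f, tuple(det),
                               start)


class TestEncounterLoglik:
    def test_final_occasion_only(self):
        h = _history([0, 0, 1])
        assert pp.encounter_history_loglik(h, [0.8, 0.8], 0.3, 0.4) == 0.0

    def test_two_occasion_hand_values(self):
        # p* = 0.6 from p_rec = p_res = 1 - sqrt(0.4)
        p = 1.0 - np.sqrt(0.4)
        h11 = _history([1, 1])
        assert pp.encounter_history_loglik(h11, [0.8], p, p) \
            == pytest.approx(np.log(0.48))
        h10 = _history([1, 0])
        assert pp.encounter_history_loglik(h10, [0.8], p, p) \
            == pytest.approx(np.log(0.52))

    def test_detection_before_first_capture_rejected(self):
        h = _history([0, 1, 1])
        object.__setattr__(h, "detections", (1, 1, 1))
        with pytest.raises(ValueError):
            pp.encounter_history_loglik(h, [0.8, 0.8], 0.3, 0.4)

    @pytest.mark.parametrize("T", [3, 5, 8])
    def test_matches_brute_force_enumeration(self, T):
        rng = np.random.default_rng(42)
        for trial in range(20):
            f = int(rng.integers(0, T - 1))
            det = [0] * T
            det[f] = 1
            for t in range(f + 1, T):
                det[t] = int(rng.random() < 0.5)
            if not any(det[f:]):
                det[f] = 1
            phi = rng.uniform(0.05, 0.95, T - 1)
            p_rec, p_res = rng.uniform(0.05, 0.9, 2)
            p_star = pp.combined_detection(p_rec, p_res)
            h = _history(det)
            assert pp.encounter_history_loglik(h, phi, p_rec, p_res) \
                == pytest.approx(brute_force_cjs(det, f, phi, p_star),
                                 abs=1e-10)

    def test_all_binary_histories_length_six(self):
        rng = np.random.default_rng(1)
        T = 6
        phi = rng.uniform(0.1, 0.9, T - 1)
        p_rec, p_res = 0.35, 0.55
        p_star = pp.combined_detection(p_rec, p_res)
        for f in range(T):
            for code in range(2 ** (T - f - 1)):
                det = [0] * T
                det[f] = 1
                for j in range(T - f - 1):
                    det[f + 1 + j] = (code >> j) & 1
                h = _history(det)
                assert pp.encounter_history_loglik(h, phi, p_rec, p_res) \
                    == pytest.approx(
                        brute_force_cjs(det, f, phi, p_star), abs=1e-10)


def test_phi_schedule_juvenile_transition(design):
    phi = np.zeros((4, design.n_regions, design.n_years - 1))
    phi[0] = 0.75  # AF
    phi[1] = 0.78  # AM
    phi[2] = 0.17  # JF
    phi[3] = 0.07  # JM
    det = [0] * design.n_years
    det[3] = 1
    h = pp.EncounterHistory("b", "JM", "New Mexico", 1998 + 3, tuple(det),
                            1998)
    sched = phi_schedule_for(h, phi, design)
    assert sched[3] == pytest.approx(0.07)  # juvenile male first interval
    assert sched[4] == pytest.approx(0.78)  # adult male afterwards


# ---------------------------------------------------------------------------
# Joint density


def test_joint_equals_sum_of_components(small_bundle, small_scenario):
    bundle, state, demog = small_bundle
    params = small_scenario.true_params
    st_full = make_state(bundle, state, fill_eps_y=0.05)
    design = bundle.design
    total = pp.joint_log_posterior(params, st_full, bundle)

    # independent reassembly from the public pieces
    X = bundle.covariate_matrix()
    dem = derive_demography(params, X, st_full)
    expected = float(np.sum(norm.logpdf(st_full.log_n[:, 0], params.mu0,
                                        0.1)))
    means = process_means(st_full.log_n, dem)
    expected += float(np.sum(norm.logpdf(st_full.log_n[:, 1:], means,
                                         params.sigma_N)))
    p_count = pp.detection_at_distance(params.xi, design.median_distance)
    for stream, divisor in (("survey", 1.0), ("grid", design.n_grids),
                            ("distance", design.n_grids)):
        gidx, _ = eps_groups(bundle, stream)
        for k, rec in enumerate(bundle.stream_records(stream)):
            i, t = design.region_index(rec.region), design.year_index(rec.year)
            p = (pp.detection_at_distance(params.xi, rec.distance)
                 if stream == "distance" else p_count)
            expected += pp.count_loglik(rec.count, np.exp(st_full.log_n[i, t]),
                                        st_full.eps_y[stream][gidx[k]], p,
                                        divisor=divisor)
        expected += float(np.sum(norm.logpdf(st_full.eps_y[stream], 0,
                                             params.sigma_y)))
    for rec in bundle.nests:
        i, t = design.region_index(rec.region), design.year_index(rec.year)
        expected += np.log(dem.omega[i, t, rec.clutch_size - 1])
        expected += (np.log(dem.pi[i, t]) if rec.fate
                     else np.log1p(-dem.pi[i, t]))
    for h in bundle.encounters:
        expected += pp.encounter_history_loglik(
            h, phi_schedule_for(h, dem.phi, design), params.p_rec,
            params.p_res)
    expected += float(np.sum(norm.logpdf(st_full.eps_2, 0, params.sigma_2)))
    expected += float(np.sum(norm.logpdf(st_full.eps_3, 0, params.sigma_3)))
    expected += float(np.sum(norm.logpdf(st_full.eps_f, 0, params.sigma_f)))
    expected += float(np.sum(norm.logpdf(
        st_full.eps_C, 0, np.asarray(params.sigma_C).reshape(4, 1, 1))))
    expected += log_prior(params, pp.ModelOptions())
    assert total == pytest.approx(expected, abs=1e-10)


def test_joint_additive_in_observations(small_design):
    scenario = pp.SimulationScenario(design=small_design,
                                     availability="full", n_nests=0,
                                     n_marked=0, seed=3)
    bundle, state, _ = pp.simulate_bundle(scenario)
    params = scenario.true_params
    empty = pp.build_bundle(small_design, covariates=bundle.covariates,
                            standardize=False)
    base_state = make_state(empty, state)
    base = pp.joint_log_posterior(params, base_state, empty)

    rec = pp.CountObservation("Texas", small_design.first_year + 2, "A",
                              140, 7)
    one = pp.build_bundle(small_design, counts=[rec],
                          covariates=bundle.covariates, standardize=False)
    one_state = make_state(one, state, fill_eps_y=0.0)
    with_one = pp.joint_log_posterior(params, one_state, one)
    i, t = 0, 2
    extra = pp.count_loglik(7, float(np.exp(state.log_n[i, t])), 0.0,
                            pp.detection_at_distance(
                                params.xi, small_design.median_distance))
    extra += float(norm.logpdf(0.0, 0.0, params.sigma_y))
    assert with_one - base == pytest.approx(extra, abs=1e-10)


def test_joint_invariant_under_region_relabelling(small_design):
    """With universal slopes, swapping two regions' labels and data leaves
    the joint density unchanged."""
    scenario = pp.SimulationScenario(design=small_design,
                                     availability="full", n_nests=6,
                                     n_marked=5, seed=9)
    bundle, state, _ = pp.simulate_bundle(scenario)
    params = scenario.true_params
    st0 = make_state(bundle, state, fill_eps_y=0.02)
    lp0 = pp.joint_log_posterior(params, st0, bundle)

    swap = {"Texas": "New Mexico", "New Mexico": "Texas",
            "Oklahoma": "Oklahoma"}

    def sw(records, field="region"):
        from dataclasses import replace
        return [replace(r, region=swap[r.region]) for r in records]

    bundle2 = pp.build_bundle(
        small_design, counts=sw(bundle.counts),
        grid_counts=sw(bundle.grid_counts), distances=sw(bundle.distances),
        nests=sw(bundle.nests),
        encounters=sw(bundle.encounters),
        covariates=sw(bundle.covariates), standardize=False)
    perm = [1, 0, 2]
    import copy
    params2 = copy.deepcopy(params)
    params2.mu0 = params.mu0[perm]
    st2 = pp.LatentState(
        log_n=st0.log_n[perm], eps_2=st0.eps_2[perm],
        eps_3=st0.eps_3[perm], eps_f=st0.eps_f[perm],
        eps_C=st0.eps_C[:, perm, :],
        eps_y={k: v.copy() for k, v in st0.eps_y.items()})
    lp2 = pp.joint_log_posterior(params2, st2, bundle2)
    assert lp2 == pytest.approx(lp0, abs=1e-8)
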