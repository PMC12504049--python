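"""Event-based model: mixtures, posteriors, ordering, staging, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from itertools import permutations

from ftdprog.debm import (BiomarkerTable, GmmFit, biomarker_screen,
                          bootstrap_ordering, clinical_correlation,
                          confound_adjust, estimate_ordering,
                          event_probabilities, fit_gmm, kendall_tau_distance,
                          ordering_cost, stage_subjects, subject_ordering,
                          validate_auc, EventOrdering)
from ftdprog.errors import InsufficientDataError


def _table(values: dict, labels, direction="increase"):
    frame = pd.DataFrame(values)
    frame.index = [f"s{i}" for i in range(len(frame))]
    return BiomarkerTable(
        values=frame,
        labels=pd.Series(list(labels), index=frame.index),
        directions={k: direction for k in values},
        transforms={k: "identity" for k in values},
    )


def _sharp_fit(name, normal=0.0, abnormal=4.0, sd=1.0):
    return GmmFit(name, "increase", normal, sd, abnormal, sd,
                  {"control": 0.05, "symptomatic": 0.6}, mse=0.0,
                  converged=True, direction_ok=True)


class TestConfoundAdjust:
    def test_pure_age_effect_removed_exactly(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(30, 70, 60)
        demo = pd.DataFrame({"subject_id": [f"s{i}" for i in range(60)],
                             "age": age,
                             "sex": ["male", "female"] * 30})
        t = _table({"bm": 1.0 + 0.02 * age}, ["control"] * 60)
        out = confound_adjust(t, demo)
        np.testing.assert_allclose(out.values["bm"], 0.0, atol=1e-10)

    def test_control_column_mean_zero_and_mask_preserved(self, grn_cohort,
                                                         debm_results):
        table, _, _, _ = debm_results
        is_ctl = (table.labels == "control").to_numpy()
        for name in table.biomarkers:
            col = table.values[name].to_numpy(float)
            assert abs(np.nanmean(col[is_ctl])) < 1e-9
        # mask identical to the raw cohort's missingness
        raw_nfl = grn_cohort.set_index("subject_id")["nfl"]
        assert table.values["nfl"].isna().equals(raw_nfl.isna())


class TestScreen:
    def test_separated_groups_all_significant(self, debm_results):
        table, _, _, _ = debm_results
        screen = biomarker_screen(table)
        assert screen["significant"].all()

    def test_constant_biomarker_not_significant(self):
        t = _table({"bm": [1.0] * 60}, ["control"] * 30 + ["symptomatic"] * 30)
        screen = biomarker_screen(t)
        assert screen["p"].iloc[0] == 1.0
        assert not screen["significant"].iloc[0]


class TestGmm:
    def test_parameter_recovery_on_well_separated_draws(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        labels = np.array(["control"] * 500 + ["symptomatic"] * 500)
        fit = fit_gmm(values, labels, "increase", biomarker="sim")
        assert fit.normal_mean == pytest.approx(0.0, abs=0.2)
        assert fit.abnormal_mean == pytest.approx(5.0, abs=0.2)
        assert fit.admitted

    def test_decrease_direction_orders_means(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(10, 1, 400), rng.normal(6, 1, 200)])
        labels = np.array(["control"] * 400 + ["symptomatic"] * 200)
        fit = fit_gmm(values, labels, "decrease", biomarker="sim")
        assert fit.abnormal_mean < fit.normal_mean
        assert fit.direction_ok

    def test_degenerate_identical_values_not_admitted(self):
        values = np.full(100, 3.0)
        labels = np.array(["control"] * 50 + ["symptomatic"] * 50)
        fit = fit_gmm(values, labels, "increase")
        assert not fit.admitted

    def test_control_abnormal_fraction_bounded(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, 400)  # single Gaussian, no abnormal state
        labels = np.array(["control"] * 200 + ["symptomatic"] * 200)
        fit = fit_gmm(values, labels, "increase")
        assert fit.mixing_fractions["control"] <= 0.10 + 1e-12

    def test_too_few_observations_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm(np.arange(12.0), np.array(["control"] * 6 + ["symptomatic"] * 6),
                    "increase")


class TestEventProbabilities:
    def test_value_at_normal_mean_is_far_tail_of_abnormal(self):
        fit = _sharp_fit("bm")
        assert fit.posterior(np.array([0.0]))[0] < 0.01

    def test_equidistant_value_gives_half(self):
        fit = _sharp_fit("bm")
        assert fit.posterior(np.array([2.0]))[0] == pytest.approx(0.5)

    def test_missing_values_flagged_nan(self):
        t = _table({"bm": [0.0, np.nan, 4.0]}, ["control"] * 3)
        P = event_probabilities(t, {"bm": _sharp_fit("bm")})
        assert np.isnan(P["bm"].iloc[1])
        assert np.isfinite(P["bm"].iloc[0])

    def test_generator_abnormal_draws_mostly_detected(self):
        """At 4-sd separation the posterior exceeds 0.5 for >= 95% of
        abnormal draws (two-Gaussian overlap integral)."""
        rng = np.random.default_rng(8)
        draws = rng.normal(4.0, 1.0, 2000)
        fit = _sharp_fit("bm")
        assert (fit.posterior(draws) > 0.5).mean() >= 0.95


class TestOrdering:
    def test_subject_ordering_sorts_by_posterior(self):
        row = pd.Series({"A": 0.9, "B": 0.2, "C": 0.7})
        assert subject_ordering(row) == ["A", "C", "B"]

    def test_ties_break_alphabetically(self):
        row = pd.Series({"c": 0.5, "a": 0.5, "b": 0.5})
        assert subject_ordering(row) == ["a", "b", "c"]

    def test_missing_biomarker_dropped_from_ranking(self):
        row = pd.Series({"A": 0.9, "B": np.nan, "C": 0.95})
        assert subject_ordering(row) == ["C", "A"]

    def test_fewer_than_two_observed_rejected(self):
        with pytest.raises(InsufficientDataError):
            subject_ordering(pd.Series({"A": 0.9, "B": np.nan}))

    def test_concordant_subjects_cost_zero(self):
        P = pd.DataFrame({"A": [0.9, 0.8], "B": [0.5, 0.6], "C": [0.1, 0.2]})
        assert ordering_cost(("A", "B", "C"), P) == pytest.approx(0.0)

    def test_single_discordant_pair_weighted_by_probability_gap(self):
        P = pd.DataFrame({"A": [1.0], "B": [0.0]})
        assert ordering_cost(("B", "A"), P) == pytest.approx(1.0)
        assert ordering_cost(("A", "B"), P) == pytest.approx(0.0)

    def test_forward_plus_reverse_cost_equals_total_gap(self):
        rng = np.random.default_rng(3)
        P = pd.DataFrame(rng.random((40, 5)), columns=list("abcde"))
        sigma = ("c", "a", "e", "b", "d")
        total = sum(abs(P[k] - P[l]).sum()
                    for i, k in enumerate("abcde") for l in "abcde"[i + 1:])
        both = ordering_cost(sigma, P) + ordering_cost(tuple(reversed(sigma)), P)
        assert both == pytest.approx(total)

    def test_cost_equivariant_under_relabeling(self):
        rng = np.random.default_rng(4)
        P = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        sigma = ("b", "d", "a", "c")
        renamed = P.rename(columns={"a": "w", "b": "x", "c": "y", "d": "z"})
        sigma2 = ("x", "z", "w", "y")
        assert ordering_cost(sigma, P) == pytest.approx(
            ordering_cost(sigma2, renamed))

    def test_two_biomarker_ordering_follows_posteriors(self):
        P = pd.DataFrame({"A": [0.9] * 10, "B": [0.1] * 10})
        assert estimate_ordering(P).sequence == ("A", "B")

    def test_exhaustive_search_is_global_minimum(self):
        rng = np.random.default_rng(9)
        names = list("abcd")
        P = pd.DataFrame(rng.random((25, 4)), columns=names)
        est = estimate_ordering(P)
        brute = min((ordering_cost(perm, P), perm)
                    for perm in permutations(names))
        assert est.cost == pytest.approx(brute[0])

    def test_greedy_matches_exhaustive_on_planted_instance(self):
        rng = np.random.default_rng(10)
        names = [f"m{j}" for j in range(6)]
        grad = np.linspace(0.85, 0.15, 6)
        P = pd.DataFrame(rng.beta(4 * grad, 4 * (1 - grad), size=(80, 6)),
                         columns=names)
        greedy = estimate_ordering(P, exhaustive_limit=1, seed=2)
        exact = estimate_ordering(P, exhaustive_limit=6)
        assert greedy.cost == pytest.approx(exact.cost)


class TestBootstrap:
    def test_count_matrix_rows_and_columns_sum_to_replicates(self, debm_results):
        table, fits, _, _ = debm_results
        pvd = bootstrap_ordering(table, fits, refit=False, n_replicates=25,
                                 seed=3)
        assert (pvd.counts.sum(axis=0) == 25).all()
        assert (pvd.counts.sum(axis=1) == 25).all()

    def test_same_seed_reproduces_counts(self, debm_results):
        table, fits, _, _ = debm_results
        a = bootstrap_ordering(table, fits, refit=False, n_replicates=10, seed=5)
        b = bootstrap_ordering(table, fits, refit=False, n_replicates=10, seed=5)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_noise_free_posteriors_concentrate_on_diagonal(self):
        # binary staircase posteriors: every replicate recovers the ordering
        n, names = 60, ["e1", "e2", "e3"]
        stages = np.repeat([0, 1, 2, 3], n // 4)
        P = pd.DataFrame({m: (stages > j).astype(float) * 0.98 + 0.01
                          for j, m in enumerate(names)},
                         index=[f"s{i}" for i in range(n)])
        table = _table({m: P[m].to_numpy() for m in names},
                       ["control"] * (n // 2) + ["symptomatic"] * (n // 2))
        fits = {m: _sharp_fit(m, normal=0.01, abnormal=0.99, sd=0.05)
                for m in names}
        pvd = bootstrap_ordering(table, fits, refit=False, n_replicates=20,
                                 seed=1, row_order=("e1", "e2", "e3"))
        np.testing.assert_array_equal(pvd.counts, np.eye(3, dtype=int) * 20)


class TestStaging:
    def test_all_normal_posteriors_stage_zero(self):
        P = pd.DataFrame({m: [0.01] for m in "abcd"})
        st_ = stage_subjects(P, EventOrdering(tuple("abcd"), 0.0))
        assert st_["discrete_stage"].iloc[0] == 0

    def test_all_abnormal_posteriors_stage_k(self):
        P = pd.DataFrame({m: [0.99] for m in "abcd"})
        st_ = stage_subjects(P, EventOrdering(tuple("abcd"), 0.0))
        assert st_["discrete_stage"].iloc[0] == 4

    def test_hand_computed_intermediate_stage(self):
        # posteriors (0.9, 0.8, 0.1, 0.05) along the ordering: the five
        # candidate log-scores peak at k = 2
        P = pd.DataFrame({"a": [0.9], "b": [0.8], "c": [0.1], "d": [0.05]})
        st_ = stage_subjects(P, EventOrdering(("a", "b", "c", "d"), 0.0))
        assert st_["discrete_stage"].iloc[0] == 2
        assert st_["continuous_stage"].iloc[0] == pytest.approx(np.mean([0.9, 0.8, 0.1, 0.05]))

    def test_all_missing_subject_excluded(self):
        P = pd.DataFrame({"a": [0.9, np.nan], "b": [0.8, np.nan]})
        st_ = stage_subjects(P, EventOrdering(("a", "b"), 0.0))
        assert len(st_) == 1

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.02, 0.95), min_size=2, max_size=6),
           st.floats(0.001, 0.04))
    def test_raising_posteriors_never_lowers_stage(self, probs, bump):
        names = [f"m{j}" for j in range(len(probs))]
        order = EventOrdering(tuple(names), 0.0)
        low = pd.DataFrame([dict(zip(names, probs))])
        high = pd.DataFrame([{k: v + bump for k, v in zip(names, probs)}])
        s_low = stage_subjects(low, order)["discrete_stage"].iloc[0]
        s_high = stage_subjects(high, order)["discrete_stage"].iloc[0]
        assert s_high >= s_low


class TestValidation:
    def test_perfectly_separated_stages_auc_one(self):
        stages = pd.DataFrame(
            {"discrete_stage": [0] * 40 + [9] * 40,
             "continuous_stage": [0.1] * 40 + [0.9] * 40},
            index=[f"s{i}" for i in range(80)])
        labels = pd.Series(["control"] * 40 + ["symptomatic"] * 40,
                           index=stages.index)
        mean, sd = validate_auc(stages, labels, folds=4, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_label_independent_stages_auc_near_half(self):
        rng = np.random.default_rng(2)
        stages = pd.DataFrame(
            {"discrete_stage": 0, "continuous_stage": rng.random(300)},
            index=[f"s{i}" for i in range(300)])
        labels = pd.Series(["control"] * 150 + ["symptomatic"] * 150,
                           index=stages.index)
        mean, _ = validate_auc(stages, labels, folds=10, seed=0)
        assert 0.35 < mean < 0.65

    def test_spearman_on_monotone_scores(self):
        stages = pd.DataFrame({"continuous_stage": [0.1, 0.2, 0.5, 0.7, 0.9]},
                              index=list("abcde"))
        scores = pd.DataFrame({"mmse": [30, 29, 25, 20, 10],
                               "cdr_ftld_sob": [0, 1, 3, 8, 16]},
                              index=list("abcde"))
        out = clinical_correlation(stages, scores,
                                   ["mmse", "cdr_ftld_sob"]).set_index("score")
        assert out.loc["mmse", "rho"] == pytest.approx(-1.0)
        assert out.loc["cdr_ftld_sob", "rho"] == pytest.approx(1.0)

    def test_spearman_matches_rank_difference_formula(self):
        # 5 untied pairs: rho = 1 - 6 * sum(d^2) / (n (n^2 - 1))
        stages = pd.DataFrame({"continuous_stage": [1, 2, 3, 4, 5]},
                              index=list("abcde"))
        scores = pd.DataFrame({"tmtb": [10, 30, 20, 50, 40]},
                              index=list("abcde"))
        out = clinical_correlation(stages, scores, ["tmtb"])
        # score ranks (1, 3, 2, 5, 4): sum d^2 = 4 -> rho = 1 - 24/120
        assert out["rho"].iloc[0] == pytest.approx(0.8)

    def test_kendall_tau_distance_counts_discordant_pairs(self):
        assert kendall_tau_distance(list("abc"), list("abc")) == 0
        assert kendall_tau_distance(list("cba"), list("abc")) == 3
        assert kendall_tau_distance(list("bac"), list("abc")) == 1
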