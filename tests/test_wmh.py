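"""Normative model and nonparametric group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ftdprog.errors import InsufficientDataError, RankDeficiencyError
from ftdprog.wmh import (adjust_wmh, cliffs_delta, dunn_posthoc,
                         fit_normative_model, fit_region_model,
                         kruskal_wallis, regional_analysis)


def _controls(age, values, sex=None):
    sex = sex if sex is not None else ["female"] * len(age)
    return pd.DataFrame({"age": age, "sex": sex, "log10_wmh": values,
                         "status": "control"})


class TestNormativeModel:
    def test_exact_recovery_on_noiseless_linear_data(self):
        age = np.array([30, 40, 50, 60, 35, 45, 55, 65], float)
        sex = ["male", "female"] * 4
        y = 2.0 + 0.01 * age  # no sex effect, no noise
        model = fit_normative_model(_controls(age, y, sex))
        assert model.age_coefficient == pytest.approx(0.01, abs=1e-12)
        assert model.sex_coefficient == pytest.approx(0.0, abs=1e-12)
        assert model.intercept == pytest.approx(2.0, abs=1e-10)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-10)

    def test_three_point_fixture_solves_normal_equations(self):
        # (40, 3.0), (50, 3.5), (60, 4.0), one sex: slope 0.05, intercept 1.0
        model = fit_normative_model(
            _controls([40.0, 50.0, 60.0], [3.0, 3.5, 4.0]))
        assert model.age_coefficient == pytest.approx(0.05, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, abs=1e-10)
        assert model.n_controls == 3

    def test_control_residual_mean_is_zero(self, grn_cohort):
        model = fit_region_model(grn_cohort, "total")
        adjusted, _ = adjust_wmh(
            grn_cohort[grn_cohort.status == "control"], model, "total")
        assert abs(adjusted["adjusted"].mean()) < 1e-10

    def test_adjustment_is_genotype_blind(self, grn_cohort):
        """Two identical records get identical adjusted values regardless of
        genotype label."""
        model = fit_region_model(grn_cohort, "total")
        row = grn_cohort[grn_cohort.status == "control"].iloc[[0]].copy()
        clone = row.copy()
        clone["genotype"] = "GRN"
        a, _ = adjust_wmh(row, model, "total")
        b, _ = adjust_wmh(clone, model, "total")
        assert a["adjusted"].iloc[0] == b["adjusted"].iloc[0]

    def test_missing_demographics_excluded_and_counted(self, grn_cohort):
        cohort = grn_cohort.head(20).copy()
        cohort.loc[cohort.index[:4], "age"] = np.nan
        model = fit_region_model(grn_cohort, "total")
        adjusted, excluded = adjust_wmh(cohort, model, "total")
        assert excluded == 4
        assert len(adjusted) == 16

    def test_too_few_controls_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_normative_model(_controls([40.0, 50.0], [3.0, 3.5]))

    def test_constant_age_single_sex_names_collinear_terms(self):
        with pytest.raises(RankDeficiencyError) as err:
            fit_normative_model(_controls([50.0] * 5, [3.0, 3.1, 3.2, 3.3, 3.4]))
        assert "age" in str(err.value)

    def test_nonpositive_volume_identifies_record(self, grn_cohort):
        cohort = grn_cohort.head(5).copy()
        cohort.loc[cohort.index[2], "wmh_total"] = -1.0
        model = fit_region_model(grn_cohort, "total")
        with pytest.raises(ValueError, match="non-positive"):
            adjust_wmh(cohort, model, "total")


class TestKruskalWallis:
    def test_three_group_toy_value(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(7.2, 2), rel=1e-9)

    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_fully_tied_data_defined_as_zero(self):
        h, p = kruskal_wallis([1, 1, 1], [1, 1, 1])
        assert (h, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.lists(st.integers(-50, 50), min_size=2, max_size=8),
                    min_size=2, max_size=4))
    def test_invariant_under_strictly_monotone_transform(self, groups):
        # cubing is strictly monotone and exact on small integers, so the
        # rank (and tie) structure is preserved exactly
        h1, _ = kruskal_wallis(*groups)
        h2, _ = kruskal_wallis(*[[float(x) ** 3 for x in g] for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-8)


def _brute_dunn_z(a, b, pooled_groups):
    """Independent rank arithmetic for one Dunn contrast."""
    pooled = [x for g in pooled_groups for x in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    sizes, offsets, start = [], [], 0
    for g in pooled_groups:
        sizes.append(len(g))
        offsets.append(start)
        start += len(g)
    def mean_rank(idx):
        return sum(ranks[offsets[idx]:offsets[idx] + sizes[idx]]) / sizes[idx]
    n = len(pooled)
    from collections import Counter
    ties = Counter(pooled)
    tie_sum = sum(t ** 3 - t for t in ties.values())
    var = (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1)))
    var *= 1.0 / sizes[a] + 1.0 / sizes[b]
    return (mean_rank(a) - mean_rank(b)) / var ** 0.5 if var > 0 else 0.0


DUNN_FIXTURES = [
    [[1, 2, 3], [4, 5, 6], [7, 8, 9]],
    [[1, 1, 2], [2, 3, 3], [4, 4, 5]],          # ties across groups
    [[10, 20], [15, 25, 35], [5, 30, 40, 50]],
    [[1, 2], [3, 4], [5, 6], [7, 8]],
    [[2.5, 2.5, 2.5], [2.5, 2.5], [1.0, 4.0]],  # heavy ties
]


class TestDunn:
    @pytest.mark.parametrize("groups", DUNN_FIXTURES)
    def test_matches_brute_force_rank_formula(self, groups):
        named = {f"g{i}": np.array(g, float) for i, g in enumerate(groups)}
        table = dunn_posthoc(named)
        for _, row in table.iterrows():
            a = int(row["group_a"][1:])
            b = int(row["group_b"][1:])
            expect = _brute_dunn_z(a, b, groups)
            assert row["z"] == pytest.approx(expect, abs=1e-10)

    def test_identical_groups_z_zero_p_one(self):
        table = dunn_posthoc({"a": np.array([1.0, 2.0, 3.0]),
                              "b": np.array([1.0, 2.0, 3.0])})
        assert table["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_caps_at_one(self):
        table = dunn_posthoc({"a": np.array([1.0, 2.0, 3.0]),
                              "b": np.array([1.5, 2.5, 3.5])},
                             family_size=50)
        assert table["p_bonferroni"].iloc[0] <= 1.0
        assert table["p_bonferroni"].iloc[0] >= table["p_raw"].iloc[0]


class TestCliffsDelta:
    def test_identical_samples_give_zero(self):
        assert cliffs_delta([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_complete_separation_gives_one(self):
        assert cliffs_delta([4, 5, 6], [1, 2, 3]) == 1.0

    def test_enumerated_pairs_with_tie(self):
        # a = {1, 2}, b = {2, 3}; the four cross pairs are
        # 1-2 (<), 1-3 (<), 2-2 (tie), 2-3 (<): delta = (0 - 3) / 4
        assert cliffs_delta([1, 2], [2, 3]) == pytest.approx(-0.75)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=12),
           st.lists(st.floats(-10, 10), min_size=1, max_size=12))
    def test_antisymmetry(self, a, b):
        assert cliffs_delta(a, b) == pytest.approx(-cliffs_delta(b, a), abs=1e-12)


class TestRegionalAnalysis:
    def test_one_comparison_row_per_region_and_pair(self, grn_cohort):
        grouping = grn_cohort["genotype"].str.cat(grn_cohort["status"], sep=":")
        out = regional_analysis(grn_cohort, grouping, regions=["total"])
        # 3 groups -> 3 pairwise contrasts for the single region
        assert len(out) == 3
        assert (out["p_bonferroni"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_bonferroni"] <= 1.0).all()
        assert out["delta"].between(-1, 1).all()

    def test_grn_symptomatic_elevation_detected(self, full_cohort):
        grouping = full_cohort["genotype"].str.cat(full_cohort["status"], sep=":")
        out = regional_analysis(full_cohort, grouping,
                                regions=["total", "left_frontal"])
        sig = out[(out.group_a == "GRN:symptomatic")
                  & (out.group_b == "noncarrier:control")]
        assert (sig["p_bonferroni"] < 0.001).all()
        assert (sig["delta"] > 0).all()

    def test_unknown_region_rejected(self, grn_cohort):
        grouping = grn_cohort["status"]
        with pytest.raises(KeyError):
            regional_analysis(grn_cohort, grouping, regions=["brainstem"])
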