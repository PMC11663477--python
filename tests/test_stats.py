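import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from anbrainage import stats
from anbrainage.errors import CollinearityError
from anbrainage.synthetic_cohort import PHENOTYPE_COLUMNS


def make_records(groups, ages, timepoints=None, participants=None, **covs):
    n = len(groups)
    timepoints = timepoints or ["baseline"] * n
    participants = participants or [f"P{i}" for i in range(n)]
    scan_ids = [f"{p}_{'bl' if t == 'baseline' else 'fu'}"
                for p, t in zip(participants, timepoints)]
    df = pd.DataFrame({
        "participant_id": participants, "scan_id": scan_ids, "group": groups,
        "timepoint": timepoints, "age": ages,
        "bmi_sds": covs.get("bmi_sds", np.zeros(n) + np.arange(n) * 0.1),
        "edi2_total": covs.get("edi2_total", 150.0 + np.arange(n)),
        "bdi2_total": covs.get("bdi2_total", 10.0 + np.arange(n) % 5),
        "illness_duration": covs.get("illness_duration", 1.0 + 0.3 * np.arange(n)),
        "ssri": covs.get("ssri", [False] * n),
        "subtype": covs.get("subtype", ["restricting"] * n),
    }, columns=PHENOTYPE_COLUMNS)
    return df


def make_results(records, scores, tissue="GM"):
    return pd.DataFrame({
        "scan_id": records["scan_id"], "tissue": tissue,
        "age": records["age"], "predicted_age": records["age"] + scores,
        "brainage_raw": scores, "brainage_corrected": scores,
    })


@pytest.fixture()
def cs1_fixture():
    records = make_records(["HC"] * 3 + ["acAN"] * 3, [14, 16, 18, 14, 16, 18])
    results = make_results(records, np.array([0.1, -0.1, 0.0, 2.1, 1.9, 2.0]))
    return records, results


class TestCrossSectional:
    def test_worked_fixture_matches_closed_form_ols(self, cs1_fixture):
        records, results = cs1_fixture
        effects = stats.cross_sectional_model(records, results, model="CS1")
        acan = next(e for e in effects if e.term == "acAN_vs_HC")
        # independent closed form: two-group OLS with 3 obs per group
        sse = 0.1 ** 2 + 0.1 ** 2 + 0.1 ** 2 + 0.1 ** 2  # residuals about group means
        s2 = sse / 4
        se = np.sqrt(s2 * (1 / 3 + 1 / 3))
        tcrit = sps.t.ppf(0.975, 4)
        assert acan.beta == pytest.approx(2.0, abs=1e-10)
        assert acan.ci_low == pytest.approx(2.0 - tcrit * se, abs=1e-8)
        assert acan.ci_high == pytest.approx(2.0 + tcrit * se, abs=1e-8)
        assert acan.p_value == pytest.approx(2 * sps.t.sf(2.0 / se, 4), rel=1e-6)

    def test_exact_group_difference_with_zero_residual(self):
        records = make_records(["HC"] * 4 + ["acAN"] * 4, [13, 15, 17, 19] * 2)
        results = make_results(records, np.array([0.0] * 4 + [2.0] * 4))
        effects = stats.cross_sectional_model(records, results, model="CS1")
        acan = next(e for e in effects if e.term == "acAN_vs_HC")
        assert acan.beta == pytest.approx(2.0, abs=1e-10)
        assert acan.p_value < 1e-12

    def test_permuted_labels_centre_on_zero(self):
        rng = np.random.default_rng(21)
        scores = rng.normal(0, 1, size=40)
        betas = []
        for _ in range(100):
            groups = rng.permutation(["HC"] * 20 + ["acAN"] * 20)
            records = make_records(list(groups), rng.uniform(12, 23, 40))
            results = make_results(records, scores)
            effects = stats.cross_sectional_model(records, results, model="CS1")
            betas.append(next(e.beta for e in effects if e.term == "acAN_vs_HC"))
        # mean permutation beta ~ N(0, sd/sqrt(100 * n/4))
        assert abs(np.mean(betas)) < 4 * np.std(scores) / np.sqrt(100 * 10)

    @pytest.mark.parametrize("model, extra_term", [
        ("CS2a", "age_c"), ("CS2b", "ssri_flag"), ("CS2c", "binge_purge"),
    ])
    def test_secondary_models_add_covariates(self, model, extra_term):
        rng = np.random.default_rng(5)
        records = make_records(
            ["HC"] * 10 + ["acAN"] * 10, rng.uniform(12, 23, 20),
            ssri=[False] * 10 + [True, False] * 5,
            subtype=["not_applicable"] * 10 + ["restricting", "binge_purge"] * 5,
        )
        results = make_results(records, rng.normal(size=20))
        effects = stats.cross_sectional_model(records, results, model=model)
        assert any(extra_term in e.term for e in effects)

    def test_rank_deficient_design_names_columns(self):
        # every patient on SSRI, every control not: ssri duplicates group
        records = make_records(["HC"] * 5 + ["acAN"] * 5, [13, 14, 15, 16, 17] * 2,
                               ssri=[False] * 5 + [True] * 5)
        results = make_results(records, np.arange(10) * 0.1)
        with pytest.raises(CollinearityError) as err:
            stats.cross_sectional_model(records, results, model="CS2b")
        assert err.value.columns

    def test_estimates_invariant_to_row_order(self, cs1_fixture):
        records, results = cs1_fixture
        e1 = stats.cross_sectional_model(records, results, model="CS1")
        perm = np.random.default_rng(3).permutation(len(records))
        e2 = stats.cross_sectional_model(records.iloc[perm].reset_index(drop=True),
                                         results.iloc[perm].reset_index(drop=True),
                                         model="CS1")
        for a, b in zip(e1, e2):
            assert a.beta == pytest.approx(b.beta, abs=1e-10)


class TestClinicalAssociations:
    def test_outcome_built_from_zscored_bmi_recovers_beta(self):
        rng = np.random.default_rng(8)
        n = 40
        records = make_records(["acAN"] * n, rng.uniform(12, 23, n),
                               bmi_sds=rng.normal(-2.8, 0.8, n),
                               edi2_total=rng.normal(220, 40, n),
                               bdi2_total=rng.normal(20, 9, n),
                               illness_duration=rng.gamma(2, 1, n))
        outcome = 2.0 * stats.zscore(records["bmi_sds"].to_numpy())
        results = make_results(records, outcome)
        effects = stats.clinical_association_model(records, results)
        by_term = {e.term: e.beta for e in effects}
        assert by_term["z_bmi_sds"] == pytest.approx(2.0, abs=1e-8)
        for term in ("z_edi2_total", "z_bdi2_total", "z_illness_duration", "age"):
            assert by_term[term] == pytest.approx(0.0, abs=1e-8)


class TestLongitudinal:
    def test_balanced_change_scores_give_mean_change(self):
        # changes {-1, -2, -3} -> time effect -2 exactly on balanced data
        records = make_records(
            ["acAN"] * 6, [14, 14.25, 16, 16.25, 18, 18.25],
            timepoints=["baseline", "followup"] * 3,
            participants=["P0", "P0", "P1", "P1", "P2", "P2"],
        )
        base = np.array([2.0, 1.5, 2.5])
        changes = np.array([-1.0, -2.0, -3.0])
        scores = np.empty(6)
        scores[0::2] = base
        scores[1::2] = base + changes
        results = make_results(records, scores)
        effects = stats.longitudinal_model(records, results, model="L1")
        time = next(e for e in effects if e.term == "followup_vs_baseline")
        assert time.beta == pytest.approx(-2.0, abs=1e-6)

    def test_time_effect_with_control_reference_group(self, small_study):
        effects = stats.longitudinal_model(small_study.records, small_study.results,
                                           model="L1")
        terms = {e.term for e in effects}
        assert "followup_vs_baseline" in terms
        assert any("acAN_vs_HC" in t for t in terms)

    def test_baseline_covariates_enter_l2(self, small_study):
        effects = stats.longitudinal_model(small_study.records, small_study.results,
                                           model="L2")
        terms = {e.term for e in effects}
        assert "bl_bmi_sds" in terms and "followup_vs_baseline" in terms


class TestChangePredictors:
    def _paired_records(self, n, rng):
        participants = np.repeat([f"P{i}" for i in range(n)], 2)
        timepoints = ["baseline", "followup"] * n
        ages = np.repeat(rng.uniform(12, 22, n), 2) + np.tile([0.0, 0.25], n)
        return make_records(["acAN"] * 2 * n, ages, timepoints=list(timepoints),
                            participants=list(participants),
                            bmi_sds=np.repeat(rng.normal(-2.8, 0.8, n), 2)
                            + np.tile([0.0, 0.0], n) + np.repeat(np.zeros(n), 2),
                            edi2_total=rng.normal(200, 30, 2 * n),
                            bdi2_total=rng.normal(15, 5, 2 * n),
                            illness_duration=np.repeat(rng.gamma(2, 1, n), 2))

    def test_exact_construction_recovers_slope(self):
        rng = np.random.default_rng(17)
        n = 20
        records = self._paired_records(n, rng)
        gains = rng.gamma(6.0, 0.4, n)
        records.loc[records["timepoint"] == "followup", "bmi_sds"] = (
            records.loc[records["timepoint"] == "baseline", "bmi_sds"].to_numpy() + gains
        )
        scores = np.zeros(2 * n)
        scores[1::2] = -0.65 * gains  # dBrainAGE depends on dBMI only
        results = make_results(records, scores)
        effects = stats.change_predictor_model(records, results)
        by_term = {e.term: e.beta for e in effects}
        assert by_term["d_bmi_sds"] == pytest.approx(-0.65, abs=1e-8)
        assert by_term["d_edi2_total"] == pytest.approx(0.0, abs=1e-8)
        assert by_term["d_bdi2_total"] == pytest.approx(0.0, abs=1e-8)

    def test_constant_changes_raise_collinearity(self):
        rng = np.random.default_rng(18)
        n = 10
        records = self._paired_records(n, rng)
        # every delta constant: indistinguishable from the intercept
        records.loc[records["timepoint"] == "followup", "bmi_sds"] = (
            records.loc[records["timepoint"] == "baseline", "bmi_sds"].to_numpy() + 1.0)
        for col in ("edi2_total", "bdi2_total"):
            records[col] = np.tile([100.0, 90.0], n)
        results = make_results(records, rng.normal(size=2 * n))
        with pytest.raises(CollinearityError):
            stats.change_predictor_model(records, results)


class TestContrasts:
    def test_contrast_equals_coefficient_difference(self, cs1_fixture):
        records, results = cs1_fixture
        _, fit = stats.cross_sectional_model(records, results, model="CS1",
                                             return_fit=True)
        contrasts = stats.pairwise_contrasts(fit, [("acAN", "HC")])
        assert contrasts[0].beta == pytest.approx(2.0, abs=1e-10)

    def test_self_contrast_flagged_degenerate(self, cs1_fixture):
        records, results = cs1_fixture
        _, fit = stats.cross_sectional_model(records, results, model="CS1",
                                             return_fit=True)
        c = stats.pairwise_contrasts(fit, [("HC", "HC")])[0]
        assert c.beta == 0.0 and c.note == "degenerate contrast"

    def test_unknown_group_rejected(self, cs1_fixture):
        records, results = cs1_fixture
        _, fit = stats.cross_sectional_model(records, results, model="CS1",
                                             return_fit=True)
        with pytest.raises(ValueError, match="AN\\?"):
            stats.pairwise_contrasts(fit, [("AN?", "HC")])


class TestAlphaAndDescriptives:
    @pytest.mark.parametrize("n_out, n_models, expected", [
        (2, 3, 0.05 / 6), (1, 1, 0.05), (2, 5, 0.005),
    ])
    def test_bonferroni_threshold(self, n_out, n_models, expected):
        assert stats.adjust_alpha(n_out, n_models) == pytest.approx(expected)

    def test_display_convention(self):
        assert stats.format_alpha(stats.adjust_alpha(2, 3)) == "0.0083"

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            stats.adjust_alpha(0, 3)

    def test_known_means_and_sds(self):
        records = make_records(["HC"] * 3 + ["acAN"] * 3, [14, 16, 18, 13, 15, 17])
        results = make_results(records, np.array([0.0, 0.0, 0.0, 2.0, 2.0, 2.0]))
        table = stats.descriptives(records, results)
        assert table.loc["age", "HC_mean"] == pytest.approx(16.0)
        assert table.loc["age", "HC_sd"] == pytest.approx(2.0)
        assert table.loc["brainage_gm", "acAN_baseline_mean"] == pytest.approx(2.0)
        assert "p_cross_sectional" in table.columns

    def test_single_group_emits_no_p_values(self):
        records = make_records(["HC"] * 4, [13, 15, 17, 19])
        results = make_results(records, np.zeros(4))
        table = stats.descriptives(records, results)
        assert "p_cross_sectional" not in table.columns
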