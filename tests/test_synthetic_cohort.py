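import numpy as np
import pandas as pd
import pytest

from anbrainage.errors import ConfigurationError
from anbrainage.synthetic_cohort import (ACAN, BASELINE, FOLLOWUP, GM, HC, WM,
                                         CohortConfig, generate_cohort,
                                         generate_phenotypes,
                                         generate_training_set, make_templates,
                                         render_map, simulate_followup)


def cfg(**kw):
    base = dict(n_hc=20, n_acan=20, n_recan=8, n_followup=12, n_training=10,
                grid_shape=(6, 6, 6), seed=3)
    base.update(kw)
    return CohortConfig(**base)


class TestConfig:
    def test_defaults_mirror_study_design(self):
        c = CohortConfig()
        assert (c.n_acan, c.n_hc, c.n_recan, c.n_followup, c.n_training) == \
            (129, 167, 39, 95, 226)
        assert c.age_range == (12.0, 23.0)

    def test_followup_cannot_exceed_acute_count(self):
        with pytest.raises(ConfigurationError):
            cfg(n_followup=25, n_acan=20)

    @pytest.mark.parametrize("bad", [dict(n_hc=-1), dict(age_range=(20, 12)),
                                     dict(voxel_size_mm=0), dict(subject_sd=-1)])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            cfg(**bad)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig.from_dict({"n_hc": 5, "bogus": 1})


class TestCounts:
    def test_default_cohort_has_430_scans(self):
        records, _ = generate_phenotypes(CohortConfig())
        assert len(records) == 335
        records2, _ = simulate_followup(records, _dummy_latents(records), CohortConfig())
        assert len(records2) == 430
        assert (records2["timepoint"] == FOLLOWUP).sum() == 95

    def test_training_set_size_and_empty_case(self):
        ages, pairs = generate_training_set(cfg(n_training=5))
        assert len(ages) == 5 and len(pairs) == 5
        assert {p[0].tissue for p in pairs} == {GM} and {p[1].tissue for p in pairs} == {WM}
        ages0, pairs0 = generate_training_set(cfg(n_training=0))
        assert len(ages0) == 0 and pairs0 == []


def _dummy_latents(records):
    rows = []
    for _, r in records.iterrows():
        rows.append(dict(scan_id=r["scan_id"], tissue=GM, b=r["age"]))
        rows.append(dict(scan_id=r["scan_id"], tissue=WM, b=r["age"]))
    return pd.DataFrame(rows)


class TestLatentConstruction:
    def test_injected_offset_recovered_exactly_without_subject_noise(self):
        c = cfg(delta_gm_acan=5.0, subject_sd=0.0)
        records, latents = generate_phenotypes(c)
        merged = records.merge(latents[latents["tissue"] == GM], on="scan_id")
        gaps = merged["b"] - merged["age"]
        assert np.allclose(gaps[merged["group"] == ACAN], 5.0)
        assert np.allclose(gaps[merged["group"] == HC], 0.0)

    def test_null_deltas_leave_group_gaps_centred(self):
        c = cfg(n_hc=300, n_acan=300, n_recan=0, n_followup=0,
                delta_gm_acan=0.0, delta_wm_acan=0.0)
        records, latents = generate_phenotypes(c)
        merged = records.merge(latents[latents["tissue"] == GM], on="scan_id")
        gaps = merged["b"] - merged["age"]
        tol = 4 * c.subject_sd / np.sqrt(300)
        for g in (HC, ACAN):
            assert abs(gaps[merged["group"] == g].mean()) < tol

    def test_ages_within_cohort_range(self):
        records, _ = generate_phenotypes(cfg())
        lo, hi = cfg().age_range
        assert records["age"].between(lo, hi).all()


class TestFollowup:
    def test_gap_change_exact_when_deterministic(self):
        c = cfg(followup_weightgain_slope=-0.65, followup_residual_sd=0.0,
                followup_bmi_gain_sd=0.0, followup_bmi_gain_mean=1.0)
        records, latents = generate_phenotypes(c)
        r2, l2 = simulate_followup(records, latents, c)
        gaps = _gap_changes(r2, l2, c)
        assert np.allclose(gaps["d_gap"], -0.65)

    def test_zero_slope_zero_residual_keeps_gap(self):
        c = cfg(followup_weightgain_slope=0.0, followup_residual_sd=0.0)
        records, latents = generate_phenotypes(c)
        r2, l2 = simulate_followup(records, latents, c)
        gaps = _gap_changes(r2, l2, c)
        assert np.allclose(gaps["d_gap"], 0.0, atol=1e-12)

    def test_ols_on_generated_pairs_recovers_slope(self):
        # independent oracle: plain least squares on the generated
        # (dBMI-SDS, gap-change) pairs
        c = cfg(n_acan=400, n_followup=400, n_hc=0, n_recan=0)
        records, latents = generate_phenotypes(c)
        r2, l2 = simulate_followup(records, latents, c)
        gaps = _gap_changes(r2, l2, c)
        slope = np.polyfit(gaps["d_bmi"], gaps["d_gap"], 1)[0]
        mc_tol = 4 * c.followup_residual_sd / (np.sqrt(400) * gaps["d_bmi"].std())
        assert slope == pytest.approx(c.followup_weightgain_slope, abs=mc_tol)

    def test_completers_gain_weight_and_age(self):
        c = cfg()
        records, latents = generate_phenotypes(c)
        r2, _ = simulate_followup(records, latents, c)
        base = r2[r2["timepoint"] == BASELINE].set_index("participant_id")
        fu = r2[r2["timepoint"] == FOLLOWUP].set_index("participant_id")
        assert (fu["bmi_sds"] > base.loc[fu.index, "bmi_sds"]).all()
        assert np.allclose(fu["age"] - base.loc[fu.index, "age"],
                           c.followup_interval_years)
        assert (fu["group"] == ACAN).all()


def _gap_changes(records, latents, config):
    gm = latents[latents["tissue"] == GM].set_index("scan_id")["b"]
    base = records[records["timepoint"] == BASELINE].set_index("participant_id")
    fu = records[records["timepoint"] == FOLLOWUP].set_index("participant_id")
    idx = fu.index
    gap_bl = gm[base.loc[idx, "scan_id"]].to_numpy() - base.loc[idx, "age"].to_numpy()
    gap_fu = gm[fu["scan_id"]].to_numpy() - fu["age"].to_numpy()
    return pd.DataFrame({
        "d_gap": gap_fu - gap_bl,
        "d_bmi": fu["bmi_sds"].to_numpy() - base.loc[idx, "bmi_sds"].to_numpy(),
    })


class TestRendering:
    def test_zero_loading_makes_map_independent_of_latent(self):
        c = cfg(voxel_noise_sd=0.0)
        t = make_templates(c)[GM]
        t.loading = np.zeros_like(t.loading)
        rng = np.random.default_rng(0)
        m1 = render_map(14.0, t, c, rng)
        m2 = render_map(21.0, t, c, rng)
        assert np.array_equal(m1.data, m2.data)

    def test_noiseless_difference_is_loading_times_f(self):
        c = cfg(voxel_noise_sd=0.0)
        t = make_templates(c)[GM]
        rng = np.random.default_rng(0)
        b1, b2 = 15.0, 19.0
        d1 = render_map(b1, t, c, rng).data
        d2 = render_map(b2, t, c, rng).data
        expected = t.loading * (t.f(b1) - t.f(b2))
        interior = (d1 > 0) & (d1 < 1) & (d2 > 0) & (d2 < 1)
        assert np.allclose((d1 - d2)[interior], expected[interior], atol=1e-12)

    def test_fixed_seed_reproduces_map_bitwise(self):
        c = cfg()
        t = make_templates(c)[WM]
        m1 = render_map(16.0, t, c, np.random.default_rng(5))
        m2 = render_map(16.0, t, c, np.random.default_rng(5))
        assert np.array_equal(m1.data, m2.data)

    def test_clipping_affects_under_one_percent_at_default_noise(self):
        c = CohortConfig(n_hc=15, n_acan=15, n_recan=5, n_followup=0, n_training=0)
        _, maps, _ = generate_cohort(c)
        total = clipped = 0
        for vm in maps.values():
            total += vm.data.size
            clipped += int(np.sum((vm.data == 0.0) | (vm.data == 1.0)))
        assert clipped / total < 0.01


class TestDeterminism:
    def test_same_config_and_seed_identical_outputs(self):
        c = cfg()
        r1, m1, l1 = generate_cohort(c)
        r2, m2, l2 = generate_cohort(c)
        assert r1.to_csv(index=False) == r2.to_csv(index=False)
        pd.testing.assert_frame_equal(l1, l2)
        for key in m1:
            assert np.array_equal(m1[key].data, m2[key].data)

    def test_no_noise_equal_age_equal_maps(self):
        c = cfg(voxel_noise_sd=0.0, subject_sd=0.0, n_training=2)
        t = make_templates(c)[GM]
        rng = np.random.default_rng(1)
        m1 = render_map(18.0, t, c, rng, scan_id="a")
        m2 = render_map(18.0, t, c, rng, scan_id="b")
        assert np.array_equal(m1.data, m2.data)
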