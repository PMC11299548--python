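"""Re-deriving calibrations: OLS, species models, mixed models, OSC, metrics."""

import numpy as np
import pandas as pd
import pytest

import stemwc as sw
from stemwc.calibfit import mixed_loglik_zero_variance, osc_closed_form_slope
from stemwc.exceptions import (
    DataQualityWarning,
    MetricsError,
    NestingError,
    OrderingError,
    RankError,
)


def _line_records(slope, intercept, x, species="spA", individual="spA-i1",
                  treatment="dry-down"):
    x = np.asarray(x, dtype=float)
    return pd.DataFrame({
        "species": species,
        "individual": individual,
        "treatment": treatment,
        "order_index": np.arange(1, len(x) + 1),
        "sqrt_epsilon": x,
        "vwc": slope * x + intercept,
    })


class TestFitMetrics:
    def test_perfect_prediction(self):
        m = sw.fit_metrics([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert m == pytest.approx((1.0, 0.0, 0.0, 0.0))

    def test_mean_prediction_is_definitional_zero_skill(self):
        obs = np.array([0.0, 1.0, 2.0, 5.0])
        pred = np.full_like(obs, obs.mean())
        m = sw.fit_metrics(obs, pred)
        assert m.rae == pytest.approx(1.0)
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        m = sw.fit_metrics([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        assert m.rmse == pytest.approx(np.sqrt(4.0 / 3.0))
        assert m.mae == pytest.approx(2.0 / 3.0)
        assert m.rae == pytest.approx(1.0)

    def test_zero_sst_undefined(self):
        with pytest.raises(MetricsError):
            sw.fit_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPooledFit:
    def test_noiseless_generator_round_trip(self, noiseless_records):
        records, truth = noiseless_records
        fr = sw.fit_pooled_calibration(records)
        assert fr.slope == pytest.approx(truth["true_slope"], abs=1e-10)
        assert fr.intercept == pytest.approx(truth["mean_intercept"], abs=1e-10)
        assert fr.r2 == pytest.approx(1.0, abs=1e-12)

    def test_three_collinear_points_exact(self):
        records = _line_records(0.25, -0.4, [2.0, 4.0, 6.0])
        fr = sw.fit_pooled_calibration(records)
        assert (fr.slope, fr.intercept) == pytest.approx((0.25, -0.4), abs=1e-12)
        assert fr.r2 == pytest.approx(1.0)

    def test_degenerate_predictor_raises(self):
        records = _line_records(0.2, -0.3, [3.0, 3.0, 3.0])
        records["vwc"] = [0.1, 0.2, 0.3]
        with pytest.raises(RankError):
            sw.fit_pooled_calibration(records)

    def test_permuted_response_ci_covers_zero(self):
        """Shuffling vwc destroys the association: the 95% slope CI should
        cover zero in at least 90% of seeded permutations."""
        cfg = sw.CalibGenConfig(seed=21, n_species=2, n_individuals_per_species=2,
                                n_segments_per_individual=10)
        records, _ = sw.generate_calibration_experiment(cfg)
        rng = np.random.default_rng(22)
        cover = 0
        for _ in range(200):
            shuffled = records.copy()
            shuffled["vwc"] = rng.permutation(shuffled["vwc"].to_numpy())
            fr = sw.fit_pooled_calibration(shuffled)
            lo, hi = fr.slope_ci
            cover += lo <= 0.0 <= hi
        assert cover >= 180


class TestSpeciesModels:
    def test_common_slope_yields_nonsignificant_interaction(self):
        """With a shared slope and species differing only in intercept, the
        species x slope interaction should rarely reach alpha=0.05 while the
        species-intercept term almost always does."""
        inter_ns = icpt_sig = 0
        for seed in range(100):
            cfg = sw.CalibGenConfig(seed=1000 + seed, n_species=4,
                                    n_individuals_per_species=2,
                                    n_segments_per_individual=8,
                                    sd_species_intercept=0.03,
                                    sd_individual_intercept=0.0,
                                    sd_residual=0.02)
            records, _ = sw.generate_calibration_experiment(cfg)
            res = sw.fit_species_models(records)
            inter_ns += res.p_interaction > 0.05
            icpt_sig += res.p_species < 0.05
        assert inter_ns >= 90
        assert icpt_sig >= 95

    def test_distinct_slopes_detected(self):
        """Species slopes spread over >= 0.05 are flagged by the interaction
        term in nearly every replicate."""
        detected = 0
        rng = np.random.default_rng(31)
        for _ in range(50):
            frames = []
            for i, slope in enumerate(np.linspace(0.20, 0.25, 4)):
                x = rng.uniform(1.8, 4.5, size=16)
                f = _line_records(slope, -0.4 + 0.01 * i, x, species=f"sp{i}",
                                  individual=f"sp{i}-i1")
                f["vwc"] += rng.normal(0, 0.02, size=len(f))
                frames.append(f)
            res = sw.fit_species_models(pd.concat(frames, ignore_index=True))
            detected += res.p_interaction < 0.05
        assert detected >= 48  # >= 95% power

    def test_duplicated_species_has_zero_interaction_ss(self):
        base = _line_records(0.22, -0.39, np.linspace(2, 5, 12))
        base["vwc"] += np.random.default_rng(5).normal(0, 0.03, len(base))
        dup = base.copy()
        dup["species"] = "spB"
        res = sw.fit_species_models(pd.concat([base, dup], ignore_index=True))
        assert res.anova.loc["_x:C(_sp)", "sum_sq"] == pytest.approx(0.0, abs=1e-12)

    def test_single_species_falls_back_to_pooled(self):
        records = _line_records(0.22, -0.39, np.linspace(2, 5, 10))
        with pytest.warns(DataQualityWarning):
            res = sw.fit_species_models(records)
        assert res.pooled_fallback
        assert res.anova is None

    def test_main_effects_slope_agrees_with_mixed(self, calib_records):
        """On common-slope data the fixed-effects ANCOVA slope and the mixed
        model's fixed slope agree within two standard errors."""
        records, _ = calib_records
        import statsmodels.formula.api as smf
        main = smf.ols("vwc ~ sqrt_epsilon + C(species)", records).fit()
        mm = sw.fit_mixed_calibration(records)
        se = max(float(main.bse["sqrt_epsilon"]), mm.slope_se)
        assert abs(float(main.params["sqrt_epsilon"]) - mm.slope) < 2 * se


class TestMixedModel:
    def test_zero_variance_generator_collapses_components(self):
        cfg = sw.CalibGenConfig(seed=1, sd_species_intercept=0.0,
                                sd_individual_intercept=0.0)
        records, _ = sw.generate_calibration_experiment(cfg)
        mm = sw.fit_mixed_calibration(records)
        assert mm.var_species <= 1e-4
        assert mm.var_individual <= 1e-4
        assert abs(mm.r2_marginal - mm.r2_conditional) < 0.01

    def test_slope_recovery_at_paper_scale(self, calib_records):
        records, truth = calib_records
        mm = sw.fit_mixed_calibration(records)
        assert abs(mm.slope - truth["true_slope"]) < 3 * mm.slope_se
        assert 0 < mm.r2_marginal <= mm.r2_conditional <= 1

    def test_wood_density_covariate_reported(self, calib_records):
        records, _ = calib_records
        mm = sw.fit_mixed_calibration(records, include_wood_density=True)
        assert mm.wood_density_coef is not None
        assert mm.wood_density_se > 0

    def test_degenerate_hierarchy_equals_ols_loglik(self):
        cfg = sw.CalibGenConfig(seed=4, n_species=1, n_individuals_per_species=1,
                                n_segments_per_individual=12)
        records, _ = sw.generate_calibration_experiment(cfg)
        mm = sw.fit_mixed_calibration(records, reml=False)
        import statsmodels.formula.api as smf
        ols = smf.ols("vwc ~ sqrt_epsilon", records).fit()
        assert mm.loglik == pytest.approx(float(ols.llf), abs=1e-6)
        assert mm.var_species == mm.var_individual == 0.0

    def test_zero_variance_loglik_matches_ols(self, calib_records):
        """The hierarchical likelihood evaluated at zero variance components
        equals the pooled OLS log-likelihood (boundary consistency)."""
        records, _ = calib_records
        import statsmodels.formula.api as smf
        ll = mixed_loglik_zero_variance(records)
        ols = smf.ols("vwc ~ sqrt_epsilon", records).fit()
        assert ll == pytest.approx(float(ols.llf), abs=1e-6)


class TestLRT:
    def test_equal_likelihood_gives_zero_statistic(self, calib_records):
        """A reduced model with the same log-likelihood as the full model
        yields statistic 0 and p = 1."""
        import dataclasses

        records, _ = calib_records
        full = sw.fit_mixed_calibration(records, reml=False)
        tie = dataclasses.replace(
            full, random_structure=("individual",), n_params=full.n_params - 1
        )
        res = sw.lrt_random_effect(full, tie)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_species_effect_detected_on_paper_scale_data(self, calib_records):
        records, _ = calib_records
        full = sw.fit_mixed_calibration(records, reml=False)
        reduced = sw.fit_mixed_calibration(records, reml=False,
                                           random_effects=("individual",))
        res = sw.lrt_random_effect(full, reduced, boundary_mixture=True)
        assert res.statistic > 0
        assert res.df == 1
        assert res.null_mixture_flag

    def test_non_nested_raises(self, calib_records):
        records, _ = calib_records
        a = sw.fit_mixed_calibration(records, reml=False, random_effects=("species",))
        b = sw.fit_mixed_calibration(records, reml=False, random_effects=("individual",))
        with pytest.raises(NestingError):
            sw.lrt_random_effect(a, b)

    def test_reml_fits_rejected(self, calib_records):
        records, _ = calib_records
        full = sw.fit_mixed_calibration(records, reml=True)
        reduced = sw.fit_mixed_calibration(records, reml=True,
                                           random_effects=("individual",))
        with pytest.raises(NestingError):
            sw.lrt_random_effect(full, reduced)


class TestDifferencing:
    def test_hand_computed_pairs(self):
        records = _line_records(0.0, 0.0, [np.sqrt(20), 4.0, 3.0])
        records["vwc"] = [0.6, 0.5, 0.3]
        d = sw.first_order_difference(records)
        assert np.allclose(d["delta_vwc"], [-0.1, -0.2])
        assert np.allclose(d["delta_sqrt_epsilon"],
                           [4.0 - np.sqrt(20), -1.0])

    def test_single_record_units_contribute_nothing(self):
        a = _line_records(0.2, -0.4, [3.0], species="spA", individual="a-i1")
        b = _line_records(0.2, -0.4, [4.0], species="spB", individual="b-i1")
        d = sw.first_order_difference(pd.concat([a, b], ignore_index=True))
        assert len(d) == 0

    def test_count_equals_sum_of_unit_sizes_minus_one(self, calib_records):
        records, _ = calib_records
        d = sw.first_order_difference(records)
        expected = sum(
            len(g) - 1
            for _, g in records.groupby(["species", "individual", "treatment"])
            if len(g) > 1
        )
        assert len(d) == expected

    def test_no_differencing_across_units(self):
        a = _line_records(0.2, -0.30, np.linspace(2, 3, 4), species="spA",
                          individual="a-i1")
        b = _line_records(0.2, +0.50, np.linspace(2, 3, 4), species="spB",
                          individual="b-i1")
        d = sw.first_order_difference(pd.concat([a, b], ignore_index=True))
        # the 0.8 intercept jump never appears in any differenced pair
        assert len(d) == 6
        assert np.abs(d["delta_vwc"]).max() < 0.5

    def test_duplicate_order_index_raises(self):
        records = _line_records(0.2, -0.4, [2.0, 3.0, 4.0])
        records.loc[2, "order_index"] = 2
        with pytest.raises(OrderingError):
            sw.first_order_difference(records)

    def test_segment_level_unit_is_configurable(self, calib_records):
        records, _ = calib_records
        d = sw.first_order_difference(records, unit_cols=("species", "sample"))
        # 'sample' encodes individual|treatment here, so the two agree
        d_default = sw.first_order_difference(records)
        assert len(d) == len(d_default)


class TestOSC:
    def test_noiseless_differences_recover_slope(self, noiseless_records):
        records, truth = noiseless_records
        d = sw.first_order_difference(records)
        fr = sw.fit_osc(d)
        assert fr.slope == pytest.approx(truth["true_slope"], abs=1e-10)
        assert fr.intercept is None

    def test_matches_closed_form_oracle(self, calib_records):
        records, _ = calib_records
        d = sw.first_order_difference(records)
        fr = sw.fit_osc(d)
        assert fr.slope == pytest.approx(osc_closed_form_slope(d), abs=1e-12)

    def test_intercept_spread_does_not_bias_slope(self):
        """The OSC slope is invariant to species-intercept spread: estimates
        from zero-spread and large-spread generators differ only by
        Monte-Carlo noise around the common truth."""
        errs_spread, errs_zero = [], []
        for seed in range(100):
            for sd, sink in ((0.08, errs_spread), (0.0, errs_zero)):
                cfg = sw.CalibGenConfig(seed=3000 + seed, n_species=4,
                                        n_individuals_per_species=2,
                                        n_segments_per_individual=8,
                                        sd_species_intercept=sd,
                                        sd_residual=0.03)
                records, truth = sw.generate_calibration_experiment(cfg)
                d = sw.first_order_difference(records)
                sink.append(sw.fit_osc(d).slope - truth["true_slope"])
        # same sampling distribution of the error: means both ~0 at MC scale
        se = np.std(errs_spread) / 10 + np.std(errs_zero) / 10
        assert abs(np.mean(errs_spread) - np.mean(errs_zero)) < 4 * se

    def test_all_zero_deltas_rank_error(self):
        d = pd.DataFrame({"delta_vwc": [0.1, 0.2, 0.3],
                          "delta_sqrt_epsilon": [0.0, 0.0, 0.0]})
        with pytest.raises(RankError):
            sw.fit_osc(d)

    def test_diagnostic_intercept_near_zero_on_clean_data(self, calib_records):
        records, _ = calib_records
        d = sw.first_order_difference(records)
        fr = sw.fit_osc(d, include_intercept=True)
        lo, hi = fr.intercept_ci
        assert lo <= 0.0 <= hi


class TestInvariants:
    def test_pooled_rmse_tracks_generator_noise(self):
        """RMSE of the pooled fit estimates the generator's residual sigma
        within 20% at the n=264 design scale (no hierarchy spreads)."""
        cfg = sw.CalibGenConfig(seed=41, sd_species_intercept=0.0,
                                sd_individual_intercept=0.0, sd_residual=0.05)
        records, _ = sw.generate_calibration_experiment(cfg)
        fr = sw.fit_pooled_calibration(records)
        assert abs(fr.rmse - 0.05) / 0.05 < 0.20
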