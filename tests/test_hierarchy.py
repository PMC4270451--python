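"""Hierarchical log-t regression: design, sampler, ratios, DIC, predictive."""

import warnings
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from hetmeta._mcmc import McmcConfig
from hetmeta.hierarchy import (
    HierarchicalConfig,
    build_design,
    compute_dic,
    draw_predictive,
    fit_hierarchical,
    variance_ratios,
)
from hetmeta.schema import ArmSummary, MetaAnalysis, Setting, StudyRecord
from hetmeta.simulate import default_config, generate_dataset


def _ma(ma_id, setting, review="R1", comparison="C1", k=2):
    studies = tuple(
        StudyRecord(review, comparison, ma_id, f"{ma_id}.S{i}",
                    ArmSummary(20, 0.1 * i, 1.0), ArmSummary(20, 0.0, 1.0))
        for i in range(k)
    )
    return MetaAnalysis(review, comparison, ma_id, setting, studies)


class TestBuildDesign:
    @staticmethod
    def _toy_collection():
        ref = Setting("general_health", "nonpharm_vs_any", "cardiovascular")
        full = Setting("obstetric", "pharm_vs_placebo", "respiratory")
        return [
            _ma("M1", ref),
            _ma("M2", full, comparison="C2"),
            _ma("M3", Setting("obstetric", "nonpharm_vs_any", "cardiovascular"),
                review="R2"),
            _ma("M4", Setting("general_health", "pharm_vs_placebo",
                              "cardiovascular"), review="R3"),
        ]

    def test_reference_setting_gives_zero_covariate_row(self):
        design = build_design(self._toy_collection())
        j_ref = design.ma_ids.index("M1")
        assert np.all(design.X[j_ref, 1:] == 0.0)
        assert design.X[j_ref, 0] == 1.0

    def test_nonreference_setting_has_three_indicator_ones(self):
        design = build_design(self._toy_collection())
        j = design.ma_ids.index("M2")
        assert design.X[j, 1:].sum() == 3.0
        for f, lvl in (("outcome_type", "obstetric"),
                       ("comparison_type", "pharm_vs_placebo"),
                       ("medical_area", "respiratory")):
            assert design.X[j, design.factor_cols[f][lvl]] == 1.0

    def test_fully_confounded_design_rejected(self):
        # only two distinct setting rows cannot identify three contrasts
        ref = Setting("general_health", "nonpharm_vs_any", "cardiovascular")
        full = Setting("obstetric", "pharm_vs_placebo", "respiratory")
        with pytest.raises(ValueError, match="singular"):
            build_design([_ma("M1", ref), _ma("M2", full, comparison="C2")])

    def test_column_sums_recount_category_frequencies(self, small_dataset):
        collection = small_dataset.collection
        design = build_design(collection)
        for factor, cols in design.factor_cols.items():
            for level, col in cols.items():
                expected = sum(getattr(ma.setting, factor) == level
                               for ma in collection)
                assert design.X[:, col].sum() == expected

    def test_absent_reference_relevels_with_warning(self):
        s1 = Setting("obstetric", "pharm_vs_placebo", "respiratory")
        s2 = Setting("obstetric", "pharm_vs_placebo", "digestive")
        mas = [_ma("M1", s1), _ma("M2", s2, comparison="C2"),
               _ma("M3", s2, review="R2")]
        with pytest.warns(UserWarning, match="releveled"):
            design = build_design(mas)
        assert design.factor_references["medical_area"] == "digestive"
        assert "medical_area:digestive" not in design.colnames


class TestSampler:
    def test_noise_free_limit_recovers_coefficients(self):
        # kappa^2 = sigma^2 = 0 with well-estimated per-MA tau^2: the
        # regression part must pin the intercept and the single contrast
        cfg = default_config(
            seed=5, n_meta_analyses=240,
            outcome_freq=(0.5, 0, 0, 0, 0, 0.5, 0, 0),
            comparison_freq=(1.0, 0, 0), area_freq=(1.0,) + (0.0,) * 10,
            kappa2=0.0, sigma2=1e-6, alpha=-2.0,
            coefficients={"outcome_type:mental_health": 0.5},
            studies_per_ma_p=0.05,
            total_n_log_median=float(np.log(2000.0)),
        )
        ds = generate_dataset(cfg)
        hier = HierarchicalConfig(
            mcmc=McmcConfig(seed=2, chains=1, burn_in=300, iterations=700)
        )
        draws = fit_hierarchical(ds.collection, hier)
        flat = draws.flat(draws.coef)
        alpha = np.median(flat[:, 0])
        col = draws.design.colnames.index("outcome_type:mental_health")
        contrast = np.median(flat[:, col])
        assert alpha == pytest.approx(-2.0, abs=0.05)
        assert contrast == pytest.approx(0.5, abs=0.05)

    def test_t5_scale_mixture_identity(self):
        # lam ~ Gamma(5/2, 5/2), eps | lam ~ N(0, 1/lam) must be t_5
        rng = np.random.default_rng(77)
        n = 100_000
        lam = rng.gamma(2.5, size=n) / 2.5
        eps = rng.standard_normal(n) / np.sqrt(lam)
        _, p = stats.kstest(eps, stats.t(5).cdf)
        assert p > 0.01

    def test_deviance_draws_consistent_with_stored_effects(self, small_dataset):
        cfg = HierarchicalConfig(
            mcmc=McmcConfig(seed=4, chains=1, burn_in=100, iterations=200),
            store_study_effects=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_hierarchical(small_dataset.collection, cfg)
        from hetmeta.hierarchy import _flatten

        y, v, _ = _flatten(small_dataset.collection)
        theta = draws.theta[0]
        dev = np.sum(np.log(2 * np.pi * v) + (y - theta) ** 2 / v, axis=1)
        assert np.allclose(dev, draws.deviance[0], rtol=1e-10)
        assert np.allclose(draws.theta_mean, theta.mean(axis=0), rtol=1e-10)


class TestVarianceRatios:
    def test_reference_has_unit_ratio(self, fitted_draws):
        ratios = variance_ratios(fitted_draws, "comparison_type")
        assert ratios[0].reference
        assert ratios[0].ratio == 1.0 and ratios[0].ci95 == (1.0, 1.0)

    def test_ratios_are_exp_of_coefficient_quantiles(self, fitted_draws):
        ratios = variance_ratios(fitted_draws, "outcome_type")
        flat = fitted_draws.flat(fitted_draws.coef)
        for r in ratios[1:]:
            col = fitted_draws.design.factor_cols["outcome_type"][r.level]
            # median of exp vs exp of (interpolated) median agree closely
            assert r.ratio == pytest.approx(np.exp(np.median(flat[:, col])),
                                            rel=1e-3)

    def test_point_mass_draws_invert_exactly(self, fitted_draws):
        # coefficient draws frozen at log 0.39 must give ratio 0.39
        frozen = fitted_draws.coef.copy()
        col = 1
        frozen[:, :, col] = np.log(0.39)
        fake = SimpleNamespace(design=fitted_draws.design, coef=frozen,
                               flat=fitted_draws.flat)
        level = fitted_draws.design.colnames[col].split(":")[1]
        r = [x for x in variance_ratios(fake, "outcome_type")
             if x.level == level][0]
        assert r.ratio == pytest.approx(0.39)
        assert r.ci95 == (pytest.approx(0.39), pytest.approx(0.39))

    def test_unknown_factor_rejected(self, fitted_draws):
        with pytest.raises(KeyError):
            variance_ratios(fitted_draws, "funding_source")


class TestDic:
    def test_fixed_effects_give_zero_pd(self, small_dataset):
        from hetmeta.hierarchy import _flatten

        y, v, _ = _flatten(small_dataset.collection)
        theta = y * 0.5
        dev = float(np.sum(np.log(2 * np.pi * v) + (y - theta) ** 2 / v))
        fake = SimpleNamespace(deviance=np.full((1, 50), dev), theta_mean=theta)
        dic = compute_dic(fake, small_dataset.collection)
        assert dic.p_d == pytest.approx(0.0, abs=1e-8)
        assert dic.dic == pytest.approx(dev)

    def test_matches_closed_form_for_known_normal_posteriors(self, small_dataset):
        # theta_ij drawn from known normal posteriors: DIC has a closed form
        # Dbar = sum log(2 pi v) + ((y-m)^2 + s^2)/v and pD = sum s^2/v
        from hetmeta.hierarchy import _flatten

        rng = np.random.default_rng(3)
        y, v, _ = _flatten(small_dataset.collection)
        m = y * 0.8
        s2 = v * 0.3
        draws = m + rng.standard_normal((1, 40_000, y.size)) * np.sqrt(s2)
        dev = (np.log(2 * np.pi * v) + (y - draws) ** 2 / v).sum(axis=2)
        fake = SimpleNamespace(deviance=dev, theta_mean=draws.mean(axis=(0, 1)))
        dic = compute_dic(fake, small_dataset.collection)
        expected_pd = np.sum(s2 / v)
        assert dic.p_d == pytest.approx(expected_pd, rel=0.02)
        expected_dbar = np.sum(np.log(2 * np.pi * v) + ((y - m) ** 2 + s2) / v)
        assert dic.mean_deviance == pytest.approx(expected_dbar, rel=0.01)


class TestPredictive:
    def test_degenerate_variances_collapse_to_linear_predictor(self, fitted_draws):
        fake = SimpleNamespace(
            design=fitted_draws.design,
            config=fitted_draws.config,
            coef=fitted_draws.coef,
            kappa2=np.full_like(fitted_draws.kappa2, 1e-300),
            sigma2=np.full_like(fitted_draws.sigma2, 1e-300),
            flat=fitted_draws.flat,
        )
        setting = Setting("general_health", "nonpharm_vs_any", "cardiovascular")
        sample = draw_predictive(fake, setting, 50_000, rng=0)
        lin = fitted_draws.flat(fitted_draws.coef)[:, 0]
        assert np.median(np.log(sample)) == pytest.approx(
            np.median(lin), abs=0.05
        )

    def test_outcome_shift_doubles_predictive_median(self, fitted_draws):
        setting = Setting("mental_health", "nonpharm_vs_any", "cardiovascular")
        col = fitted_draws.design.factor_cols["outcome_type"]["mental_health"]
        shifted_coef = fitted_draws.coef.copy()
        shifted_coef[:, :, col] += np.log(2.0)
        fake = SimpleNamespace(
            design=fitted_draws.design, config=fitted_draws.config,
            coef=shifted_coef, kappa2=fitted_draws.kappa2,
            sigma2=fitted_draws.sigma2, flat=fitted_draws.flat,
        )
        base = draw_predictive(fitted_draws, setting, 200_000, rng=1)
        shifted = draw_predictive(fake, setting, 200_000, rng=1)
        assert np.median(shifted) == pytest.approx(2 * np.median(base), rel=0.05)

    def test_matches_composition_sampling_oracle(self, fitted_draws):
        # independent re-implementation by composition over posterior draws
        setting = Setting("signs_symptoms", "pharm_vs_placebo", "digestive")
        sample = draw_predictive(fitted_draws, setting, 400_000, rng=5)

        rng = np.random.default_rng(99)
        design = fitted_draws.design
        x = np.zeros(design.p)
        x[0] = 1.0
        for f in ("outcome_type", "comparison_type", "medical_area"):
            lvl = getattr(setting, f)
            if lvl in design.factor_cols[f]:
                x[design.factor_cols[f][lvl]] = 1.0
        coef = fitted_draws.flat(fitted_draws.coef)
        c = design.comp_type_levels.index(setting.comparison_type)
        o = design.outcome_levels.index(setting.outcome_type)
        k2 = fitted_draws.flat(fitted_draws.kappa2)[:, c]
        s2 = fitted_draws.flat(fitted_draws.sigma2)[:, o]
        n = 400_000
        idx = rng.integers(0, coef.shape[0], n)
        lam = rng.gamma(2.5, size=n) / 2.5
        oracle = np.exp(
            coef[idx] @ x
            + rng.standard_normal(n) * np.sqrt(k2[idx])
            + rng.standard_normal(n) * np.sqrt(s2[idx] / lam)
        )
        assert np.median(np.log(sample)) == pytest.approx(
            np.median(np.log(oracle)), abs=0.03
        )

    def test_unfitted_category_rejected(self, fitted_draws):
        fitted = set(fitted_draws.design.factor_cols["medical_area"])
        fitted.add(fitted_draws.design.factor_references["medical_area"])
        from hetmeta.schema import MEDICAL_AREAS

        # the 80-MA fixture spans ~11 reviews, far fewer than needed to
        # observe all 11 areas (deterministic under the fixture seed)
        absent = sorted(set(MEDICAL_AREAS) - fitted)
        assert absent
        setting = Setting("general_health", "nonpharm_vs_any", absent[0])
        with pytest.raises(KeyError, match="not present"):
            draw_predictive(fitted_draws, setting, 100, rng=0)
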