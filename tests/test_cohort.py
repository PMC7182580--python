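import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from octaflow import (
    SingularDesignError,
    check_assumptions,
    fisher_exact_2x2,
    fit_association_model,
    fit_group_model,
    make_cohort,
    mean_arterial_pressure,
    power_correlation,
    ttest_from_summary,
)
from octaflow.cohort import records_to_frame
from octaflow.simulate import CohortSpec
from .oracles import fisher_oracle, pooled_t_oracle


class TestMAP:
    def test_single_reading(self):
        assert mean_arterial_pressure([(120, 80)]) == pytest.approx(93.3333, abs=1e-3)

    def test_three_readings_average(self):
        readings = [(120, 80), (126, 84), (114, 76)]
        assert mean_arterial_pressure(readings) == pytest.approx(93.3333, abs=1e-3)

    @pytest.mark.parametrize("reading", [(80, 80), (70, 90), (50, 0)])
    def test_invalid_pressures_rejected(self, reading):
        with pytest.raises(ValueError):
            mean_arterial_pressure([reading])


class TestAssumptions:
    def test_equal_variances_give_unit_f(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 10
        res = check_assumptions(a, b)
        assert res["folded_f"] == pytest.approx(1.0)
        assert res["folded_f_p"] == pytest.approx(1.0)

    def test_doubled_sd_gives_f_of_four(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a.mean() + 2 * (a - a.mean())
        assert check_assumptions(a, b)["folded_f"] == pytest.approx(4.0)

    def test_shapiro_accepts_gaussian_samples(self):
        hits = sum(
            check_assumptions(
                np.random.default_rng(s).normal(size=500),
                np.random.default_rng(1000 + s).normal(size=500),
            )["normal"][0]
            for s in range(100)
        )
        assert hits >= 90

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            check_assumptions([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTTest:
    def test_equal_means_null(self):
        res = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        a = ttest_from_summary(86, 13, 12, 102, 13, 19)
        b = ttest_from_summary(102, 13, 19, 86, 13, 12)
        assert a["p"] == pytest.approx(b["p"])
        assert a["t"] == pytest.approx(-b["t"])

    def test_map_group_difference_from_printed_summaries(self):
        res = ttest_from_summary(86, 13, 12, 102, 13, 19)
        assert res["df"] == 29
        assert res["t"] == pytest.approx(
            pooled_t_oracle(86, 13, 12, 102, 13, 19), rel=1e-12
        )
        assert res["p"] == pytest.approx(0.002, abs=0.001)

    def test_haematocrit_difference_is_overwhelming(self):
        assert ttest_from_summary(29, 4, 12, 44, 3, 19)["p"] < 0.0001


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)

    def test_sex_table(self):
        assert fisher_exact_2x2(2, 10, 10, 9) == pytest.approx(0.07, abs=0.005)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 16, size=4))
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestPower:
    def test_study_design_point(self):
        # r is printed to two decimals, so the closed form lands near 0.81
        assert power_correlation(41, 0.43, 0.05) == pytest.approx(0.80, abs=0.02)

    def test_null_correlation_gives_alpha(self):
        assert power_correlation(100, 1e-12, 0.05) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n_and_r(self):
        by_n = [power_correlation(n, 0.43, 0.05) for n in (10, 20, 41, 80)]
        by_r = [power_correlation(41, r, 0.05) for r in (0.1, 0.3, 0.43, 0.6)]
        assert all(a < b for a, b in zip(by_n, by_n[1:]))
        assert all(a < b for a, b in zip(by_r, by_r[1:]))

    def test_agrees_with_monte_carlo(self):
        n, r, reps = 41, 0.43, 10000
        rng = np.random.default_rng(11)
        z = rng.normal(size=(reps, n, 2))
        x = z[:, :, 0]
        y = r * x + np.sqrt(1 - r * r) * z[:, :, 1]
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        rhat = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = rhat * np.sqrt((n - 2) / (1 - rhat**2))
        mc = float((2 * stats.t.sf(np.abs(t), n - 2) < 0.05).mean())
        assert power_correlation(n, r, 0.05) == pytest.approx(mc, abs=0.02)

    def test_out_of_range_rejected(self):
        for bad in [(3, 0.4, 0.05), (41, 1.0, 0.05), (41, 0.4, 0.0)]:
            with pytest.raises(ValueError):
                power_correlation(*bad)


def _independent_rows(seed: int, n: int = 41, slope: float = 0.5):
    """Eye table with no subject-level variance and known fixed effects."""
    rng = np.random.default_rng(seed)
    sid = [f"S{i:02d}" for i in range(31)] + [f"S{i:02d}" for i in range(n - 31)]
    trbf = rng.normal(55, 20, n)
    mp = rng.normal(95, 12, n)
    lat = rng.choice(["OD", "OS"], n)
    vti = 0.3 + slope * trbf / 100 + rng.normal(0, 0.1, n)
    return pd.DataFrame(
        dict(subject_id=sid, trbf=trbf, map=mp, laterality=lat, vti=vti)
    )


class TestAssociationModel:
    def test_zero_subject_variance_matches_ols(self):
        df = _independent_rows(5)
        fit = fit_association_model(df, "vti")
        X = sm.add_constant(
            np.column_stack(
                [
                    df["trbf"] / 100,
                    df["map"],
                    (df["laterality"] == "OS").astype(float),
                ]
            )
        )
        ols = sm.OLS(df["vti"].to_numpy(), X).fit()
        assert fit.beta == pytest.approx(float(ols.params[1]), rel=1e-6)

    def test_predictor_rescaling_scales_beta_exactly(self):
        df = _independent_rows(6)
        per_100 = fit_association_model(df, "vti", predictor_scale=100.0)
        per_unit = fit_association_model(df, "vti", predictor_scale=1.0)
        assert per_100.beta == pytest.approx(100.0 * per_unit.beta, rel=1e-9)

    def test_singular_design_names_columns(self):
        df = _independent_rows(7)
        df["map2"] = df["map"]
        with pytest.raises(SingularDesignError, match="map"):
            fit_association_model(df, "vti", covariates=("map", "map2"))

    def test_ci_brackets_estimate_and_variances_nonnegative(self):
        subs, eyes = make_cohort(CohortSpec(seed=3))
        fit = fit_association_model(records_to_frame(subs, eyes), "vti")
        assert fit.ci_low <= fit.beta <= fit.ci_high
        assert fit.var_subject >= 0 and fit.var_residual > 0


class TestGroupModel:
    def _symmetric_frame(self):
        # identical outcome/covariate patterns in both groups
        rows = []
        rng = np.random.default_rng(9)
        base = rng.normal(0.5, 0.1, 10)
        mp = rng.normal(95, 10, 10)
        for g, prefix in (("SCR", "A"), ("NC", "B")):
            for i in range(10):
                rows.append(
                    dict(
                        subject_id=f"{prefix}{i}",
                        group=g,
                        laterality="OD" if i % 2 else "OS",
                        map=mp[i],
                        vti=base[i],
                    )
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_null_effect(self):
        g = fit_group_model(self._symmetric_frame(), "vti")
        assert g.beta == pytest.approx(0.0, abs=1e-8)
        assert g.p_value > 0.99

    def test_swapping_labels_negates_beta(self):
        subs, eyes = make_cohort(CohortSpec(seed=4))
        df = records_to_frame(subs, eyes)
        g1 = fit_group_model(df, "vti")
        flipped = df.copy()
        flipped["group"] = flipped["group"].map({"SCR": "NC", "NC": "SCR"})
        g2 = fit_group_model(flipped, "vti")
        assert g2.beta == pytest.approx(-g1.beta, rel=1e-6)

    def test_recovers_generating_group_difference(self):
        # default cohort generates a VTI gap of 0.61 - 0.42 = 0.19
        subs, eyes = make_cohort(CohortSpec(seed=12))
        g = fit_group_model(records_to_frame(subs, eyes), "vti")
        se = (g.ci_high - g.ci_low) / 2  # half-width ~ t * SE
        assert abs(g.beta - 0.19) <= 2 * se

    def test_reports_raw_group_summaries(self):
        subs, eyes = make_cohort(CohortSpec(seed=5))
        df = records_to_frame(subs, eyes)
        g = fit_group_model(df, "trbf")
        assert g.mean_scr == pytest.approx(
            df.loc[df.group == "SCR", "trbf"].mean()
        )
        assert g.sd_nc == pytest.approx(
            df.loc[df.group == "NC", "trbf"].std(ddof=1)
        )
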