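"""Group regressions, partial correlations, Bonferroni control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import limbictract as lt
from limbictract.stats import (clinical_correlation, group_regression,
                               partial_correlation, roi_analysis,
                               tractwise_analysis)
from limbictract.synthetic import CohortSpec, simulate_profile_cohort


def random_subjects(rng, n=12):
    """Small random subject table with both groups present."""
    groups = ["control"] * (n // 2) + ["patient"] * (n - n // 2)
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "group": groups,
            "age": rng.uniform(20, 60, n),
            "education": rng.uniform(8, 20, n),
            "duration": np.where(np.array(groups) == "patient",
                                 rng.uniform(0, 25, n), 0.0),
        }
    )


def ols_oracle(y, X):
    """Brute-force normal equations: beta, t and p for column 1."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[1, 1])
    t = beta[1] / se
    p = 2 * sps.t.sf(abs(t), df)
    return beta[1], t, p


def design_of(subjects):
    g = (subjects["group"] == "patient").astype(float)
    return np.column_stack([np.ones(len(subjects)), g, subjects["age"],
                            subjects["education"], subjects["duration"]])


class TestGroupRegression:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            subjects = random_subjects(rng, n=int(rng.integers(8, 13)))
            y = rng.normal(size=len(subjects))
            coef, t, p = group_regression(y, subjects)
            b_o, t_o, p_o = ols_oracle(y, design_of(subjects))
            assert abs(coef - b_o) < 1e-10
            assert abs(t - t_o) < 1e-10
            assert abs(p - p_o) < 1e-10

    def test_constant_response(self):
        rng = np.random.default_rng(3)
        subjects = random_subjects(rng)
        coef, t, p = group_regression(np.full(len(subjects), 5.0), subjects)
        assert coef == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_noiseless_group_effect_recovered_exactly(self):
        rng = np.random.default_rng(4)
        subjects = random_subjects(rng, n=20)
        X = design_of(subjects)
        y = 2.0 * X[:, 1] + 0.5 * X[:, 2] - 0.1 * X[:, 3]
        coef, t, p = group_regression(y, subjects)
        assert coef == pytest.approx(2.0, abs=1e-10)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_unbiased(self):
        """Over replicates the estimated group coefficient is centred on the
        true effect (within 2 Monte-Carlo standard errors)."""
        rng = np.random.default_rng(5)
        beta = 0.7
        subjects = random_subjects(rng, n=40)
        X = design_of(subjects)
        ests = []
        for _ in range(400):
            y = beta * X[:, 1] + rng.normal(0, 1.0, size=40)
            ests.append(group_regression(y, subjects)[0])
        ests = np.asarray(ests)
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - beta) < 2 * se + 1e-12

    def test_small_n_and_collinearity_rejected(self):
        rng = np.random.default_rng(6)
        subjects = random_subjects(rng, n=6)
        with pytest.raises(ValueError, match="too few"):
            group_regression(np.zeros(6), subjects)
        subjects = random_subjects(rng, n=12)
        subjects["education"] = subjects["age"]  # exact collinearity
        with pytest.raises(ValueError, match="rank-deficient"):
            group_regression(np.zeros(12), subjects)


class TestRoiAnalysis:
    def test_single_cell_gives_one_row(self):
        rng = np.random.default_rng(7)
        subjects = random_subjects(rng, n=16)
        means = pd.DataFrame({"subject": subjects["id"], "bundle": "fornix_L",
                              "metric": "fa", "value": rng.normal(size=16)})
        table = roi_analysis(means, subjects)
        assert len(table) == 1
        assert set(table.columns) >= {"bundle", "metric", "coefficient", "t", "p"}

    def test_missing_subject_listed(self):
        rng = np.random.default_rng(8)
        subjects = random_subjects(rng, n=10)
        means = pd.DataFrame({"subject": subjects["id"][:-1], "bundle": "b",
                              "metric": "fa", "value": rng.normal(size=9)})
        with pytest.raises(ValueError, match="s9"):
            roi_analysis(means, subjects)

    def test_null_type_one_error_calibrated(self):
        """Under the null the ROI-level test rejects at ~alpha."""
        rej = 0
        n_rep = 300
        for rep in range(n_rep):
            p, s, _ = simulate_profile_cohort(CohortSpec(seed=40_000 + rep))
            means = (p.groupby(["subject", "bundle", "metric"])["value"]
                     .mean().rename("value").reset_index())
            rej += roi_analysis(means, s)["p"].iloc[0] < 0.05
        ci = 2 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < ci + 0.01

    def test_effect_sign_recovered(self):
        """A radial-diffusivity-style increase yields a positive group
        coefficient in nearly every replicate."""
        pos = 0
        for rep in range(60):
            p, s, _ = simulate_profile_cohort(
                CohortSpec(seed=50_000 + rep), effect_d=1.2, effect_direction=+1,
                effect_points=(0, 29), metric="rd")  # tract-wide increase
            means = (p.groupby(["subject", "bundle", "metric"])["value"]
                     .mean().rename("value").reset_index())
            pos += roi_analysis(means, s)["coefficient"].iloc[0] > 0
        assert pos >= 57  # >= 95%


class TestTractwiseAnalysis:
    def test_output_shape_and_flag_consistency(self):
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=1), effect_d=1.2)
        res = tractwise_analysis(p, s)[("fornix_L", "fa")]
        assert res.p_values.shape == (30,)
        assert np.array_equal(res.significant, res.p_values < 0.05 / 30)

    def test_auto_smooths_raw_profiles(self):
        """Raw input is smoothed before testing, equal to smoothing by hand."""
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=2), effect_d=1.2)
        auto = tractwise_analysis(p, s)[("fornix_L", "fa")]
        manual = p.copy()
        wide = manual.pivot(index="subject", columns="point", values="value")
        sm = wide.apply(lambda row: lt.smooth_profile(row.to_numpy()), axis=1,
                        result_type="expand")
        manual["value"] = sm.stack().reindex(
            manual.set_index(["subject", "point"]).index).to_numpy()
        manual["smoothed"] = True
        by_hand = tractwise_analysis(manual, s)[("fornix_L", "fa")]
        assert np.allclose(auto.p_values, by_hand.p_values, atol=1e-12)

    def test_bonferroni_monotone_in_alpha(self):
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=3), effect_d=0.8)
        res_hi = tractwise_analysis(p, s, alpha=0.05)[("fornix_L", "fa")]
        res_lo = tractwise_analysis(p, s, alpha=0.01)[("fornix_L", "fa")]
        assert np.all(res_hi.significant | ~res_lo.significant)

    def test_degenerate_alpha_flags_everything(self):
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=4))
        res = tractwise_analysis(p, s, alpha=30.0)[("fornix_L", "fa")]
        assert res.significant.all()  # threshold 30/30 = 1 > any p


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 50))
        r, p = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identity_gives_unit_correlation(self):
        x = np.arange(20.0)
        r, p = partial_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(10, 16))
            x, y = rng.normal(size=(2, n))
            C = rng.normal(size=(n, 2))
            r, p = partial_correlation(x, y, C)
            Z = np.column_stack([np.ones(n), C])
            H = Z @ np.linalg.solve(Z.T @ Z, Z.T)
            rx, ry = x - H @ x, y - H @ y
            r_o = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
            t_o = r_o * np.sqrt((n - 4) / (1 - r_o ** 2))
            p_o = 2 * sps.t.sf(abs(t_o), n - 4)
            assert abs(r - r_o) < 1e-10 and abs(p - p_o) < 1e-10

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=(2, 40))
        C = rng.normal(size=(40, 3))
        r_xy, p_xy = partial_correlation(x, y, C)
        r_yx, p_yx = partial_correlation(y, x, C)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        r_scaled, _ = partial_correlation(3.0 * x - 7.0, -2.0 * y + 1.0, 5 * C + 2)
        assert r_scaled == pytest.approx(-r_xy, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"x": rng.normal(size=60), "y": rng.normal(size=60),
                           "c1": rng.normal(size=60), "c2": rng.normal(size=60)})
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        r, p = partial_correlation(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_monte_carlo_recovers_true_partial_r(self):
        """Trivariate normal with known partial correlation 0.5, n = 33."""
        rng = np.random.default_rng(13)
        rho = 0.5
        ests = []
        for _ in range(1000):
            c = rng.normal(size=33)
            x = 0.8 * c + rng.normal(size=33)
            e_y = rho * (x - 0.8 * c) / 1.0 + np.sqrt(1 - rho ** 2) * rng.normal(size=33)
            y = -0.5 * c + e_y
            ests.append(partial_correlation(x, y, c[:, None])[0])
        assert abs(np.mean(ests) - rho) < 0.05

    def test_zero_residual_variance_rejected(self):
        rng = np.random.default_rng(14)
        c = rng.normal(size=20)
        x = 2.0 * c + 1.0  # exactly explained by the covariate
        with pytest.raises(ValueError, match="residual variance"):
            partial_correlation(x, rng.normal(size=20), c[:, None])


class TestClinicalCorrelation:
    def test_strong_negative_coupling_flagged_at_locus(self):
        p, s, truth = simulate_profile_cohort(
            CohortSpec(seed=60_001, panss_coupling={"panss_total": -0.6}))
        res = clinical_correlation(p, s, scores=("panss_total",))
        r = res[("fornix_L", "fa", "panss_total")]
        locus = truth["locus"]
        assert r.significant[locus]
        assert r.r_values[locus] < 0

    def test_constant_score_rejected(self):
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=61))
        s.loc[s["group"] == "patient", "panss_total"] = 40.0
        with pytest.raises(ValueError, match="residual variance"):
            clinical_correlation(p, s, scores=("panss_total",))

    def test_missing_score_column_rejected(self):
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=62))
        with pytest.raises(ValueError, match="nonexistent"):
            clinical_correlation(p, s, scores=("nonexistent",))

    def test_too_few_patients_rejected(self):
        p, s, _ = simulate_profile_cohort(CohortSpec(seed=63, n_patient=5))
        with pytest.raises(ValueError, match="at least 8 patients"):
            clinical_correlation(p, s, scores=("panss_total",))
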