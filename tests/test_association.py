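"""Association layer: standardization, fits, descriptives, blocks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from placmed.association import (
    CorrelationBlockGrouper,
    DegenerateInputError,
    ModelFitError,
    Standardizer,
    association_scan,
    bonferroni_threshold,
    compare_groups,
    correlation_blocks,
    correlation_blocks_from_corr,
    ellipse_area,
    fit_linear,
    fit_logistic,
    standardize,
)
from placmed.params import GenerativeParams
from placmed.simulate import generate_cohort, subsample_case_control


class TestEllipseArea:
    def test_circle(self):
        assert ellipse_area(2, 2) == pytest.approx(math.pi)

    def test_mean_axes_value(self):
        # product of the mean axes, not the mean of per-subject products
        assert ellipse_area(18.60, 17.24) == pytest.approx(
            18.60 * 17.24 * math.pi / 4
        )
        assert ellipse_area(18.60, 17.24) == pytest.approx(251.85, abs=0.01)

    @given(
        a=st.floats(0.1, 100), b=st.floats(0.1, 100), c=st.floats(0.01, 10)
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_monotone(self, a, b, c):
        assert ellipse_area(a, b) == ellipse_area(b, a)
        assert ellipse_area(a + c, b) > ellipse_area(a, b)

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            ellipse_area(0.0, 3.0)


def exact_moments(values, mean, sd):
    """Affine-rescale so the sample mean/SD are exactly (mean, sd)."""
    v = np.asarray(values, float)
    return mean + sd * (v - v.mean()) / v.std(ddof=1)


class TestStandardize:
    def test_two_point_symmetry(self):
        sv = standardize(pd.Series([-1.0, 1.0]))
        assert np.allclose(sv.values, [-0.7071, 0.7071], atol=1e-4)

    def test_z_formula(self):
        # β scale of the case-group CpG distribution: mean 0.37, SD 0.10;
        # a β of 0.49 standardizes to z = 1.2
        x = exact_moments(np.random.default_rng(0).normal(size=200), 0.37, 0.10)
        sv = standardize(pd.Series(x))
        assert sv.source_mean == pytest.approx(0.37)
        assert sv.source_sd == pytest.approx(0.10)
        assert np.allclose(sv.values, (x - 0.37) / 0.10)
        sc = Standardizer().fit(pd.DataFrame({"beta": x}))
        z = sc.transform(pd.DataFrame({"beta": [0.49]}))["beta"].iloc[0]
        assert z == pytest.approx(1.2)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            standardize(pd.Series([3.0, 3.0, 3.0]))
        with pytest.raises(DegenerateInputError):
            standardize(pd.Series([3.0]))

    def test_missing_stays_missing(self):
        sv = standardize(pd.Series([1.0, np.nan, 3.0]))
        assert np.isnan(sv.values.iloc[1])

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=40).filter(
            lambda v: np.std(v) > 1e-6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_with_unit_moments(self, values):
        z1 = standardize(pd.Series(values)).values
        assert abs(z1.mean()) < 1e-10
        assert abs(z1.std(ddof=1) - 1) < 1e-10
        z2 = standardize(z1).values
        assert np.allclose(z1, z2, atol=1e-10)

    def test_transformer_roundtrip_and_clone(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [0.1, 0.2, 0.4]})
        sc = Standardizer().fit(X)
        out = sc.transform(X)
        assert np.allclose(out.mean(), 0, atol=1e-12)
        assert clone(sc).fit(X).means_ == sc.means_


class TestCompareGroups:
    def test_pooled_t_from_printed_summaries(self):
        """Placental weight: 86 cases mean 466.24 (54.58) vs 79 controls
        504.80 (56.07) gives |t| ~ 4.47, p < 1e-4."""
        rng = np.random.default_rng(1)
        w_cases = exact_moments(rng.normal(size=86), 466.24, 54.58)
        w_controls = exact_moments(rng.normal(size=79), 504.80, 56.07)
        cohort = pd.DataFrame(
            {
                "case_status": [1] * 86 + [0] * 79,
                "placental_weight": np.concatenate([w_cases, w_controls]),
            }
        )
        # independent oracle: textbook pooled-variance t from the summaries
        sp2 = (85 * 54.58**2 + 78 * 56.07**2) / 163
        t_expected = (466.24 - 504.80) / math.sqrt(sp2 * (1 / 86 + 1 / 79))
        out = compare_groups(cohort, ["placental_weight"])
        assert out["statistic"].iloc[0] == pytest.approx(t_expected, abs=1e-6)
        assert abs(out["statistic"].iloc[0]) == pytest.approx(4.47, abs=0.01)
        assert out["p_value"].iloc[0] < 1e-4

    def test_identical_groups(self):
        x = np.arange(10, dtype=float)
        cohort = pd.DataFrame(
            {"case_status": [1] * 10 + [0] * 10, "v": np.concatenate([x, x])}
        )
        out = compare_groups(cohort, ["v"])
        assert out["statistic"].iloc[0] == pytest.approx(0.0)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_chi2_zero_for_identical_proportions(self):
        cohort = pd.DataFrame(
            {"case_status": [1] * 20 + [0] * 40, "flag": [1, 0] * 10 + [1, 0] * 20}
        )
        out = compare_groups(cohort, ["flag"])
        assert out["kind"].iloc[0] == "categorical"
        assert out["statistic"].iloc[0] == pytest.approx(0.0)

    def test_unknown_variable(self):
        with pytest.raises(KeyError):
            compare_groups(pd.DataFrame({"case_status": [0, 1]}), ["nope"])


def two_by_two(a, b, c, d):
    """exposed cases, exposed controls, unexposed cases, unexposed controls"""
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1.0] * (a + b) + [0.0] * (c + d)
    return pd.Series(y), pd.DataFrame({"x": x})


class TestLogistic:
    def test_matches_cross_product_odds_ratio(self):
        y, X = two_by_two(30, 10, 20, 40)
        res = fit_logistic(y, X)["x"]
        assert res.odds_ratio == pytest.approx((30 * 40) / (10 * 20), abs=1e-6)
        lo, hi = res.or_ci
        assert lo <= res.odds_ratio <= hi

    def test_independent_predictor_gives_unit_or(self):
        y, X = two_by_two(20, 20, 20, 20)
        assert fit_logistic(y, X)["x"].odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_constant_predictor_rejected(self):
        y = pd.Series([0, 1, 0, 1])
        with pytest.raises(DegenerateInputError):
            fit_logistic(y, pd.DataFrame({"x": [1.0] * 4}))

    def test_complete_separation_detected(self):
        y = pd.Series([0] * 20 + [1] * 20)
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
        with pytest.raises(ModelFitError, match="separation"):
            fit_logistic(y, X)

    def test_fractional_outcome_accepted(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": rng.normal(size=200)})
        p = 1 / (1 + np.exp(-X["x"]))
        res = fit_logistic(p, X)["x"]
        assert res.coefficient == pytest.approx(1.0, abs=1e-6)


class TestLinear:
    def test_exact_fit(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0])
        res = fit_linear(x, pd.DataFrame({"x": x}))["x"]
        assert res.coefficient == pytest.approx(1.0)
        assert res.se == pytest.approx(0.0, abs=1e-10)

    def test_null_simulation(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"x": rng.normal(size=10_000)})
        y = rng.normal(size=10_000)
        res = fit_linear(pd.Series(y), X)["x"]
        assert abs(res.coefficient) < 3 * res.se

    def test_girls_calibration_recovery(self):
        """Generator run at beta1 = -0.21 recovers the coefficient to 3 SEs."""
        p = GenerativeParams(n_subjects=20_000, seed=33, beta1=-0.21)
        c = generate_cohort(p)
        terms = pd.DataFrame(
            {
                "z_meth": standardize(c["beta_CpG 11"]).values,
                "gestational_age": c["gestational_age"].astype(float),
                "female": c["female"].astype(float),
            }
        )
        res = fit_linear(standardize(c["placental_area"]).values, terms)["z_meth"]
        assert abs(res.coefficient - (-0.21)) < 3 * res.se

    def test_rank_deficient_rejected(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ModelFitError, match="rank"):
            fit_linear(pd.Series(rng.normal(size=50)), X)


@pytest.fixture(scope="module")
def scan_inputs():
    p = GenerativeParams(n_subjects=40_000, seed=34)
    cohort = generate_cohort(p)
    cc = subsample_case_control(cohort, 300, 300, seed=35)
    wide = cc.set_index("subject_id")[[f"beta_{c}" for c in p.cpg_ids]]
    wide.columns = list(p.cpg_ids)
    # differential missingness across CpGs
    rng = np.random.default_rng(36)
    wide.loc[wide.index[rng.uniform(size=len(wide)) < 0.2], "CpG 7"] = np.nan
    return cc, wide


class TestScan:
    def test_cardinality_and_differential_n(self, scan_inputs):
        cc, wide = scan_inputs
        scan = association_scan(wide, cc)
        assert len(scan) == 5 * 3 * 2
        assert (scan.groupby("model").size() == 15).all()
        all_rows = scan[scan.stratum == "all"].set_index(["cpg", "model"])
        assert all_rows.loc[("CpG 7", "logistic"), "n"] < all_rows.loc[
            ("CpG 11", "logistic"), "n"
        ]

    def test_row_order_invariance(self, scan_inputs):
        cc, wide = scan_inputs
        a = association_scan(wide, cc).sort_values(["cpg", "stratum", "model"])
        shuffled = cc.sample(frac=1.0, random_state=7).reset_index(drop=True)
        b = association_scan(wide, shuffled).sort_values(["cpg", "stratum", "model"])
        assert np.allclose(
            a["coefficient"].to_numpy(), b["coefficient"].to_numpy(), equal_nan=True
        )

    def test_sensitivity_toggles(self, scan_inputs):
        cc, wide = scan_inputs
        scan = association_scan(wide, cc, drop_ets=True, exclude_alcohol=True)
        n_alc = (cc["alcohol_use"] == 1).sum()
        assert n_alc > 0
        full = association_scan(wide, cc)
        assert (
            scan[scan.stratum == "all"]["n"].max()
            <= full[full.stratum == "all"]["n"].max() - 1
        )

    def test_true_effect_detected(self, scan_inputs):
        cc, wide = scan_inputs
        scan = association_scan(wide, cc)
        row = scan[
            (scan.cpg == "CpG 11") & (scan.stratum == "all") & (scan.model == "logistic")
        ].iloc[0]
        assert row["or"] > 1.2 and row["p"] < 0.01


def printed_corr_structure():
    cpgs = ["CpG 2", "CpG 3.4", "CpG 5", "CpG 7", "CpG 11"]
    r = np.full((5, 5), 0.10)
    np.fill_diagonal(r, 1.0)
    r[0, 1] = r[1, 0] = 0.66
    pairs = {(2, 3): 0.36, (2, 4): 0.52, (3, 4): 0.44}
    for (i, j), v in pairs.items():
        r[i, j] = r[j, i] = v
    return pd.DataFrame(r, index=cpgs, columns=cpgs)


class TestBlocks:
    def test_printed_structure_gives_two_blocks(self):
        part = correlation_blocks_from_corr(printed_corr_structure(), cutoff=0.30)
        assert part.n_blocks == 2
        assert sorted(map(sorted, part.blocks)) == [
            ["CpG 11", "CpG 5", "CpG 7"],
            ["CpG 2", "CpG 3.4"],
        ]

    def test_all_uncorrelated_gives_singletons(self):
        corr = pd.DataFrame(np.eye(3), columns=list("abc"), index=list("abc"))
        assert correlation_blocks_from_corr(corr, 0.3).n_blocks == 3

    def test_all_correlated_gives_one_block(self):
        corr = pd.DataFrame(
            np.full((3, 3), 0.5) + 0.5 * np.eye(3),
            columns=list("abc"), index=list("abc"),
        )
        assert correlation_blocks_from_corr(corr, 0.3).n_blocks == 1

    def test_blocks_from_generated_data(self):
        p = GenerativeParams(n_subjects=3000, seed=37)
        c = generate_cohort(p)
        beta = c[[f"beta_{x}" for x in p.cpg_ids]]
        beta.columns = list(p.cpg_ids)
        part = correlation_blocks(beta, cutoff=0.30)
        assert part.n_blocks == 2

    def test_grouper_estimator(self):
        p = GenerativeParams(n_subjects=2000, seed=38)
        c = generate_cohort(p)
        beta = c[[f"beta_{x}" for x in p.cpg_ids]]
        beta.columns = list(p.cpg_ids)
        g = CorrelationBlockGrouper(cutoff=0.30).fit(beta)
        assert len(g.labels_) == 5
        assert g.partition_.n_blocks == len(set(g.labels_))
        assert clone(g).cutoff == 0.30

    def test_isolated_cpg_warns(self):
        rng = np.random.default_rng(5)
        beta = pd.DataFrame({"a": rng.uniform(size=10), "b": rng.uniform(size=10)})
        beta["c"] = np.nan
        with pytest.warns(UserWarning, match="isolated"):
            part = correlation_blocks(beta, 0.3)
        assert ["c"] in part.blocks

    def test_single_cpg_rejected(self):
        with pytest.raises(ValueError):
            correlation_blocks(pd.DataFrame({"a": [0.1, 0.2]}), 0.3)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n_blocks,expected", [(0.05, 2, 0.025), (0.05, 5, 0.01), (0.1, 1, 0.1)]
    )
    def test_threshold(self, alpha, n_blocks, expected):
        assert bonferroni_threshold(n_blocks, alpha) == pytest.approx(expected)

    def test_from_partition(self):
        part = correlation_blocks_from_corr(printed_corr_structure(), 0.30)
        assert bonferroni_threshold(part, 0.05) == pytest.approx(0.025)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0, 0.05)
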