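"""Statistical layer: ANOVA against an explicit design-matrix oracle,
least-squares means, the paired t-test and summary tables."""

import numpy as np
import pandas as pd
import pytest

from colonyflux.stagestats import (
    average_t3,
    fit_lm_anova,
    lsm_pairwise,
    paired_t,
    stage_summary,
)


def toy_table():
    """Balanced 2x3 design, n=12, integer responses."""
    rows = []
    y = iter([3, 5, 4, 6, 8, 9, 2, 4, 5, 7, 9, 12])
    for sex in ("female", "male"):
        for stage in ("pre_laying", "incubation", "chick_rearing"):
            for _ in range(2):
                rows.append({"sex": sex, "stage": stage, "y": next(y)})
    return pd.DataFrame(rows)


def unbalanced_table():
    rows = []
    y = iter([3.0, 5.0, 4.0, 6.0, 7.0, 8.0, 9.0, 2.0, 4.0, 5.0, 7.0, 9.0, 12.0, 1.0])
    counts = {("female", "pre_laying"): 3, ("female", "incubation"): 2,
              ("female", "chick_rearing"): 2, ("male", "pre_laying"): 2,
              ("male", "incubation"): 3, ("male", "chick_rearing"): 2}
    for (sex, stage), n in counts.items():
        for _ in range(n):
            rows.append({"sex": sex, "stage": stage, "y": next(y)})
    return pd.DataFrame(rows)


def sum_coded_design(df):
    """Explicit sum-to-zero design matrix for sex * stage (oracle)."""
    sex = np.where(df["sex"] == "female", 1.0, -1.0)
    stages = ["pre_laying", "incubation", "chick_rearing"]
    s1 = np.where(df["stage"] == stages[0], 1.0, np.where(df["stage"] == stages[2], -1.0, 0.0))
    s2 = np.where(df["stage"] == stages[1], 1.0, np.where(df["stage"] == stages[2], -1.0, 0.0))
    X = np.column_stack([np.ones(len(df)), sex, s1, s2, sex * s1, sex * s2])
    blocks = {"Intercept": [0], "sex": [1], "stage": [2, 3], "interaction": [4, 5]}
    return X, blocks


def rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def type3_ss_oracle(df, response="y"):
    """Type III SS by dropping each term's columns from the full sum-coded
    design (brute-force projection arithmetic)."""
    y = df[response].to_numpy(float)
    X, blocks = sum_coded_design(df)
    full = rss(X, y)
    out = {}
    for term, cols in blocks.items():
        keep = [j for j in range(X.shape[1]) if j not in cols]
        out[term] = rss(X[:, keep], y) - full
    out["Residual"] = full
    return out


class TestAverageT3:
    @pytest.mark.parametrize(
        "samples,expected",
        [((4.0, 6.0), 5.0), ((3.2,), 3.2)],
    )
    def test_mean_of_available_samples(self, samples, expected):
        assert average_t3(samples) == pytest.approx(expected)

    def test_no_samples_is_missing(self):
        assert np.isnan(average_t3(()))


class TestAnova:
    def test_type3_matches_design_matrix_oracle(self):
        df = toy_table()
        res = fit_lm_anova(df, "y", interaction=True)
        oracle = type3_ss_oracle(df)
        for term, key in [("C(sex)", "sex"), ("C(stage)", "stage"),
                          ("C(sex):C(stage)", "interaction"), ("Residual", "Residual")]:
            assert res.table.loc[term, "sum_sq"] == pytest.approx(oracle[key], abs=1e-8)
        mse = oracle["Residual"] / res.table.loc["Residual", "df"]
        f_sex = (oracle["sex"] / 1) / mse
        assert res.table.loc["C(sex)", "F"] == pytest.approx(f_sex, abs=1e-8)

    def test_type2_matches_sequential_oracle_on_unbalanced_data(self):
        df = unbalanced_table()
        res = fit_lm_anova(df, "y", interaction=False)
        y = df["y"].to_numpy(float)
        X, blocks = sum_coded_design(df)
        Xm = X[:, :4]  # main-effects design
        ss_sex = rss(Xm[:, [0, 2, 3]], y) - rss(Xm, y)
        ss_stage = rss(Xm[:, [0, 1]], y) - rss(Xm, y)
        assert res.table.loc["C(sex)", "sum_sq"] == pytest.approx(ss_sex, abs=1e-8)
        assert res.table.loc["C(stage)", "sum_sq"] == pytest.approx(ss_stage, abs=1e-8)

    def test_balanced_design_type2_equals_type3_main_effects(self):
        df = toy_table()
        a3 = fit_lm_anova(df, "y", interaction=True)
        a2 = fit_lm_anova(df, "y", interaction=False)
        for term in ("C(sex)", "C(stage)"):
            assert a2.table.loc[term, "sum_sq"] == pytest.approx(
                a3.table.loc[term, "sum_sq"], abs=1e-8
            )

    def test_constant_response_gives_zero_f_unit_p(self):
        df = toy_table().assign(y=5.0)
        res = fit_lm_anova(df, "y", interaction=True)
        for term in ("C(sex)", "C(stage)", "C(sex):C(stage)"):
            assert res.table.loc[term, "F"] == 0.0
            assert res.table.loc[term, "PR(>F)"] == 1.0

    def test_single_level_factor_rejected(self):
        df = toy_table()
        df = df[df["sex"] == "female"]
        with pytest.raises(ValueError):
            fit_lm_anova(df, "y", interaction=True)

    def test_empty_cell_with_interaction_reports_cell_counts(self):
        df = toy_table()
        df = df[~((df["sex"] == "male") & (df["stage"] == "incubation"))]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_lm_anova(df, "y", interaction=True)


class TestLsm:
    def test_balanced_lsm_equals_cell_means(self):
        df = toy_table()
        res = fit_lm_anova(df, "y", interaction=False)
        lsm = lsm_pairwise(res, "stage")
        raw = df.groupby("stage")["y"].mean()
        for stage in raw.index:
            assert lsm.means.loc[stage, "lsm"] == pytest.approx(raw[stage], abs=1e-10)

    def test_unbalanced_lsm_is_equally_weighted_cell_mean_average(self):
        df = unbalanced_table()
        res = fit_lm_anova(df, "y", interaction=True)  # saturated model
        lsm = lsm_pairwise(res, "stage")
        cell = df.groupby(["stage", "sex"])["y"].mean()
        for stage in ("pre_laying", "incubation", "chick_rearing"):
            expected = 0.5 * (cell[stage, "female"] + cell[stage, "male"])
            assert lsm.means.loc[stage, "lsm"] == pytest.approx(expected, abs=1e-10)

    def test_tukey_adjustment_never_below_unadjusted(self):
        df = unbalanced_table()
        res = fit_lm_anova(df, "y", interaction=False)
        adj = lsm_pairwise(res, "stage", adjust="tukey").contrasts
        raw = lsm_pairwise(res, "stage", adjust="none").contrasts
        assert (adj["p_adj"].to_numpy() >= raw["p_adj"].to_numpy() - 1e-12).all()

    def test_identical_groups_give_p_near_one(self):
        df = toy_table()
        df["y"] = np.tile([1.0, 2.0], 6)  # same values in every cell
        res = fit_lm_anova(df, "y", interaction=False)
        lsm = lsm_pairwise(res, "stage")
        assert (lsm.contrasts["p_adj"] > 0.99).all()

    def test_absent_factor_rejected(self):
        res = fit_lm_anova(toy_table(), "y", interaction=False)
        with pytest.raises(ValueError):
            lsm_pairwise(res, "mass")


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computed_differences(self):
        # differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.464, df = 2
        t, df, p = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-3)
        assert t == pytest.approx(3.464, abs=1e-3)
        assert df == 2

    def test_sign_flip_symmetry(self):
        t1, _, p1 = paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        t2, _, p2 = paired_t([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_nonzero_mean_flagged_infinite(self):
        t, df, p = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0])


class TestStageSummary:
    def test_matches_hand_computation(self):
        df = pd.DataFrame(
            {
                "stage": ["pre_laying"] * 3 + ["incubation"] * 3,
                "t3": [2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
            }
        )
        out = stage_summary(df, columns=("t3",))
        pre = out[(out["stage"] == "pre_laying")].iloc[0]
        assert pre["mean"] == pytest.approx(3.0)
        assert pre["sd"] == pytest.approx(1.0)
        assert pre["n"] == 3

    def test_single_bird_sd_flagged_missing(self):
        df = pd.DataFrame({"stage": ["pre_laying"], "t3": [3.0]})
        out = stage_summary(df, columns=("t3",))
        assert np.isnan(out.iloc[0]["sd"])

    def test_constant_values_zero_sd(self):
        df = pd.DataFrame({"stage": ["incubation"] * 4, "t3": [2.5] * 4})
        out = stage_summary(df, columns=("t3",))
        assert out[out["stage"] == "incubation"].iloc[0]["sd"] == 0.0
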