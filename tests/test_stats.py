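"""Inferential statistics: mixed ANOVA, trends, regressions, Go/No-go."""

import numpy as np
import pandas as pd
import pytest

from nfloop.gonogo import simulate_gonogo
from nfloop.simulate import learning_trajectory
from nfloop import stats as gstats


def simulated_beta_table(seed=0, n_per_group=10, n_runs=7, noise_sd=0.1, nf_slope=None):
    """SMA beta table drawn directly from the learning-trajectory model."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, group in enumerate(("NF", "control")):
        slope = nf_slope if (group == "NF" and nf_slope is not None) else None
        traj = learning_trajectory(group, n_runs, slope=slope)
        for s in range(n_per_group):
            offset = rng.normal(0, 0.05)
            for r in range(n_runs):
                rows.append(
                    {
                        "subject": f"{group}{s}",
                        "group": group,
                        "run": r + 1,
                        "beta": traj[r] + offset + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_group_by_run_degrees_of_freedom(self):
        table = simulated_beta_table()
        res = gstats.mixed_anova(table, "beta", within=["run"], between=["group"], subject="subject")
        g = res.effect("group")
        assert (g.df1, g.df2) == (1, 18)
        r = res.effect("run")
        assert (r.df1, r.df2) == (6, 108)
        gr = res.effect("group * run")
        assert (gr.df1, gr.df2) == (6, 108)

    def test_all_equal_values_degenerate(self):
        table = simulated_beta_table(noise_sd=0.0)
        table["beta"] = 1.0
        res = gstats.mixed_anova(table, "beta", ["run"], ["group"], "subject")
        assert res.table.F.isna().all() or (res.table.F.fillna(0) == 0).all()

    def test_against_hand_sums_of_squares_2x2x2(self):
        # oracle: explicit split-plot SS on a 2 groups x 4 subjects x
        # 2x2 within table, written out from cell means
        rng = np.random.default_rng(3)
        rows = []
        for gi, g in enumerate(("A", "B")):
            for s in range(4):
                for w1 in (0, 1):
                    for w2 in (0, 1):
                        rows.append(
                            {
                                "subject": f"{g}{s}",
                                "group": g,
                                "w1": w1,
                                "w2": w2,
                                "y": rng.normal(gi + 0.5 * w1 + 0.2 * w1 * w2, 1.0),
                            }
                        )
        df = pd.DataFrame(rows)
        res = gstats.mixed_anova(df, "y", ["w1", "w2"], ["group"], "subject")

        y = df.pivot_table(index="subject", columns=["w1", "w2"], values="y")
        groups = df.drop_duplicates("subject").set_index("subject").group.loc[y.index]
        data = y.to_numpy().reshape(8, 2, 2)  # subject x w1 x w2
        grand = data.mean()
        gmask = (groups == "A").to_numpy()
        n, a = 4, 2
        # between part
        gm = np.stack([data[gmask].mean(), data[~gmask].mean()])
        ss_group = n * 4 * ((gm - grand) ** 2).sum()
        sm = data.mean(axis=(1, 2))
        ss_subj = 4 * ((sm - np.where(gmask, gm[0], gm[1])) ** 2).sum()
        # w1
        w1m = data.mean(axis=(0, 2))
        ss_w1 = 8 * 2 * ((w1m - grand) ** 2).sum()
        cell_gw1 = np.stack([data[gmask].mean(axis=(0, 2)), data[~gmask].mean(axis=(0, 2))])
        ss_gw1 = n * 2 * ((cell_gw1 - gm[:, None] - w1m[None] + grand) ** 2).sum()
        subj_w1 = data.mean(axis=2)
        ss_w1_err = (
            2 * ((subj_w1 - sm[:, None] - cell_gw1[(~gmask).astype(int)] + np.where(gmask, gm[0], gm[1])[:, None]) ** 2).sum()
        )
        assert res.effect("group").ss == pytest.approx(ss_group, abs=1e-10)
        assert res.effect("w1").ss == pytest.approx(ss_w1, abs=1e-10)
        assert res.effect("group * w1").ss == pytest.approx(ss_gw1, abs=1e-10)
        # error terms via the package's df bookkeeping
        assert res.effect("group").df2 == 6
        assert res.effect("w1").df2 == 6
        F_group = (ss_group / 1) / (ss_subj / 6)
        assert res.effect("group").F == pytest.approx(F_group, abs=1e-10)
        F_w1 = (ss_w1 / 1) / (ss_w1_err / 6)
        assert res.effect("w1").F == pytest.approx(F_w1, abs=1e-10)

    def test_cross_checked_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        table = simulated_beta_table(seed=9, n_per_group=6, n_runs=4)
        ours = gstats.mixed_anova(table, "beta", ["run"], ["group"], "subject")
        theirs = pg.mixed_anova(
            data=table, dv="beta", within="run", between="group", subject="subject"
        ).set_index("Source")
        assert ours.effect("group").F == pytest.approx(theirs.loc["group", "F"], rel=1e-8)
        assert ours.effect("run").F == pytest.approx(theirs.loc["run", "F"], rel=1e-8)
        assert ours.effect("group * run").F == pytest.approx(
            theirs.loc["Interaction", "F"], rel=1e-8
        )

    def test_unbalanced_rejected(self):
        table = simulated_beta_table().iloc[:-1]
        with pytest.raises(ValueError, match="within-cell|unbalanced|missing"):
            gstats.mixed_anova(table, "beta", ["run"], ["group"], "subject")

    def test_gg_epsilon_range(self):
        table = simulated_beta_table(seed=1)
        res = gstats.mixed_anova(table, "beta", ["run"], ["group"], "subject")
        eps = res.effect("run").gg_epsilon
        assert 1.0 / 6.0 <= eps <= 1.0


class TestLinearTrend:
    def test_flat_groups_small_f(self):
        table = simulated_beta_table(seed=2, nf_slope=0.0)
        out = gstats.linear_trend_interaction(table)
        assert out["p"] > 0.01

    def test_noiseless_contrast_difference_closed_form(self):
        table = simulated_beta_table(seed=0, noise_sd=0.0)
        table["beta"] = table.apply(
            lambda r: learning_trajectory(r.group, 7)[r.run - 1], axis=1
        )
        out = gstats.linear_trend_interaction(table)
        w = out["weights"]
        expected = 0.062 * (w**2).sum()  # slope times sum of squared weights
        assert out["contrast_diff"] == pytest.approx(expected, abs=1e-10)

    def test_df_1_18(self):
        out = gstats.linear_trend_interaction(simulated_beta_table())
        assert (out["df1"], out["df2"]) == (1, 18)


class TestTTests:
    def test_paired_df_9(self):
        rng = np.random.default_rng(0)
        out = gstats.paired_t(rng.normal(size=10), rng.normal(size=10))
        assert out["df"] == 9

    def test_identical_pairs(self):
        x = np.arange(5.0)
        out = gstats.paired_t(x, x)
        assert out["t"] == 0.0
        assert out["degenerate"]

    def test_hand_formula_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        out = gstats.paired_t(x, y)
        assert out["t"] == pytest.approx(t_hand, abs=1e-12)
        assert out["df"] == 2


class TestRunRegression:
    def test_seven_points_df(self):
        reg = gstats.fit_run_regression(np.arange(7) * 0.1 + np.random.default_rng(0).normal(0, 0.01, 7))
        assert (reg.df1, reg.df2) == (1, 5)

    def test_exact_line(self):
        reg = gstats.fit_run_regression(2.0 * np.arange(1, 8) + 1.0)
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.r2 == pytest.approx(1.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3 points"):
            gstats.fit_run_regression(np.array([1.0, 2.0]))


class TestCompareSlopes:
    def test_identical_regressions(self):
        rng = np.random.default_rng(4)
        y = np.arange(7) * 0.5 + rng.normal(0, 0.1, 7)
        a = gstats.fit_run_regression(y)
        out = gstats.compare_slopes(a, gstats.fit_run_regression(y))
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["df"] == 10

    def test_pooled_se_hand_oracle(self):
        rng = np.random.default_rng(5)
        ya = 0.3 * np.arange(1, 8) + rng.normal(0, 0.2, 7)
        yb = -0.1 * np.arange(1, 8) + rng.normal(0, 0.2, 7)
        a, b = gstats.fit_run_regression(ya), gstats.fit_run_regression(yb)
        s2 = (a.sse + b.sse) / 10
        se = np.sqrt(s2 * (1 / a.sxx + 1 / b.sxx))
        t_hand = (a.slope - b.slope) / se
        out = gstats.compare_slopes(a, b)
        assert out["t"] == pytest.approx(t_hand, abs=1e-12)


class TestDeviationContrast:
    def _table(self, seed=0, injected_roi=None):
        rng = np.random.default_rng(seed)
        rois = ["SMA", "M1_L", "M1_R", "PMC_L", "PMC_R", "PPC_L", "PPC_R"]
        rows = []
        for group in ("NF", "control"):
            for s in range(10):
                for r in range(1, 8):
                    for roi in rois:
                        beta = rng.normal(0.3, 0.05)
                        if injected_roi == roi and group == "NF":
                            beta += 0.08 * (r - 1)
                        rows.append(
                            {"subject": f"{group}{s}", "group": group, "run": r, "roi": roi, "beta": beta}
                        )
        return pd.DataFrame(rows)

    def test_identical_rois_give_zero_f(self):
        table = self._table()
        table["beta"] = 1.0
        out = gstats.deviation_contrast_3way(table)
        assert (out.F.fillna(0) == 0).all()

    def test_injected_trend_maximizes_f_at_target(self):
        out = gstats.deviation_contrast_3way(self._table(seed=1, injected_roi="SMA"))
        assert out.loc[out.F.idxmax(), "roi"] == "SMA"
        assert out.loc[out.roi == "SMA", "p"].iloc[0] < 0.01

    def test_df_pattern(self):
        out = gstats.deviation_contrast_3way(self._table(seed=2))
        assert (out.df1 == 1).all()
        assert (out.df2 == 18).all()

    def test_missing_roi_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="missing ROI"):
            gstats.deviation_contrast_3way(table[~((table.subject == "NF0") & (table.roi == "SMA"))])


@pytest.fixture(scope="module")
def study_tables():
        tables, groups = {}, {}
        for g in ("NF", "control"):
            for s in range(10):
                sid = f"{g}{s}"
                shift = -30.0 if g == "NF" else 0.0
                effect = {
                    ("left", "pre"): 380.0,
                    ("left", "post"): 380.0,
                    ("right", "pre"): 380.0,
                    ("right", "post"): 380.0 + shift,
                }
                tables[sid] = simulate_gonogo(effect, seed=1000 * (g == "NF") + s)
                groups[sid] = g
        return tables, groups


class TestGonogoAnalysis:

    def test_three_way_dfs_and_interaction(self, study_tables):
        tables, groups = study_tables
        out = gstats.analyze_gonogo(tables, groups)
        res = out["anova"]
        assert res.effect("group").df2 == 18
        hgs = res.effect("group * hand * session")
        assert (hgs.df1, hgs.df2) == (1, 18)
        # the generated NF-right speed-up drives the 3-way interaction
        assert hgs.p < 0.05

    def test_posthoc_structure(self, study_tables):
        tables, groups = study_tables
        out = gstats.analyze_gonogo(tables, groups)
        ph = out["posthoc"]
        assert len(ph) == 4
        assert (ph.df == 9).all()
        nf_right = ph[(ph.group == "NF") & (ph.hand == "right")].iloc[0]
        assert nf_right.p < 0.05


class TestPerformanceRegression:
    def test_df_1_8_for_ten_subjects(self):
        rng = np.random.default_rng(6)
        reg = gstats.nf_performance_regression(rng.normal(size=10), rng.normal(size=10))
        assert (reg.df1, reg.df2) == (1, 8)

    def test_exact_line(self):
        db = np.linspace(0, 1, 10)
        reg = gstats.nf_performance_regression(db, 10.0 * db - 17.0)
        assert reg.r2 == pytest.approx(1.0)
        assert reg.slope == pytest.approx(10.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            gstats.nf_performance_regression(np.ones(2), np.ones(2))
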