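"""Summary-statistics inference layer vs printed tables and raw-data oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from fishgaze.errors import DegenerateInputError, ValidationError
from fishgaze.inference import (
    GroupSummary,
    games_howell_summary,
    kruskal_wallis,
    ln_transform,
    mixed_prepost_anova,
    one_sample_t_summary,
    oneway_anova_summary,
    spearman,
    tukey_hsd_summary,
    welch_anova_summary,
)

# printed group summaries: mean time in ROI (%), real-stimulus experiment
ROI_REAL = [
    GroupSummary("BIC", 55.05, 7.22, 11),
    GroupSummary("BNIC", 41.58, 8.20, 12),
    GroupSummary("ISOL", 22.67, 3.17, 10),
]
# and the video-playback experiment
ROI_VIDEO = [
    GroupSummary("BVIC", 41.46, 1.82, 23),
    GroupSummary("BVNIC", 30.03, 1.77, 23),
    GroupSummary("VISOL", 24.00, 2.54, 23),
]


def _raw_groups(seed=0, k=3, n=12):
    rng = np.random.default_rng(seed)
    return [rng.normal(10 + 3 * i, 1.0 + i, size=n + i) for i in range(k)]


class TestWelchAnova:
    def test_reproduces_published_f(self):
        res = welch_anova_summary(ROI_REAL)
        assert res.statistic == pytest.approx(9.31, rel=0.005)

    def test_equal_means_give_zero(self):
        groups = [GroupSummary(str(i), 5.0, 1.0, 10) for i in range(3)]
        assert welch_anova_summary(groups).statistic == pytest.approx(0.0)

    def test_homoscedastic_balanced_case_equals_classic_f(self):
        # the small-sample correction vanishes as n grows, so equality with
        # the classic F is asymptotic; n = 200 puts it inside 0.5%
        groups = [
            GroupSummary("a", 1.0, 0.5, 200),
            GroupSummary("b", 2.0, 0.5, 200),
            GroupSummary("c", 1.5, 0.5, 200),
        ]
        w = welch_anova_summary(groups).statistic
        f = oneway_anova_summary(groups).statistic
        assert w == pytest.approx(f, rel=0.005)

    def test_matches_raw_data_oracle(self):
        import pingouin as pg
        import pandas as pd

        groups = _raw_groups(seed=4)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.concatenate([[i] * len(g) for i, g in enumerate(groups)]),
            }
        )
        oracle = pg.welch_anova(data=df, dv="y", between="g")
        summaries = [GroupSummary.from_raw(str(i), g) for i, g in enumerate(groups)]
        res = welch_anova_summary(summaries)
        assert res.statistic == pytest.approx(float(oracle["F"].iloc[0]), rel=1e-9)
        assert res.df[1] == pytest.approx(float(oracle["ddof2"].iloc[0]), rel=1e-9)

    def test_invariant_under_rescaling(self):
        base = welch_anova_summary(ROI_REAL).statistic
        scaled = welch_anova_summary(
            [GroupSummary(g.label, g.mean * 3.7, g.sem * 3.7, g.n) for g in ROI_REAL]
        ).statistic
        assert scaled == pytest.approx(base)


class TestOnewayAnova:
    def test_reproduces_published_f(self):
        res = oneway_anova_summary(ROI_VIDEO)
        assert res.statistic == pytest.approx(18.32, rel=0.005)
        assert res.df == (2, 66)

    def test_identical_groups_give_zero(self):
        groups = [GroupSummary("a", 5.0, 1.0, 10), GroupSummary("b", 5.0, 1.0, 10)]
        assert oneway_anova_summary(groups).statistic == pytest.approx(0.0)

    def test_two_groups_equal_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(0.8, 1, 14)
        summaries = [GroupSummary.from_raw("a", a), GroupSummary.from_raw("b", b)]
        F = oneway_anova_summary(summaries).statistic
        t, _ = sps.ttest_ind(a, b)
        assert F == pytest.approx(t**2, rel=1e-9)

    def test_matches_raw_data_oracle(self):
        groups = _raw_groups(seed=5)
        F, p = sps.f_oneway(*groups)
        summaries = [GroupSummary.from_raw(str(i), g) for i, g in enumerate(groups)]
        res = oneway_anova_summary(summaries)
        assert res.statistic == pytest.approx(F, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-6)


class TestPostHoc:
    def test_games_howell_reproduces_published_p(self):
        res = {(r.group_a, r.group_b): r.p for r in games_howell_summary(ROI_REAL)}
        assert res[("BIC", "ISOL")] == pytest.approx(0.003, abs=5e-4)
        assert res[("BIC", "ISOL")] < 0.05
        assert res[("BNIC", "ISOL")] > 0.05
        assert res[("BIC", "BNIC")] > 0.05

    def test_identical_groups_not_significant(self):
        groups = [GroupSummary(str(i), 5.0, 1.0, 10) for i in range(3)]
        for fam in (games_howell_summary, tukey_hsd_summary):
            assert all(r.p > 0.999 for r in fam(groups))

    def test_huge_separation_is_overwhelming(self):
        groups = [GroupSummary("a", 0.0, 0.316, 10), GroupSummary("b", 10.0, 0.316, 10)]
        assert games_howell_summary(groups)[0].p < 1e-4

    def test_games_howell_matches_raw_oracle(self):
        import pingouin as pg
        import pandas as pd

        groups = _raw_groups(seed=6)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.concatenate([[str(i)] * len(g) for i, g in enumerate(groups)]),
            }
        )
        oracle = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        summaries = [GroupSummary.from_raw(str(i), g) for i, g in enumerate(groups)]
        ours = {(r.group_a, r.group_b): r for r in games_howell_summary(summaries)}
        for row in oracle.itertuples():
            r = ours[(str(row.A), str(row.B))]
            assert r.p == pytest.approx(float(row.pval), abs=1e-6)

    def test_tukey_matches_raw_oracle(self):
        groups = _raw_groups(seed=7, n=10)
        # balanced case for scipy's tukey_hsd
        groups = [g[:10] for g in groups]
        oracle = sps.tukey_hsd(*groups)
        summaries = [GroupSummary.from_raw(str(i), g) for i, g in enumerate(groups)]
        ours = {(r.group_a, r.group_b): r for r in tukey_hsd_summary(summaries)}
        for i in range(3):
            for j in range(i + 1, 3):
                assert ours[(str(i), str(j))].p == pytest.approx(
                    oracle.pvalue[i, j], abs=1e-6
                )


class TestOneSampleT:
    def test_reproduces_published_value(self):
        res = one_sample_t_summary(22.67, 3.17, 10, 25.0)
        assert res.statistic == pytest.approx(-0.735, abs=0.001)
        assert res.df == (9,)
        assert res.p == pytest.approx(0.48, abs=0.01)

    def test_null_mean_gives_unit_p(self):
        res = one_sample_t_summary(5.0, 1.0, 8, 5.0)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_identity_with_raw_computation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(4, 2, size=15)
        t_raw, p_raw = sps.ttest_1samp(x, 3.0)
        g = GroupSummary.from_raw("x", x)
        res = one_sample_t_summary(g.mean, g.sem, g.n, 3.0)
        assert res.statistic == pytest.approx(t_raw, rel=1e-9)
        assert res.p == pytest.approx(p_raw, rel=1e-9)

    def test_bad_sem_rejected(self):
        with pytest.raises(DegenerateInputError):
            one_sample_t_summary(5.0, 0.0, 10, 4.0)


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_matches_rank_formula_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = kruskal_wallis([a, b])
        # brute-force: H from the rank-sum definition, no ties
        ranks = {1.0: 1, 2.0: 2, 3.0: 3, 4.0: 4, 5.0: 5, 6.0: 6}
        n = 6
        h = 12.0 / (n * (n + 1)) * sum(
            sum(ranks[v] for v in g) ** 2 / len(g) for g in (a, b)
        ) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h)

    def test_tiny_groups_warn(self):
        res = kruskal_wallis([[1.0], [2.0], [3.0]])
        assert "warning" in res.detail

    def test_total_n_too_small(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0], [2.0]])


class TestSpearman:
    def test_monotone_series(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).statistic == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_permutation_p_is_seeded_and_calibrated(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r1 = spearman(x, y, seed=9)
        r2 = spearman(x, y, seed=9)
        assert r1.p == r2.p
        # independent series: p should not be extreme
        assert r1.p > 0.05


class TestMixedPrePost:
    def test_identical_phases_give_zero_f(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = mixed_prepost_anova(pre, pre, ["a", "a", "a", "b", "b", "b"])
        assert res.interaction.statistic == 0.0
        assert res.phase.statistic == 0.0

    def test_interaction_matches_mixed_anova_oracle(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(4)
        n = 12
        groups = ["a"] * n + ["b"] * n
        pre = np.concatenate([rng.normal(10, 2, n), rng.normal(10, 2, n)])
        post = np.concatenate([rng.normal(8, 2, n), rng.normal(10, 2, n)])
        res = mixed_prepost_anova(pre, post, groups)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(2 * n), 2),
                "group": np.tile(groups, 2),
                "phase": ["pre"] * 2 * n + ["post"] * 2 * n,
                "y": np.concatenate([pre, post]),
            }
        )
        oracle = pg.mixed_anova(
            data=long, dv="y", within="phase", subject="subject", between="group"
        )
        inter = oracle[oracle["Source"] == "Interaction"].iloc[0]
        assert res.interaction.statistic == pytest.approx(float(inter["F"]), rel=1e-6)
        assert res.interaction.df == (int(inter["DF1"]), int(inter["DF2"]))

    def test_phase_drop_in_one_group_detected(self):
        rng = np.random.default_rng(5)
        n = 23
        groups = ["drop"] * n + ["flat"] * n
        pre = np.concatenate([rng.normal(50, 10, n), rng.normal(30, 10, n)])
        post = np.concatenate([rng.normal(35, 10, n), rng.normal(30, 10, n)])
        res = mixed_prepost_anova(pre, post, groups)
        assert res.interaction.p < 0.05
        assert res.contrasts["pre_vs_post@drop"].p < 0.05
        assert res.contrasts["pre_vs_post@flat"].p > 0.05

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(6)
        n = 20
        groups = ["a"] * n + ["b"] * n
        hits = 0
        reps = 400
        for _ in range(reps):
            pre = rng.normal(0, 1, 2 * n)
            post = rng.normal(0, 1, 2 * n)
            if mixed_prepost_anova(pre, post, groups).interaction.p < 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.08

    def test_unbalanced_phases_rejected(self):
        with pytest.raises(ValidationError):
            mixed_prepost_anova([1.0, np.nan], [1.0, 2.0], ["a", "b"])


def test_ln_transform_requires_positive_values():
    out = ln_transform([[1.0, np.e], [np.e**2]])
    assert out[0][1] == pytest.approx(1.0)
    assert out[1][0] == pytest.approx(2.0)
    with pytest.raises(ValidationError):
        ln_transform([[0.0, 1.0]])
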