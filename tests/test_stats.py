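import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dsrisk.stats import (
    arcsine_sqrt,
    chisq_upper_tail,
    f_upper_tail,
    kruskal_wallis,
    lsd_posthoc,
    normalize_band_intensity,
    one_way_anova,
    two_way_anova,
)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_decomposition(self):
        # groups {1,2},{3,4},{5,6}: SS_between = 16, SS_within = 1.5,
        # F = (16/2)/(1.5/3) = 16
        res = one_way_anova({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert (res.df_num, res.df_den) == (2, 3)
        assert res.f_statistic == pytest.approx(16.0)
        assert res.ms_error == pytest.approx(0.5)

    def test_agrees_with_scipy(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, size=12).tolist() for i in range(4)}
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(float(f))
        assert res.p_value == pytest.approx(float(p))

    def test_ss_conservation(self, rng):
        for _ in range(20):
            groups = {f"g{i}": rng.normal(0, 1, size=int(rng.integers(3, 15)))
                      for i in range(int(rng.integers(2, 6)))}
            allv = np.concatenate(list(groups.values()))
            ss_total = ((allv - allv.mean()) ** 2).sum()
            res = one_way_anova(groups)
            ss_sum = (res.f_statistic * res.ms_error * res.df_num
                      + res.ms_error * res.df_den)
            assert ss_sum == pytest.approx(ss_total, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero residual variance"):
            one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})


class TestTwoWayAnova:
    @staticmethod
    def _grid(rng, n_rep=3, effects=None):
        rows = []
        for trt in ("dsDVV", "dsSC", "dsGUS", "H2O"):
            for day in (2, 4, 6):
                for _ in range(n_rep):
                    mu = 0.0
                    if effects:
                        mu = effects.get(trt, 0.0) + effects.get(day, 0.0)
                    rows.append({"treatment": trt, "day": day,
                                 "expression": mu + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_df_structure_4x3x3(self, rng):
        res = two_way_anova(self._grid(rng), "expression")
        by = {r.term: r for r in res}
        assert (by["treatment"].df_num, by["treatment"].df_den) == (3, 24)
        assert (by["day"].df_num, by["day"].df_den) == (2, 24)
        assert (by["treatment:day"].df_num, by["treatment:day"].df_den) == (6, 24)

    def test_additive_effects_leave_interaction_null(self, rng):
        rejections = 0
        for seed in range(40):
            local = np.random.default_rng(seed)
            df = self._grid(local, n_rep=4,
                            effects={"dsDVV": 3.0, "dsSC": -2.0, 2: 1.0, 6: -1.0})
            by = {r.term: r for r in two_way_anova(df, "expression")}
            assert by["treatment"].p_value < 0.01  # planted main effect found
            rejections += by["treatment:day"].p_value < 0.05
        assert rejections <= 8  # interaction stays near nominal alpha

    def test_single_replicate_interaction_rejected(self, rng):
        with pytest.raises(ValueError, match="cells"):
            two_way_anova(self._grid(rng, n_rep=1), "expression")

    def test_no_interaction_mode_runs_with_single_rep(self, rng):
        res = two_way_anova(self._grid(rng, n_rep=1), "expression", interaction=False)
        assert {r.term for r in res} == {"treatment", "day"}


class TestKruskalWallis:
    def test_df_is_groups_minus_one(self):
        groups = {f"t{i}": [2 * i + 1, 2 * i + 2] for i in range(5)}
        res = kruskal_wallis(groups)
        assert res.df == 4

    def test_hand_rank_arithmetic_with_ties(self):
        # values 1,2,2,3 / 2,4: mid-ranks 1, 3, 3, 5, 3, 6
        groups = {"a": [1, 2, 2, 3], "b": [2, 4]}
        n = 6
        r_a, r_b = [1, 3, 3, 5], [3, 6]
        h = 12 / (n * (n + 1)) * (sum(r_a) ** 2 / 4 + sum(r_b) ** 2 / 2) - 3 * (n + 1)
        tie = 1 - (3**3 - 3) / (n**3 - n)  # one tie group of size 3
        res_raw = kruskal_wallis(groups, tie_correction=False)
        res_tie = kruskal_wallis(groups, tie_correction=True)
        assert res_raw.h_statistic == pytest.approx(h)
        assert res_tie.h_statistic == pytest.approx(h / tie)

    def test_tie_corrected_agrees_with_scipy(self, rng):
        groups = {f"g{i}": rng.integers(0, 8, size=10).astype(float).tolist()
                  for i in range(3)}
        res = kruskal_wallis(groups, tie_correction=True)
        h, p = sps.kruskal(*groups.values())
        assert res.h_statistic == pytest.approx(float(h))
        assert res.p_value == pytest.approx(float(p))

    def test_degenerate_ranking_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kruskal_wallis({"a": [1.0, 1.0], "b": [1.0, 1.0]})


class TestLsdPosthoc:
    def test_identical_groups_p_one(self):
        table = lsd_posthoc({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert table.loc[0, "p_value"] == pytest.approx(1.0)
        assert not table.loc[0, "significant"]

    def test_four_groups_six_pairs(self, rng):
        groups = {f"g{i}": rng.normal(0, 1, 8).tolist() for i in range(4)}
        assert len(lsd_posthoc(groups)) == 6

    def test_planted_shift_flagged(self, rng):
        groups = {"ctrl": rng.normal(0, 0.5, 12).tolist(),
                  "shift": rng.normal(5.0, 0.5, 12).tolist()}
        table = lsd_posthoc(groups)
        assert bool(table.loc[0, "significant"])

    def test_pairwise_t_matches_scipy_pooled(self):
        groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 3.0, 4.0, 5.0]}
        table = lsd_posthoc(groups)
        # two groups: LSD t equals the pooled-variance two-sample t
        t, p = sps.ttest_ind(groups["a"], groups["b"], equal_var=True)
        assert table.loc[0, "t"] == pytest.approx(float(t))
        assert table.loc[0, "p_value"] == pytest.approx(float(p))


class TestTailFunctions:
    def test_chisq_at_zero_is_one(self):
        assert chisq_upper_tail(0.0, 4) == 1.0

    def test_printed_pvalues_reproduced(self):
        assert round(chisq_upper_tail(14.230, 4), 3) == 0.007
        assert round(f_upper_tail(4.544, 3, 54), 3) == 0.007

    def test_chisq_closed_form_even_df(self):
        # for df=4 the tail has closed form exp(-x/2) * (1 + x/2)
        for x in (0.5, 3.0, 7.5462, 14.230):
            assert chisq_upper_tail(x, 4) == pytest.approx(
                np.exp(-x / 2) * (1 + x / 2), rel=1e-10
            )

    def test_monotone_nonincreasing(self):
        xs = np.linspace(0, 30, 100)
        chis = [chisq_upper_tail(x, 4) for x in xs]
        fs = [f_upper_tail(x, 3, 54) for x in xs]
        assert all(b <= a + 1e-15 for a, b in zip(chis, chis[1:]))
        assert all(b <= a + 1e-15 for a, b in zip(fs, fs[1:]))

    def test_f_approaches_chisq_for_large_df2(self):
        x = 2.5
        df1 = 3
        approx = f_upper_tail(x, df1, 10**7)
        assert approx == pytest.approx(chisq_upper_tail(df1 * x, df1), rel=1e-4)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chisq_upper_tail(-1.0, 4)
        with pytest.raises(ValueError):
            f_upper_tail(-1.0, 3, 54)


class TestBandNormalization:
    def test_percent_of_baseline(self):
        out = normalize_band_intensity([(0, 400.0), (12, 300.0), (24, 200.0)])
        assert [v for _, v in out] == pytest.approx([100.0, 75.0, 50.0])

    def test_flat_series_stays_at_hundred(self):
        out = normalize_band_intensity([(t, 250.0) for t in (0, 12, 24, 36, 48)])
        assert all(v == 100.0 for _, v in out)

    def test_halved_value(self):
        out = normalize_band_intensity([(0, 200.0), (12, 100.0)])
        assert out[1][1] == 50.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_band_intensity([(0, 0.0), (12, 10.0)])


def test_arcsine_transform_bounds():
    out = arcsine_sqrt([0.0, 0.25, 1.0])
    assert out == pytest.approx([0.0, np.arcsin(0.5), np.pi / 2])
    with pytest.raises(ValueError):
        arcsine_sqrt([1.2])
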