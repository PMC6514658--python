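"""Statistical layer: correlations, agreement, ANOVA/LSD letters, stepwise fits."""

import numpy as np
import pandas as pd
import pytest

from rgbpheno.models import (
    anova_lsd,
    correlate,
    level_agreement,
    simplify_model,
    stepwise_fit,
)


def _noise_frame(rng, n=192, p=10, prefix="x"):
    return pd.DataFrame(rng.normal(size=(n, p)),
                        columns=[f"{prefix}{i}" for i in range(p)])


class TestCorrelate:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=50)
        tab = correlate(pd.DataFrame({"x": x, "gy": x}), response="gy")
        row = tab.set_index("variable").loc["x"]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-20 and row["stars"] == "***"

    def test_constant_variable_warns_nan(self, rng):
        df = pd.DataFrame({"x": np.ones(30), "gy": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="constant"):
            tab = correlate(df, response="gy")
        assert np.isnan(tab["r"].iloc[0])

    def test_independent_gaussians_rarely_exceed_0p2(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({"x": r.normal(size=192), "gy": r.normal(size=192)})
            if abs(correlate(df, response="gy")["r"].iloc[0]) < 0.2:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_programmed_snr_recovered(self):
        """An index built as signal + noise recovers its design correlation."""
        target = 0.6
        rs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            gy = r.normal(size=192)
            x = target * gy + np.sqrt(1 - target**2) * r.normal(size=192)
            rs.append(correlate(pd.DataFrame({"x": x, "gy": gy}),
                                response="gy")["r"].iloc[0])
        assert np.mean(rs) == pytest.approx(target, abs=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate(pd.DataFrame({"x": [1.0, 2.0], "gy": [1.0, 2.0]}),
                      response="gy")


class TestLevelAgreement:
    def _frames(self, rng, n=60):
        ground = pd.DataFrame({
            "plot_id": [f"p{i}" for i in range(n)],
            "ga": rng.uniform(0, 1, n),
        })
        return ground

    def test_identical_levels(self, rng):
        ground = self._frames(rng)
        tab = level_agreement(ground, ground.copy())
        assert tab["r"].iloc[0] == pytest.approx(1.0)
        assert tab["anova_p"].iloc[0] > 0.9

    def test_constant_bias_detected_by_anova(self, rng):
        ground = self._frames(rng, n=192)
        uav = ground.copy()
        uav["ga"] = uav["ga"] + 0.3
        tab = level_agreement(ground, uav)
        assert tab["r"].iloc[0] == pytest.approx(1.0)
        assert tab["anova_p"].iloc[0] < 1e-6

    def test_attenuated_noisy_level_recovers_r(self):
        rs = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            g = r.uniform(0, 1, 192)
            target = 0.8
            u = target * (g - g.mean()) / g.std() + np.sqrt(1 - target**2) \
                * r.normal(size=192)
            ground = pd.DataFrame({"plot_id": range(192), "ga": g})
            uav = pd.DataFrame({"plot_id": range(192), "ga": u})
            rs.append(level_agreement(ground, uav)["r"].iloc[0])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.05)

    def test_unmatched_plots_listed(self, rng):
        ground = self._frames(rng)
        uav = ground.iloc[:-1].copy()
        with pytest.raises(ValueError, match="p59"):
            level_agreement(ground, uav)


class TestAnovaLsd:
    def test_identical_groups_share_letter(self, rng):
        v = rng.normal(size=10)
        tab = anova_lsd(np.concatenate([v, v]), ["a"] * 10 + ["b"] * 10)
        letters = tab.set_index("group")["letters"]
        assert letters["a"] == letters["b"]

    def test_separated_groups_all_distinct(self, rng):
        values, groups = [], []
        for i, mu in enumerate([0, 100, 200, 300]):
            values.extend(mu + rng.normal(0, 1, 8))
            groups.extend([f"g{i}"] * 8)
        tab = anova_lsd(values, groups)
        assert len(set(tab["letters"])) == 4
        assert all(len(l) == 1 for l in tab["letters"])

    def test_descending_mean_order_and_letter_a_on_top(self, rng):
        values = np.concatenate([rng.normal(10, 1, 8), rng.normal(0, 1, 8)])
        tab = anova_lsd(values, ["hi"] * 8 + ["lo"] * 8)
        assert list(tab["group"]) == ["hi", "lo"]
        assert tab["letters"].iloc[0] == "a"

    def test_null_groups_usually_share_a_letter(self):
        """Type-I behavior: 4 groups from one distribution mostly share a letter."""
        share = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            tab = anova_lsd(r.normal(size=40), np.repeat(list("abcd"), 10))
            common = set.intersection(*(set(l) for l in tab["letters"]))
            share += bool(common)
        assert share >= 0.6 * n_seeds

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd([1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError):
            anova_lsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestStepwise:
    def test_true_predictor_recovered_among_noise(self):
        found = 0
        n_seeds = 25
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df = _noise_frame(r)
            df["gy"] = 0.8 * df["x3"] + r.normal(scale=1.0, size=192)
            fit = stepwise_fit(df, response="gy", direction="forward")
            found += "x3" in fit.predictors
        assert found >= 0.95 * n_seeds

    def test_null_data_yields_low_r2(self):
        ok = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            df = _noise_frame(r)
            df["gy"] = r.normal(size=192)
            fit = stepwise_fit(df, response="gy", direction="forward")
            ok += fit.r2 < 0.15
        assert ok >= 0.9 * n_seeds

    def test_generative_r2_recovered(self):
        r2s = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            df = _noise_frame(r, p=5)
            signal = df[["x0", "x1"]].sum(axis=1)
            # var(signal)=2; choose noise for R^2 = 0.6
            noise_sd = np.sqrt(2 * (1 - 0.6) / 0.6)
            df["gy"] = signal + r.normal(scale=noise_sd, size=192)
            r2s.append(stepwise_fit(df, response="gy", direction="both").r2)
        assert np.mean(r2s) == pytest.approx(0.6, abs=0.08)

    def test_deterministic_given_fixed_table(self, rng):
        df = _noise_frame(rng)
        df["gy"] = df["x0"] - df["x5"] + rng.normal(size=192)
        f1 = stepwise_fit(df, response="gy", direction="both")
        f2 = stepwise_fit(df, response="gy", direction="both")
        assert f1.predictors == f2.predictors
        assert f1.aic == f2.aic

    def test_backward_prunes_to_signal(self, rng):
        df = _noise_frame(rng, p=6)
        df["gy"] = 1.5 * df["x1"] + rng.normal(scale=0.5, size=192)
        fit = stepwise_fit(df, response="gy", direction="backward")
        assert "x1" in fit.predictors

    def test_equation_string_mentions_terms(self, rng):
        df = _noise_frame(rng, p=3)
        df["gy"] = 2 * df["x0"] + rng.normal(scale=0.1, size=192)
        fit = stepwise_fit(df, response="gy")
        assert fit.equation().startswith("gy =")
        assert "x0" in fit.equation()
        assert fit.summary().attrs["r2"] == pytest.approx(fit.r2)

    def test_multivariate_beats_best_single_predictor(self, rng):
        """Complementary predictors: joint R2 exceeds any marginal r^2."""
        n = 192
        asi = rng.normal(size=n)
        index = rng.normal(size=n)
        gy = -0.6 * asi + 0.6 * index + rng.normal(scale=0.6, size=n)
        df = pd.DataFrame({"asi": asi, "index": index, "gy": gy})
        fit = stepwise_fit(df, response="gy", direction="forward")
        marginals = correlate(df, response="gy")
        assert fit.r2 > (marginals["r"] ** 2).max()


class TestSimplify:
    def test_insignificant_predictor_dropped(self, rng):
        df = _noise_frame(rng, p=2)
        df["gy"] = 2.0 * df["x0"] + rng.normal(scale=0.5, size=192)
        full = stepwise_fit(df, response="gy", direction="backward")
        if "x1" not in full.predictors:  # force the nonsignificant term in
            full.predictors.append("x1")
        simple = simplify_model(full, df)
        assert simple.predictors == ["x0"]
        assert simple.simplified

    def test_collinear_pair_keeps_stronger_marginal(self, rng):
        n = 300
        a = rng.normal(size=n)
        b = a + rng.normal(scale=0.05, size=n)  # |r(a,b)| ~ 0.999
        gy = a + rng.normal(scale=0.5, size=n)
        df = pd.DataFrame({"a": a, "b": b, "gy": gy})
        fit = stepwise_fit(df, response="gy", direction="backward")
        fit.predictors = ["a", "b"]
        simple = simplify_model(fit, df)
        assert simple.predictors == ["a"]

    def test_simplified_r2_never_exceeds_full(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            df = _noise_frame(r, p=8)
            df["gy"] = df["x0"] + 0.3 * df["x1"] + r.normal(size=192)
            full = stepwise_fit(df, response="gy", direction="forward")
            simple = simplify_model(full, df)
            assert simple.r2 <= full.r2 + 1e-12

    def test_all_dropped_returns_intercept_only(self, rng):
        df = _noise_frame(rng, p=3)
        df["gy"] = rng.normal(size=192)
        fit = stepwise_fit(df, response="gy", direction="backward")
        fit.predictors = ["x0", "x1"]
        with pytest.warns(UserWarning, match="intercept"):
            simple = simplify_model(fit, df)
        assert simple.predictors == []
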