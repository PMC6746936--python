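"""VIF filtering, exhaustive AIC ranking and rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dxafem.stats import aic_rank, spearman_rho, vif_filter


def _orthogonal_frame(n=24, p=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, p))
    a -= a.mean(axis=0)                      # center so correlations vanish
    q, _ = np.linalg.qr(a)
    return pd.DataFrame(q, columns=[f"v{i}" for i in range(p)])


class TestVIF:
    def test_orthogonal_predictors_all_unity(self):
        x = _orthogonal_frame()
        res = vif_filter(x)
        assert res.removed == []
        for v in res.vif.values():
            assert v == pytest.approx(1.0, abs=1e-8)

    def test_correlated_pair_formula(self):
        """Two predictors with sample correlation exactly 0.8: VIF = 2.778."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)      # b now orthogonal to a
        b /= b.std()
        x = pd.DataFrame({"a": a, "b": 0.8 * a + 0.6 * b})
        res = vif_filter(x, threshold=10.0)
        for v in res.vif.values():
            assert v == pytest.approx(1.0 / (1.0 - 0.64), rel=1e-9)

    def test_duplicated_column_removed(self):
        x = _orthogonal_frame(p=3)
        x["dup"] = x["v0"]
        with pytest.warns(UserWarning, match="collinear"):
            res = vif_filter(x)
        assert len(res.retained) == 3
        assert all(np.isfinite(v) for v in res.vif.values())

    def test_order_invariant_under_column_permutation(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(30, 5))
        base[:, 4] = base[:, 0] * 0.97 + rng.normal(size=30) * 0.05
        x = pd.DataFrame(base, columns=list("abcde"))
        r1 = vif_filter(x, threshold=5.0)
        r2 = vif_filter(x[list("edcba")], threshold=5.0)
        assert r1.retained == r2.retained


class TestAICRank:
    def test_single_predictor_weight_one(self):
        x = _orthogonal_frame(p=1)
        y = 2.0 * x["v0"].to_numpy() + 0.1
        res = aic_rank(x, y)
        assert len(res.models) == 1
        assert res.models["weight"].iloc[0] == pytest.approx(1.0)
        assert res.cumulative_weights["v0"] == pytest.approx(1.0)

    def test_delta_two_weight_split(self):
        """Two models with delta-AIC = 2 get weights 0.731 / 0.269."""
        w = np.exp([0.0, -1.0])
        w /= w.sum()
        assert w[0] == pytest.approx(0.731, abs=5e-4)
        assert w[1] == pytest.approx(0.269, abs=5e-4)

    def test_weights_sum_to_one(self, rng):
        x = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        y = rng.normal(size=25)
        res = aic_rank(x, y)
        assert res.models["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("p", [3, 4, 5])
    def test_matches_naive_normal_equation_oracle(self, p, rng):
        """Brute-force oracle: normal-equation fits, direct RSS, hand AIC."""
        n = 22
        x = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"v{i}" for i in range(p)]
        )
        y = rng.normal(size=n) + x.iloc[:, 0].to_numpy()
        res = aic_rank(x, y)

        xs = ((x - x.mean()) / x.std(ddof=1)).to_numpy()
        aics = []
        subsets = []
        for r in range(1, p + 1):
            for sub in itertools.combinations(range(p), r):
                a = np.column_stack([np.ones(n), xs[:, list(sub)]])
                beta = np.linalg.solve(a.T @ a, a.T @ y)
                rss = float(((y - a @ beta) ** 2).sum())
                aics.append(n * np.log(rss / n) + 2 * (len(sub) + 2))
                subsets.append(sub)
        aics = np.array(aics)
        w = np.exp(-(aics - aics.min()) / 2)
        w /= w.sum()
        cum = {
            f"v{j}": w[[j in s for s in subsets]].sum() for j in range(p)
        }
        for name, expected in cum.items():
            assert res.cumulative_weights[name] == pytest.approx(expected, abs=1e-8)

    def test_matches_statsmodels_rss_on_sampled_subsets(self, rng):
        import statsmodels.api as sm

        x = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        y = rng.normal(size=20)
        res = aic_rank(x, y)
        xs = (x - x.mean()) / x.std(ddof=1)
        for _, row in res.models.sample(5, random_state=0).iterrows():
            cols = list(row["subset"])
            fit = sm.OLS(y, sm.add_constant(xs[cols].to_numpy())).fit()
            assert row["rss"] == pytest.approx(fit.ssr, rel=1e-10)

    def test_too_many_predictors_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(40, 16)))
        x.columns = [f"v{i}" for i in range(16)]
        with pytest.raises(ValueError, match="pre-filter"):
            aic_rank(x, rng.normal(size=40))

    def test_known_drivers_rank_top_two(self):
        """Strong two-driver signal on a synthetic cohort: the drivers take
        the top two cumulative weights."""
        rng = np.random.default_rng(5)
        x = pd.DataFrame(
            rng.normal(size=(28, 8)), columns=[f"v{i}" for i in range(8)]
        )
        sig = 0.8 * x["v2"] + 0.8 * x["v5"]
        y = sig + rng.normal(scale=0.3 * sig.std(), size=28)
        res = aic_rank(x, y)
        assert set(res.cumulative_weights.index[:2]) == {"v2", "v5"}


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, _ = spearman_rho(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_hand_example(self):
        rho, _ = spearman_rho(np.array([1, 2, 3]), np.array([3, 1, 2]))
        assert rho == pytest.approx(-0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho(np.ones(5), np.arange(5.0))

    def test_permutation_p_close_to_t_approx(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        y = x + rng.normal(scale=0.8, size=15)
        rho_t, p_t = spearman_rho(x, y, method="t")
        rho_p, p_p = spearman_rho(x, y, method="permutation", rng=rng, n_perm=4000)
        assert rho_t == rho_p
        assert p_p == pytest.approx(p_t, abs=0.02)
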