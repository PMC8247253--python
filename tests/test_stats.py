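import numpy as np
import pandas as pd
import pytest

from fwlesion.phantom import simulate_outcome_table
from fwlesion.stats import (
    bonferroni,
    cohens_kappa,
    correlation_suite,
    logistic_cie,
    oneway_manova,
    paired_t,
    partial_correlation,
)


class TestPairedT:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        t, df, p = paired_t(x, x)
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_matches_closed_form(self):
        x = np.array([3.1, 2.8, 4.0, 3.3, 3.9])
        y = np.array([2.5, 2.9, 3.1, 3.0, 3.2])
        d = x - y
        oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, df, p = paired_t(x, y)
        assert t == pytest.approx(oracle, abs=1e-12)
        assert df == 4
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(oracle), 4), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        t1, _, p1 = paired_t(x, y)
        t2, _, p2 = paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_constant_nonzero_difference_flagged(self):
        t, _, p = paired_t(np.arange(4.0) + 1.0, np.arange(4.0))
        assert np.isinf(t) and 0 < p < 1e-300


class TestManova:
    def _toy(self, shift=(0.0, 0.5, 1.0, 1.5), n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, s in zip("abcd", shift):
            for _ in range(n):
                rows.append({"group": g, "m1": rng.normal(s), "m2": rng.normal(-s, 2)})
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_f(self):
        block = pd.DataFrame({"m1": [0.1, 0.5, 0.9], "m2": [1.0, 2.5, 2.0]})
        long = pd.concat(
            [block.assign(group=g) for g in "abcd"], ignore_index=True
        )
        rep = oneway_manova(long, ["m1", "m2"])
        assert np.allclose(rep.univariate["F"], 0.0)
        assert np.allclose(rep.univariate["eta2g"], 0.0)
        assert np.allclose(rep.univariate["p"], 1.0)

    def test_f_and_eta2g_match_sum_of_squares_oracle(self):
        long = self._toy()
        rep = oneway_manova(long, ["m1", "m2"])
        for metric in ("m1", "m2"):
            vals = long[metric].to_numpy()
            groups = long["group"].to_numpy()
            grand = vals.mean()
            ssb = sum(
                (groups == g).sum() * (vals[groups == g].mean() - grand) ** 2
                for g in "abcd"
            )
            ssw = sum(
                ((vals[groups == g] - vals[groups == g].mean()) ** 2).sum()
                for g in "abcd"
            )
            row = rep.univariate.set_index("metric").loc[metric]
            assert row["F"] == pytest.approx((ssb / 3) / (ssw / 20), abs=1e-10)
            assert row["eta2g"] == pytest.approx(ssb / (ssb + ssw), abs=1e-10)

    def test_pillai_matches_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        long = self._toy(seed=3)
        rep = oneway_manova(long, ["m1", "m2"])
        mv = MANOVA.from_formula("m1 + m2 ~ C(group)", data=long)
        tbl = mv.mv_test().results["C(group)"]["stat"]
        assert rep.pillai == pytest.approx(float(tbl.loc["Pillai's trace", "Value"]))

    def test_posthoc_bonferroni_multiplication(self):
        long = self._toy(seed=4)
        rep = oneway_manova(long, ["m1"])
        ph = rep.posthoc
        assert len(ph) == 6
        assert np.allclose(ph["p_bonferroni"], np.minimum(1.0, 6 * ph["p_raw"]))
        assert (ph["p_bonferroni"] >= ph["p_raw"] - 1e-15).all()

    def test_small_groups_rejected(self):
        long = pd.DataFrame({"group": ["a", "b", "b"], "m1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            oneway_manova(long, ["m1"])


class TestCorrelations:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        from scipy import stats as sps

        r, p = partial_correlation(x, y)
        ro, po = sps.pearsonr(x, y)
        assert r == pytest.approx(ro, abs=1e-12)
        assert p == pytest.approx(po, abs=1e-10)

    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 4))
        r, _ = partial_correlation(x[:, 0], x[:, 1], x[:, 2:])
        prec = np.linalg.inv(np.corrcoef(x.T))
        assert r == pytest.approx(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("xyzu"))
        r, p = partial_correlation(df["x"], df["y"], df[["z", "u"]].to_numpy())
        out = pingouin.partial_corr(df, x="x", y="y", covar=["z", "u"])
        assert r == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(out["p_val"].iloc[0]), abs=1e-8)

    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 20)
        r, p = partial_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-100

    def test_orthogonal_covariate_changes_nothing_but_df(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        z = rng.normal(size=50)
        # orthogonalize z against x and y in-sample
        basis = np.column_stack([np.ones(50), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        r0, _ = partial_correlation(x, y)
        r1, _ = partial_correlation(x, y, z[:, None])
        assert r1 == pytest.approx(r0, abs=1e-10)

    def test_constant_column_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(np.ones(10), np.arange(10.0))

    def test_suite_bonferroni_family(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=["a", "b", "c", "d"])
        out = correlation_suite(df, [("a", "b"), ("a", "c"), ("b", "d")])
        assert np.allclose(
            out["pearson_p_bonferroni"], np.minimum(1.0, 3 * out["pearson_p"])
        )


class TestLogisticCIE:
    def test_null_confounder_excluded(self):
        table = simulate_outcome_table(400, exposure_logodds=0.8, seed=6)
        rep = logistic_cie(table, "outcome", "exposure", ["noise"])
        assert rep.retained == []
        assert rep.final_or == pytest.approx(rep.crude_or)
        assert rep.ledger["pct_change"].iloc[0] < 10.0

    def test_built_in_confounder_retained(self):
        table = simulate_outcome_table(
            600, exposure_logodds=0.4, confounder_to_exposure=1.2,
            confounder_logodds=1.2, seed=7,
        )
        rep = logistic_cie(table, "outcome", "exposure", ["confounder", "noise"])
        assert "confounder" in rep.retained
        assert rep.ledger.set_index("candidate").loc["confounder", "pct_change"] >= 10.0
        assert rep.crude_ci[0] < rep.crude_or < rep.crude_ci[1]
        assert 0.0 <= rep.pseudo_r2 <= 1.0

    def test_or_matches_statsmodels_reference(self):
        import statsmodels.api as sm

        table = simulate_outcome_table(300, exposure_logodds=0.6, seed=8)
        rep = logistic_cie(table, "outcome", "exposure", [])
        x = sm.add_constant(table[["exposure"]].astype(float))
        ref = sm.Logit(table["outcome"].astype(float), x).fit(disp=0)
        assert rep.crude_or == pytest.approx(float(np.exp(ref.params["exposure"])), rel=1e-8)

    def test_single_class_outcome_rejected(self):
        table = simulate_outcome_table(50, exposure_logodds=0.0, seed=9)
        table["outcome"] = 1
        with pytest.raises(ValueError, match="single class"):
            logistic_cie(table, "outcome", "exposure", [])

    def test_separation_detected(self):
        n = 40
        x = np.concatenate([np.linspace(-2, -0.5, 20), np.linspace(0.5, 2, 20)])
        table = pd.DataFrame({"exposure": x, "outcome": (x > 0).astype(int)})
        with pytest.raises(ValueError, match="separation"):
            logistic_cie(table, "outcome", "exposure", [])


class TestCohensKappa:
    def test_perfect_agreement(self):
        r = np.array([0, 1, 0, 1, 1, 0])
        kappa, ci = cohens_kappa(r, r)
        assert kappa == pytest.approx(1.0)
        assert ci[1] <= 1.0

    def test_chance_agreement_is_zero(self):
        # constructed 2x2 table with p_obs = p_exp: independence at 50/50
        r1 = np.array([0, 0, 1, 1])
        r2 = np.array([0, 1, 0, 1])
        kappa, _ = cohens_kappa(r1, r2)
        assert kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(10)
        r1 = rng.integers(0, 2, 200)
        r2 = np.where(rng.random(200) < 0.85, r1, 1 - r1)
        kappa, _ = cohens_kappa(r1, r2)
        assert kappa == pytest.approx(sklearn_metrics.cohen_kappa_score(r1, r2), abs=1e-12)

    def test_hand_computed_table(self):
        # 2x2 table: a=20 both yes, d=50 both no, b=5, c=25 disagreements
        r1 = np.array([1] * 25 + [0] * 75)
        r2 = np.array([1] * 20 + [0] * 5 + [1] * 25 + [0] * 50)
        kappa, _ = cohens_kappa(r1, r2)
        p_obs = 0.70
        p_exp = 0.25 * 0.45 + 0.75 * 0.55
        assert kappa == pytest.approx((p_obs - p_exp) / (1 - p_exp), abs=1e-12)

    def test_degenerate_raters_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_kappa(np.ones(5, int), np.ones(5, int))


def test_bonferroni_clamps_at_one():
    adj = bonferroni([0.01, 0.3, 0.9], 6)
    assert np.allclose(adj, [0.06, 1.0, 1.0])
    assert (adj >= [0.01, 0.3, 0.9]).all()
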