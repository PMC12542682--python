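import numpy as np
import pandas as pd
import pytest

from conftest import random_table
from ecospart import nutrients as nt
from ecospart.containers import NUTRIENT_VARS, OtuTable
from ecospart.diversity import bray_curtis


def nutrient_frame(rows, index=None):
    idx = index or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx, columns=list(NUTRIENT_VARS))


class TestMncIndex:
    def test_column_standardization_closed_form(self):
        nut = nutrient_frame(np.tile([[2.0], [4.0], [6.0]], (1, 8)))
        res = nt.mnc_index(nut)
        assert res.standardized.iloc[:, 0].tolist() == [0.0, 0.5, 1.0]
        assert res.index.tolist() == [0.0, 0.5, 1.0]

    def test_sample_maximal_everywhere_scores_one(self, rng):
        vals = rng.random((5, 8))
        vals[2] = vals.max(axis=0) + 1.0
        res = nt.mnc_index(nutrient_frame(vals))
        assert res.index.iloc[2] == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        vals = nutrient_frame(rng.random((6, 8)))
        before = nt.mnc_index(vals).index
        vals2 = vals.copy()
        vals2["TN"] = vals2["TN"] * 37.5 + 4.0
        after = nt.mnc_index(vals2).index
        pd.testing.assert_series_equal(before, after, atol=1e-12)

    def test_constant_column_named_in_error(self, rng):
        vals = nutrient_frame(rng.random((4, 8)))
        vals["TP"] = 3.14
        with pytest.raises(ValueError, match="TP"):
            nt.mnc_index(vals)

    def test_index_bounded(self, rng):
        res = nt.mnc_index(nutrient_frame(rng.random((10, 8))))
        assert res.index.between(0, 1).all()
        assert np.allclose(res.standardized.min(), 0)
        assert np.allclose(res.standardized.max(), 1)


class TestBetaScalar:
    def test_lcbd_sums_to_one(self, rng):
        dm = bray_curtis(random_table(rng, 7, 9))
        lcbd = nt.beta_scalar(dm)
        assert lcbd.sum() == pytest.approx(1.0, abs=1e-9)

    def test_outlier_sample_dominates(self, rng):
        counts = np.full((5, 6), 50)
        counts += rng.integers(0, 3, size=counts.shape)
        counts[4] = [500, 0, 0, 0, 0, 0]
        t = OtuTable(counts, sample_ids=[f"s{i}" for i in range(5)],
                     otu_ids=[f"o{j}" for j in range(6)])
        lcbd = nt.beta_scalar(bray_curtis(t))
        assert lcbd.idxmax() == "s4"

    def test_identical_samples_undefined(self):
        t = OtuTable(np.full((4, 3), 7), sample_ids=list("abcd"),
                     otu_ids=list("xyz"))
        with pytest.raises(ValueError, match="identical"):
            nt.beta_scalar(bray_curtis(t))

    def test_mean_pairwise_mode(self, rng):
        dm = bray_curtis(random_table(rng, 5, 6))
        mp = nt.beta_scalar(dm, method="mean_pairwise")
        assert mp.iloc[0] == pytest.approx(dm.data[0, 1:].sum() / 4)


class TestOlsBnc:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = nt.ols_bnc(2 * x, x)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError):
            nt.ols_bnc(np.arange(5.0), np.ones(5))


class TestRfRank:
    def test_planted_predictors_recovered(self, rng):
        counts = rng.integers(1, 200, size=(40, 25))
        t = OtuTable(counts, sample_ids=[f"s{i}" for i in range(40)],
                     otu_ids=[f"o{j}" for j in range(25)])
        rel = counts / counts.sum(axis=1, keepdims=True)
        y = 30 * rel[:, 0] + 25 * rel[:, 1] + 20 * rel[:, 2] \
            + rng.normal(0, 0.03, 40)
        rk = nt.rf_rank(t, y, n_iter=10, cv_folds=5, cv_repeats=1,
                        top_k=10, seed=0, n_estimators=60, mda_forests=5)
        top10_gini = set(rk.top_by_gini[:10])
        top10_mda = set(rk.top_by_mda[:10])
        assert {"o0", "o1", "o2"} <= top10_gini
        assert {"o0", "o1", "o2"} <= top10_mda

    def test_same_seed_identical_ranking(self, rng):
        t = random_table(rng, 20, 15)
        y = np.random.default_rng(5).random(20)
        a = nt.rf_rank(t, y, n_iter=3, cv_folds=4, cv_repeats=1, top_k=5,
                       seed=7, n_estimators=30, mda_forests=2)
        b = nt.rf_rank(t, y, n_iter=3, cv_folds=4, cv_repeats=1, top_k=5,
                       seed=7, n_estimators=30, mda_forests=2)
        assert a.top_by_gini == b.top_by_gini
        pd.testing.assert_frame_equal(a.importances, b.importances)

    def test_top_k_capped(self, rng):
        t = random_table(rng, 12, 6)
        rk = nt.rf_rank(t, np.arange(12.0), n_iter=2, cv_folds=3,
                        cv_repeats=1, top_k=50, seed=1, n_estimators=20,
                        mda_forests=1)
        assert len(rk.top_by_gini) == 6


class TestBncPower:
    def test_coupled_nutrients_give_significant_specialist_regression(
            self, battery50):
        """With coupling 0.8, MNC ~ specialist β-diversity is significant
        (p < 0.05) in at least 90% of 50 survey replicates, while the
        generalist regression stays non-significant in most."""
        sig_spec = (battery50.bnc_p_specialist < 0.05).mean()
        sig_gen = (battery50.bnc_p_generalist >= 0.05).mean()
        assert sig_spec >= 0.9
        assert sig_gen >= 0.8

    def test_uncoupled_nutrients_are_calibrated(self):
        """With coupling 0, the permutation p of |corr(MNC, specialist β)|
        is uniform across simulation seeds."""
        import scipy.stats
        from ecospart import diversity as dv
        from ecospart.synthetic import (simulate_metacommunity,
                                        simulate_nutrients)
        pvals = []
        for s in range(60):
            table, _, _, truth = simulate_metacommunity(
                n_sites=10, n_otus=120, depth=15_000, seed=3000 + s)
            m = simulate_nutrients(table, truth, coupling=0.0, seed=4000 + s)
            mnc = nt.mnc_index(m.nutrients).index.to_numpy()
            sub = table.select_otus(truth.otus_of("specialist")) \
                .drop_empty_otus()
            beta = nt.beta_scalar(
                dv.bray_curtis(sub, relative=True)).to_numpy()
            r_obs = abs(np.corrcoef(mnc, beta)[0, 1])
            rng = np.random.default_rng(5000 + s)
            hits = sum(
                abs(np.corrcoef(rng.permutation(mnc), beta)[0, 1]) >= r_obs
                for _ in range(99))
            pvals.append((1 + hits) / 100)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        assert (np.array(pvals) < 0.05).mean() <= 0.15


def chain_data(n=500, b1=0.8, b2=0.7, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = b1 * x + np.sqrt(1 - b1**2) * rng.normal(size=n)
    y = b2 * m + np.sqrt(1 - b2**2) * rng.normal(size=n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


def chain_path():
    pm = pd.DataFrame(False, index=["X", "M", "Y"], columns=["X", "M", "Y"])
    pm.loc["M", "X"] = True
    pm.loc["Y", "M"] = True
    return pm


class TestPlsPm:
    def test_single_indicator_chain_recovers_standardized_betas(self):
        data = chain_data()
        res = nt.plspm(data, {"X": ["x"], "M": ["m"], "Y": ["y"]},
                       chain_path(), n_boot=0, bootstrap=False, seed=0)
        z = (data - data.mean()) / data.std(ddof=0)
        beta_mx = float(np.polyfit(z["x"], z["m"], 1)[0])
        beta_ym = float(np.polyfit(z["m"], z["y"], 1)[0])
        assert res.paths.loc["M", "X"] == pytest.approx(beta_mx, abs=1e-9)
        assert res.paths.loc["Y", "M"] == pytest.approx(beta_ym, abs=1e-9)

    def test_chain_parameter_recovery_and_total_effect(self):
        res = nt.plspm(chain_data(), {"X": ["x"], "M": ["m"], "Y": ["y"]},
                       chain_path(), n_boot=0, bootstrap=False, seed=0)
        assert res.paths.loc["M", "X"] == pytest.approx(0.8, abs=0.05)
        assert res.paths.loc["Y", "M"] == pytest.approx(0.7, abs=0.05)
        assert res.total_effects.loc["Y", "X"] == pytest.approx(
            res.paths.loc["M", "X"] * res.paths.loc["Y", "M"], abs=1e-9)

    def test_gof_formula_identity(self):
        res = nt.plspm(chain_data(), {"X": ["x"], "M": ["m"], "Y": ["y"]},
                       chain_path(), n_boot=0, bootstrap=False, seed=0)
        hand = np.sqrt(res.communalities.mean() * res.r2.mean())
        assert res.gof == pytest.approx(hand, abs=1e-9)

    def test_multi_indicator_block_loads_positively(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=300)
        data = pd.DataFrame({
            "x1": latent + 0.4 * rng.normal(size=300),
            "x2": latent + 0.4 * rng.normal(size=300),
            "y": 0.6 * latent + 0.8 * rng.normal(size=300),
        })
        pm = pd.DataFrame(False, index=["X", "Y"], columns=["X", "Y"])
        pm.loc["Y", "X"] = True
        res = nt.plspm(data, {"X": ["x1", "x2"], "Y": ["y"]}, pm,
                       n_boot=100, seed=4)
        assert (res.loadings["X"] > 0.8).all()
        assert res.paths.loc["Y", "X"] > 0.4
        assert res.boot_ci.loc[("Y", "X"), "significant"]

    def test_cyclic_path_matrix_rejected(self):
        pm = chain_path()
        pm.loc["X", "Y"] = True
        with pytest.raises(ValueError, match="lower-triangular"):
            nt.plspm(chain_data(), {"X": ["x"], "M": ["m"], "Y": ["y"]}, pm)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            nt.plspm(chain_data(), {"X": ["x", "m"], "M": ["m"], "Y": ["y"]},
                     chain_path())
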