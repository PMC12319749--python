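import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from caudconn import stats, synthgen
from caudconn.stats import (
    ModelSpec,
    fit_linear_model,
    fit_mixed_model,
    holm_correct,
    lrt_select,
    mediate_bca,
    pca_composite,
)


class TestLinearModel:
    def test_identity_fit(self):
        df = pd.DataFrame({"y": np.arange(10.0)})
        df["x"] = df["y"]
        tidy, res = fit_linear_model(df, ModelSpec("y", ["x"]))
        assert tidy.set_index("term").loc["x", "estimate"] == pytest.approx(1.0)
        assert res.rsquared == pytest.approx(1.0)

    def test_planted_coefficient_recovered(self):
        rng = np.random.default_rng(0)
        n = 2000
        age = rng.standard_normal(n)
        y = -0.3 * age + rng.standard_normal(n) * np.sqrt(1 - 0.09)
        df = pd.DataFrame({"y": y, "age": age})
        tidy, _ = fit_linear_model(df, ModelSpec("y", ["age"], standardize=True))
        assert tidy.set_index("term").loc["age", "estimate"] == pytest.approx(
            -0.3, abs=0.03
        )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((50, 3)), columns=["y", "a", "b"])
        t1, _ = fit_linear_model(df, ModelSpec("y", ["a", "b"]))
        t2, _ = fit_linear_model(
            df.sample(frac=1, random_state=2), ModelSpec("y", ["a", "b"])
        )
        assert np.allclose(t1["estimate"], t2["estimate"])

    def test_missing_column_reported(self):
        with pytest.raises(KeyError, match="missing"):
            fit_linear_model(pd.DataFrame({"y": [1.0, 2.0]}), ModelSpec("y", ["x"]))


class TestMixedModel:
    def _long(self, re_sd, n_subj=100, n_rep=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            u = rng.normal(0, re_sd)
            x = rng.standard_normal(n_rep)
            y = 0.5 * x + u + rng.standard_normal(n_rep)
            for xi, yi in zip(x, y):
                rows.append({"subject": f"S{s}", "x": xi, "y": yi})
        return pd.DataFrame(rows)

    def test_degenerate_random_effect_matches_ols(self):
        df = self._long(re_sd=0.0)
        tidy_me, _ = fit_mixed_model(df, ModelSpec("y", ["x"], random_intercept="subject"))
        tidy_ols, _ = fit_linear_model(df, ModelSpec("y", ["x"]))
        est_me = tidy_me.set_index("term").loc["x", "estimate"]
        est_ols = tidy_ols.set_index("term").loc["x", "estimate"]
        assert est_me == pytest.approx(est_ols, abs=1e-3)

    def test_variance_components_recovered(self):
        df = self._long(re_sd=1.0, n_subj=200, seed=3)
        _, res = fit_mixed_model(df, ModelSpec("y", ["x"], random_intercept="subject"))
        assert float(res.cov_re.iloc[0, 0]) == pytest.approx(1.0, rel=0.15)
        assert float(res.scale) == pytest.approx(1.0, rel=0.15)


class TestLrtSelect:
    def _fits(self, effect, n=180, seed=0):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.standard_normal((2, n))
        y = 0.5 * x1 + effect * x2 + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        return smf.ols("y ~ x1", df).fit(), smf.ols("y ~ x1 + x2", df).fit()

    def test_identical_models_keep_nothing(self):
        nested, _ = self._fits(0.0)
        out = lrt_select(nested, nested)
        assert out["stat"] == 0.0 and not out["keep_full"]

    def test_strong_effect_retained(self):
        nested, full = self._fits(0.8)
        out = lrt_select(nested, full)
        assert out["keep_full"] and out["df"] == 1

    def test_non_nested_rejected(self):
        nested, full = self._fits(0.0)
        with pytest.raises(ValueError, match="nested"):
            lrt_select(full, nested)


class TestMediation:
    def _data(self, a=-0.5, b=0.4, cp=-0.2, n=400, seed=0, noise=1.0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        m = a * x + noise * rng.standard_normal(n)
        y = cp * x + b * m + noise * rng.standard_normal(n)
        return pd.DataFrame({"x": x, "m": m, "y": y})

    def test_effect_decomposition_identity(self):
        # indirect + direct equals the total-effect regression coefficient
        res = mediate_bca(self._data(), "x", "m", "y", n_boot=1000, seed=1,
                          standardize=False)
        total_fit = smf.ols("y ~ x", self._data()).fit()
        assert res.indirect + res.c_prime == pytest.approx(res.total, abs=1e-8)
        assert res.total == pytest.approx(total_fit.params["x"], abs=1e-8)

    def test_planted_paths_recovered_with_ci(self):
        df = self._data(n=2000, seed=2, noise=0.3)
        res = mediate_bca(df, "x", "m", "y", n_boot=1000, seed=3, standardize=False)
        assert res.indirect == pytest.approx(-0.2, abs=0.02)
        assert res.prop_mediated == pytest.approx(0.5, abs=0.05)
        lo, hi = res.ci["indirect"]
        assert lo <= res.indirect <= hi
        assert hi < 0  # CI excludes zero for a strong planted effect

    def test_null_predictor_covers_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.standard_normal((300, 3)), columns=["x", "m", "y"])
        res = mediate_bca(df, "x", "m", "y", n_boot=1000, seed=108, standardize=False)
        for key in ("indirect", "direct", "total"):
            lo, hi = res.ci[key]
            assert lo <= 0 <= hi
            assert abs(getattr(res, key if key != "direct" else "c_prime")) < 0.15

    def test_bca_reduces_to_percentile_when_uncorrected(self):
        rng = np.random.default_rng(7)
        boot = rng.standard_normal(20001)
        jack = np.zeros(100)  # zero acceleration
        theta = float(np.median(boot))  # z0 ~ 0
        (lo, hi), z0, acc = stats._bca_interval(boot, theta, jack, alpha=0.05)
        assert abs(z0) < 0.01 and acc == 0.0
        assert lo == pytest.approx(np.quantile(boot, 0.025), abs=0.02)
        assert hi == pytest.approx(np.quantile(boot, 0.975), abs=0.02)

    def test_guards(self):
        df = self._data()
        with pytest.raises(ValueError, match="seed"):
            mediate_bca(df, "x", "m", "y")
        with pytest.raises(ValueError, match="n_boot"):
            mediate_bca(df, "x", "m", "y", n_boot=10, seed=1)


class TestPcaComposite:
    def test_rank_one_table(self):
        rng = np.random.default_rng(0)
        latent = rng.standard_normal(100)
        df = pd.DataFrame({f"t{j}": (j + 1.0) * latent for j in range(6)})
        res = pca_composite(df)
        assert res.share == pytest.approx(1.0)
        assert np.allclose(np.abs(res.loadings), 1 / np.sqrt(6))
        assert res.loadings.mean() > 0

    def test_independent_columns_share_near_one_sixth(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((4000, 6)), columns=list("abcdef"))
        res = pca_composite(df)
        assert res.share == pytest.approx(1 / 6, abs=0.02)

    def test_matches_brute_force_eigensolve(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((60, 6)) @ rng.standard_normal((6, 6)),
                          columns=list("abcdef"))
        res = pca_composite(df)
        z = (df - df.mean()) / df.std(ddof=1)
        corr = z.T @ z / (len(df) - 1)
        vals, vecs = np.linalg.eigh(corr.to_numpy())
        assert res.share == pytest.approx(vals[-1] / 6, abs=1e-10)
        v = vecs[:, -1] * np.sign(vecs[:, -1].mean())
        assert np.allclose(np.abs(res.loadings), np.abs(v), atol=1e-10)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            pca_composite(df)


class TestHolm:
    def test_single_p_unchanged(self):
        adj, rej = holm_correct([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_stepped_example(self):
        adj, rej = holm_correct([0.01, 0.04])
        assert np.allclose(adj, [0.02, 0.04])
        assert rej.all()

    def test_all_ones(self):
        adj, rej = holm_correct([1.0, 1.0, 1.0])
        assert np.allclose(adj, 1.0) and not rej.any()

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_between_bonferroni_and_unadjusted(self, ps):
        adj, rej = holm_correct(ps, alpha=0.05)
        bonf = multipletests(ps, alpha=0.05, method="bonferroni")[1] < 0.05
        raw = np.asarray(ps) < 0.05
        assert np.all(rej >= bonf)  # Holm rejects a superset of Bonferroni
        assert np.all(rej <= raw)  # and a subset of unadjusted

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.2])


class TestModelBattery:
    @pytest.fixture(scope="class")
    def cohort(self):
        subjects = synthgen.generate_subject_table(n=150, seed=55)
        subjects = synthgen.generate_behavior(subjects, seed=56)
        # measured connectivity: planted differentiation plus measurement
        # noise, split into per-target z values (battery-level check only;
        # the full BOLD route is exercised in the acceptance tests)
        rng = np.random.default_rng(57)
        rows = []
        for _, s in subjects.iterrows():
            for cond, d in [
                ("rest", s["diff_rest_true"]),
                ("1-back", s["diff_task_true"]),
                ("2-back", s["diff_task_true"] + 0.03),
                ("3-back", s["diff_task_true"] + 0.06),
            ]:
                zf = 0.35 + d / 2 + rng.normal(0, 0.03)
                zd = 0.35 - d / 2 + rng.normal(0, 0.03)
                rows.append(
                    {"subject_id": s["subject_id"], "condition": cond,
                     "z_fpn": zf, "z_dmn": zd, "differentiation": zf - zd,
                     "n_volumes_used": 90}
                )
        return pd.DataFrame(rows), subjects

    def test_battery_recovers_planted_structure(self, cohort):
        records, subjects = cohort
        bundle = stats.run_paper_models(records, subjects, n_boot=1000, seed=9)
        assert bundle["rest_lme_lrt"]["keep_full"]  # age x target interaction
        rest_diff = bundle["rest_diff_model"].set_index("term")
        assert rest_diff.loc["bp_caudate", "estimate"] > 0
        med = bundle["mediation_rest"]
        assert med.indirect < 0
        assert med.ci["indirect"][1] < 0
        assert 0.5 < bundle["memory_composite"].share < 0.7
        assert "posthoc_holm" in bundle

    def test_battery_deterministic(self, cohort):
        records, subjects = cohort
        b1 = stats.run_paper_models(records, subjects, n_boot=1000, seed=9)
        b2 = stats.run_paper_models(records, subjects, n_boot=1000, seed=9)
        pd.testing.assert_frame_equal(b1["rest_lme"], b2["rest_lme"])
        assert b1["mediation_rest"].ci == b2["mediation_rest"].ci

    def test_global_null_keeps_no_interaction(self):
        null_paths = synthgen.MediationPaths(0.0, 0.0, 0.0)
        subjects = synthgen.generate_subject_table(
            n=80, seed=60, mediation_rest=null_paths, mediation_task=null_paths,
            diff_rest_mean=0.0, diff_task_mean=0.0,
        )
        subjects = synthgen.generate_behavior(subjects, link=0.0, seed=61)
        rng = np.random.default_rng(62)
        rows = []
        for _, s in subjects.iterrows():
            for cond in ("rest", "1-back", "2-back", "3-back"):
                zf = 0.35 + rng.normal(0, 0.05)
                zd = 0.35 + rng.normal(0, 0.05)
                rows.append(
                    {"subject_id": s["subject_id"], "condition": cond,
                     "z_fpn": zf, "z_dmn": zd, "differentiation": zf - zd,
                     "n_volumes_used": 90}
                )
        bundle = stats.run_paper_models(pd.DataFrame(rows), subjects, n_boot=1000, seed=63)
        med = bundle["mediation_rest"]
        lo, hi = med.ci["indirect"]
        assert lo <= 0 <= hi
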