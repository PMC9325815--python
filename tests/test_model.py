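import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from selresp.markers import KinshipMatrix
from selresp.model import ConvergenceError, MixedModel, RandomTerm, Residual
from .conftest import make_markers


def one_way_data(q=40, nrep=5, s2g=3.0, s2e=2.0, mu=10.0, seed=1):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), q)
    y = mu + np.repeat(g, nrep) + rng.normal(0, np.sqrt(s2e), q * nrep)
    return pd.DataFrame({"entry": np.repeat([f"e{i:02d}" for i in range(q)], nrep),
                         "y": y})


class TestSolvePlugIn:
    def test_balanced_shrinkage_closed_form(self):
        q, nrep, s2g, s2e = 40, 5, 3.0, 2.0
        df = one_way_data(q, nrep, s2g, s2e)
        res = MixedModel(df, "y", random=[RandomTerm("entry")]).solve(
            {"entry": s2g, "residual": s2e})
        lam = nrep * s2g / (nrep * s2g + s2e)
        ybar = df.groupby("entry")["y"].mean().to_numpy()
        np.testing.assert_allclose(res.blups("entry").to_numpy(),
                                   lam * (ybar - ybar.mean()), atol=1e-8)
        # exact PEV diagonal including the grand-mean adjustment
        base = s2g * s2e / (nrep * s2g + s2e)
        cdiag = base + (s2g - base) / q
        np.testing.assert_allclose(
            np.diag(res.prediction_error_matrix("entry")), cdiag, atol=1e-8)

    def test_large_variance_limit_recovers_gls_deviations(self):
        df = one_way_data(20, 4)
        res = MixedModel(df, "y", random=[RandomTerm("entry")]).solve(
            {"entry": 1e8, "residual": 2.0})
        ybar = df.groupby("entry")["y"].mean().to_numpy()
        np.testing.assert_allclose(res.blups("entry").to_numpy(),
                                   ybar - ybar.mean(), atol=1e-5)

    def test_normal_equations_residual_small(self):
        df = one_way_data(15, 3)
        res = MixedModel(df, "y", random=[RandomTerm("entry")]).solve(
            {"entry": 1.0, "residual": 1.0})
        assert res.mme_residual() < 1e-8

    def test_no_random_terms_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"f": np.repeat(list("abc"), 7),
                           "y": rng.normal(10, 1, 21)})
        res = MixedModel(df, "y", fixed=["f"]).solve({"residual": 1.0})
        X = np.column_stack([np.ones(21), (df.f == "b").astype(float),
                             (df.f == "c").astype(float)])
        beta = np.linalg.lstsq(X, df.y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(res.fe_params.to_numpy(), beta, atol=1e-9)

    def test_rerun_reproduces_fit_solution(self):
        """Re-solving at the fitted components changes nothing."""
        df = one_way_data(25, 4)
        model = MixedModel(df, "y", random=[RandomTerm("entry")])
        fit = model.fit()
        rerun = model.solve(dict(zip(fit.vc.names, fit.vc.values)))
        np.testing.assert_allclose(rerun.blups("entry").to_numpy(),
                                   fit.blups("entry").to_numpy(), atol=1e-10)
        np.testing.assert_allclose(rerun.fe_params.to_numpy(),
                                   fit.fe_params.to_numpy(), atol=1e-10)


class TestREML:
    def test_balanced_one_way_matches_anova_estimators(self):
        q, nrep = 40, 5
        df = one_way_data(q, nrep, seed=3)
        fit = MixedModel(df, "y", random=[RandomTerm("entry")]).fit(tol=1e-10)
        ybar = df.groupby("entry")["y"].mean().to_numpy()
        msb = nrep * ybar.var(ddof=1)
        msw = df.groupby("entry")["y"].var(ddof=1).mean()
        assert fit.vc["entry"] == pytest.approx((msb - msw) / nrep, rel=1e-5)
        assert fit.vc["residual"] == pytest.approx(msw, rel=1e-5)

    def test_single_component_recovery_within_three_se(self):
        df = one_way_data(q=150, nrep=4, s2g=4.0, s2e=1.0, seed=4)
        fit = MixedModel(df, "y", random=[RandomTerm("entry")]).fit()
        se = fit.vc.as_frame().loc["entry", "se"]
        assert abs(fit.vc["entry"] - 4.0) < 3 * se

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        df = one_way_data(q=30, nrep=4, seed=5)
        ours = MixedModel(df, "y", random=[RandomTerm("entry")]).fit(tol=1e-10)
        md = sm.MixedLM(df["y"], np.ones((len(df), 1)), groups=df["entry"])
        ref = md.fit(reml=True)
        assert ours.vc["entry"] == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                                 rel=1e-4)
        assert ours.vc["residual"] == pytest.approx(float(ref.scale), rel=1e-4)

    def test_matches_lme4_crossed_random_effects(self, tmp_path):
        rng = np.random.default_rng(6)
        a = np.repeat(np.arange(12), 12)
        b = np.tile(np.arange(12), 12)
        y = (5 + rng.normal(0, 1.3, 12)[a] + rng.normal(0, 0.8, 12)[b]
             + rng.normal(0, 1.0, 144))
        df = pd.DataFrame({"fa": [f"a{i}" for i in a],
                           "fb": [f"b{i}" for i in b], "y": y})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ (1|fa) + (1|fb), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(vc$vcov[vc$grp=="fa"], vc$vcov[vc$grp=="fb"],
                vc$vcov[vc$grp=="Residual"], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        va, vb, ve = map(float, out.stdout.split())
        fit = MixedModel(df, "y", random=[RandomTerm("fa"), RandomTerm("fb")]
                         ).fit(tol=1e-10)
        assert fit.vc["fa"] == pytest.approx(va, rel=1e-3, abs=1e-6)
        assert fit.vc["fb"] == pytest.approx(vb, rel=1e-3, abs=1e-6)
        assert fit.vc["residual"] == pytest.approx(ve, rel=1e-3)

    def test_fixed_component_returned_unchanged(self):
        df = one_way_data(20, 3, seed=7)
        fit = MixedModel(df, "y", random=[RandomTerm("entry")]).fit(
            fix={"entry": 1.0})
        assert fit.vc["entry"] == 1.0
        assert "entry" in fit.vc.fixed
        assert np.isnan(fit.vc.as_frame().loc["entry", "se"])

    def test_rescaling_response_scales_components(self):
        df = one_way_data(25, 4, seed=8)
        fit1 = MixedModel(df, "y", random=[RandomTerm("entry")]).fit(tol=1e-10)
        df2 = df.assign(y=df.y * 10.0)
        fit2 = MixedModel(df2, "y", random=[RandomTerm("entry")]).fit(tol=1e-10)
        assert fit2.vc["entry"] == pytest.approx(100 * fit1.vc["entry"], rel=1e-4)
        assert fit2.vc["residual"] == pytest.approx(100 * fit1.vc["residual"],
                                                    rel=1e-4)

    def test_heterogeneous_residual_groups(self):
        rng = np.random.default_rng(9)
        n = 600
        grp = np.repeat(["a", "b"], n // 2)
        sd = np.where(grp == "a", 1.0, 3.0)
        f = np.tile(np.arange(20), n // 20)
        df = pd.DataFrame({"grp": grp, "f": [f"f{i}" for i in f],
                           "y": rng.normal(0, 1.0, 20)[f] + rng.normal(0, sd)})
        fit = MixedModel(df, "y", random=[RandomTerm("f")],
                         residual=Residual(groups="grp")).fit()
        assert fit.vc["residual[a]"] < fit.vc["residual[b]"]
        assert fit.vc["residual[b]"] == pytest.approx(9.0, rel=0.35)

    def test_boundary_component_flagged(self):
        # no entry signal at all -> variance pinned at zero boundary
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"entry": np.repeat([f"e{i}" for i in range(30)], 4),
                           "y": rng.normal(0, 1, 120)})
        fit = MixedModel(df, "y", random=[RandomTerm("entry")]).fit()
        assert fit.vc["entry"] <= 1e-6
        assert "entry" in fit.vc.boundary


class TestKinshipStructures:
    def test_blups_invariant_to_kinship_scaling(self, small_kinship):
        """Rescaling K is absorbed by the re-estimated variance; BLUPs agree."""
        rng = np.random.default_rng(11)
        K = small_kinship
        L = K.factor()
        g = L @ rng.normal(size=L.shape[1]) * np.sqrt(2.0)
        df = pd.DataFrame({
            "entry": np.tile(K.entry_ids, 4),
            "y": np.tile(g, 4) + rng.normal(0, 1.0, 4 * K.n)})
        fit1 = MixedModel(df, "y", random=[RandomTerm("entry", kinship=K,
                                                      name="g")]).fit(tol=1e-10)
        K2 = KinshipMatrix(K.entry_ids, K.values * 3.0)
        fit2 = MixedModel(df, "y", random=[RandomTerm("entry", kinship=K2,
                                                      name="g")]).fit(tol=1e-10)
        assert fit2.vc["g"] == pytest.approx(fit1.vc["g"] / 3.0, rel=1e-3)
        np.testing.assert_allclose(fit2.blups("g").to_numpy(),
                                   fit1.blups("g").to_numpy(), atol=1e-5)

    def test_singular_kinship_handled_by_factorization(self):
        # rank-deficient K (more entries than markers) still solves
        mk = make_markers(20, 8, seed=12)
        from selresp.markers import vanraden_kinship
        K = vanraden_kinship(mk)
        assert np.linalg.matrix_rank(K.values) < K.n
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"entry": np.tile(K.entry_ids, 3),
                           "y": rng.normal(0, 1, 3 * K.n)})
        res = MixedModel(df, "y", random=[RandomTerm("entry", kinship=K,
                                                     name="g")]).solve(
            {"g": 2.0, "residual": 1.0})
        C = res.prediction_error_matrix("g").to_numpy()
        # 0 <= diag(C) <= diag(K sigma2_g)
        assert (np.diag(C) >= -1e-10).all()
        assert (np.diag(C) <= 2.0 * np.diag(K.values) + 1e-8).all()

    def test_aliased_fixed_columns_dropped_deterministically(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"f1": np.repeat(["a", "b"], 10),
                           "f2": np.repeat(["x", "y"], 10),  # aliased with f1
                           "y": rng.normal(size=20)})
        model = MixedModel(df, "y", fixed=["f1", "f2"])
        assert model.dropped_fixed == ["f2[y]"]

    def test_unconditional_variance_identity(self, small_kinship):
        """Over repeated data simulations, var(ghat) equals D - C elementwise
        (the joint-distribution identity the selection simulation rests on)."""
        K = small_kinship
        s2g, s2e = 2.0, 1.5
        nrep = 3
        rng = np.random.default_rng(14)
        df = pd.DataFrame({"entry": np.tile(K.entry_ids, nrep),
                           "y": np.zeros(nrep * K.n)})
        model = MixedModel(df, "y", random=[RandomTerm("entry", kinship=K,
                                                       name="g")])
        res = model.solve({"g": s2g, "residual": s2e})
        C = res.prediction_error_matrix("g").to_numpy()
        D = K.values * s2g
        M = D - C
        # linear map y -> ghat, then Monte Carlo over datasets in one matmul
        blk = model.term_blocks["g"][0]
        cinv = res._ev.cinv
        T = blk.L @ (cinv[blk.sl, :] @ (model.W.T / s2e))
        S = 4000
        L = K.factor()
        G = L @ rng.standard_normal((L.shape[1], S)) * np.sqrt(s2g)
        Y = np.tile(G, (nrep, 1)) + rng.standard_normal((nrep * K.n, S)) * np.sqrt(s2e)
        ghat = T @ Y
        emp = ghat @ ghat.T / S
        mc_se = np.sqrt((np.outer(np.diag(M), np.diag(M)) + M**2) / S)
        assert np.all(np.abs(emp - M) < 5 * mc_se + 1e-3)


class TestErrors:
    def test_empty_data_rejected(self):
        df = pd.DataFrame({"entry": [], "y": []})
        with pytest.raises(ValueError):
            MixedModel(df, "y", random=[RandomTerm("entry")])

    def test_unknown_fix_component(self):
        df = one_way_data(10, 2)
        with pytest.raises(KeyError):
            MixedModel(df, "y", random=[RandomTerm("entry")]).fit(
                fix={"nope": 1.0})

    def test_solve_requires_all_components(self):
        df = one_way_data(10, 2)
        with pytest.raises(KeyError):
            MixedModel(df, "y", random=[RandomTerm("entry")]).solve(
                {"entry": 1.0})

    def test_entries_missing_from_kinship_rejected(self, small_kinship):
        df = pd.DataFrame({"entry": ["nope1", "nope2"], "y": [1.0, 2.0]})
        with pytest.raises(KeyError, match="absent from kinship"):
            MixedModel(df, "y", random=[RandomTerm("entry",
                                                   kinship=small_kinship)])

    def test_summary_renders(self):
        fit = MixedModel(one_way_data(10, 3), "y",
                         random=[RandomTerm("entry")]).fit()
        text = fit.summary()
        assert "Variance components" in text and "REML" in text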