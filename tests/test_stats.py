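"""Inferential layer: BH-FDR, Spearman, mixed models, stepwise, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from betadesync.stats import (
    ModelSpec,
    bh_fdr,
    fit_model,
    pairwise_contrasts,
    select_family,
    spearman,
    stepwise_backward,
)


def bh_bruteforce(p, q):
    """Literal step-up definition: reject H_(i) for i <= k,
    k = max{i : p_(i) <= i q / m}."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestBhFdr:
    def test_all_rejected_example(self):
        reject, adj = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()
        assert np.all(adj <= 0.05)

    def test_none_rejected(self):
        reject, adj = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_only_smallest_rejected(self):
        reject, _ = bh_fdr([0.001, 0.8, 0.9], q=0.05)
        assert reject.tolist() == [True, False, False]

    def test_adjusted_monotone_and_dominating(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        _, adj = bh_fdr(p, q=0.05)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10),
        st.floats(0.01, 0.2),
    )
    def test_matches_bruteforce_stepup(self, p, q):
        reject, _ = bh_fdr(p, q=q)
        assert reject.tolist() == bh_bruteforce(p, q).tolist()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([0.1], q=1.5)
        with pytest.raises(ValueError):
            bh_fdr([])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(12.0)
        assert spearman(x, 3 * x + 1).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_ties_match_midrank_closed_form(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(0, 5, size=20).astype(float)
            y = rng.integers(0, 5, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx = sp_stats.rankdata(x)
            ry = sp_stats.rankdata(y)
            closed = np.corrcoef(rx, ry)[0, 1]
            assert spearman(x, y).rho == pytest.approx(closed, abs=1e-12)

    def test_exact_permutation_matches_scipy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 5.0, 3.0, 6.0, 4.0])
        res = spearman(x, y)
        assert res.method == "exact-permutation"

        def statistic(yy):
            return sp_stats.spearmanr(x, yy).statistic

        oracle = sp_stats.permutation_test(
            (y,),
            statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        assert res.pvalue == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman(x, y)
        assert res.method == "t-approximation"
        ref = sp_stats.spearmanr(x, y)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])


def lmm_data(rng, n_groups=20, n_rep=6, effect=0.0, junk=True):
    rows = []
    for i in range(n_groups):
        b = rng.normal(0, 0.4)
        grp = "a" if i < n_groups // 2 else "b"
        for _ in range(n_rep):
            x = rng.normal()
            y = 1.0 + effect * x + b + rng.normal(0, 1.0)
            row = {"participant": f"p{i:02d}", "group": grp, "x": x, "y": y}
            if junk:
                row["junk"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestFitModel:
    def test_intercept_only_constant_data(self):
        df = pd.DataFrame(
            {
                "participant": ["a"] * 4 + ["b"] * 4,
                "y": [2.5] * 8,
            }
        )
        spec = ModelSpec("y", terms=(), groups="participant")
        fit = fit_model(spec, df, force_ghq=True)
        assert fit.params["Intercept"] == pytest.approx(2.5, abs=1e-6)

    def test_gaussian_lmm_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM (ML) gives the same
        estimates and likelihood as the closed-form marginal ML fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        df = lmm_data(rng, effect=0.5)
        spec = ModelSpec("y", (("x",),), groups="participant")
        a = fit_model(spec, df)
        assert a.backend == "closed-form-ml"
        X = np.column_stack([np.ones(len(df)), df["x"]])
        ml = sm.MixedLM(df["y"], X, groups=df["participant"]).fit(reml=False)
        assert np.allclose(a.params.values, np.asarray(ml.fe_params), atol=1e-5)
        assert a.loglik == pytest.approx(float(ml.llf), abs=1e-5)
        assert np.allclose(
            a.cov.values.diagonal() ** 0.5, np.asarray(ml.bse_fe), rtol=1e-3
        )

    def test_positive_family_requires_positive_response(self):
        rng = np.random.default_rng(4)
        df = lmm_data(rng)
        spec = ModelSpec(
            "y", (("x",),), groups="participant", family="inverse_gaussian"
        )
        with pytest.raises(ValueError, match="positive"):
            fit_model(spec, df)

    def test_missing_variable_reported(self):
        df = pd.DataFrame({"participant": ["a"], "y": [1.0]})
        spec = ModelSpec("y", (("nope",),), groups="participant")
        with pytest.raises(ValueError, match="nope"):
            fit_model(spec, df)

    def test_hierarchy_enforced_in_spec(self):
        with pytest.raises(ValueError, match="marginal"):
            ModelSpec("y", (("a", "b"),), groups="participant")


class TestSelectFamily:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(5)
        df = lmm_data(rng)
        spec = ModelSpec("y", (("x",),), groups="participant")
        best, table = select_family(spec, df, (("gaussian", "identity"),))
        assert best.family == "gaussian"
        assert len(table) == 1

    def test_gaussian_data_prefers_gaussian(self):
        rng = np.random.default_rng(6)
        df = lmm_data(rng)
        df["y"] = df["y"] - df["y"].min() + 0.5  # positive support
        spec = ModelSpec("y", (("x",),), groups="participant")
        best, table = select_family(
            spec,
            df,
            (
                ("inverse_gaussian", "identity"),
                ("gaussian", "identity"),
                ("gamma", "identity"),
            ),
        )
        assert best.family == "gaussian"
        assert table["aic"].idxmin() == 1

    def test_inverse_gaussian_data_prefers_inverse_gaussian(self):
        """Family recovery: IG/identity data picks IG/identity most often."""
        wins = 0
        n_rep = 12
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            G, nper = 24, 10
            g = np.repeat(np.arange(G), nper)
            mu = 0.25 + 0.1 * (np.arange(G) < G // 2).astype(float)[g]
            mu = mu + rng.normal(0, 0.02, G)[g]
            lam = 1 / 0.15
            nu = rng.normal(size=G * nper)
            yy = (
                mu
                + mu**2 * nu**2 / (2 * lam)
                - mu
                / (2 * lam)
                * np.sqrt(4 * mu * lam * nu**2 + mu**2 * nu**4)
            )
            z = rng.uniform(size=G * nper)
            y = np.where(z <= mu / (mu + yy), yy, mu**2 / yy)
            df = pd.DataFrame(
                {
                    "participant": g,
                    "group": np.where(np.arange(G) < G // 2, "a", "b")[g],
                    "y": y,
                }
            )
            spec = ModelSpec("y", (("group",),), groups="participant")
            best, _ = select_family(
                spec,
                df,
                (("inverse_gaussian", "identity"), ("gaussian", "identity")),
            )
            wins += best.family == "inverse_gaussian"
        assert wins > n_rep / 2

    def test_tie_prefers_declared_order(self):
        rng = np.random.default_rng(8)
        df = lmm_data(rng)
        spec = ModelSpec("y", (("x",),), groups="participant")
        best, table = select_family(
            spec, df, (("gaussian", "identity"), ("gaussian", "identity"))
        )
        assert len(table) == 2
        assert best.family == "gaussian"


class TestStepwise:
    def test_hierarchy_protects_main_effects(self):
        spec = ModelSpec(
            "y",
            (("a",), ("b",), ("a", "b")),
            groups="participant",
        )
        assert spec.removable_terms() == [("a", "b")]

    def test_trace_reproducible(self):
        rng = np.random.default_rng(9)
        df = lmm_data(rng, effect=0.8)
        spec = ModelSpec("y", (("x",), ("junk",)), groups="participant")
        _, _, t1 = stepwise_backward(spec, df)
        _, _, t2 = stepwise_backward(spec, df)
        pd.testing.assert_frame_equal(t1, t2)

    def test_aic_criterion(self):
        rng = np.random.default_rng(10)
        df = lmm_data(rng, effect=1.0)
        spec = ModelSpec("y", (("x",), ("junk",)), groups="participant")
        final, fit, trace = stepwise_backward(spec, df, criterion="aic")
        assert ("x",) in final.terms
        assert ("junk",) not in final.terms

    def test_invalid_criterion(self):
        spec = ModelSpec("y", (("x",),), groups="participant")
        with pytest.raises(ValueError):
            stepwise_backward(spec, pd.DataFrame(), criterion="bogus")


class TestContrasts:
    def _fit(self, rng, n_cond=3):
        conds = [f"c{i}" for i in range(n_cond)]
        rows = []
        for i in range(16):
            b = rng.normal(0, 0.3)
            for c in conds:
                for grp in ("a", "b"):
                    rows.append(
                        {
                            "participant": f"p{i}",
                            "condition": c,
                            "group": grp,
                            "y": 1.0
                            + 0.5 * conds.index(c)
                            + b
                            + rng.normal(0, 0.4),
                        }
                    )
        df = pd.DataFrame(rows)
        spec = ModelSpec(
            "y", (("condition",), ("group",)), groups="participant"
        )
        return fit_model(spec, df)

    def test_three_level_factor_three_contrasts(self):
        fit = self._fit(np.random.default_rng(11))
        cs = pairwise_contrasts(fit, "condition")
        assert len(cs) == 3

    def test_two_factor_crossing_fifteen_contrasts(self):
        fit = self._fit(np.random.default_rng(12))
        cs = pairwise_contrasts(fit, ["condition", "group"])
        assert len(cs) == len(list(itertools.combinations(range(6), 2))) == 15

    def test_adjusted_dominates_raw(self):
        fit = self._fit(np.random.default_rng(13))
        cs = pairwise_contrasts(fit, ["condition", "group"])
        assert np.all(cs.table["p_adj"] >= cs.table["p"] - 1e-15)

    def test_single_level_factor_rejected(self):
        fit = self._fit(np.random.default_rng(14))
        fit.data = fit.data.assign(constant="only")
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, "constant")

    def test_qq_diagnostic_reports_shapiro(self, tmp_path):
        from betadesync.stats import qq_diagnostic

        fit = self._fit(np.random.default_rng(16))
        path = tmp_path / "qq.png"
        stat, p = qq_diagnostic(fit, str(path))
        assert 0 < stat <= 1
        assert 0 <= p <= 1
        assert path.exists()

    def test_null_rejection_rate_near_alpha(self):
        """Equal cell means: ~5% raw rejections, no more after BH."""
        rng = np.random.default_rng(15)
        raw = 0
        adj = 0
        total = 0
        for _ in range(40):
            rows = []
            for i in range(12):
                b = rng.normal(0, 0.3)
                for c in ("c0", "c1", "c2"):
                    rows.append(
                        {
                            "participant": f"p{i}",
                            "condition": c,
                            "y": b + rng.normal(0, 0.5),
                        }
                    )
            df = pd.DataFrame(rows)
            spec = ModelSpec("y", (("condition",),), groups="participant")
            fit = fit_model(spec, df)
            cs = pairwise_contrasts(fit, "condition")
            raw += int((cs.table["p"] < 0.05).sum())
            adj += int(cs.table["reject"].sum())
            total += len(cs)
        assert raw / total < 0.15
        assert adj <= raw
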