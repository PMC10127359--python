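"""Binomial GLM/GLMM fitting, design builders, pruning and reports."""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit

from conftest import design_from_glmm_df
from aridtrait import models
from aridtrait.models import (
    ConvergenceError,
    DesignError,
    DesignSpec,
    Term,
    build_general_design,
    build_relative_design,
    dr_to_binomial,
    fit_report,
    glm_fit,
    glmm_fit,
    glmm_marginal_loglik,
    prune_nonsignificant,
    significance_stars,
)
from aridtrait.synthetic import simulate_glmm_dataset
from aridtrait.traits import derive_table, scale_within_species
from aridtrait.synthetic import simulate_assay


def simple_design(X, names, y, n, groups=None):
    terms = [Term(nm, [i], "intercept" if nm == "intercept" else "main")
             for i, nm in enumerate(names)]
    return DesignSpec(X=np.asarray(X, float), column_names=names,
                      successes=np.asarray(y), trials=np.asarray(n),
                      terms=terms, groups=groups)


class TestDrToBinomial:
    @pytest.mark.parametrize(
        "dr,expected",
        [(1.0, 192), (0.671875, 129), (0.5, 96)],
    )
    def test_half_hour_units_are_exact(self, dr, expected):
        s, n = dr_to_binomial(dr, 96.0, 0.5)
        assert (s[0], n[0]) == (expected, 192)

    def test_non_divisible_horizon_rejected(self):
        with pytest.raises(ValueError):
            dr_to_binomial(0.5, 96.0, 0.7)


class TestGlmClosedForms:
    def test_intercept_only_is_logit_of_proportion(self):
        d = simple_design([[1.0]], ["intercept"], [30], [96])
        fit = glm_fit(d)
        assert fit.coefficients[0] == pytest.approx(np.log(30 / 66), abs=1e-8)

    def test_two_group_slope_is_logit_difference(self):
        X = [[1.0, 0.0], [1.0, 1.0]]
        d = simple_design(X, ["intercept", "g"], [40, 70], [100, 100])
        fit = glm_fit(d)
        logit = lambda p: np.log(p / (1 - p))
        assert fit.coefficients[0] == pytest.approx(logit(0.4), abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(
            logit(0.7) - logit(0.4), abs=1e-8
        )

    def test_score_equations_hold_at_optimum(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.standard_normal((200, 2))])
        eta = X @ np.array([-0.5, 1.0, -0.7])
        y = rng.binomial(25, expit(eta))
        d = simple_design(X, ["intercept", "a", "b"], y, np.full(200, 25))
        fit = glm_fit(d)
        score = X.T @ (y - 25 * fit.fitted_proportions)
        assert np.max(np.abs(score)) < 1e-6


def test_glm_matches_generic_optimizer_oracle():
    """IRLS coefficients agree with a generic quasi-Newton maximisation of
    the same binomial likelihood started from zero."""
    rng = np.random.default_rng(42)
    n_obs, trials = 200, 30
    X = np.column_stack([np.ones(n_obs), rng.standard_normal((n_obs, 3))])
    beta_true = np.array([0.3, -0.9, 0.5, 1.2])
    y = rng.binomial(trials, expit(X @ beta_true))
    d = simple_design(X, ["intercept", "a", "b", "c"], y, np.full(n_obs, trials))
    fit = glm_fit(d)

    def nll(b):
        eta = X @ b
        return -np.sum(y * eta - trials * np.logaddexp(0, eta))

    def grad(b):
        return -X.T @ (y - trials * expit(X @ b))

    res = optimize.minimize(nll, np.zeros(4), jac=grad, method="BFGS",
                            options={"gtol": 1e-10})
    assert fit.coefficients == pytest.approx(res.x, abs=1e-6)


def test_glm_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(7)
    X = np.column_stack([np.ones(150), rng.standard_normal((150, 2))])
    y = rng.binomial(20, expit(X @ np.array([-0.2, 0.8, -0.5])))
    d = simple_design(X, ["intercept", "a", "b"], y, np.full(150, 20))
    fit = glm_fit(d)
    ref = sm.GLM(np.column_stack([y, 20 - y]), X,
                 family=sm.families.Binomial()).fit()
    assert fit.coefficients == pytest.approx(ref.params, abs=1e-6)
    assert fit.standard_errors == pytest.approx(ref.bse, rel=1e-4)
    assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-8)


def test_glm_detects_separation_and_rank_deficiency():
    X = np.array([[1.0, 0.0], [1.0, 1.0]])
    d = simple_design(X, ["intercept", "g"], [0, 50], [50, 50])
    with pytest.raises(ConvergenceError):
        glm_fit(d)  # group proportions 0 and 1: complete separation
    Xr = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
    with pytest.raises(DesignError, match="aliased"):
        simple_design(Xr, ["intercept", "x", "x2"], np.zeros(10, int),
                      np.full(10, 5))


def test_aic_and_pseudo_r2_identities():
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(100), rng.standard_normal(100)])
    y = rng.binomial(10, expit(X @ np.array([0.2, 1.0])))
    d = simple_design(X, ["intercept", "x"], y, np.full(100, 10))
    fit = glm_fit(d)
    assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * 2)
    assert 0 <= fit.pseudo_r2 <= 1
    assert 0 <= fit.pseudo_r2_deviance <= 1


class TestGlmm:
    def test_sd_zero_reproduces_glm_loglik_exactly(self):
        df = simulate_glmm_dataset([-0.5, 0.8], 0.0, 6, 20, trials=15, seed=1)
        d = design_from_glmm_df(df)
        glm = glm_fit(d)
        ll0 = glmm_marginal_loglik(d, glm.coefficients, 0.0)
        assert ll0 == pytest.approx(glm.log_likelihood, abs=1e-10)

    def test_degenerate_random_effect_recovers_glm(self):
        """Data generated with sigma_species = 0: the GLMM should estimate a
        near-zero random SD and fixed effects matching the plain GLM."""
        import warnings

        df = simulate_glmm_dataset([-0.5, 0.8], 0.0, 8, 40, trials=30, seed=2)
        d = design_from_glmm_df(df)
        glm = glm_fit(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # SD may sit at the boundary
            fit = glmm_fit(d)
        assert fit.random_intercept_sd < 0.05
        assert fit.coefficients == pytest.approx(glm.coefficients, abs=1e-3)

    def test_quadrature_point_count_converged(self):
        df = simulate_glmm_dataset([-0.8, 0.5, -1.0], 0.6, 8, 25,
                                   trials=192, seed=3)
        d = design_from_glmm_df(df)
        fit = glmm_fit(d, quadrature_points=15)
        ll15 = glmm_marginal_loglik(d, fit.coefficients,
                                    fit.random_intercept_sd, 15)
        ll31 = glmm_marginal_loglik(d, fit.coefficients,
                                    fit.random_intercept_sd, 31)
        assert abs(ll15 - ll31) < 1e-6

    def test_matches_lme4_glmer(self, tmp_path):
        """Fixed effects, random SD and SEs agree with lme4::glmer at the
        same adaptive quadrature order."""
        df = simulate_glmm_dataset([-0.8, 0.5, -1.0], 0.6, 8,
                                   [20, 12, 7, 39, 18, 25, 9, 14],
                                   trials=192, seed=11)
        d = design_from_glmm_df(df)
        fit = glmm_fit(d)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- glmer(cbind(successes, trials - successes) ~ x1 + x2 +
                       (1 | species), data = d, family = binomial, nAGQ = 15)
            co <- summary(m)$coefficients
            cat(sprintf('%.10f\\n', co[, 'Estimate']))
            cat(sprintf('%.10f\\n', co[, 'Std. Error']))
            cat(sprintf('%.10f\\n', sqrt(unlist(VarCorr(m)))))
        """))
        out = subprocess.run(["Rscript", "--vanilla", str(script)],
                             capture_output=True, text=True, check=True)
        vals = [float(v) for v in out.stdout.split()]
        r_beta, r_se, r_sd = vals[0:3], vals[3:6], vals[6]
        assert fit.coefficients == pytest.approx(r_beta, abs=2e-4)
        assert fit.standard_errors == pytest.approx(r_se, rel=2e-2)
        assert fit.random_intercept_sd == pytest.approx(r_sd, abs=2e-3)

    def test_needs_grouping_factor(self):
        d = simple_design(np.ones((10, 1)), ["intercept"],
                          np.arange(10) % 3, np.full(10, 5))
        with pytest.raises(DesignError):
            glmm_fit(d)


@pytest.fixture(scope="module")
def demo_traits():
    from aridtrait.config import default_config

    cfg = default_config()
    series, _ = simulate_assay(cfg.assay_config())
    table, _ = derive_table(series, 96.0)
    return scale_within_species(table)


class TestDesignBuilders:
    def test_general_design_row_layout(self, demo_traits):
        d = build_general_design(demo_traits, include_fwc=True)
        assert d.column_names == [
            "intercept", "tunneler", "roller", "log_bm", "wlr", "wlt",
            "tunneler:log_bm", "roller:log_bm", "fwc",
        ]
        assert np.linalg.matrix_rank(d.X) == 9
        without = build_general_design(demo_traits, include_fwc=False)
        assert np.linalg.matrix_rank(without.X) == 8
        # a dweller row has zero guild indicators and interactions
        i = np.flatnonzero((d.X[:, 1] == 0) & (d.X[:, 2] == 0))[0]
        assert d.X[i, 6] == 0 and d.X[i, 7] == 0
        # a roller row carries roller x log BM = log BM
        j = np.flatnonzero(d.X[:, 2] == 1)[0]
        assert d.X[j, 7] == d.X[j, 3]
        assert d.groups is not None and d.n_groups == 8

    def test_relative_design_reference_absorbed(self, demo_traits):
        d = build_relative_design(demo_traits, reference="C_erraticus")
        sp_cols = [c for c in d.column_names if c.startswith("species[")]
        assert len(sp_cols) == 7
        assert "species[C_erraticus]" not in d.column_names
        ref_rows = np.all(d.X[:, 4:] == 0, axis=1)
        assert ref_rows.sum() > 0  # reference species rows have no indicator
        with pytest.raises(DesignError):
            build_relative_design(demo_traits, reference="nope")

    def test_scaled_columns_required(self, demo_traits):
        with pytest.raises(DesignError, match="scaled"):
            build_relative_design(demo_traits.drop(columns=["scaled_bm"]))


class TestPruning:
    def test_empty_candidate_list_changes_nothing(self):
        df = simulate_glmm_dataset([-0.5, 0.8], 0.0, 4, 40, trials=20, seed=5)
        d = design_from_glmm_df(df)
        fit0 = glm_fit(d)
        fit, spec, audit = prune_nonsignificant(d, glm_fit, candidate_terms=[])
        assert audit == []
        assert fit.coefficients == pytest.approx(fit0.coefficients)

    def test_unknown_candidate_rejected(self):
        df = simulate_glmm_dataset([0.0], 0.0, 4, 10, trials=5, seed=5)
        d = design_from_glmm_df(df)
        with pytest.raises(DesignError):
            prune_nonsignificant(d, glm_fit, candidate_terms=["nope"])

    def test_interaction_demoted_before_main_effect_dropped(self):
        """With a null interaction but active main effects, the interaction
        goes first and the mains survive."""
        rng = np.random.default_rng(9)
        n = 400
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), a, b, a * b])
        y = rng.binomial(20, expit(-0.3 + 1.0 * a - 0.8 * b))
        terms = [
            Term("intercept", [0], "intercept"),
            Term("a", [1]),
            Term("b", [2]),
            Term("a:b", [3], "interaction", parents=["a", "b"]),
        ]
        d = DesignSpec(X=X, column_names=["intercept", "a", "b", "a:b"],
                       successes=y, trials=np.full(n, 20), terms=terms)
        fit, spec, audit = prune_nonsignificant(d, glm_fit, alpha=0.05)
        names = [t.name for t in spec.terms]
        assert "a:b" not in names and {"a", "b"} <= set(names)
        assert audit and audit[0]["term"] == "a:b"


def test_fit_report_stars_and_layout():
    df = simulate_glmm_dataset([-2.0, 1.5], 0.0, 4, 50, trials=40, seed=6)
    d = design_from_glmm_df(df)
    fit = glm_fit(d)
    text = fit_report(fit, label_map={"x1": "covariate one"})
    assert "covariate one" in text
    assert "AIC" in text and "pseudo_R2" in text
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.2) == "NS"
    assert significance_stars(0.009) == "**"
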