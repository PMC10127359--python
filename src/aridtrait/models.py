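"""Binomial GLM and GLMM inference for desiccation-resistance proportions.

Desiccation resistance (survival time / horizon) is modelled as a binomial
count of survived half-hour units out of the horizon's total, so that
interval-censored survival midpoints (x.5 hours) are exactly representable.

Two fitters are provided, both written here rather than delegated:

* :func:`glm_fit` — logit-link binomial GLM maximised by iteratively
  reweighted least squares (IRLS), stopping when the score norm falls below
  tolerance; standard errors from the observed information.
* :func:`glmm_fit` — binomial GLMM with a single Gaussian random intercept
  per group (species), marginal likelihood integrated by adaptive
  Gauss-Hermite quadrature (re-centred at each group's conditional mode)
  and maximised numerically; fixed-effect standard errors from the
  numerical Hessian conditional on the variance parameter.

Design builders mirror the study's two formulas: a general effects model
``DR ~ nesting * log BM + WLR + WLT (+ fWC) + (1 | species)`` and a relative
effects model ``DR ~ species + scaled BM + scaled WLR + scaled WLT``.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import linalg, optimize
from scipy.special import expit, gammaln
from scipy.stats import chi2, norm


class ConvergenceError(RuntimeError):
    """Fit did not converge (or the data are separated)."""


class DesignError(ValueError):
    """Invalid model design (rank deficiency, bad response, ...)."""


@dataclasses.dataclass
class Term:
    """A named group of design-matrix columns (possibly multi-column)."""

    name: str
    columns: list[int]
    kind: str = "main"  # "intercept" | "main" | "interaction"
    parents: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class DesignSpec:
    """Design matrix, binomial response and term metadata for one model."""

    X: np.ndarray
    column_names: list[str]
    successes: np.ndarray
    trials: np.ndarray
    terms: list[Term]
    groups: np.ndarray | None = None  # integer codes for the random intercept
    group_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.successes = np.asarray(self.successes)
        self.trials = np.asarray(self.trials)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_names):
            raise DesignError("X shape does not match column names")
        if len(self.successes) != len(self.X) or len(self.trials) != len(self.X):
            raise DesignError("response length does not match design rows")
        if np.any(self.trials < 1):
            raise DesignError("trials must be >= 1 for every record")
        if np.any(self.successes < 0) or np.any(self.successes > self.trials):
            raise DesignError("successes must lie in [0, trials]")
        self._check_rank()

    def _check_rank(self) -> None:
        n, p = self.X.shape
        if n < p:
            raise DesignError(f"more columns ({p}) than rows ({n})")
        _, r, piv = linalg.qr(self.X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(self.X.shape) * np.finfo(float).eps
        aliased = [self.column_names[piv[i]] for i in range(p) if diag[i] <= tol]
        if aliased:
            raise DesignError(f"design is rank deficient; aliased columns: {aliased}")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_groups(self) -> int:
        if self.groups is None:
            return 0
        return int(self.groups.max()) + 1

    def drop_term(self, name: str) -> "DesignSpec":
        """A new DesignSpec with the named term's columns removed."""
        victim = next((t for t in self.terms if t.name == name), None)
        if victim is None:
            raise DesignError(f"no term named {name!r}")
        keep = [j for j in range(self.X.shape[1]) if j not in victim.columns]
        remap = {old: new for new, old in enumerate(keep)}
        terms = [
            Term(t.name, [remap[c] for c in t.columns], t.kind, list(t.parents))
            for t in self.terms
            if t.name != name
        ]
        return DesignSpec(
            X=self.X[:, keep],
            column_names=[self.column_names[j] for j in keep],
            successes=self.successes,
            trials=self.trials,
            terms=terms,
            groups=self.groups,
            group_names=self.group_names,
        )


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclasses.dataclass
class ModelFit:
    """A fitted binomial GLM or GLMM with Wald inference."""

    method: str  # "glm" | "glmm"
    column_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_z: np.ndarray
    p_values: np.ndarray
    stars: list[str]
    log_likelihood: float
    aic: float
    pseudo_r2: float  # squared Pearson corr(observed, fitted proportions)
    pseudo_r2_deviance: float
    random_intercept_sd: float | None
    converged: bool
    n_obs: int
    n_groups: int
    fitted_proportions: np.ndarray
    cov: np.ndarray
    n_params: int

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.column_names.index(name)])


def dr_to_binomial(
    dr: float | np.ndarray, horizon_h: float, unit_h: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a desiccation-resistance proportion to (successes, trials).

    ``trials = horizon / unit`` survived-time units; with the default 0.5 h
    unit every half-hour survival midpoint maps to an integer count.
    """
    ratio = horizon_h / unit_h
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"horizon {horizon_h} is not a multiple of unit {unit_h}")
    trials = int(round(ratio))
    dr_arr = np.atleast_1d(np.asarray(dr, dtype=float))
    if np.any((dr_arr <= 0) | (dr_arr > 1)):
        raise ValueError("dr must lie in (0, 1]")
    successes = np.rint(dr_arr * trials).astype(int)
    return successes, np.full_like(successes, trials)


def _binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    return float(np.sum(const + y * np.log(p) + (n - y) * np.log1p(-p)))


def _pseudo_r2_pearson(y: np.ndarray, n: np.ndarray, fitted: np.ndarray) -> float:
    obs = y / n
    if np.ptp(obs) == 0 or np.ptp(fitted) == 0:
        return 0.0
    return float(np.corrcoef(obs, fitted)[0, 1] ** 2)


def _pseudo_r2_deviance(y, n, fitted) -> float:
    ll = _binom_loglik(y, n, fitted)
    p0 = np.full_like(fitted, y.sum() / n.sum())
    ll0 = _binom_loglik(y, n, p0)
    p_sat = np.clip(y / n, 1e-12, 1 - 1e-12)
    ll_sat = _binom_loglik(y, n, p_sat)
    if ll_sat - ll0 <= 0:
        return 0.0
    return float(np.clip((ll - ll0) / (ll_sat - ll0), 0.0, 1.0))


def glm_fit(
    design: DesignSpec,
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> ModelFit:
    """Binomial logit GLM maximised by IRLS.

    Iterates weighted least squares on the working response until the score
    ``X'(y - n p)`` has sup-norm below ``score_tol``. Diverging linear
    predictors (complete separation) raise :class:`ConvergenceError`.
    """
    X, y, n = design.X, design.successes.astype(float), design.trials.astype(float)
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        if np.any(np.abs(eta) > 40):
            raise ConvergenceError(
                "linear predictor diverged (|eta| > 40): complete or "
                "quasi-complete separation"
            )
        p = expit(eta)
        mu = n * p
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        w = np.clip(n * p * (1 - p), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        beta = linalg.solve(xtw @ X, xtw @ z, assume_a="pos")
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")
    # a converged |eta| > 20 means fitted probabilities within 2e-9 of 0 or
    # 1 — the IRLS signature of complete or quasi-complete separation
    if np.any(np.abs(X @ beta) > 20):
        raise ConvergenceError(
            "fitted linear predictor exceeds 20 in magnitude: complete or "
            "quasi-complete separation"
        )
    p = expit(X @ beta)
    w = n * p * (1 - p)
    info = (X.T * w) @ X
    cov = linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z_stat = beta / se
    p_vals = 2 * norm.sf(np.abs(z_stat))
    ll = _binom_loglik(y, n, p)
    k = X.shape[1]
    return ModelFit(
        method="glm",
        column_names=list(design.column_names),
        coefficients=beta,
        standard_errors=se,
        wald_z=z_stat,
        p_values=p_vals,
        stars=[significance_stars(pv) for pv in p_vals],
        log_likelihood=ll,
        aic=-2 * ll + 2 * k,
        pseudo_r2=_pseudo_r2_pearson(y, n, p),
        pseudo_r2_deviance=_pseudo_r2_deviance(y, n, p),
        random_intercept_sd=None,
        converged=True,
        n_obs=design.n_obs,
        n_groups=design.n_groups,
        fitted_proportions=p,
        cov=cov,
        n_params=k,
    )


# --- GLMM: adaptive Gauss-Hermite marginal likelihood -----------------------


def _group_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    groups: np.ndarray,
    n_groups: int,
    sd: float,
    b0: np.ndarray,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for each group's conditional mode of the random intercept.

    Returns the modes and the negative curvature ``-h''`` at the mode, where
    ``h(b) = loglik_group(b) + log phi(b; 0, sd^2)``.
    """
    b = b0.copy()
    inv_var = 1.0 / sd**2
    for _ in range(max_iter):
        p = expit(eta0 + b[groups])
        grad = np.bincount(groups, weights=y - n * p, minlength=n_groups) - b * inv_var
        curv = (
            np.bincount(groups, weights=n * p * (1 - p), minlength=n_groups) + inv_var
        )
        step = grad / curv
        step = np.clip(step, -5 * sd - 1, 5 * sd + 1)  # damp early wild steps
        b = b + step
        if np.max(np.abs(step)) < 1e-11:
            break
    p = expit(eta0 + b[groups])
    curv = np.bincount(groups, weights=n * p * (1 - p), minlength=n_groups) + inv_var
    return b, curv


def glmm_marginal_loglik(
    design: DesignSpec,
    beta: np.ndarray,
    sd: float,
    quadrature_points: int = 15,
    _mode_cache: dict | None = None,
) -> float:
    """Marginal binomial log-likelihood with the random intercept integrated
    out by adaptive Gauss-Hermite quadrature (``sd = 0`` collapses to the GLM
    log-likelihood exactly)."""
    if design.groups is None:
        raise DesignError("design has no grouping factor")
    X, y, n = design.X, design.successes.astype(float), design.trials.astype(float)
    groups = design.groups
    n_groups = design.n_groups
    eta0 = X @ np.asarray(beta, dtype=float)
    const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
    if sd == 0.0:
        p = np.clip(expit(eta0), 1e-12, 1 - 1e-12)
        return const + float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))
    b0 = np.zeros(n_groups)
    if _mode_cache is not None and "b" in _mode_cache:
        b0 = _mode_cache["b"]
    modes, curv = _group_modes(eta0, y, n, groups, n_groups, sd, b0)
    if _mode_cache is not None:
        _mode_cache["b"] = modes
    sigma_hat = 1.0 / np.sqrt(curv)
    z, w = hermgauss(quadrature_points)
    # integral ~ sqrt(2) sigma_hat * sum_k w_k exp(z_k^2) exp(h(b_k))
    bk = modes[None, :] + np.sqrt(2.0) * sigma_hat[None, :] * z[:, None]  # (q, G)
    eta = eta0[None, :] + bk[:, groups]
    eta = np.clip(eta, -500, 500)
    ll_obs = y[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta)
    h = np.zeros((quadrature_points, n_groups))
    for k in range(quadrature_points):
        h[k] = np.bincount(groups, weights=ll_obs[k], minlength=n_groups)
    h += -0.5 * np.log(2 * np.pi) - np.log(sd) - bk**2 / (2 * sd**2)
    logterms = np.log(w)[:, None] + z[:, None] ** 2 + h
    m = logterms.max(axis=0)
    log_int = m + np.log(np.sum(np.exp(logterms - m), axis=0))
    log_int += 0.5 * np.log(2.0) + np.log(sigma_hat)
    return const + float(np.sum(log_int))


def glmm_fit(
    design: DesignSpec,
    quadrature_points: int = 15,
    start: np.ndarray | None = None,
    boundary_sd: float = 1e-2,
) -> ModelFit:
    """Binomial GLMM with one Gaussian random intercept per group, fitted by
    maximum likelihood over ``(beta, log sd)``.

    The marginal likelihood is evaluated with adaptive Gauss-Hermite
    quadrature (default 15 nodes). Fixed-effect standard errors come from
    the numerical Hessian in ``beta`` at the optimum, conditional on the
    estimated variance parameter (the usual mixed-model convention). A
    fitted SD below ``boundary_sd`` triggers a boundary warning; the fit is
    still reported.
    """
    if design.groups is None or design.n_groups < 2:
        raise DesignError("glmm_fit needs a grouping factor with >= 2 levels")
    p_fix = design.X.shape[1]
    if start is None:
        beta0 = glm_fit(design).coefficients
    else:
        beta0 = np.asarray(start, dtype=float)
    x0 = np.concatenate([beta0, [np.log(0.5)]])
    cache: dict = {}

    def nll(params: np.ndarray) -> float:
        beta, log_sd = params[:p_fix], params[p_fix]
        return -glmm_marginal_loglik(
            design, beta, float(np.exp(log_sd)), quadrature_points, cache
        )

    bounds = [(None, None)] * p_fix + [(-8.0, 5.0)]
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise ConvergenceError(f"GLMM optimisation failed: {res.message}")
    beta_hat = res.x[:p_fix]
    sd_hat = float(np.exp(res.x[p_fix]))
    if sd_hat < boundary_sd:
        warnings.warn(
            f"random-intercept SD estimated at the boundary ({sd_hat:.2e}); "
            "the groups show no excess heterogeneity",
            stacklevel=2,
        )
    ll = -res.fun

    # numerical Hessian in beta, conditional on sd_hat
    def nll_beta(beta: np.ndarray) -> float:
        return -glmm_marginal_loglik(design, beta, sd_hat, quadrature_points, cache)

    h = 1e-5 * (1.0 + np.abs(beta_hat))
    hess = np.empty((p_fix, p_fix))
    f0 = nll_beta(beta_hat)
    for i in range(p_fix):
        for j in range(i, p_fix):
            ei = np.zeros(p_fix)
            ej = np.zeros(p_fix)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                fpp = nll_beta(beta_hat + 2 * ei)
                fp = nll_beta(beta_hat + ei)
                fm = nll_beta(beta_hat - ei)
                fmm = nll_beta(beta_hat - 2 * ei)
                hess[i, i] = (-fpp + 16 * fp - 30 * f0 + 16 * fm - fmm) / (
                    12 * h[i] ** 2
                )
            else:
                fpp = nll_beta(beta_hat + ei + ej)
                fpm = nll_beta(beta_hat + ei - ej)
                fmp = nll_beta(beta_hat - ei + ej)
                fmm = nll_beta(beta_hat - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                    4 * h[i] * h[j]
                )
    try:
        cov = linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except linalg.LinAlgError:  # pragma: no cover - pathological designs
        cov = np.full((p_fix, p_fix), np.nan)
        se = np.full(p_fix, np.nan)
    z_stat = np.divide(beta_hat, se, out=np.zeros_like(beta_hat), where=se > 0)
    p_vals = 2 * norm.sf(np.abs(z_stat))

    # conditional fitted proportions at the estimated modes
    y = design.successes.astype(float)
    n = design.trials.astype(float)
    eta0 = design.X @ beta_hat
    if sd_hat > 0:
        modes, _ = _group_modes(
            eta0, y, n, design.groups, design.n_groups, sd_hat,
            cache.get("b", np.zeros(design.n_groups)),
        )
        fitted = expit(eta0 + modes[design.groups])
    else:
        fitted = expit(eta0)
    k = p_fix + 1  # fixed effects + random-intercept variance
    return ModelFit(
        method="glmm",
        column_names=list(design.column_names),
        coefficients=beta_hat,
        standard_errors=se,
        wald_z=z_stat,
        p_values=p_vals,
        stars=[significance_stars(pv) for pv in p_vals],
        log_likelihood=ll,
        aic=-2 * ll + 2 * k,
        pseudo_r2=_pseudo_r2_pearson(y, n, fitted),
        pseudo_r2_deviance=_pseudo_r2_deviance(y, n, fitted),
        random_intercept_sd=sd_hat,
        converged=True,
        n_obs=design.n_obs,
        n_groups=design.n_groups,
        fitted_proportions=fitted,
        cov=cov,
        n_params=k,
    )


# --- design builders ---------------------------------------------------------


def _complete_records(table: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    df = table[table["died_in_assay"]].dropna(subset=list(cols))
    if df.empty:
        raise DesignError("no complete records (no individuals died with traits)")
    return df.reset_index(drop=True)


def build_general_design(
    table: pd.DataFrame,
    include_fwc: bool = False,
    horizon_h: float = 96.0,
    trials_unit_h: float = 0.5,
) -> DesignSpec:
    """General effects model design:
    ``DR ~ nesting * log BM + WLR + WLT (+ fWC)`` with species as the
    grouping factor for a random intercept. Dwellers are the reference
    guild; tunneler and roller enter as indicators plus their interactions
    with log body mass.
    """
    needed = ["water_loss_rate", "water_loss_tolerance"]
    if include_fwc:
        needed.append("fractional_water_content")
    df = _complete_records(table, needed)
    for guild, grp in df.groupby("nesting_strategy"):
        if len(grp) < 2:
            warnings.warn(
                f"nesting guild {guild!r} has only {len(grp)} complete record(s)",
                stacklevel=2,
            )
    tun = (df["nesting_strategy"] == "tunneler").astype(float).to_numpy()
    rol = (df["nesting_strategy"] == "roller").astype(float).to_numpy()
    logbm = df["log_body_mass"].to_numpy()
    cols = [
        np.ones(len(df)),
        tun,
        rol,
        logbm,
        df["water_loss_rate"].to_numpy(),
        df["water_loss_tolerance"].to_numpy(),
        tun * logbm,
        rol * logbm,
    ]
    names = [
        "intercept",
        "tunneler",
        "roller",
        "log_bm",
        "wlr",
        "wlt",
        "tunneler:log_bm",
        "roller:log_bm",
    ]
    terms = [
        Term("intercept", [0], "intercept"),
        Term("nesting", [1, 2], "main"),
        Term("log_bm", [3], "main"),
        Term("wlr", [4], "main"),
        Term("wlt", [5], "main"),
        Term("nesting:log_bm", [6, 7], "interaction", parents=["nesting", "log_bm"]),
    ]
    if include_fwc:
        cols.append(df["fractional_water_content"].to_numpy())
        names.append("fwc")
        terms.append(Term("fwc", [8], "main"))
    # drop structurally empty guild columns (e.g. no rollers in the data)
    X = np.column_stack(cols)
    present = df["nesting_strategy"].unique()
    species = sorted(df["species"].unique())
    codes = df["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    successes, trials = dr_to_binomial(
        df["desiccation_resistance"].to_numpy(), horizon_h, trials_unit_h
    )
    if "roller" not in present or "tunneler" not in present:
        keep = [
            j
            for j, nm in enumerate(names)
            if not (
                ("roller" in nm and "roller" not in present)
                or ("tunneler" in nm and "tunneler" not in present)
            )
        ]
        X = X[:, keep]
        names = [names[j] for j in keep]
        terms = _rebuild_terms(terms, keep)
    return DesignSpec(
        X=X,
        column_names=names,
        successes=successes,
        trials=trials,
        terms=terms,
        groups=codes,
        group_names=species,
    )


def _rebuild_terms(terms: list[Term], keep: list[int]) -> list[Term]:
    remap = {old: new for new, old in enumerate(keep)}
    out = []
    for t in terms:
        cols = [remap[c] for c in t.columns if c in remap]
        if cols:
            out.append(Term(t.name, cols, t.kind, list(t.parents)))
    return out


def build_relative_design(
    table: pd.DataFrame,
    reference: str | None = None,
    horizon_h: float = 96.0,
    trials_unit_h: float = 0.5,
) -> DesignSpec:
    """Relative effects model design:
    ``DR ~ species + scaled WLR + scaled WLT + scaled BM`` (plain GLM).

    ``reference`` names the species absorbed into the intercept (default:
    first species in sorted order).
    """
    needed = ["scaled_wlr", "scaled_wlt", "scaled_bm"]
    if not set(needed) <= set(table.columns):
        raise DesignError("scaled columns missing; run scale_within_species first")
    df = _complete_records(table, needed)
    species = sorted(df["species"].unique())
    if reference is None:
        reference = species[0]
    if reference not in species:
        raise DesignError(
            f"reference species {reference!r} not in data (have {species})"
        )
    others = [s for s in species if s != reference]
    cols = [
        np.ones(len(df)),
        df["scaled_wlr"].to_numpy(),
        df["scaled_wlt"].to_numpy(),
        df["scaled_bm"].to_numpy(),
    ]
    names = ["intercept", "scaled_wlr", "scaled_wlt", "scaled_bm"]
    terms = [
        Term("intercept", [0], "intercept"),
        Term("scaled_wlr", [1], "main"),
        Term("scaled_wlt", [2], "main"),
        Term("scaled_bm", [3], "main"),
    ]
    sp_cols = list(range(4, 4 + len(others)))
    for s in others:
        cols.append((df["species"] == s).astype(float).to_numpy())
        names.append(f"species[{s}]")
    terms.append(Term("species", sp_cols, "main"))
    successes, trials = dr_to_binomial(
        df["desiccation_resistance"].to_numpy(), horizon_h, trials_unit_h
    )
    return DesignSpec(
        X=np.column_stack(cols),
        column_names=names,
        successes=successes,
        trials=trials,
        terms=terms,
        groups=None,
        group_names=None,
    )


# --- term pruning -------------------------------------------------------------


def term_wald_p(fit: ModelFit, term: Term) -> float:
    """Joint Wald chi-square p-value for a (possibly multi-column) term."""
    idx = term.columns
    b = fit.coefficients[idx]
    v = fit.cov[np.ix_(idx, idx)]
    stat = float(b @ linalg.solve(v, b))
    return float(chi2.sf(stat, len(idx)))


def prune_nonsignificant(
    design: DesignSpec,
    fitter: Callable[[DesignSpec], ModelFit],
    candidate_terms: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[ModelFit, DesignSpec, list[dict]]:
    """Backward pruning of non-significant candidate terms.

    Repeatedly drops (largest p first, refitting after each drop) candidate
    terms whose joint Wald p is at or above ``alpha``. Interaction terms are
    considered before main effects, and a main effect is never dropped while
    an interaction involving it remains — a non-significant interaction is
    thereby demoted to an additive term first. Returns the final fit, its
    design, and an audit log of the drops.
    """
    spec = design
    fit = fitter(spec)
    audit: list[dict] = []
    if candidate_terms is not None and not set(candidate_terms) <= {
        t.name for t in spec.terms
    }:
        raise DesignError("candidate_terms contains unknown term names")
    while True:
        cands = [
            t
            for t in spec.terms
            if t.kind != "intercept"
            and (candidate_terms is None or t.name in candidate_terms)
        ]
        interactions = [t for t in cands if t.kind == "interaction"]
        locked = {
            p for t in spec.terms if t.kind == "interaction" for p in t.parents
        }
        mains = [t for t in cands if t.kind != "interaction" and t.name not in locked]
        dropped = False
        # interactions are eligible first; a main effect is only droppable
        # once no interaction involving it remains
        for pool in (interactions, mains):
            if not pool:
                continue
            worst_p, worst = max(
                ((term_wald_p(fit, t), t) for t in pool), key=lambda x: x[0]
            )
            if worst_p >= alpha:
                spec = spec.drop_term(worst.name)
                audit.append(
                    {"term": worst.name, "p": float(worst_p), "action": "dropped"}
                )
                fit = fitter(spec)
                dropped = True
                break
        if not dropped or len(spec.terms) <= 1:
            break
    return fit, spec, audit


def fit_report(fit: ModelFit, label_map: dict[str, str] | None = None) -> str:
    """Human-readable coefficient table in the study's layout.

    One row per coefficient with estimate +/- SE, Wald z, p and significance
    stars (* p<0.05, ** p<0.01, *** p<0.001, NS otherwise), preceded by fit
    metadata. Pseudo-R-squared is the squared Pearson correlation between
    observed and fitted proportions; a deviance-based alternative is also
    reported.
    """
    labels = label_map or {}
    lines = [
        f"method\t{fit.method.upper()} (binomial, logit link)",
        f"n_obs\t{fit.n_obs}",
        f"n_groups\t{fit.n_groups if fit.n_groups else '-'}",
        f"log_likelihood\t{fit.log_likelihood:.3f}",
        f"AIC\t{fit.aic:.2f}",
        "pseudo_R2 (squared Pearson corr, observed vs fitted)\t"
        f"{fit.pseudo_r2:.3f}",
        f"pseudo_R2 (deviance-based)\t{fit.pseudo_r2_deviance:.3f}",
    ]
    if fit.random_intercept_sd is not None:
        lines.append(f"random_intercept_sd\t{fit.random_intercept_sd:.4f}")
    lines.append("term\testimate\tSE\tz\tp\tsig")
    for i, name in enumerate(fit.column_names):
        lines.append(
            f"{labels.get(name, name)}\t{fit.coefficients[i]:+.4f}\t"
            f"{fit.standard_errors[i]:.4f}\t{fit.wald_z[i]:+.3f}\t"
            f"{fit.p_values[i]:.4g}\t{fit.stars[i]}"
        )
    lines.append("sig codes\t*** p<0.001, ** p<0.01, * p<0.05, NS not significant")
    return "\n".join(lines) + "\n"
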