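"""Random-intercept logistic regression of alcohol use on context.

The model for situation i of participant j is

    logit P(y_ij = 1) = x_ij' beta + u_j,   u_j ~ N(0, sigma_u^2),

with x_ij = (1, brightness, loudness, attendance, prior drinks).  The
marginal likelihood integrates the random intercept out per cluster; here
that integral is evaluated by adaptive Gauss-Hermite quadrature (nodes
recentred at each cluster's posterior mode and rescaled by its curvature),
and the likelihood is maximised with a quasi-Newton optimiser started from
the ordinary logistic fit.  Standard errors are cluster-level sandwich
estimates (the "maximum likelihood robust" convention), so confidence
intervals remain honest under residual within-person dependence.

Fit indices:

* McKelvey & Zavoina pseudo-R2, fixed-effects flavour: the variance of the
  fixed linear predictor over the latent total Var(Xb) + sigma_u^2 + pi^2/3.
* A Hosmer-Lemeshow test computed on the fixed-part probabilities only,
  decile groups, chi-square with g-2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logsumexp
from statsmodels.tools import numdiff

from clipcontext.config import COARSE_LEVELS, SOURCES

LATENT_RESIDUAL_VAR = np.pi**2 / 3.0  # logistic latent residual variance

_SEPARATION_BOUND = 15.0  # |beta| beyond this flags quasi-separation


class HosmerLemeshowResult(NamedTuple):
    chi2: float
    pvalue: float
    df: int


class RandomInterceptLogit:
    """Two-level logistic model with a Gaussian random intercept.

    Parameters
    ----------
    endog : (n,) binary outcome.
    exog : (n, p) design matrix *without* a constant; one is prepended.
    groups : (n,) cluster labels (e.g. participant ids).
    exog_names : optional names for the p predictors.
    n_nodes : Gauss-Hermite nodes for the adaptive quadrature.
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        exog_names: Optional[Sequence[str]] = None,
        n_nodes: int = 15,
        add_constant: bool = True,
    ):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
        g = np.asarray(groups)
        if y.size != X.shape[0] or y.size != g.size:
            raise ValueError("endog, exog and groups must have matching lengths")
        if not np.isfinite(X).all():
            raise ValueError("exog contains non-finite values")
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("endog must be binary 0/1")
        if uniq.size < 2:
            raise ValueError("endog is constant; the model is not identified")
        if np.unique(g).size < 10:
            raise ValueError("need at least 10 clusters")
        if n_nodes < 12:
            raise ValueError("use at least 12 quadrature nodes")

        if exog_names is None:
            exog_names = [f"x{i + 1}" for i in range(X.shape[1])]
        if add_constant:
            X = np.column_stack([np.ones(y.size), X])
            names = ["const", *exog_names]
        else:
            names = list(exog_names)

        order = np.argsort(g, kind="stable")
        self.endog = y[order]
        self.exog = X[order]
        self.groups = g[order]
        _, starts = np.unique(self.groups, return_index=True)
        self._starts = starts
        self.n_groups = starts.size
        gi = np.zeros(self.endog.size, dtype=int)
        gi[starts[1:]] = 1
        self._gi = np.cumsum(gi)
        self.nobs = y.size
        self.exog_names = names
        self.param_names = [*names, "sigma_u"]
        nodes, weights = hermgauss(n_nodes)
        self._nodes = nodes
        self._logw = np.log(weights)
        self.n_nodes = n_nodes

    # -- likelihood --------------------------------------------------------

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self._starts)

    def _modes(self, eta0: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mode and curvature scale of u_j for each cluster."""
        u = np.zeros(self.n_groups)
        y = self.endog
        gi = self._gi
        for _ in range(50):
            p = expit(eta0 + sigma * u[gi])
            grad = sigma * self._group_sum(y - p) - u
            hess = -(sigma**2) * self._group_sum(p * (1.0 - p)) - 1.0
            u -= grad / hess
            if np.max(np.abs(grad)) < 1e-10:
                break
        p = expit(eta0 + sigma * u[gi])
        hess = -(sigma**2) * self._group_sum(p * (1.0 - p)) - 1.0
        return u, 1.0 / np.sqrt(-hess)

    def loglike_obs(self, params: np.ndarray) -> np.ndarray:
        """Per-cluster log marginal likelihood contributions."""
        beta = params[:-1]
        sigma = params[-1]
        eta0 = self.exog @ beta
        y = self.endog
        if sigma < 1e-10:
            ll = y * eta0 - np.logaddexp(0.0, eta0)
            return self._group_sum(ll)
        mode, scale = self._modes(eta0, sigma)
        gi = self._gi
        # adaptive nodes u_jk = mode_j + sqrt(2) * scale_j * t_k
        contrib = np.empty((self.n_groups, self.n_nodes))
        for k, t in enumerate(self._nodes):
            u_k = mode + np.sqrt(2.0) * scale * t
            eta = eta0 + sigma * u_k[gi]
            ll = y * eta - np.logaddexp(0.0, eta)
            contrib[:, k] = self._group_sum(ll) - 0.5 * u_k**2 + t**2 + self._logw[k]
        return logsumexp(contrib, axis=1) + 0.5 * np.log(2.0) + np.log(scale) - 0.5 * np.log(2 * np.pi)

    def loglike(self, params: np.ndarray) -> float:
        return float(self.loglike_obs(params).sum())

    # -- estimation --------------------------------------------------------

    def fit(
        self,
        start_params: Optional[np.ndarray] = None,
        gtol: float = 1e-8,
        maxiter: int = 200,
    ) -> "RandomInterceptLogitResults":
        import statsmodels.api as sm

        if start_params is None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    logit0 = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=100)
                start_params = np.append(logit0.params, 0.5)
            except Exception:
                start_params = np.append(np.zeros(self.exog.shape[1]), 0.5)

        neg = lambda th: -self.loglike(th)
        bounds = [(None, None)] * (len(self.param_names) - 1) + [(0.0, None)]
        res = optimize.minimize(
            neg,
            start_params,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
        )
        if not res.success:
            # retry from the stall point with a coarser finite-difference step
            res2 = optimize.minimize(
                neg,
                res.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol, "eps": 1e-6},
            )
            if res2.fun <= res.fun:
                res = res2
        params = res.x
        converged = bool(res.success)
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
        if not converged:
            warnings.warn(
                f"random-intercept logit did not converge (gradient norm {grad_norm:.2e})",
                RuntimeWarning,
            )
        separation = bool(np.any(np.abs(params[:-1]) > _SEPARATION_BOUND))
        if separation:
            warnings.warn("possible (quasi-)separation: very large coefficients", RuntimeWarning)
        cov = self._sandwich_cov(params)
        return RandomInterceptLogitResults(
            model=self,
            params=params,
            cov_params_arr=cov,
            llf=-res.fun,
            converged=converged,
            grad_norm=grad_norm,
            separation=separation,
        )

    def _sandwich_cov(self, params: np.ndarray) -> np.ndarray:
        """Cluster-level sandwich covariance H^-1 (sum s_j s_j') H^-1."""
        at_boundary = params[-1] < 1e-6
        k = params.size - (1 if at_boundary else 0)

        def obj(th_free):
            th = np.append(th_free, params[-1]) if at_boundary else th_free
            return self.loglike_obs(th)

        def obj_total(th_free):
            return obj(th_free).sum()

        free = params[:-1] if at_boundary else params
        scores = numdiff.approx_fprime(free, obj, centered=True)  # (n_groups, k)
        hess = numdiff.approx_hess(free, obj_total)
        try:
            hinv = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            hinv = np.linalg.pinv(hess)
        meat = scores.T @ scores
        cov_free = hinv @ meat @ hinv
        if at_boundary:
            cov = np.zeros((params.size, params.size))
            cov[:k, :k] = cov_free
        else:
            cov = cov_free
        return cov


@dataclass
class RandomInterceptLogitResults:
    """Estimates, uncertainties and fit diagnostics for one fitted model."""

    model: RandomInterceptLogit
    params: np.ndarray
    cov_params_arr: np.ndarray
    llf: float
    converged: bool
    grad_norm: float
    separation: bool

    @property
    def param_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.model.param_names)

    @property
    def sigma_u(self) -> float:
        return float(self.params[-1])

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.clip(np.diag(self.cov_params_arr), 0.0, None))
        return pd.Series(se, index=self.model.param_names)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cov_params_arr, index=self.model.param_names, columns=self.model.param_names
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        se = self.bse.to_numpy()
        lo = self.params - z * se
        hi = self.params + z * se
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.model.param_names)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(beta) with Wald CIs, for the fixed effects (constant excluded)."""
        ci = self.conf_int(alpha)
        rows = []
        for name in self.model.exog_names:
            if name == "const":
                continue
            b = self.param_series[name]
            rows.append(
                {
                    "term": name,
                    "OR": np.exp(b),
                    "ci_lo": np.exp(ci.loc[name, "lower"]),
                    "ci_hi": np.exp(ci.loc[name, "upper"]),
                }
            )
        return pd.DataFrame(rows)

    def predict_fixed(self, exog: Optional[np.ndarray] = None) -> np.ndarray:
        """Fixed-part probabilities logistic(x'beta), random intercept at 0."""
        X = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        return expit(X @ self.params[:-1])

    def mz_r2(self, fixed_only: bool = True) -> float:
        """McKelvey & Zavoina pseudo-R2.

        fixed_only=True puts only Var(Xb) in the numerator while keeping
        sigma_u^2 in the latent denominator; fixed_only=False drops
        sigma_u^2 from the denominator entirely.
        """
        eta = self.model.exog @ self.params[:-1]
        v_fix = float(np.var(eta))
        if fixed_only:
            return v_fix / (v_fix + self.sigma_u**2 + LATENT_RESIDUAL_VAR)
        return v_fix / (v_fix + LATENT_RESIDUAL_VAR)

    def hosmer_lemeshow(self, g: int = 10) -> HosmerLemeshowResult:
        return hosmer_lemeshow_ml(self, self.model.endog, self.model.exog, g=g, add_constant=False)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-intercept logistic regression",
            f"  n obs: {self.model.nobs}   n clusters: {self.model.n_groups}   "
            f"log-lik: {self.llf:.3f}   converged: {self.converged}",
            f"  sigma_u: {self.sigma_u:.4f}   MZ R2 (fixed): {self.mz_r2():.4f}",
            f"{'term':<14}{'coef':>10}{'se':>10}{'OR':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.model.param_names:
            b = self.param_series[name]
            se = self.bse[name]
            orr = np.exp(b) if name != "sigma_u" else np.nan
            lines.append(
                f"{name:<14}{b:>10.4f}{se:>10.4f}{orr:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level surface
# ---------------------------------------------------------------------------


def fit_random_intercept_logit(
    y,
    X,
    cluster_ids,
    exog_names: Optional[Sequence[str]] = None,
    n_nodes: int = 15,
) -> RandomInterceptLogitResults:
    """Fit the random-intercept logistic model; see RandomInterceptLogit."""
    return RandomInterceptLogit(y, X, cluster_ids, exog_names=exog_names, n_nodes=n_nodes).fit()


def mz_r2_fixed(fit: RandomInterceptLogitResults, X: Optional[np.ndarray] = None) -> float:
    """Fixed-effects McKelvey & Zavoina R2 of a fitted model."""
    if X is None:
        return fit.mz_r2(fixed_only=True)
    X = np.asarray(X, dtype=float)
    if X.shape[1] == fit.params.size - 2:  # no constant supplied
        X = np.column_stack([np.ones(X.shape[0]), X])
    eta = X @ fit.params[:-1]
    v_fix = float(np.var(eta))
    return v_fix / (v_fix + fit.sigma_u**2 + LATENT_RESIDUAL_VAR)


def hosmer_lemeshow_ml(
    fit,
    y,
    X,
    g: int = 10,
    add_constant: bool = True,
) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow test on the fixed-part probabilities.

    Observations are split into g groups by deciles of the fixed-part
    predicted probability (ties go to the lower group; empty groups are
    merged, reducing the degrees of freedom), and

        chi2 = sum_g (O_g - E_g)^2 / (E_g * (1 - E_g / n_g))

    is referred to a chi-square with (groups - 2) df.  A small p-value
    indicates poor fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    if hasattr(fit, "predict_fixed"):
        X_arr = np.asarray(X, dtype=float)
        if add_constant and X_arr.shape[1] == fit.params.size - 2:
            X_arr = np.column_stack([np.ones(X_arr.shape[0]), X_arr])
        p_hat = fit.predict_fixed(X_arr)
    else:  # allow raw probabilities
        p_hat = np.asarray(fit, dtype=float).ravel()
    n = y.size
    if n < 10 * g:
        raise ValueError(f"need at least {10 * g} observations for {g} groups")
    # perfect degenerate fit: p in {0,1} matching y exactly
    if np.all((p_hat == 0) | (p_hat == 1)) and np.array_equal(p_hat, y):
        return HosmerLemeshowResult(0.0, 1.0, max(g - 2, 1))

    edges = np.quantile(p_hat, np.linspace(0, 1, g + 1)[1:-1])
    grp = np.searchsorted(edges, p_hat, side="left")  # ties to the lower group
    chi2 = 0.0
    n_groups = 0
    carry_y: list[np.ndarray] = []
    carry_p: list[np.ndarray] = []
    for gi in range(g):
        sel = grp == gi
        ys = np.concatenate([*(carry_y or [np.empty(0)]), y[sel]])
        ps = np.concatenate([*(carry_p or [np.empty(0)]), p_hat[sel]])
        if ys.size == 0:
            continue
        e = ps.sum()
        ng = ys.size
        var = e * (1.0 - e / ng)
        if var <= 0:
            # carry a degenerate group into the next one
            carry_y, carry_p = [ys], [ps]
            continue
        carry_y, carry_p = [], []
        chi2 += (ys.sum() - e) ** 2 / var
        n_groups += 1
    df = max(n_groups - 2, 1)
    pvalue = float(stats.chi2.sf(chi2, df))
    return HosmerLemeshowResult(float(chi2), pvalue, df)


_SOURCE_PREFIX = {"participants": "p", "annotators": "a", "algorithms": "g"}
MODEL_TERMS = ("brightness", "loudness", "attendance", "prior_drinks")


def table3_report(
    source_table: pd.DataFrame,
    g: int = 10,
    n_nodes: int = 15,
    sources: Sequence[str] = SOURCES,
) -> pd.DataFrame:
    """Nine random-intercept logistic models: 3 sources x 3 coarse locations.

    Expects a per-situation table with columns ``{p,a,g}_brightness``,
    ``{p,a,g}_loudness``, ``{p,a,g}_attendance``, plus ``alcohol``,
    ``prior_drinks``, ``location_coarse`` and ``participant_id``.  Rows are
    one per (source, location, term) with OR/CI, plus per-model R2 and
    Hosmer-Lemeshow columns.  A stratum whose model cannot be fitted is
    flagged and skipped rather than aborting the report.
    """
    rows = []
    for source in sources:
        pre = _SOURCE_PREFIX[source]
        for coarse in COARSE_LEVELS:
            sub = source_table[source_table["location_coarse"] == coarse]
            meta = {"source": source, "location": coarse, "n": len(sub)}
            try:
                y = sub["alcohol"].to_numpy()
                X = sub[
                    [f"{pre}_brightness", f"{pre}_loudness", f"{pre}_attendance", "prior_drinks"]
                ].to_numpy(dtype=float)
                fit = fit_random_intercept_logit(
                    y, X, sub["participant_id"].to_numpy(), exog_names=list(MODEL_TERMS), n_nodes=n_nodes
                )
                try:
                    hl = fit.hosmer_lemeshow(g=g)
                except ValueError:  # stratum too small for g groups
                    hl = HosmerLemeshowResult(np.nan, np.nan, 0)
                ors = fit.odds_ratios()
                for _, r in ors.iterrows():
                    rows.append(
                        {
                            **meta,
                            "term": r["term"],
                            "OR": r["OR"],
                            "ci_lo": r["ci_lo"],
                            "ci_hi": r["ci_hi"],
                            "sigma_u": fit.sigma_u,
                            "r2_mz": fit.mz_r2(),
                            "hl_chi2": hl.chi2,
                            "hl_p": hl.pvalue,
                            "converged": fit.converged,
                            "error": "",
                        }
                    )
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {
                        **meta,
                        "term": "",
                        "OR": np.nan,
                        "ci_lo": np.nan,
                        "ci_hi": np.nan,
                        "sigma_u": np.nan,
                        "r2_mz": np.nan,
                        "hl_chi2": np.nan,
                        "hl_p": np.nan,
                        "converged": False,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
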