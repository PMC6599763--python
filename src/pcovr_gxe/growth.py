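"""Multi-informant measurement model and sG×E latent growth curve model.

Two estimators:

* :class:`InformantFactorModel` — a single-factor measurement model for
  the 3-informant x 3-wave parenting indicators, fit by maximum
  likelihood (factor variance fixed to 1 for identification), with
  full-information likelihood over missing indicators.  Factor scores use
  the Bartlett (weighted least squares) estimator and are standardized.

* :class:`LatentGrowthSGxE` — a linear latent growth curve model for the
  three-wave outcome (intercept and slope factors, fixed time codes
  0,1,2 so the intercept is the wave-1 level), with both growth factors
  regressed on the standardized parenting factor score, all standardized
  polygenic component scores, the focal component x parenting product,
  and the covariates sex, age and family structure.  Estimation is
  maximum likelihood: an iterated-GLS closed-form path when all three
  waves are observed, and a quasi-Newton full-information path under
  missing outcomes.  Standard errors are Huber-White sandwich estimates
  over subject-level likelihood contributions, emulating robust ("MLR")
  inference.  Exogenous correlations among the components and between
  components and parenting (gene-environment correlation) are reported
  from sample moments of the standardized predictors, which is the
  maximum-likelihood estimate under the two-step factor-score approach.

The two-step latent-by-observed interaction (products of standardized
Bartlett scores) is transparent and fast but mildly attenuates
interaction coefficients when factor-score reliability is below 1; the
recovery tests quantify this.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "InformantFactorModel",
    "MeasurementFit",
    "LatentGrowthSGxE",
    "SgxeFit",
    "fit_measurement",
    "fit_lgcm_sgxe",
    "simple_slopes",
    "quadratic_robustness",
    "informant_sensitivity",
]

_RESID_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# measurement model


@dataclass
class MeasurementFit:
    loadings: np.ndarray
    residual_variances: np.ndarray
    means: np.ndarray
    factor_scores: np.ndarray  # standardized Bartlett scores
    score_reliability: float
    loglik: float
    converged: bool
    indicator_names: list[str]


class InformantFactorModel(BaseEstimator):
    """Single-factor ML measurement model with FIML over missing entries.

    Factor variance is fixed to 1; loadings, intercepts and residual
    variances are free.  ``transform`` returns standardized Bartlett
    factor scores computed from each row's observed indicators.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, indicators: pd.DataFrame | np.ndarray):
        X, names = _as_matrix(indicators)
        n, k = X.shape
        if k < 3:
            raise ValueError("a single-factor model needs at least 3 indicators")
        observed_var = np.nanvar(X, axis=0)
        if (observed_var <= 0).any():
            bad = names[int(np.argmax(observed_var <= 0))]
            raise ValueError(f"indicator {bad} has no variance")
        n_params = 3 * k
        if n <= n_params:
            raise ValueError(f"n={n} too small for {n_params} parameters")
        self.indicator_names_ = names

        if not np.isnan(X).any():
            lam, theta, mu, ll, conv = self._fit_complete(X)
        else:
            lam, theta, mu, ll, conv = self._fit_fiml(X)

        if (theta < _RESID_FLOOR).any():
            warnings.warn(
                "Heywood case: residual variance bounded at 1e-6", UserWarning
            )
            theta = np.maximum(theta, _RESID_FLOOR)
        # sign convention: loadings sum positive
        if lam.sum() < 0:
            lam = -lam
        self.loadings_ = lam
        self.residual_variances_ = theta
        self.means_ = mu
        self.loglik_ = ll
        self.converged_ = conv
        info = float(lam @ (lam / theta))
        self.score_reliability_ = info / (info + 1.0)
        self.factor_scores_ = self.transform(X)
        return self

    def _fit_complete(self, X: np.ndarray):
        from sklearn.decomposition import FactorAnalysis

        fa = FactorAnalysis(n_components=1, rotation=None, max_iter=self.max_iter, tol=self.tol)
        fa.fit(X)
        lam = fa.components_[0].copy()
        theta = np.maximum(fa.noise_variance_.copy(), _RESID_FLOOR)
        mu = X.mean(axis=0)
        ll = self._loglik(X, lam, theta, mu)
        return lam, theta, mu, ll, fa.n_iter_ < self.max_iter

    def _fit_fiml(self, X: np.ndarray):
        k = X.shape[1]
        # start values from complete rows if available, else marginal moments
        complete = ~np.isnan(X).any(axis=1)
        if complete.sum() > 3 * k:
            lam0, theta0, mu0, *_ = self._fit_complete(X[complete])
        else:
            mu0 = np.nanmean(X, axis=0)
            v = np.nanvar(X, axis=0)
            lam0 = np.sqrt(np.maximum(v * 0.5, 1e-3))
            theta0 = np.maximum(v - lam0**2, 0.05)
        x0 = np.concatenate([mu0, lam0, np.log(np.maximum(theta0, _RESID_FLOOR))])
        patterns = _missing_patterns(X)

        def nll(params):
            mu = params[:k]
            lam = params[k : 2 * k]
            theta = np.exp(params[2 * k :])
            total = 0.0
            for obs, rows in patterns:
                lam_o, th_o, mu_o = lam[obs], theta[obs], mu[obs]
                sigma = np.outer(lam_o, lam_o) + np.diag(th_o)
                try:
                    chol = np.linalg.cholesky(sigma)
                except np.linalg.LinAlgError:
                    return 1e12
                resid = X[np.ix_(rows, obs)] - mu_o
                sol = np.linalg.solve(chol, resid.T)
                quad = (sol**2).sum()
                logdet = 2 * np.log(np.diag(chol)).sum()
                total += 0.5 * (
                    len(rows) * (obs.sum() * np.log(2 * np.pi) + logdet) + quad
                )
            return total

        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", options={"maxiter": self.max_iter, "ftol": 1e-9}
        )
        mu = res.x[:k]
        lam = res.x[k : 2 * k]
        theta = np.exp(res.x[2 * k :])
        return lam, theta, mu, -res.fun, bool(res.success)

    @staticmethod
    def _loglik(X, lam, theta, mu):
        sigma = np.outer(lam, lam) + np.diag(theta)
        chol = np.linalg.cholesky(sigma)
        resid = X - mu
        sol = np.linalg.solve(chol, resid.T)
        logdet = 2 * np.log(np.diag(chol)).sum()
        n, k = X.shape
        return float(-0.5 * (n * (k * np.log(2 * np.pi) + logdet) + (sol**2).sum()))

    def transform(self, indicators) -> np.ndarray:
        """Standardized Bartlett factor scores from observed indicators."""
        X, names = _as_matrix(indicators)
        if names != self.indicator_names_ and len(names) == len(self.indicator_names_):
            names = self.indicator_names_
        lam, theta, mu = self.loadings_, self.residual_variances_, self.means_
        scores = np.full(X.shape[0], np.nan)
        for i in range(X.shape[0]):
            obs = ~np.isnan(X[i])
            if not obs.any():
                continue
            w = lam[obs] / theta[obs]
            denom = float(w @ lam[obs])
            if denom <= 0:
                continue
            scores[i] = float(w @ (X[i, obs] - mu[obs])) / denom
        good = ~np.isnan(scores)
        scores[good] = (scores[good] - scores[good].mean()) / scores[good].std()
        return scores

    def measurement_fit_(self) -> MeasurementFit:
        return MeasurementFit(
            loadings=self.loadings_,
            residual_variances=self.residual_variances_,
            means=self.means_,
            factor_scores=self.factor_scores_,
            score_reliability=self.score_reliability_,
            loglik=self.loglik_,
            converged=self.converged_,
            indicator_names=self.indicator_names_,
        )


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{i + 1}" for i in range(arr.shape[1])]


def _missing_patterns(X: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by their observed-entry pattern (rows with no
    observed entries are dropped)."""
    isobs = ~np.isnan(X)
    keys = {}
    for i, row in enumerate(isobs):
        if not row.any():
            continue
        keys.setdefault(row.tobytes(), []).append(i)
    out = []
    for key, rows in keys.items():
        obs = np.frombuffer(key, dtype=bool).copy()
        out.append((obs, np.asarray(rows)))
    return out


def fit_measurement(indicators) -> MeasurementFit:
    """Functional wrapper over :class:`InformantFactorModel`."""
    return InformantFactorModel().fit(indicators).measurement_fit_()


# ---------------------------------------------------------------------------
# latent growth curve sG×E model


@dataclass
class SgxeFit:
    coefficients: pd.DataFrame  # equation, predictor, b, se, beta, ci_low, ci_high, p
    growth_means: np.ndarray  # (mu_I, mu_S)
    growth_disturbance_cov: np.ndarray  # 2x2 Psi
    residual_variances: np.ndarray  # per-wave theta
    rge: pd.DataFrame  # exogenous correlations (components x {parenting, components})
    loglik: float
    converged: bool
    n_subjects: int
    predictor_names: list[str]
    predictor_sds: np.ndarray
    eta_sds: np.ndarray  # model-implied SDs of intercept and slope
    time_codes: tuple[float, ...] = (0.0, 1.0, 2.0)
    measurement: MeasurementFit | None = None
    model_se: pd.DataFrame | None = None  # non-robust SEs, for diagnostics

    def coef(self, equation: str, predictor: str) -> pd.Series:
        tab = self.coefficients
        row = tab[(tab["equation"] == equation) & (tab["predictor"] == predictor)]
        if row.empty:
            raise KeyError(f"no coefficient for {predictor!r} in {equation!r} equation")
        return row.iloc[0]


class LatentGrowthSGxE(BaseEstimator):
    """sG×E latent growth curve estimator (two-step factor-score interaction).

    Parameters
    ----------
    focal : component whose interaction with parenting enters the model.
    time_codes : factor loadings of the slope; (0, 1, 2) makes the
        intercept the wave-1 level.
    quadratic : include squared focal component and squared parenting as
        additional predictors of both growth factors.
    all_interactions : interact every component with parenting, not only
        the focal one.
    indicator_cols : parenting indicator columns (default: all ``par_*``).
    """

    def __init__(
        self,
        focal: str = "C1",
        time_codes: tuple[float, ...] = (0.0, 1.0, 2.0),
        quadratic: bool = False,
        all_interactions: bool = False,
        indicator_cols: list[str] | None = None,
        robust: bool = True,
        max_iter: int = 500,
    ):
        self.focal = focal
        self.time_codes = time_codes
        self.quadratic = quadratic
        self.all_interactions = all_interactions
        self.indicator_cols = indicator_cols
        self.robust = robust
        self.max_iter = max_iter

    # -- data assembly ------------------------------------------------------

    def _assemble(self, table: pd.DataFrame):
        outcome_cols = sorted(
            [c for c in table.columns if re.fullmatch(r"y_w\d+", c)],
            key=lambda c: int(c[3:]),
        )
        if len(outcome_cols) < 3:
            raise ValueError("need at least 3 outcome waves (columns y_w1, y_w2, y_w3)")
        comp_cols = sorted(
            [c for c in table.columns if re.fullmatch(r"C\d+", c)],
            key=lambda c: int(c[1:]),
        )
        if not comp_cols:
            raise ValueError("no component score columns (C1, C2, ...) found")
        if self.focal not in comp_cols:
            raise ValueError(f"focal component {self.focal!r} not among {comp_cols}")
        ind_cols = self.indicator_cols or [c for c in table.columns if c.startswith("par_")]
        if len(ind_cols) < 3:
            raise ValueError("need at least 3 parenting indicator columns")
        covar_cols = [c for c in ("sex", "age", "fam_structure") if c in table.columns]

        # complete-case on exogenous predictors; FIML on outcomes/indicators
        exog_ok = ~table[comp_cols + covar_cols].isna().any(axis=1)
        has_outcome = ~table[outcome_cols].isna().all(axis=1)
        has_indicator = ~table[ind_cols].isna().all(axis=1)
        keep = exog_ok & has_outcome & has_indicator
        df = table.loc[keep].reset_index(drop=True)

        measurement = InformantFactorModel().fit(df[ind_cols])
        parenting = measurement.factor_scores_

        comps = df[comp_cols].to_numpy(dtype=float)
        if (comps.std(axis=0) == 0).any():
            raise ValueError("zero-variance component score")
        comps = (comps - comps.mean(axis=0)) / comps.std(axis=0)

        names = ["Parenting"] + comp_cols
        cols = [parenting] + [comps[:, i] for i in range(len(comp_cols))]
        inter_targets = comp_cols if self.all_interactions else [self.focal]
        for c in inter_targets:
            cols.append(parenting * comps[:, comp_cols.index(c)])
            names.append(f"Parenting x {c}")
        if self.quadratic:
            focal_z = comps[:, comp_cols.index(self.focal)]
            if focal_z.std() == 0:
                raise ValueError("zero-variance focal component")
            cols.append(focal_z**2 - 1.0)
            names.append(f"{self.focal}^2")
            cols.append(parenting**2 - 1.0)
            names.append("Parenting^2")
        for c in covar_cols:
            cols.append(df[c].to_numpy(dtype=float))
            names.append({"sex": "Sex", "age": "Age", "fam_structure": "Family structure"}[c])
        Xp = np.column_stack(cols)
        Y = df[outcome_cols[:3]].to_numpy(dtype=float)

        rge = _exogenous_correlations(parenting, comps, comp_cols)
        return Xp, names, Y, measurement, rge, comps, comp_cols

    # -- estimation ---------------------------------------------------------

    def fit(self, table: pd.DataFrame):
        Xp, names, Y, measurement, rge, comps, comp_cols = self._assemble(table)
        n, q = Xp.shape[0], Xp.shape[1] + 1  # +1 intercept
        lam = np.column_stack([np.ones(3), np.asarray(self.time_codes, dtype=float)])
        X = np.column_stack([np.ones(n), Xp])

        complete = ~np.isnan(Y).any(axis=1)
        C0, psi0, th0 = _fast_ml(X[complete], Y[complete], lam)
        if complete.all():
            C, psi, th = C0, psi0, th0
            params = _pack(C, psi, th)
            ll = -_nll_complete(params, X, Y, lam, q)
            converged = True
        else:
            params0 = _pack(C0, psi0, th0)
            patterns = _missing_patterns(Y)

            def nll(p):
                return _nll_fiml(p, X, Y, lam, q, patterns)

            res = optimize.minimize(
                nll, params0, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": 1e-9},
            )
            params = res.x
            C, psi, th = _unpack(params, q)
            ll = -res.fun
            converged = bool(res.success)
            if not converged:
                warnings.warn("FIML optimizer did not report convergence", UserWarning)

        # sandwich (and model-based) standard errors
        patterns = _missing_patterns(Y)

        def per_subject_ll(p):
            return _subject_logliks(p, X, Y, lam, q, patterns)

        def total_nll(p):
            return -per_subject_ll(p).sum()

        A = _numeric_hessian(total_nll, params)
        try:
            A_inv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "observed-data information matrix is singular"
            ) from exc
        if self.robust:
            S = _numeric_jacobian(per_subject_ll, params)
            B = S.T @ S
            V = A_inv @ B @ A_inv
        else:
            V = A_inv
        if np.diag(V).min() < 0 or np.diag(A_inv).min() < 0:
            warnings.warn(
                "non-positive-definite information: SEs may be unreliable", UserWarning
            )
        se_all = np.sqrt(np.abs(np.diag(V)))
        se_model = np.sqrt(np.abs(np.diag(A_inv)))

        # assemble the coefficient table
        sds_x = Xp.std(axis=0)
        eta_sd = np.empty(2)
        for eq in range(2):
            lin = X @ C[eq]
            eta_sd[eq] = np.sqrt(lin.var() + psi[eq, eq])
        rows = []
        model_rows = []
        for eq, eq_name in enumerate(("intercept", "slope")):
            for jx, name in enumerate(names):
                idx = eq * q + (jx + 1)
                b = C[eq, jx + 1]
                se = se_all[idx]
                beta = b * sds_x[jx] / eta_sd[eq]
                rows.append(
                    {
                        "equation": eq_name,
                        "predictor": name,
                        "b": b,
                        "se": se,
                        "beta": beta,
                        "ci_low": b - 1.96 * se,
                        "ci_high": b + 1.96 * se,
                        "p": 2 * stats.norm.sf(abs(b) / se) if se > 0 else np.nan,
                    }
                )
                model_rows.append(
                    {"equation": eq_name, "predictor": name, "se_model": se_model[idx]}
                )

        self.fit_ = SgxeFit(
            coefficients=pd.DataFrame(rows),
            growth_means=C[:, 0].copy(),
            growth_disturbance_cov=psi,
            residual_variances=th,
            rge=rge,
            loglik=float(ll),
            converged=converged,
            n_subjects=n,
            predictor_names=names,
            predictor_sds=sds_x,
            eta_sds=eta_sd,
            time_codes=tuple(float(t) for t in self.time_codes),
            measurement=measurement.measurement_fit_(),
            model_se=pd.DataFrame(model_rows),
        )
        self.coefficients_ = self.fit_.coefficients
        self.loglik_ = float(ll)
        self.converged_ = converged
        return self


def _exogenous_correlations(parenting, comps, comp_cols) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(comp_cols):
        rows.append(
            {
                "pair": f"{c} ~ Parenting",
                "r": float(np.corrcoef(comps[:, i], parenting)[0, 1]),
            }
        )
    for i in range(len(comp_cols)):
        for jx in range(i + 1, len(comp_cols)):
            rows.append(
                {
                    "pair": f"{comp_cols[i]} ~ {comp_cols[jx]}",
                    "r": float(np.corrcoef(comps[:, i], comps[:, jx])[0, 1]),
                }
            )
    return pd.DataFrame(rows)


# -- likelihood machinery ----------------------------------------------------


def _pack(C, psi, th) -> np.ndarray:
    return np.concatenate([C.ravel(), [psi[0, 0], psi[0, 1], psi[1, 1]], th])


def _unpack(params: np.ndarray, q: int):
    C = params[: 2 * q].reshape(2, q)
    psi = np.array(
        [[params[2 * q], params[2 * q + 1]], [params[2 * q + 1], params[2 * q + 2]]]
    )
    th = params[2 * q + 3 : 2 * q + 6]
    return C, psi, th


def _sigma(psi, th, lam) -> np.ndarray:
    return lam @ psi @ lam.T + np.diag(th)


def _fast_ml(X, Y, lam, max_iter: int = 200, tol: float = 1e-12):
    """Iterated-GLS maximum likelihood for complete three-wave outcomes."""
    xtx = X.T @ X
    B_ols = np.linalg.solve(xtx, X.T @ Y).T  # 3 x q
    C = np.linalg.lstsq(lam, B_ols, rcond=None)[0]  # 2 x q
    n = X.shape[0]
    psi = np.eye(2) * 0.1
    th = np.ones(3) * 0.1
    A = _moment_design(lam)
    for _ in range(max_iter):
        E = Y - X @ C.T @ lam.T
        S = E.T @ E / n
        u = np.linalg.solve(A, _vech(S))
        psi_new = np.array([[u[0], u[1]], [u[1], u[2]]])
        th_new = np.maximum(u[3:], 1e-10)
        # keep Psi positive semidefinite (floor eigenvalues)
        w, v = np.linalg.eigh(psi_new)
        psi_new = (v * np.maximum(w, 1e-10)) @ v.T
        sigma = _sigma(psi_new, th_new, lam)
        sig_inv = np.linalg.inv(sigma)
        M = np.linalg.inv(lam.T @ sig_inv @ lam) @ lam.T @ sig_inv
        C_new = (M @ B_ols).reshape(2, -1)
        delta = np.abs(C_new - C).max()
        C, psi, th = C_new, psi_new, th_new
        if delta < tol:
            break
    return C, psi, th


def _moment_design(lam) -> np.ndarray:
    """Linear map (psiII, psiIS, psiSS, th1..3) -> vech(Sigma)."""
    rows = []
    idx = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    for s, t in idx:
        row = [
            1.0,
            lam[s, 1] + lam[t, 1],
            lam[s, 1] * lam[t, 1],
            1.0 if (s == t and s == 0) else 0.0,
            1.0 if (s == t and s == 1) else 0.0,
            1.0 if (s == t and s == 2) else 0.0,
        ]
        rows.append(row)
    return np.asarray(rows)


def _vech(S) -> np.ndarray:
    return np.array([S[0, 0], S[0, 1], S[0, 2], S[1, 1], S[1, 2], S[2, 2]])


def _nll_complete(params, X, Y, lam, q) -> float:
    C, psi, th = _unpack(params, q)
    sigma = _sigma(psi, th, lam)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e12
    E = Y - X @ C.T @ lam.T
    sol = np.linalg.solve(chol, E.T)
    logdet = 2 * np.log(np.diag(chol)).sum()
    n = X.shape[0]
    return float(0.5 * (n * (3 * np.log(2 * np.pi) + logdet) + (sol**2).sum()))


def _nll_fiml(params, X, Y, lam, q, patterns) -> float:
    C, psi, th = _unpack(params, q)
    total = 0.0
    for obs, rows in patterns:
        lam_o = lam[obs]
        sigma = lam_o @ psi @ lam_o.T + np.diag(th[obs])
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        E = Y[np.ix_(rows, obs)] - X[rows] @ C.T @ lam_o.T
        sol = np.linalg.solve(chol, E.T)
        logdet = 2 * np.log(np.diag(chol)).sum()
        total += 0.5 * (
            len(rows) * (obs.sum() * np.log(2 * np.pi) + logdet) + (sol**2).sum()
        )
    return float(total)


def _subject_logliks(params, X, Y, lam, q, patterns) -> np.ndarray:
    C, psi, th = _unpack(params, q)
    out = np.zeros(X.shape[0])
    for obs, rows in patterns:
        lam_o = lam[obs]
        sigma = lam_o @ psi @ lam_o.T + np.diag(th[obs])
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            out[rows] = -1e8
            continue
        E = Y[np.ix_(rows, obs)] - X[rows] @ C.T @ lam_o.T
        sol = np.linalg.solve(chol, E.T)
        logdet = 2 * np.log(np.diag(chol)).sum()
        out[rows] = -0.5 * (
            obs.sum() * np.log(2 * np.pi) + logdet + (sol**2).sum(axis=0)
        )
    return out


def _numeric_jacobian(fn, x, eps: float = 1e-6) -> np.ndarray:
    f0 = fn(x)
    J = np.empty((f0.shape[0], x.shape[0]))
    for jx in range(x.shape[0]):
        h = eps * (1 + abs(x[jx]))
        xp = x.copy()
        xp[jx] += h
        J[:, jx] = (fn(xp) - f0) / h
    return J


def _numeric_hessian(fn, x, eps: float = 1e-5) -> np.ndarray:
    p = x.shape[0]
    H = np.empty((p, p))
    hs = eps * (1 + np.abs(x))
    f0 = fn(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xp = x.copy()
        xp[i] += hs[i]
        fp[i] = fn(xp)
        xp[i] -= 2 * hs[i]
        fm[i] = fn(xp)
    for i in range(p):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hs[i] ** 2
        for jx in range(i + 1, p):
            xpp = x.copy()
            xpp[i] += hs[i]
            xpp[jx] += hs[jx]
            xmm = x.copy()
            xmm[i] -= hs[i]
            xmm[jx] -= hs[jx]
            H[i, jx] = H[jx, i] = (
                fn(xpp) - fp[i] - fp[jx] + 2 * f0 - fm[i] - fm[jx] + fn(xmm)
            ) / (2 * hs[i] * hs[jx])
    return H


# ---------------------------------------------------------------------------
# functional wrappers and auxiliary analyses


def fit_lgcm_sgxe(table: pd.DataFrame, focal: str = "C1", **kwargs) -> SgxeFit:
    return LatentGrowthSGxE(focal=focal, **kwargs).fit(table).fit_


def simple_slopes(fit: SgxeFit, levels: tuple[float, float] = (-1.0, 1.0)) -> pd.DataFrame:
    """Model-implied outcome means per wave for the four {component level} x
    {parenting level} cells, other predictors at their means (zero effect
    contribution: means enter through the fitted intercept only)."""
    names = fit.predictor_names
    focal = next(
        (nm.split(" x ")[1] for nm in names if nm.startswith("Parenting x ")), None
    )
    if focal is None:
        raise ValueError("fit contains no Parenting x component interaction")
    rows = []
    for g in levels:
        for e in levels:
            eta = fit.growth_means.copy()
            for eq in range(2):
                coefs = dict(
                    zip(
                        names,
                        fit.coefficients[fit.coefficients["equation"] == ("intercept", "slope")[eq]][
                            "b"
                        ].to_numpy(),
                    )
                )
                eta[eq] += (
                    coefs.get("Parenting", 0.0) * e
                    + coefs.get(focal, 0.0) * g
                    + coefs.get(f"Parenting x {focal}", 0.0) * g * e
                )
            for w, t in enumerate(fit.time_codes):
                rows.append(
                    {
                        "component_level": g,
                        "parenting_level": e,
                        "wave": w + 1,
                        "predicted": eta[0] + t * eta[1],
                    }
                )
    return pd.DataFrame(rows)


def quadratic_robustness(table: pd.DataFrame, focal: str = "C1", **kwargs) -> dict:
    """Refit with squared focal-component and squared-parenting predictors
    and report whether the interaction's significance classification moves."""
    base = fit_lgcm_sgxe(table, focal=focal, quadratic=False, **kwargs)
    quad = fit_lgcm_sgxe(table, focal=focal, quadratic=True, **kwargs)
    name = f"Parenting x {focal}"
    out = {"base": base, "quadratic": quad, "interaction": {}}
    for eq in ("intercept", "slope"):
        p0 = base.coef(eq, name)["p"]
        p1 = quad.coef(eq, name)["p"]
        out["interaction"][eq] = {
            "p_base": float(p0),
            "p_quadratic": float(p1),
            "significant_base": bool(p0 < 0.05),
            "significant_quadratic": bool(p1 < 0.05),
            "classification_changed": bool((p0 < 0.05) != (p1 < 0.05)),
        }
    return out


def informant_sensitivity(
    table: pd.DataFrame, focal: str = "C1", informants=("self", "mother", "father"), **kwargs
) -> dict[str, SgxeFit]:
    """Refit using only one informant's wave-indicators for the parenting
    factor; informants with < 2 usable indicators are skipped."""
    fits: dict[str, SgxeFit] = {}
    for inf in informants:
        cols = [c for c in table.columns if c.startswith(f"par_{inf}_")]
        usable = [c for c in cols if table[c].notna().sum() > 0]
        if len(usable) < 2:
            warnings.warn(f"informant {inf!r} has < 2 usable indicators; skipped", UserWarning)
            continue
        fits[inf] = fit_lgcm_sgxe(table, focal=focal, indicator_cols=usable, **kwargs)
    return fits
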