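"""Negative-binomial mixed models of cell usage against visual depth.

The model sequence mirrors the analysis design:

* M0 — intercept-only NB2 model;
* M1 — VMD as a fixed effect;
* M2 — M1 plus a Normal random intercept per playground zone, absorbing
  zone-level baseline differences (rota, equipment attraction);
* M3 — group-specific VMD slopes (one per gender x year-group cell) and
  group baseline offsets, plus the zone random intercept.

Family is NB2: Var(y) = mu + mu^2 / theta.  For the mixed models the
zone random intercept is integrated out by adaptive Gauss-Hermite
quadrature (default 15 nodes; 1 node is the Laplace approximation).
Group slopes are parameterised directly (one slope per group rather than
reference + interaction contrasts), so each slope's Wald p-value, its
incidence rate ratio exp(beta_g), and the percent change
100*(IRR - 1) per 1-unit VMD increase read off the fit directly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats as sps
from scipy.special import gammaln, digamma

logger = logging.getLogger("playvis")

_ETA_CLIP = 50.0
MODEL_NAMES = ("M0", "M1", "M2", "M3")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the nested M0-M3 sequence."""

    name: str
    vmd: bool
    group_terms: bool
    random_zone: bool

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")


M0 = ModelSpec("M0", vmd=False, group_terms=False, random_zone=False)
M1 = ModelSpec("M1", vmd=True, group_terms=False, random_zone=False)
M2 = ModelSpec("M2", vmd=True, group_terms=False, random_zone=True)
M3 = ModelSpec("M3", vmd=True, group_terms=True, random_zone=True)
MODEL_SEQUENCE = (M0, M1, M2, M3)


def model_spec(name: str) -> ModelSpec:
    return {m.name: m for m in MODEL_SEQUENCE}[name]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _design(spec: ModelSpec, data: pd.DataFrame):
    """Design matrix and parameter names for the mean model."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    groups: list[str] = []
    if spec.group_terms:
        groups = sorted(data["group"].astype(str).unique())
        gcodes = data["group"].astype(str).to_numpy()
        for g in groups[1:]:
            cols.append((gcodes == g).astype(float))
            names.append(f"offset[{g}]")
        for g in groups:
            cols.append(np.where(gcodes == g, data["vmd"].to_numpy(float), 0.0))
            names.append(f"slope[{g}]")
    elif spec.vmd:
        cols.append(data["vmd"].to_numpy(float))
        names.append("slope")
    return np.column_stack(cols), names, groups


def _data_hash(y, vmd, zone, group) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(y, dtype=np.float64).tobytes())
    h.update(np.ascontiguousarray(vmd, dtype=np.float64).tobytes())
    h.update("|".join(map(str, zone)).encode())
    h.update("|".join(map(str, group)).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _nb_mu_terms(y, theta, eta_u):
    """mu-dependent part of the NB2 log-pmf,
    y*log(mu/(theta+mu)) + theta*log(theta/(theta+mu)), written with
    log1p so the Poisson limit (theta -> infinity) stays accurate.

    ``eta_u`` is the linear predictor including the random intercept;
    broadcasting over quadrature nodes is supported.
    """
    eta_u = np.clip(eta_u, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta_u)
    return y * eta_u - y * np.log(theta + mu) - theta * np.log1p(mu / theta)


def _lgamma_ratio(y, theta):
    """log Gamma(y + theta) - log Gamma(theta), stable for large theta.

    For very large theta the two gammaln values cancel catastrophically;
    counts are integers, so the ratio is then the exact finite sum
    sum_{j<y} log(theta + j).
    """
    ymax = int(y.max()) if len(y) else 0
    if theta <= 1e6 or ymax > 1000:
        return gammaln(y + theta) - gammaln(theta)
    out = np.zeros_like(y, dtype=float)
    for j in range(ymax):
        out += np.where(y > j, np.log(theta + j), 0.0)
    return out


class _MarginalNLL:
    """Negative marginal log-likelihood with analytic gradient.

    The per-zone integral over the random intercept is evaluated with
    adaptive Gauss-Hermite quadrature: nodes are centred on the
    conditional mode and scaled by the conditional curvature each
    evaluation.  The gradient holds the adaptation fixed — the exact
    integral does not depend on the adaptation point, so the neglected
    terms are of the order of the quadrature error itself.
    """

    def __init__(self, X, y, zone_codes, n_zones, random_zone, n_quad=15):
        self.X = X
        self.y = y.astype(float)
        self.random = random_zone
        self.n_quad = n_quad
        if random_zone:
            self.zidx = [np.flatnonzero(zone_codes == z) for z in range(n_zones)]
            self.modes = np.zeros(n_zones)
            xk, wk = hermgauss(n_quad)
            self.xk = xk
            self.logwk = np.log(wk) + xk**2
        self.n_zones = n_zones

    # -- conditional mode per zone ------------------------------------
    def _zone_mode(self, z, eta, theta, sig2):
        y = self.y[self.zidx[z]]
        eta_z = eta[self.zidx[z]]
        u = self.modes[z]

        def grad_hess(u):
            mu = np.exp(np.clip(eta_z + u, -_ETA_CLIP, _ETA_CLIP))
            frac = mu / (theta + mu)
            g = np.sum(y - (y + theta) * frac) - u / sig2
            h = -np.sum((y + theta) * theta * frac / (theta + mu)) - 1.0 / sig2
            return g, h

        for _ in range(50):
            g, h = grad_hess(u)
            step = -g / h
            # dampen huge Newton steps
            if abs(step) > 5.0:
                step = np.sign(step) * 5.0
            u_new = u + step
            if abs(step) < 1e-11:
                u = u_new
                break
            u = u_new
        self.modes[z] = u
        _, h = grad_hess(u)
        s = 1.0 / np.sqrt(-h)
        return u, s

    # -- objective ------------------------------------------------------
    def value_and_grad(self, params):
        p = self.X.shape[1]
        beta = params[:p]
        theta = np.exp(params[p])
        eta = self.X @ beta
        y = self.y
        const = np.sum(_lgamma_ratio(y, theta) - gammaln(y + 1))
        dconst_dlogtheta = theta * np.sum(digamma(y + theta) - digamma(theta))

        if not self.random:
            ll = const + np.sum(_nb_mu_terms(y, theta, eta))
            mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
            frac = mu / (theta + mu)
            r = y - (y + theta) * frac
            gbeta = self.X.T @ r
            glogtheta = dconst_dlogtheta + theta * np.sum(
                1.0 - np.log1p(mu / theta) - (y + theta) / (theta + mu)
            )
            grad = np.concatenate([gbeta, [glogtheta]])
            return -ll, -grad

        sigma = np.exp(params[p + 1])
        sig2 = sigma**2
        ll = const
        r = np.zeros(len(y))
        glogtheta_mu = 0.0
        glogsigma = 0.0
        for z in range(self.n_zones):
            idx = self.zidx[z]
            yz = y[idx]
            eta_z = eta[idx]
            uhat, s = self._zone_mode(z, eta, theta, sig2)
            uk = uhat + np.sqrt(2.0) * s * self.xk  # (nq,)
            eta_uk = eta_z[:, None] + uk[None, :]
            terms = _nb_mu_terms(yz[:, None], theta, eta_uk)  # (nz, nq)
            gk = terms.sum(axis=0) - 0.5 * np.log(2 * np.pi * sig2) - uk**2 / (2 * sig2)
            logint_k = self.logwk + gk
            m = logint_k.max()
            wexp = np.exp(logint_k - m)
            sw = wexp.sum()
            ll += m + np.log(sw) + 0.5 * np.log(2.0) + np.log(s)
            pk = wexp / sw  # posterior node weights

            mu_k = np.exp(np.clip(eta_uk, -_ETA_CLIP, _ETA_CLIP))
            frac_k = mu_k / (theta + mu_k)
            r[idx] = yz - (yz + theta) * (frac_k @ pk)
            glogtheta_mu += theta * np.sum(
                (1.0 - np.log1p(mu_k / theta) - (yz[:, None] + theta) / (theta + mu_k)) @ pk
            )
            glogsigma += float(pk @ (uk**2 / sig2 - 1.0))

        gbeta = self.X.T @ r
        glogtheta = dconst_dlogtheta + glogtheta_mu
        grad = np.concatenate([gbeta, [glogtheta, glogsigma]])
        return -ll, -grad

    def loglik(self, params) -> float:
        return -self.value_and_grad(params)[0]


def marginal_loglik(
    data: pd.DataFrame,
    spec: ModelSpec,
    beta: np.ndarray,
    theta: float,
    sigma: float = 0.0,
    n_quad: int = 15,
) -> float:
    """Marginal NB2 log-likelihood at fixed parameters (for cross-checks)."""
    X, _, _ = _design(spec, data)
    y = data["count"].to_numpy(float)
    zones = sorted(data["zone"].astype(str).unique())
    zcodes = data["zone"].astype(str).map({z: i for i, z in enumerate(zones)}).to_numpy()
    nll = _MarginalNLL(X, y, zcodes, len(zones), spec.random_zone and sigma > 0, n_quad)
    params = np.concatenate([np.asarray(beta, float), [np.log(theta)]])
    if spec.random_zone and sigma > 0:
        params = np.concatenate([params, [np.log(sigma)]])
    return nll.loglik(params)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    spec: ModelSpec
    param_names: list[str]
    params: np.ndarray  # internal scale: beta..., log(theta)[, log(sigma)]
    cov: np.ndarray  # covariance on the internal scale
    loglik: float
    n_obs: int
    k_params: int
    groups: list[str]
    zones: list[str]
    vmd_range: tuple[float, float]
    data_hash: str
    converged: bool
    sigma_boundary: bool = False
    message: str = ""
    zone_modes: dict = field(default_factory=dict)
    n_quad: int = 15

    @property
    def p_mean(self) -> int:
        extra = 2 if self.spec.random_zone else 1
        return len(self.params) - extra

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.params[: self.p_mean], index=self.param_names[: self.p_mean])

    @property
    def beta_se(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov)[: self.p_mean])
        return pd.Series(se, index=self.param_names[: self.p_mean])

    @property
    def theta(self) -> float:
        return float(np.exp(self.params[self.p_mean]))

    @property
    def sigma_zone(self) -> float:
        if not self.spec.random_zone:
            return 0.0
        return float(np.exp(self.params[self.p_mean + 1]))

    @property
    def sigma2_zone(self) -> float:
        return self.sigma_zone**2

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + np.log(self.n_obs) * self.k_params

    @property
    def deviance(self) -> float:
        """-2 logLik; differences along the nested sequence are LRT statistics."""
        return -2.0 * self.loglik

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.clip(np.diag(self.cov), 0, None))
        zval = self.params / np.where(se > 0, se, np.nan)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": se,
                "z": zval,
                "p": 2 * sps.norm.sf(np.abs(zval)),
            },
            index=self.param_names,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "coefficients": {n: float(v) for n, v in zip(self.param_names, self.params)},
            "se": {
                n: float(s)
                for n, s in zip(self.param_names, np.sqrt(np.clip(np.diag(self.cov), 0, None)))
            },
            "theta": self.theta,
            "sigma2_zone": self.sigma2_zone,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
        }


def _fd_hessian(gradfun, x, h=1e-5):
    d = len(x)
    H = np.zeros((d, d))
    for j in range(d):
        step = h * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        H[:, j] = (gradfun(xp) - gradfun(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_quad: int = 15,
    start: np.ndarray | None = None,
    maxiter: int = 500,
) -> ModelFit:
    """Maximise the NB2 marginal likelihood for one model of the sequence.

    ``data`` needs columns ``count``, ``vmd``, ``group``, ``zone``
    (``vmd``/``group`` are only used when the spec requires them).
    Non-convergence is flagged on the returned fit, never silent.
    """
    required = {"count", "zone"} | ({"vmd"} if spec.vmd else set()) | (
        {"group"} if spec.group_terms else set()
    )
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns {sorted(missing)}")
    y = data["count"].to_numpy(float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not (y > 0).any():
        raise ValueError("all counts are zero; the model is degenerate")
    zones = sorted(data["zone"].astype(str).unique())
    if spec.random_zone and len(zones) < 2:
        raise ValueError("random zone intercept requires >= 2 zones")
    zcodes = data["zone"].astype(str).map({z: i for i, z in enumerate(zones)}).to_numpy()
    X, names, groups = _design(spec, data)
    vmd_vals = data["vmd"].to_numpy(float) if "vmd" in data.columns else np.array([np.nan])

    nll = _MarginalNLL(X, y, zcodes, len(zones), spec.random_zone, n_quad)

    if start is None:
        # crude but robust start: log-linear least squares + moderate dispersion
        zlog = np.log(y + 0.5)
        beta0, *_ = np.linalg.lstsq(X, zlog, rcond=None)
        start = np.concatenate(
            [beta0, [0.0] + ([np.log(0.3)] if spec.random_zone else [])]
        )

    log_sigma_floor = np.log(1e-4)
    bounds = [(None, None)] * X.shape[1] + [(-10.0, 15.0)]
    if spec.random_zone:
        bounds.append((log_sigma_floor, 3.0))

    res = optimize.minimize(
        nll.value_and_grad,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
    )
    converged = bool(res.success)
    if not converged:
        # line searches can stall on the last digit of the quadrature
        # approximation; a tiny gradient means we are at the optimum anyway
        gnorm = float(np.max(np.abs(res.jac)))
        if gnorm < 1e-3 * max(1.0, abs(res.fun)):
            converged = True
        else:  # one restart from the stall point
            res2 = optimize.minimize(
                nll.value_and_grad,
                res.x,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-5},
            )
            if res2.fun <= res.fun:
                res = res2
            gnorm = float(np.max(np.abs(res.jac)))
            converged = bool(res.success) or gnorm < 1e-3 * max(1.0, abs(res.fun))
    params = res.x
    loglik = -float(res.fun)

    sigma_boundary = bool(
        spec.random_zone and params[-1] <= log_sigma_floor + 1e-6
    )
    if sigma_boundary:
        logger.warning(
            "%s: zone variance estimated at the boundary (sigma^2 ~ 0)", spec.name
        )

    gradfun = lambda x: nll.value_and_grad(x)[1]
    H = _fd_hessian(gradfun, params)
    try:
        cov = np.linalg.inv(H)
        if (np.diag(cov) <= 0).any():
            raise np.linalg.LinAlgError("non-PD Hessian")
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        logger.warning("%s: Hessian not positive definite; using pseudo-inverse", spec.name)

    k = X.shape[1] + 1 + (1 if spec.random_zone else 0)
    fit = ModelFit(
        spec=spec,
        param_names=names + ["log_theta"] + (["log_sigma"] if spec.random_zone else []),
        params=params,
        cov=cov,
        loglik=loglik,
        n_obs=len(y),
        k_params=k,
        groups=groups,
        zones=zones,
        vmd_range=(float(np.nanmin(vmd_vals)), float(np.nanmax(vmd_vals))),
        data_hash=_data_hash(
            y,
            np.nan_to_num(data["vmd"].to_numpy(float)) if "vmd" in data.columns else np.zeros(len(y)),
            zcodes,
            data["group"].tolist() if "group" in data.columns else [""] * len(y),
        ),
        converged=converged,
        sigma_boundary=sigma_boundary,
        message=str(res.message),
        zone_modes={z: float(m) for z, m in zip(zones, getattr(nll, "modes", np.zeros(0)))},
        n_quad=n_quad,
    )
    if not converged:
        logger.warning("%s did not converge: %s", spec.name, res.message)
    return fit


def fit_sequence(data: pd.DataFrame, n_quad: int = 15) -> dict[str, ModelFit]:
    """Fit M0-M3 on the same data; returns name -> fit."""
    return {m.name: fit_model(m, data, n_quad=n_quad) for m in MODEL_SEQUENCE}


# ---------------------------------------------------------------------------
# Overdispersion / zero inflation diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DispersionDiagnostics:
    pearson_ratio: float
    zero_observed: float
    zero_expected: float
    overdispersed: bool
    zero_inflated: bool

    OVERDISPERSION_THRESHOLD = 1.5
    ZERO_EXCESS_THRESHOLD = 0.02


def check_overdispersion(data: pd.DataFrame) -> DispersionDiagnostics:
    """Pearson dispersion of a Poisson fit with the M1 mean structure,
    plus observed vs Poisson-implied zero shares.

    A ratio well above 1 (> 1.5 by convention here) indicates
    overdispersion and motivates the NB2 family; an observed zero share
    exceeding the Poisson-implied share by more than 2 points flags
    possible zero inflation.
    """
    import statsmodels.api as sm

    y = data["count"].to_numpy(float)
    if len(y) < 2:
        raise ValueError("need at least 2 rows")
    if not (y > 0).any():
        raise ValueError("all counts are zero; dispersion undefined")
    X = np.column_stack([np.ones(len(y)), data["vmd"].to_numpy(float)])
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    df_resid = len(y) - X.shape[1]
    ratio = float(fit.pearson_chi2 / df_resid)
    if ratio < 1e-12:
        logger.warning("Pearson dispersion ratio ~ 0: counts show no variability")
    mu = np.asarray(fit.mu)
    zero_obs = float(np.mean(y == 0))
    zero_exp = float(np.mean(np.exp(-mu)))
    return DispersionDiagnostics(
        pearson_ratio=ratio,
        zero_observed=zero_obs,
        zero_expected=zero_exp,
        overdispersed=ratio > DispersionDiagnostics.OVERDISPERSION_THRESHOLD,
        zero_inflated=zero_obs - zero_exp > DispersionDiagnostics.ZERO_EXCESS_THRESHOLD,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models(fits: list[ModelFit], alpha: float = 0.05) -> pd.DataFrame:
    """Likelihood-ratio comparison along the nested sequence.

    For each adjacent pair: LRT = 2 * delta logLik with df = delta
    parameters; the test that adds the zone variance (sigma^2 = 0 on the
    boundary of its space) uses the 50:50 chi-square mixture p-value.
    The ``selected`` column marks the lowest-AIC model among those
    justified by consecutive significant LRT steps.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    fits = sorted(fits, key=lambda f: MODEL_NAMES.index(f.spec.name))
    h0 = fits[0].data_hash
    for f in fits[1:]:
        if f.data_hash != h0:
            raise ValueError("fits were not computed on identical data")
    for a, b in zip(fits[:-1], fits[1:]):
        if b.k_params <= a.k_params:
            raise ValueError(f"{b.spec.name} is not an extension of {a.spec.name}")

    rows = []
    justified = {fits[0].spec.name}
    chain_ok = True
    for prev, cur in zip([None] + fits[:-1], fits):
        row = {
            "model": cur.spec.name,
            "loglik": cur.loglik,
            "k": cur.k_params,
            "aic": cur.aic,
            "bic": cur.bic,
        }
        if prev is not None:
            lrt = 2.0 * (cur.loglik - prev.loglik)
            df = cur.k_params - prev.k_params
            boundary = cur.spec.random_zone and not prev.spec.random_zone and df == 1
            if lrt < -1e-6:
                logger.warning(
                    "logLik decreased from %s to %s (%.4g); convergence suspect",
                    prev.spec.name,
                    cur.spec.name,
                    lrt,
                )
            lrt_c = max(lrt, 0.0)
            if boundary:
                p = 1.0 if lrt_c == 0 else 0.5 * sps.chi2.sf(lrt_c, 1)
            else:
                p = sps.chi2.sf(lrt_c, df)
            row.update(
                {
                    "delta_aic": cur.aic - prev.aic,
                    "delta_bic": cur.bic - prev.bic,
                    "lrt": lrt,
                    "lrt_df": df,
                    "lrt_p": p,
                    "boundary_mixture": boundary,
                }
            )
            if chain_ok and p < alpha:
                justified.add(cur.spec.name)
            else:
                chain_ok = False
        rows.append(row)
    report = pd.DataFrame(rows).set_index("model")
    best = report.loc[sorted(justified), "aic"].idxmin()
    report["selected"] = report.index == best
    return report


# ---------------------------------------------------------------------------
# Group effects and predictions
# ---------------------------------------------------------------------------

@dataclass
class GroupSlopeEffect:
    group: str
    slope: float
    se: float
    p: float
    irr: float
    pct_change: float


def group_effects(fit: ModelFit) -> list[GroupSlopeEffect]:
    """Per-group VMD slope, Wald p, IRR = exp(slope), percent change.

    Requires a converged M3-style fit (one directly-parameterised slope
    per group).
    """
    if not fit.spec.group_terms:
        raise ValueError("group effects need a fit with group-specific slopes (M3)")
    if not fit.converged:
        logger.warning("group_effects on a non-converged fit; interpret with care")
    effects = []
    names = fit.param_names
    for g in fit.groups:
        pname = f"slope[{g}]"
        if pname not in names:
            raise ValueError(f"non-estimable slope for group {g!r}")
        j = names.index(pname)
        b = float(fit.params[j])
        cjj = float(fit.cov[j, j])
        se = float(np.sqrt(cjj)) if cjj > 0 else np.nan
        z = b / se if se and np.isfinite(se) else np.nan
        effects.append(
            GroupSlopeEffect(
                group=g,
                slope=b,
                se=se,
                p=float(2 * sps.norm.sf(abs(z))),
                irr=float(np.exp(b)),
                pct_change=float(100.0 * (np.exp(b) - 1.0)),
            )
        )
    return effects


def effects_frame(effects: list[GroupSlopeEffect], school: str = "") -> pd.DataFrame:
    """Effects shaped like the reporting tables (school, group, p, % change)."""
    return pd.DataFrame(
        {
            "school": school,
            "group": [e.group for e in effects],
            "slope": [e.slope for e in effects],
            "se": [e.se for e in effects],
            "p": [e.p for e in effects],
            "irr": [e.irr for e in effects],
            "pct_change": [e.pct_change for e in effects],
        }
    )


def predicted_counts(
    fit: ModelFit, vmd_grid, group: str | None = None, level: float = 0.95
) -> pd.DataFrame:
    """Predicted mean count across VMD at u_zone = 0, with a delta-rule
    confidence band on the response scale.

    Values outside the fitted VMD range trigger an extrapolation warning.
    """
    vmd_grid = np.asarray(vmd_grid, dtype=float)
    lo, hi = fit.vmd_range
    if np.nanmin(vmd_grid) < lo - 1e-9 or np.nanmax(vmd_grid) > hi + 1e-9:
        logger.warning(
            "predicted_counts: extrapolation beyond the fitted VMD range [%.3g, %.3g]",
            lo,
            hi,
        )
    p = fit.p_mean
    names = fit.param_names[:p]
    Xg = np.zeros((len(vmd_grid), p))
    Xg[:, names.index("intercept")] = 1.0
    if fit.spec.group_terms:
        if group is None:
            raise ValueError("group required for a fit with group terms")
        if group not in fit.groups:
            raise ValueError(f"unknown group {group!r}")
        oname = f"offset[{group}]"
        if oname in names:
            Xg[:, names.index(oname)] = 1.0
        Xg[:, names.index(f"slope[{group}]")] = vmd_grid
    elif fit.spec.vmd:
        Xg[:, names.index("slope")] = vmd_grid
    eta = Xg @ fit.params[:p]
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", Xg, fit.cov[:p, :p], Xg))
    zq = sps.norm.ppf(0.5 + level / 2)
    return pd.DataFrame(
        {
            "vmd": vmd_grid,
            "mu": np.exp(eta),
            "lo": np.exp(eta - zq * se_eta),
            "hi": np.exp(eta + zq * se_eta),
            "group": group if group is not None else "all",
        }
    )
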