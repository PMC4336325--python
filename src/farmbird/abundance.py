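"""Regional abundance preparation and the Poisson log-normal mixed model.

Survey preparation applies the monitoring scheme's rules: squares with fewer
than 5 of their 10 points in farmland are dropped; per point the annual value
is the maximum of the two visits, except for flagged migrant species where
only the second visit counts; point values are summed to region x year, and
the number of farmland points is recorded as the effort covariate.

The abundance model is a Poisson GLMM with log link,

    log E[N_ijk] = alpha + b1*C_i + b2*F_i + b3*P_ij + sum_k bk*X_ik
                   + u_i + v_j + eps_ijk,

with Gaussian random intercepts for region (u), year (v) and observation
(eps; the OLRE absorbing extra-Poisson dispersion — the log-normal Poisson
model). Estimation maximizes the Laplace-approximated marginal likelihood:
fixed effects and random-effect modes are found jointly by damped Newton
iterations (the penalized Poisson log-likelihood is concave), and the
variance parameters by a derivative-free outer search over log-SDs. The
observation-level block is eliminated analytically (it is diagonal), so each
Newton step solves a dense system of size p + n_regions + n_years.

Continuous covariates are standardized internally for conditioning;
coefficients and their standard errors are reported on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import substream
from .synthetic import SpeciesProfile

__all__ = [
    "ModelFit",
    "prepare_counts",
    "fit_glmm",
    "overdispersion_ratio",
    "r2_mixed",
    "predictive_power",
    "predict_abundance",
]

_ETA_MAX = 30.0  # exp() guard


# ---------------------------------------------------------------------------
# survey preparation


def prepare_counts(
    visits: pd.DataFrame,
    species: Sequence[SpeciesProfile] | pd.DataFrame,
    min_farmland_points: int = 5,
) -> pd.DataFrame:
    """Aggregate two-visit point counts to region x year abundances.

    ``visits`` needs columns species_id, region_id, year, square_id,
    point_id, visit1_count, visit2_count, point_is_farmland. Filtering and
    summing use the farmland points of squares passing the
    ``min_farmland_points``-of-10 filter; region-years where a species was
    never detected keep explicit zero rows. Unknown species in the visit
    table raise a reference error.
    """
    if isinstance(species, pd.DataFrame):
        migrant = dict(zip(species["species_id"], species["migrant_second_visit_only"]))
    else:
        migrant = {p.species_id: p.migrant_second_visit_only for p in species}
    unknown = set(visits["species_id"]) - set(migrant)
    if unknown:
        raise KeyError(f"visit table references unknown species: {sorted(unknown)}")

    v = visits.copy()
    # squares passing the farmland filter, judged on their point layout per year
    farm_pts = (
        v[v["point_is_farmland"]]
        .groupby(["region_id", "square_id", "year"])["point_id"]
        .nunique()
        .rename("n_farm_points")
    )
    keep = farm_pts[farm_pts >= min_farmland_points].reset_index()
    v = v.merge(keep[["region_id", "square_id", "year"]], on=["region_id", "square_id", "year"])
    v = v[v["point_is_farmland"]]

    is_migrant = v["species_id"].map(migrant).astype(bool)
    annual = np.where(
        is_migrant, v["visit2_count"], np.maximum(v["visit1_count"], v["visit2_count"])
    )
    v = v.assign(annual=annual)
    agg = (
        v.groupby(["species_id", "region_id", "year"], as_index=False)
        .agg(abundance=("annual", "sum"), n_points=("point_id", "nunique"))
    )
    # effort is a property of the region-year, not of the species
    effort = (
        keep.groupby(["region_id", "year"], as_index=False)["n_farm_points"]
        .sum()
        .rename(columns={"n_farm_points": "n_points"})
    )
    full = pd.DataFrame({"species_id": sorted(set(visits["species_id"]))}).merge(
        effort, how="cross"
    )
    out = full.merge(
        agg[["species_id", "region_id", "year", "abundance"]],
        on=["species_id", "region_id", "year"],
        how="left",
    )
    out["abundance"] = out["abundance"].fillna(0).astype(int)
    return out[["species_id", "region_id", "year", "abundance", "n_points"]]


# ---------------------------------------------------------------------------
# model fit container


@dataclass
class ModelFit:
    """A fitted Poisson log-normal mixed model.

    ``params`` and ``se`` are keyed ``"alpha"`` plus the covariate names, on
    the original covariate scale. Variance components are ``None`` for
    random effects not included in the fit.
    """

    params: dict[str, float]
    se: dict[str, float]
    var_region: float | None
    var_year: float | None
    var_obs: float | None
    loglik: float
    converged: bool
    covariates: list[str]
    re_modes: dict[str, dict] = field(default_factory=dict)
    n: int = 0
    edf_random: float = 0.0  # effective parameters spent on random effects
    # internal state for diagnostics / prediction
    _y: np.ndarray | None = field(default=None, repr=False)
    _mu_cond: np.ndarray | None = field(default=None, repr=False)
    _eta_fixed: np.ndarray | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        return self.params["alpha"]

    @property
    def fitted(self) -> np.ndarray:
        """Conditional means at the joint mode (training rows)."""
        return self._mu_cond

    def total_random_variance(self) -> float:
        return sum(v for v in (self.var_region, self.var_year, self.var_obs) if v is not None)


# ---------------------------------------------------------------------------
# Laplace machinery


class _Design:
    """Fixed-effect matrix plus random-intercept indicator blocks.

    The combined matrix U = [X | Z_region | Z_year] is never materialized:
    products with U exploit the indicator structure (bincount segment sums),
    which makes a Newton step O(n p^2) instead of O(n m^2).
    """

    def __init__(self, y, X, region_codes, year_codes, olre):
        self.y = y
        self.X = X
        self.rc = region_codes
        self.yc = year_codes
        self.n, self.p = X.shape
        self.olre = olre
        self.q_region = int(region_codes.max()) + 1 if region_codes is not None else 0
        self.q_year = int(year_codes.max()) + 1 if year_codes is not None else 0
        self.m = self.p + self.q_region + self.q_year

    def U_dot(self, c: np.ndarray) -> np.ndarray:
        out = self.X @ c[: self.p]
        j = self.p
        if self.q_region:
            out = out + c[j : j + self.q_region][self.rc]
            j += self.q_region
        if self.q_year:
            out = out + c[j : j + self.q_year][self.yc]
        return out

    def Ut_dot(self, v: np.ndarray) -> np.ndarray:
        parts = [self.X.T @ v]
        if self.q_region:
            parts.append(np.bincount(self.rc, weights=v, minlength=self.q_region))
        if self.q_year:
            parts.append(np.bincount(self.yc, weights=v, minlength=self.q_year))
        return np.concatenate(parts)

    def gram(self, w: np.ndarray) -> np.ndarray:
        """U' diag(w) U assembled blockwise."""
        p, qr, qy = self.p, self.q_region, self.q_year
        G = np.zeros((self.m, self.m))
        Xw = self.X * w[:, None]
        G[:p, :p] = Xw.T @ self.X
        r0, y0 = p, p + qr
        if qr:
            XtZr = np.stack(
                [np.bincount(self.rc, weights=Xw[:, a], minlength=qr) for a in range(p)]
            )
            G[:p, r0 : r0 + qr] = XtZr
            G[r0 : r0 + qr, :p] = XtZr.T
            G[r0 : r0 + qr, r0 : r0 + qr][np.diag_indices(qr)] = np.bincount(
                self.rc, weights=w, minlength=qr
            )
        if qy:
            XtZy = np.stack(
                [np.bincount(self.yc, weights=Xw[:, a], minlength=qy) for a in range(p)]
            )
            G[:p, y0 : y0 + qy] = XtZy
            G[y0 : y0 + qy, :p] = XtZy.T
            G[y0 : y0 + qy, y0 : y0 + qy][np.diag_indices(qy)] = np.bincount(
                self.yc, weights=w, minlength=qy
            )
        if qr and qy:
            M = np.zeros((qr, qy))
            np.add.at(M, (self.rc, self.yc), w)
            G[r0 : r0 + qr, y0 : y0 + qy] = M
            G[y0 : y0 + qy, r0 : r0 + qr] = M.T
        return G

    def penalty_diag(self, variances):
        P = np.zeros(self.m)
        j = self.p
        if self.q_region:
            P[j : j + self.q_region] = 1.0 / variances["region"]
            j += self.q_region
        if self.q_year:
            P[j : j + self.q_year] = 1.0 / variances["year"]
        return P


def _safe_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve with a Levenberg-style ridge fallback for near-singular systems."""
    ridge = 0.0
    scale = float(np.abs(np.diag(A)).max()) or 1.0
    for _ in range(8):
        try:
            return np.linalg.solve(A + ridge * np.eye(len(A)), b)
        except np.linalg.LinAlgError:
            ridge = max(ridge * 10.0, 1e-10 * scale)
    return np.linalg.lstsq(A, b, rcond=None)[0]


def _inner_mode(design: _Design, variances, c0, e0, tol=1e-9, maxiter=80):
    """Joint (fixed effects + random modes) penalized Poisson optimum."""
    y, n = design.y, design.n
    P = design.penalty_diag(variances)
    inv_se2 = 1.0 / variances["obs"] if design.olre else None
    c = c0.copy()
    e = e0.copy() if design.olre else np.zeros(n)

    def objective(c, e):
        eta = np.clip(design.U_dot(c) + e, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        f = float(y @ eta - mu.sum() - 0.5 * (P * c * c).sum())
        if design.olre:
            f -= 0.5 * inv_se2 * float(e @ e)
        return f, mu

    f, mu = objective(c, e)
    converged = False
    for _ in range(maxiter):
        resid = y - mu
        g_c = design.Ut_dot(resid) - P * c
        if design.olre:
            g_e = resid - inv_se2 * e
            d = mu + inv_se2
            S = design.gram(mu - mu * mu / d) + np.diag(P)
            rhs = g_c - design.Ut_dot(mu * g_e / d)
            dc = _safe_solve(S, rhs)
            de = (g_e - mu * design.U_dot(dc)) / d
        else:
            A = design.gram(mu) + np.diag(P)
            dc = _safe_solve(A, g_c)
            de = np.zeros(n)
        gnorm = max(np.abs(g_c).max(), np.abs(g_e).max() if design.olre else 0.0)
        if gnorm < tol * (1.0 + abs(f)):
            converged = True
            break
        step = 1.0
        for _ in range(30):
            f_new, mu_new = objective(c + step * dc, e + step * de)
            if f_new >= f - 1e-12:
                break
            step *= 0.5
        c, e = c + step * dc, e + step * de
        if abs(f_new - f) < tol * (1.0 + abs(f)):
            f, mu = f_new, mu_new
            converged = True
            break
        f, mu = f_new, mu_new
    return c, e, f, mu, converged


def _laplace_nll(design: _Design, variances, state):
    """Negative Laplace log-likelihood at given variance parameters."""
    c, e, f, mu, conv = _inner_mode(design, variances, state["c"], state["e"])
    if not np.isfinite(f):
        return np.inf  # leave the warm start untouched
    state.update(c=c, e=e, conv=conv)
    y, p = design.y, design.p
    ll = f - float(gammaln(y + 1).sum())
    # -(1/2) log det D
    if design.q_region:
        ll -= 0.5 * design.q_region * np.log(variances["region"])
    if design.q_year:
        ll -= 0.5 * design.q_year * np.log(variances["year"])
    if design.olre:
        ll -= 0.5 * design.n * np.log(variances["obs"])
    # -(1/2) log det H_uu over the random-effect block only
    q_v = design.q_region + design.q_year
    P_v = design.penalty_diag(variances)[p : p + q_v]
    if design.olre:
        d = mu + 1.0 / variances["obs"]
        H_vv = design.gram(mu - mu * mu / d)[p:, p:] + np.diag(P_v)
        ll -= 0.5 * float(np.log(d).sum())
    else:
        H_vv = design.gram(mu)[p:, p:] + np.diag(P_v)
    if q_v:
        sign, logdet = np.linalg.slogdet(H_vv)
        if sign <= 0:
            return np.inf
        ll -= 0.5 * logdet
    return -ll


def fit_glmm(
    data: pd.DataFrame,
    covariates: Sequence[str],
    random_effects: Sequence[str] = ("region", "year", "obs"),
    response: str = "abundance",
    standardize: bool = True,
    start_sd: float = 0.3,
) -> ModelFit:
    """Fit the Poisson log-normal mixed model.

    Parameters
    ----------
    data : DataFrame
        One row per region x year with the response and covariate columns
        (``region_id`` / ``year`` required when the corresponding random
        intercept is requested).
    covariates : sequence of str
        Fixed-effect columns (climatic suitability, farmland proportion,
        effort, crop shares...). An intercept is always included.
    random_effects : subset of {"region", "year", "obs"}
        Gaussian random intercepts to include; ``"obs"`` is the
        observation-level effect of the log-normal Poisson model.
    """
    data = data.reset_index(drop=True)
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    bad = set(random_effects) - {"region", "year", "obs"}
    if bad:
        raise ValueError(f"unknown random effects: {sorted(bad)}")
    y = data[response].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("response must be non-negative")
    if y.sum() == 0:
        raise ValueError("all-zero response: intercept is unbounded below")
    n = len(y)

    Xraw = data[list(covariates)].to_numpy(dtype=float)
    if standardize and Xraw.shape[1]:
        means = Xraw.mean(axis=0)
        sds = Xraw.std(axis=0, ddof=0)
        sds[sds == 0] = 1.0
    else:
        means = np.zeros(Xraw.shape[1])
        sds = np.ones(Xraw.shape[1])
    X = np.hstack([np.ones((n, 1)), (Xraw - means) / sds])
    p = X.shape[1]

    region_codes = year_codes = None
    region_levels = year_levels = None
    if "region" in random_effects:
        if n < 2 or data["region_id"].nunique() < 2:
            raise ValueError("region random intercept needs >= 2 regions")
        region_levels, region_codes = np.unique(data["region_id"], return_inverse=True)
    if "year" in random_effects:
        if data["year"].nunique() < 2:
            raise ValueError("year random intercept needs >= 2 years")
        year_levels, year_codes = np.unique(data["year"], return_inverse=True)
    olre = "obs" in random_effects

    design = _Design(y, X, region_codes, year_codes, olre)
    state = {"c": np.zeros(design.m), "e": np.zeros(n), "conv": True}
    state["c"][0] = np.log(max(y.mean(), 0.1))

    theta_names = [r for r in ("region", "year", "obs") if r in random_effects]
    if theta_names:
        from scipy.optimize import minimize

        def nll(theta):
            # smooth penalty outside the box keeps the surface non-flat, so a
            # boundary optimum (variance -> 0) is still a clean convergence
            pen = float(np.sum(np.clip(theta - 4.0, 0, None) ** 2)
                        + np.sum(np.clip(-8.0 - theta, 0, None) ** 2))
            theta = np.clip(theta, -8.0, 4.0)
            variances = dict.fromkeys(("region", "year", "obs"), 1.0)
            variances.update({nm: float(np.exp(2 * t)) for nm, t in zip(theta_names, theta)})
            return _laplace_nll(design, variances, state) + 100.0 * pen

        x0 = np.full(len(theta_names), np.log(start_sd))
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-6, "maxfev": 600})
        theta = np.clip(res.x, -8.0, 4.0)
        variances = dict.fromkeys(("region", "year", "obs"), 1.0)
        variances.update({nm: float(np.exp(2 * t)) for nm, t in zip(theta_names, theta)})
        final_nll = _laplace_nll(design, variances, state)
        outer_ok = bool(res.success)
    else:
        variances = dict.fromkeys(("region", "year", "obs"), 1.0)
        final_nll = _laplace_nll(design, variances, state)
        outer_ok = True

    c, e = state["c"], state["e"]
    eta = np.clip(design.U_dot(c) + (e if olre else 0.0), -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)

    # covariance of (beta, u) from the joint Hessian; beta block via Schur
    P = design.penalty_diag(variances)
    if olre:
        d = mu + 1.0 / variances["obs"]
        S = design.gram(mu - mu * mu / d) + np.diag(P)
    else:
        S = design.gram(mu) + np.diag(P)
    cov_std = np.linalg.pinv(S)[:p, :p]

    # effective df of the random effects: trace of the shrinkage hat matrix,
    # q - tr(D^-1 M^-1) with M the RE block of the joint Hessian. Needed for
    # an honest Pearson/df overdispersion ratio on the conditional fit.
    edf_random = 0.0
    q_v = design.q_region + design.q_year
    P_v = P[p:]
    S_re_inv = None
    if q_v:
        if olre:
            S_re = design.gram(mu - mu * mu / d)[p:, p:] + np.diag(P_v)
        else:
            S_re = design.gram(mu)[p:, p:] + np.diag(P_v)
        S_re_inv = np.linalg.pinv(S_re)
        edf_random += q_v - float(np.sum(P_v * np.diag(S_re_inv)))
    if olre:
        inv_se2 = 1.0 / variances["obs"]
        trace_e = inv_se2 * float(np.sum(1.0 / d))
        if q_v:
            C = design.gram(mu * mu / (d * d))[p:, p:]
            trace_e += inv_se2 * float(np.trace(S_re_inv @ C))
        edf_random += design.n - trace_e

    # map standardized-scale coefficients back to the original scale
    T = np.eye(p)
    for j in range(1, p):
        T[0, j] = -means[j - 1] / sds[j - 1]
        T[j, j] = 1.0 / sds[j - 1]
    beta_orig = T @ c[:p]
    cov_orig = T @ cov_std @ T.T
    se_orig = np.sqrt(np.clip(np.diag(cov_orig), 0.0, None))

    names = ["alpha"] + list(covariates)
    re_modes: dict[str, dict] = {}
    j = p
    if design.q_region:
        re_modes["region"] = dict(zip(region_levels, c[j : j + design.q_region]))
        j += design.q_region
    if design.q_year:
        re_modes["year"] = dict(zip(year_levels, c[j : j + design.q_year]))
    if olre:
        re_modes["obs"] = {"modes": e.copy()}

    return ModelFit(
        params=dict(zip(names, beta_orig)),
        se=dict(zip(names, se_orig)),
        var_region=variances["region"] if "region" in random_effects else None,
        var_year=variances["year"] if "year" in random_effects else None,
        var_obs=variances["obs"] if olre else None,
        loglik=-float(final_nll),
        converged=bool(outer_ok and state["conv"]),
        covariates=list(covariates),
        re_modes=re_modes,
        n=n,
        edf_random=float(edf_random),
        _y=y,
        _mu_cond=mu,
        _eta_fixed=X @ c[:p],
    )


# ---------------------------------------------------------------------------
# diagnostics


def overdispersion_ratio(fit: ModelFit, data: pd.DataFrame | None = None) -> float:
    """Pearson chi-square over residual degrees of freedom, conditional fit.

    Ratios well above 1 flag extra-Poisson variance that the model's random
    structure has not absorbed.
    """
    if not fit.converged:
        raise ValueError("overdispersion ratio requires a converged fit")
    y, mu = fit._y, fit._mu_cond
    df = fit.n - (len(fit.covariates) + 1) - fit.edf_random
    if df <= 0:
        raise ValueError("no residual degrees of freedom left after fixed and random effects")
    pearson = float(((y - mu) ** 2 / np.maximum(mu, 1e-12)).sum())
    return pearson / df


def r2_mixed(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for the mixed model.

    Variance decomposition on the latent (log-link) scale: marginal R^2 is
    var(fixed linear predictor) over the total of fixed, random-intercept and
    distribution-specific variance; conditional R^2 adds the random-intercept
    variance to the numerator. The distribution-specific variance uses the
    log-normal approximation ``ln(1 + 1/lambda_bar)`` with ``lambda_bar`` the
    mean marginal expected count ``exp(eta_fixed + sigma_tot^2 / 2)``.
    """
    if not fit.converged:
        raise ValueError("R^2 requires a converged fit")
    var_f = float(np.var(fit._eta_fixed))
    var_r = fit.total_random_variance()
    lam = float(np.mean(np.exp(np.clip(fit._eta_fixed + 0.5 * var_r, -_ETA_MAX, _ETA_MAX))))
    var_d = float(np.log1p(1.0 / max(lam, 1e-12)))
    total = var_f + var_r + var_d
    if total <= 0:
        raise ValueError("total latent variance is zero; R^2 undefined")
    return var_f / total, (var_f + var_r) / total


def predict_abundance(
    fit: ModelFit,
    covariate_values: pd.DataFrame,
    use_random_effects: bool = True,
) -> np.ndarray:
    """Expected regional abundance for new covariate rows.

    The linear predictor uses original-scale coefficients; random intercepts
    enter at their conditional modes for regions/years seen in training and
    at 0 (the population level) for new ones — in particular future years.
    The observation-level effect is always 0 for prediction. The exponential
    back-transform is applied after assembling the predictor.
    """
    missing = [c for c in fit.covariates if c not in covariate_values.columns]
    if missing:
        raise ValueError(f"missing covariates for prediction: {missing}")
    eta = np.full(len(covariate_values), fit.alpha)
    for c in fit.covariates:
        eta += fit.params[c] * covariate_values[c].to_numpy(dtype=float)
    if use_random_effects:
        if "region" in fit.re_modes and "region_id" in covariate_values.columns:
            modes = fit.re_modes["region"]
            eta += covariate_values["region_id"].map(lambda r: modes.get(r, 0.0)).to_numpy()
        if "year" in fit.re_modes and "year" in covariate_values.columns:
            modes = fit.re_modes["year"]
            eta += covariate_values["year"].map(lambda yv: modes.get(yv, 0.0)).to_numpy()
    return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def predictive_power(
    data: pd.DataFrame,
    covariates: Sequence[str],
    seed: int,
    max_retries: int = 20,
    **fit_kwargs,
) -> float:
    """Half-split predictive R^2 against the y = x line.

    Fits the model on a random half of the rows, predicts the held-out half,
    and scores 1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2), i.e. the
    R^2 of the observed-vs-predicted scatter around the identity line (an
    unbiased forecaster with perfect sharpness scores 1). Degenerate splits
    are retried on fresh substreams.
    """
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 rows for a half split")
    for attempt in range(max_retries):
        rng = substream(seed, "half-split", attempt)
        perm = rng.permutation(n)
        tr, te = perm[: n // 2], perm[n // 2 :]
        try:
            fit = fit_glmm(data.iloc[tr], covariates, **fit_kwargs)
        except ValueError:
            continue
        obs = data.iloc[te]["abundance"].to_numpy(dtype=float)
        if np.allclose(obs, obs.mean()):
            continue
        pred = predict_abundance(fit, data.iloc[te])
        sse = float(((obs - pred) ** 2).sum())
        sst = float(((obs - obs.mean()) ** 2).sum())
        return 1.0 - sse / sst
    raise ValueError(f"no usable half split found in {max_retries} attempts")
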