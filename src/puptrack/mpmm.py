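"""Move-persistence mixed-effects model.

Movement is a first-difference correlated random walk in local planar
kilometre coordinates,

    d_t = gamma_t * d_{t-1} + eps_t,     eps_t ~ N(0, diag(sx^2, sy^2)),

where d_t is the displacement over one regular time step and gamma_t in
(0, 1) is the move persistence: the autocorrelation of successive
displacements in both speed and direction.  Persistence is linked to
covariates on the logit scale with a Gaussian random intercept per animal,

    logit(gamma_t) = x_t' beta + b_i,    b_i ~ N(0, sigma_b^2).

The random intercepts are integrated out with a per-animal Laplace
approximation (the inner mode found by damped Newton; the problem is
one-dimensional per animal, so the approximation is cheap and accurate).
Maximum-likelihood estimation uses a robust simplex pass to generate
starting values followed by quasi-Newton (L-BFGS-B) polishing; standard
errors come from the inverse observed information.

Persistence above 0.70 is conventionally read as directed travel and below
0.30 as area-restricted search; the band between is ambiguous.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from puptrack.regularize import RegularTrack
from puptrack.selection import aicc, akaike_table

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

COVARIATE_ORDER = ["sex_female", "mass", "length", "postwean",
                   "week", "dist_shore", "ln_depth"]

_LOGIT_CLIP = 30.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_LOGIT_CLIP, _LOGIT_CLIP)))


@dataclass
class ModelData:
    """Stacked per-step data for the persistence likelihood.

    d[t] is the current displacement (km), p[t] the previous one; X the
    design matrix (intercept first); animal_idx maps steps to animals.
    """

    d: np.ndarray                # (n, 2)
    p: np.ndarray                # (n, 2)
    X: np.ndarray                # (n, q)
    colnames: list
    animal_idx: np.ndarray       # (n,) int
    animal_ids: list
    track_idx: np.ndarray        # (n,) int
    times: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return self.d.shape[0]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def subset_animals(self, keep: list) -> "ModelData":
        keep_set = {self.animal_ids.index(a) for a in keep}
        mask = np.isin(self.animal_idx, list(keep_set))
        old_to_new = {old: new for new, old in enumerate(sorted(keep_set))}
        return ModelData(
            d=self.d[mask], p=self.p[mask], X=self.X[mask],
            colnames=list(self.colnames),
            animal_idx=np.array([old_to_new[a] for a in self.animal_idx[mask]]),
            animal_ids=[self.animal_ids[i] for i in sorted(keep_set)],
            track_idx=self.track_idx[mask],
            times=None if self.times is None else self.times[mask],
        )

    def with_covariates(self, covariates: list) -> "ModelData":
        cols = [0] + [self.colnames.index(c) for c in covariates]
        return ModelData(
            d=self.d, p=self.p, X=self.X[:, cols],
            colnames=[self.colnames[i] for i in cols],
            animal_idx=self.animal_idx, animal_ids=list(self.animal_ids),
            track_idx=self.track_idx, times=self.times,
        )


def _pup_value(pup: dict, name: str):
    if name == "sex_female":
        sex = pup.get("sex")
        if sex in ("male", "female"):
            return 1.0 if sex == "female" else 0.0
        return np.nan
    aliases = {"mass": ("mass", "mass_wean"), "length": ("length", "length_wean"),
               "postwean": ("postwean", "postwean_days")}
    for key in aliases.get(name, (name,)):
        if key in pup and pd.notna(pup[key]):
            return float(pup[key])
    return np.nan


def build_model_data(tracks: list[RegularTrack],
                     covariates: list | None = None) -> ModelData:
    """Assemble displacements and the design matrix from regular tracks.

    Displacements are computed in km on an equirectangular projection about
    each track's centroid.  Covariates attach at the destination location
    of each displacement.  Animals missing any requested biometric are
    excluded (logged), matching the omission of animals without biometrics.
    """
    covariates = list(covariates) if covariates is not None else list(COVARIATE_ORDER)
    per_animal = [c for c in covariates if c in ("sex_female", "mass", "length", "postwean")]

    usable_animals = []
    for rt in tracks:
        if rt.animal_id in usable_animals:
            continue
        vals = [_pup_value(rt.pup, c) for c in per_animal]
        if any(np.isnan(v) for v in vals):
            log.info("excluding %s: missing biometrics", rt.animal_id)
            continue
        usable_animals.append(rt.animal_id)

    d_all, p_all, X_all, a_all, k_all, t_all = [], [], [], [], [], []
    for k, rt in enumerate(tracks):
        if rt.animal_id not in usable_animals:
            continue
        df = rt.data
        if len(df) < 3:
            continue
        lon = df["lon"].to_numpy(float)
        lat = df["lat"].to_numpy(float)
        lat0 = float(np.mean(lat))
        lon0 = float(np.mean(lon))
        x = np.radians(lon - lon0) * EARTH_RADIUS_KM * np.cos(np.radians(lat0))
        y = np.radians(lat - lat0) * EARTH_RADIUS_KM
        disp = np.column_stack([np.diff(x), np.diff(y)])  # m-1 displacements
        d_t = disp[1:]
        d_prev = disp[:-1]
        dest = slice(2, len(df))  # destination rows of d_t

        row = {c: _pup_value(rt.pup, c) for c in per_animal}
        cols = []
        for c in covariates:
            if c in per_animal:
                cols.append(np.full(d_t.shape[0], row[c]))
            else:
                colmap = {"week": "week", "dist_shore": "dist_shore_km",
                          "ln_depth": "ln_depth", "depth": "depth_m"}
                src = colmap.get(c, c)
                if src not in df:
                    raise ValueError(f"covariate {c!r} not present on track {rt.track_id}")
                vals = df[src].to_numpy(float)[dest]
                if np.any(~np.isfinite(vals)):
                    raise ValueError(f"covariate {c!r} has missing values")
                cols.append(vals)
        X = np.column_stack([np.ones(d_t.shape[0])] + cols) if cols else \
            np.ones((d_t.shape[0], 1))

        d_all.append(d_t)
        p_all.append(d_prev)
        X_all.append(X)
        a_all.append(np.full(d_t.shape[0], usable_animals.index(rt.animal_id)))
        k_all.append(np.full(d_t.shape[0], k))
        t_all.append(df["time"].to_numpy("datetime64[ns]")[dest])

    if not d_all:
        raise ValueError("no usable tracks")
    return ModelData(
        d=np.concatenate(d_all), p=np.concatenate(p_all),
        X=np.concatenate(X_all), colnames=["intercept"] + covariates,
        animal_idx=np.concatenate(a_all).astype(int), animal_ids=usable_animals,
        track_idx=np.concatenate(k_all).astype(int),
        times=np.concatenate(t_all),
    )


# ---------------------------------------------------------------------------
# likelihood


def _cond_parts(md: ModelData, eta: np.ndarray, sx2: float, sy2: float):
    """Per-step conditional log-likelihood and its first two derivatives
    with respect to the linear predictor eta."""
    g = _sigmoid(eta)
    gp = g * (1.0 - g)
    gpp = gp * (1.0 - 2.0 * g)
    rx = md.d[:, 0] - g * md.p[:, 0]
    ry = md.d[:, 1] - g * md.p[:, 1]
    ll = (-0.5 * np.log(2 * np.pi * sx2) - rx**2 / (2 * sx2)
          - 0.5 * np.log(2 * np.pi * sy2) - ry**2 / (2 * sy2))
    u = rx * md.p[:, 0] / sx2 + ry * md.p[:, 1] / sy2
    v = md.p[:, 0] ** 2 / sx2 + md.p[:, 1] ** 2 / sy2
    grad = u * gp
    hess = u * gpp - v * gp**2
    return ll, grad, hess


def _inner_mode(md: ModelData, eta0: np.ndarray, sx2: float, sy2: float,
                sigma_b2: float, b0: np.ndarray | None = None,
                max_iter: int = 50, tol: float = 1e-9):
    """Damped Newton for the per-animal random-intercept modes (1-D each)."""
    nb = md.n_animals
    b = np.zeros(nb) if b0 is None else b0.copy()
    for _ in range(max_iter):
        ll, grad, hess = _cond_parts(md, eta0 + b[md.animal_idx], sx2, sy2)
        g = np.bincount(md.animal_idx, weights=grad, minlength=nb) - b / sigma_b2
        h = np.bincount(md.animal_idx, weights=hess, minlength=nb) - 1.0 / sigma_b2
        h = np.minimum(h, -1e-10)
        step = -g / h
        step = np.clip(step, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(g)) < tol:
            break
    ll, grad, hess = _cond_parts(md, eta0 + b[md.animal_idx], sx2, sy2)
    cond_ll = np.bincount(md.animal_idx, weights=ll, minlength=nb)
    h = np.bincount(md.animal_idx, weights=hess, minlength=nb) - 1.0 / sigma_b2
    h = np.minimum(h, -1e-10)
    return b, cond_ll, h


def nll_mpmm(md: ModelData, beta: np.ndarray, log_sigma_b: float | None,
             log_sigma_step: np.ndarray, _warm: dict | None = None) -> float:
    """Negative marginal log-likelihood (Laplace over random intercepts).

    With ``log_sigma_b`` None the model has no random intercept and the
    conditional likelihood at b = 0 is returned.  Non-finite parameters
    raise; an inner failure returns +inf with a warning.
    """
    theta = np.concatenate([np.atleast_1d(beta),
                            [] if log_sigma_b is None else [log_sigma_b],
                            np.atleast_1d(log_sigma_step)])
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite parameters")
    sx2 = float(np.exp(2.0 * log_sigma_step[0]))
    sy2 = float(np.exp(2.0 * log_sigma_step[1]))
    eta0 = md.X @ np.asarray(beta, dtype=float)
    if log_sigma_b is None:
        ll, _, _ = _cond_parts(md, eta0, sx2, sy2)
        return -float(np.sum(ll))
    sigma_b2 = float(np.exp(2.0 * log_sigma_b))
    sigma_b2 = max(sigma_b2, 1e-12)
    b0 = None if _warm is None else _warm.get("b")
    try:
        b, cond_ll, h = _inner_mode(md, eta0, sx2, sy2, sigma_b2, b0)
    except FloatingPointError:  # pragma: no cover - defensive
        log.warning("inner optimization failed; returning +inf")
        return np.inf
    if _warm is not None:
        _warm["b"] = b
    marg = cond_ll - b**2 / (2 * sigma_b2) - 0.5 * np.log(sigma_b2) - 0.5 * np.log(-h)
    val = -float(np.sum(marg))
    if not np.isfinite(val):
        log.warning("non-finite marginal likelihood; returning +inf")
        return np.inf
    return val


@dataclass
class MpmmFit:
    covariates: list
    random_intercept: bool
    beta: pd.DataFrame                 # estimate, se, z, p per coefficient
    sigma_b: float
    b_i: dict
    sigma_step: tuple
    gamma: np.ndarray
    gamma_se: np.ndarray | None
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    md: ModelData = field(repr=False, default=None)
    cov_beta: np.ndarray | None = field(repr=False, default=None)

    @property
    def formula(self) -> str:
        terms = list(self.covariates)
        if self.random_intercept:
            terms.append("(1 | id)")
        return "~ " + (" + ".join(terms) if terms else "1")

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        out = self.beta.copy()
        out["lo"] = out["estimate"] - z * out["se"]
        out["hi"] = out["estimate"] + z * out["se"]
        return out

    def to_json(self, path) -> None:
        obj = {
            "formula": self.formula,
            "beta": self.beta.reset_index().to_dict(orient="records"),
            "sigma_b": self.sigma_b, "sigma_step": list(self.sigma_step),
            "b_i": self.b_i, "logLik": self.loglik, "k": self.k, "n": self.n,
            "AICc": self.aicc, "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _pack(md, covariates, random_intercept):
    q = 1 + len(covariates)
    scales = np.ones(q)
    for j in range(1, q):
        s = float(np.std(md.X[:, j]))
        scales[j] = s if s > 1e-12 else 1.0
    return q, scales


def fit_mpmm(md: ModelData, covariates: list | None = None,
             random_intercept: bool = True,
             maxiter: int = 400) -> MpmmFit:
    """Two-stage ML fit of the move-persistence mixed model.

    A Nelder-Mead pass from moment-based starting values generates initial
    estimates; L-BFGS-B then polishes them.  Standard errors come from the
    inverse observed information (central-difference Hessian); gamma is
    predicted with plug-in random intercepts.
    """
    if covariates is None:
        covariates = [c for c in COVARIATE_ORDER if c in md.colnames]
    md_f = md.with_covariates(covariates)
    q, scales = _pack(md_f, covariates, random_intercept)
    Xs = md_f.X / scales
    md_s = ModelData(md_f.d, md_f.p, Xs, md_f.colnames, md_f.animal_idx,
                     md_f.animal_ids, md_f.track_idx, md_f.times)

    # moment starts: project d on p for a pooled persistence estimate
    num = float(np.sum(md_f.d * md_f.p))
    den = float(np.sum(md_f.p * md_f.p))
    g0 = min(max(num / den if den > 0 else 0.5, 0.05), 0.95)
    beta0 = np.zeros(q)
    beta0[0] = np.log(g0 / (1 - g0))
    resid = md_f.d - g0 * md_f.p
    ls0 = np.log(np.maximum(np.std(resid, axis=0), 1e-3))
    theta0 = np.concatenate([beta0, [np.log(0.1)] if random_intercept else [],
                             ls0])
    warm: dict = {}

    def obj(theta):
        beta = theta[:q]
        if random_intercept:
            lsb = theta[q]
            lss = theta[q + 1:q + 3]
        else:
            lsb = None
            lss = theta[q:q + 2]
        try:
            return nll_mpmm(md_s, beta, lsb, lss, _warm=warm)
        except (ValueError, FloatingPointError):
            return np.inf

    lb_sigma = np.log(1e-3)
    bounds = ([(None, None)] * q
              + ([(lb_sigma, np.log(5.0))] if random_intercept else [])
              + [(lb_sigma, np.log(1e3))] * 2)
    pre = optimize.minimize(obj, theta0, method="Nelder-Mead", bounds=bounds,
                            options={"maxiter": 300, "xatol": 1e-4, "fatol": 1e-6})
    res = optimize.minimize(obj, pre.x, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7})
    theta = res.x if res.fun <= pre.fun else pre.x
    converged = bool((res.success or pre.success) and np.isfinite(res.fun))

    # observed information (central differences in the scaled space);
    # a random-intercept variance stuck at its floor is held fixed
    npar = theta.size
    free = np.ones(npar, dtype=bool)
    if random_intercept and theta[q] <= lb_sigma + 1e-6:
        free[q] = False
    idx_free = np.flatnonzero(free)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    Hf = np.zeros((idx_free.size, idx_free.size))
    f0 = obj(theta)
    for a, i in enumerate(idx_free):
        for bb, j in enumerate(idx_free[a:], start=a):
            ei = np.zeros(npar); ei[i] = h[i]
            ej = np.zeros(npar); ej[j] = h[j]
            if i == j:
                Hf[a, a] = (obj(theta + ei) - 2 * f0 + obj(theta - ei)) / h[i] ** 2
            else:
                Hf[a, bb] = Hf[bb, a] = (
                    obj(theta + ei + ej) - obj(theta + ei - ej)
                    - obj(theta - ei + ej) + obj(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    cov = np.full((npar, npar), np.nan)
    try:
        cov_f = np.linalg.inv(Hf)
        if np.any(np.diag(cov_f) < 0):
            cov_f = np.linalg.pinv(Hf)
        cov[np.ix_(idx_free, idx_free)] = cov_f
        se_scaled = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_scaled = np.full(npar, np.nan)
        converged = False

    beta_s = theta[:q]
    beta_nat = beta_s / scales
    se_nat = se_scaled[:q] / scales
    D = np.diag(1.0 / scales)
    cov_beta = D @ cov[:q, :q] @ D if np.all(np.isfinite(cov[:q, :q])) else None

    if random_intercept:
        sigma_b = float(np.exp(theta[q]))
        lss = theta[q + 1:q + 3]
    else:
        sigma_b = 0.0
        lss = theta[q:q + 2]
    sigma_step = tuple(np.exp(lss))

    # plug-in random effects and fitted gamma at the optimum
    eta0 = md_s.X @ beta_s
    sx2, sy2 = float(np.exp(2 * lss[0])), float(np.exp(2 * lss[1]))
    if random_intercept:
        b, _, _ = _inner_mode(md_s, eta0, sx2, sy2, max(sigma_b**2, 1e-12))
    else:
        b = np.zeros(md_s.n_animals)
    eta = eta0 + b[md_s.animal_idx]
    gamma = _sigmoid(eta)

    gamma_se = None
    if cov_beta is not None:
        var_eta = np.einsum("ij,jk,ik->i", md_f.X, cov_beta, md_f.X)
        gamma_se = gamma * (1 - gamma) * np.sqrt(np.maximum(var_eta, 0.0))

    z = beta_nat / se_nat
    pvals = 2 * stats.norm.sf(np.abs(z))
    beta_tbl = pd.DataFrame(
        {"estimate": beta_nat, "se": se_nat, "z": z, "p": pvals},
        index=md_f.colnames,
    )

    k = q + (1 if random_intercept else 0) + 2
    n = md_f.n_steps
    loglik = -float(min(res.fun, pre.fun))
    fit = MpmmFit(
        covariates=list(covariates), random_intercept=random_intercept,
        beta=beta_tbl, sigma_b=sigma_b,
        b_i=dict(zip(md_f.animal_ids, b.tolist())),
        sigma_step=sigma_step, gamma=gamma, gamma_se=gamma_se,
        loglik=loglik, k=k, n=n, aicc=aicc(loglik, k, n),
        converged=converged, md=md_f, cov_beta=cov_beta,
    )
    if not converged:
        log.warning("mpmm fit %s did not converge cleanly", fit.formula)
    return fit


def classify_gamma(gamma, directed: float = 0.70, ars: float = 0.30):
    """Label each step: gamma > 0.70 directed travel, < 0.30 area-restricted
    search, otherwise intermediate (strict inequalities both sides)."""
    g = np.asarray(getattr(gamma, "gamma", gamma), dtype=float)
    labels = np.where(g > directed, "directed_travel",
                      np.where(g < ars, "area_restricted_search", "intermediate"))
    counts = {lab: int((labels == lab).sum())
              for lab in ("directed_travel", "intermediate", "area_restricted_search")}
    return labels, counts


def osa_residuals(fit: MpmmFit) -> dict:
    """Standardized one-step-ahead residuals per axis (plug-in forecast)."""
    md = fit.md
    rx = (md.d[:, 0] - fit.gamma * md.p[:, 0]) / fit.sigma_step[0]
    ry = (md.d[:, 1] - fit.gamma * md.p[:, 1]) / fit.sigma_step[1]
    return {"x": rx, "y": ry}


def model_select(md: ModelData, candidates: list[list],
                 random_intercept: bool = True) -> tuple[pd.DataFrame, dict]:
    """Fit every candidate covariate set and rank by AICc.

    Returns (ranking table, fits keyed by formula).  Non-converged fits are
    excluded from the ranking (logged).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits = {}
    rows = []
    for cov in candidates:
        fit = fit_mpmm(md, covariates=cov, random_intercept=random_intercept)
        fits[fit.formula] = fit
        if not fit.converged:
            log.warning("excluding non-converged candidate %s", fit.formula)
            continue
        rows.append({"model": fit.formula, "df": fit.k, "LL": fit.loglik,
                     "n": fit.n, "AICc": fit.aicc})
    if not rows:
        raise RuntimeError("all candidate fits failed")
    return akaike_table(rows), fits


def vif(md: ModelData, covariates: list | None = None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j) of covariate j
    regressed on the others (with intercept)."""
    covariates = covariates or [c for c in md.colnames if c != "intercept"]
    if len(covariates) < 2:
        raise ValueError("VIF needs at least two covariates")
    cols = [md.colnames.index(c) for c in covariates]
    X = md.X[:, cols]
    out = {}
    for j, name in enumerate(covariates):
        y = X[:, j]
        others = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean())**2))
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            log.warning("covariate %s is perfectly collinear", name)
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass
class CvSummary:
    coef_quantiles: pd.DataFrame       # 5% / 95% per coefficient
    est_trend: pd.Series               # % of refits inside full-model 95% CI
    estimates: pd.DataFrame            # one row per refit
    n_attempted: int
    n_converged: int


def loo_cv(md: ModelData, covariates: list | None = None,
           full_fit: MpmmFit | None = None) -> CvSummary:
    """Leave-one-animal-out refits of the persistence model.

    Each animal is dropped in turn and the model refitted; the summary
    reports per-coefficient 5%/95% quantiles across refits and the
    percentage of refits whose estimate lies inside the full model's 95%
    Wald interval.  Non-converged refits are skipped (denominator adjusted).
    """
    if md.n_animals < 3:
        raise ValueError("leave-one-out needs at least three animals")
    if full_fit is None:
        full_fit = fit_mpmm(md, covariates=covariates)
    covariates = full_fit.covariates
    rows = []
    n_attempted = 0
    for animal in md.animal_ids:
        n_attempted += 1
        keep = [a for a in md.animal_ids if a != animal]
        sub = md.subset_animals(keep)
        fit = fit_mpmm(sub, covariates=covariates,
                       random_intercept=full_fit.random_intercept)
        if not fit.converged:
            log.warning("LOO refit without %s failed to converge; skipped", animal)
            continue
        rows.append(fit.beta["estimate"].rename(animal))
    est = pd.DataFrame(rows)
    qs = est.quantile([0.05, 0.95]).T
    qs.columns = ["q05", "q95"]
    ci = full_fit.wald_ci(0.95)
    inside = (est.ge(ci["lo"], axis=1) & est.le(ci["hi"], axis=1))
    trend = 100.0 * inside.mean(axis=0)
    return CvSummary(coef_quantiles=qs, est_trend=trend, estimates=est,
                     n_attempted=n_attempted, n_converged=len(est))
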