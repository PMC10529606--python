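"""Linear (mixed) models of trip characteristics.

Trip frequency (one row per animal) is modelled with an ordinary linear
model; trip distance, trip duration and haulout duration (one row per
complete trip, ln-transformed) carry a Gaussian random intercept for pup
identity.  All fits use maximum likelihood so AICc ranking and
likelihood-ratio comparisons across fixed-effect structures are valid.
Marginal and conditional R2 follow the variance-partition formulas
R2m = var_f / (var_f + var_re + var_res), R2c = (var_f + var_re) / (same).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from puptrack.selection import aicc, akaike_table, lr_test

log = logging.getLogger(__name__)

SINGULAR_TOL = 1e-6


@dataclass
class LmFit:
    response: str
    transform: str                 # "identity" | "ln"
    fixed: list
    random_intercept: bool
    coef: pd.DataFrame             # estimate, se, t
    re_var: float
    resid_var: float
    loglik: float
    k: int
    n: int
    aicc: float
    r2_marginal: float
    r2_conditional: float
    singular: bool

    @property
    def formula(self) -> str:
        terms = list(self.fixed) if self.fixed else ["1"]
        if self.random_intercept:
            terms.append("(1 | id)")
        return "~ " + " + ".join(terms)


def _design(table: pd.DataFrame, fixed: list) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for term in fixed:
        if "*" in term or ":" in term:
            a, b = [s.strip() for s in term.replace("*", ":").split(":")]
            X[term] = _column(table, a) * _column(table, b)
        else:
            X[term] = _column(table, term)
    return X


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name == "sex":
        col = table["sex"]
        if col.dtype == object:
            return (col == "female").astype(float).to_numpy()
        return (col.to_numpy(float) == 2).astype(float)  # tabular 1=male, 2=female
    return table[name].to_numpy(float)


def fit_trip_model(table: pd.DataFrame, response: str, fixed: list,
                   random_intercept: bool = True,
                   transform: str = "identity") -> LmFit:
    """ML fit of one trip-characteristic model.

    ``transform='ln'`` models ln(response); non-positive rows raise with
    their index listed.  With a random intercept at the variance floor the
    ``singular`` flag is set and R2m = R2c.
    """
    data = table.dropna(subset=[response]).copy()
    y = data[response].to_numpy(float)
    if transform == "ln":
        bad = np.flatnonzero(y <= 0)
        if bad.size:
            raise ValueError(f"ln-transform needs positive values; offending rows: "
                             f"{data.index[bad].tolist()}")
        y = np.log(y)
    X = _design(data, fixed)
    p = X.shape[1]
    n = len(y)

    if random_intercept:
        groups = data["id"].to_numpy()
        model = sm.MixedLM(y, X, groups=groups)
        res = None
        import warnings
        for method in ("lbfgs", "powell"):
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(reml=False, method=method, maxiter=500, disp=False)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if res is not None and not np.isfinite(res.llf):
            res = None  # degenerate profile likelihood at the RE boundary
        k = p + 2  # fixed effects + RE variance + residual variance
        if res is not None:
            params = np.asarray(res.fe_params)
            se = np.asarray(res.bse_fe)
            # statsmodels stores cov_re on the natural (response) scale
            re_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
            resid_var = float(res.scale)
            loglik = float(res.llf)
            singular = re_var < SINGULAR_TOL * resid_var
        else:
            # RE variance at the boundary: the ML fit degenerates to OLS
            log.warning("mixed fit singular for %s ~ %s; using boundary fit",
                        response, "+".join(fixed) or "1")
            ols = sm.OLS(y, X.to_numpy()).fit()
            params = np.asarray(ols.params)
            se = np.asarray(ols.bse)
            re_var = 0.0
            resid_var = float(ols.ssr / n)
            loglik = float(ols.llf)
            singular = True
        coef = pd.DataFrame({"estimate": params, "se": se}, index=list(X.columns))
    else:
        res = sm.OLS(y, X.to_numpy()).fit()
        params = res.params
        re_var = 0.0
        resid_var = float(res.ssr / n)  # ML variance
        loglik = float(res.llf)
        k = p + 1
        singular = False
        coef = pd.DataFrame({
            "estimate": np.asarray(params), "se": np.asarray(res.bse),
        }, index=list(X.columns))

    coef["t"] = coef["estimate"] / coef["se"]
    coef["p"] = 2 * stats.norm.sf(np.abs(coef["t"]))

    fitted_fixed = X.to_numpy() @ np.asarray(params)
    var_f = float(np.var(fitted_fixed))
    denom = var_f + re_var + resid_var
    r2m = var_f / denom if denom > 0 else np.nan
    r2c = (var_f + re_var) / denom if denom > 0 else np.nan

    try:
        crit = aicc(loglik, k, n)
    except ValueError:
        log.warning("AICc undefined for %s (n=%d, k=%d)", response, n, k)
        crit = np.nan
    return LmFit(
        response=response, transform=transform, fixed=list(fixed),
        random_intercept=random_intercept, coef=coef, re_var=re_var,
        resid_var=resid_var, loglik=loglik, k=k, n=n,
        aicc=crit, r2_marginal=r2m, r2_conditional=r2c,
        singular=singular,
    )


def _is_nested(small: LmFit, big: LmFit) -> bool:
    return (set(small.fixed) <= set(big.fixed)
            and small.random_intercept == big.random_intercept)


def rank_and_test(fits: list[LmFit]) -> tuple[pd.DataFrame, dict | None]:
    """AICc ranking plus the likelihood-ratio confirmation of the winner.

    The best-AICc model is compared against the highest-LL candidate when
    the two differ and are nested; requesting a non-nested LR comparison
    raises.
    """
    usable = [f for f in fits if np.isfinite(f.aicc)]
    if not usable:
        raise ValueError("no candidate has a defined AICc (n too small)")
    if len(usable) < len(fits):
        log.warning("dropping %d candidate(s) with undefined AICc",
                    len(fits) - len(usable))
    fits = usable
    rows = [{"model": f.formula, "df": f.k, "LL": f.loglik, "n": f.n,
             "AICc": f.aicc} for f in fits]
    table = akaike_table(rows)
    by_formula = {f.formula: f for f in fits}
    best = by_formula[table["model"].iloc[0]]
    highest_ll = max(fits, key=lambda f: f.loglik)
    lr = None
    if highest_ll.formula != best.formula:
        if not _is_nested(best, highest_ll):
            raise ValueError("LR confirmation requested for non-nested models")
        lr = lr_test(highest_ll.loglik, best.loglik, highest_ll.k, best.k)
    return table, lr


def summary_stats(values: pd.Series | np.ndarray) -> dict:
    """Mean, sample sd, SE, and CV (%) of one column."""
    x = pd.Series(values).dropna().to_numpy(float)
    n = x.size
    if n < 2:
        log.warning("summary_stats: n < 2, dispersion undefined")
        return {"n": n, "mean": float(x.mean()) if n else np.nan,
                "sd": np.nan, "se": np.nan, "cv_pct": np.nan}
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return {"n": n, "mean": mean, "sd": sd, "se": sd / np.sqrt(n),
            "cv_pct": 100.0 * sd / mean if mean != 0 else 0.0 if sd == 0 else np.nan}


def pearson_test(x, y) -> dict:
    """Pearson correlation with its t-based p-value (pairwise complete)."""
    df = pd.DataFrame({"x": x, "y": y}).dropna()
    r, p = stats.pearsonr(df["x"], df["y"])
    return {"r": float(r), "p": float(p), "n": len(df)}


def welch_ttest(a, b) -> dict:
    """Welch two-sample t-test (unequal variances)."""
    a = pd.Series(a).dropna().to_numpy(float)
    b = pd.Series(b).dropna().to_numpy(float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "n1": a.size, "n2": b.size}
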