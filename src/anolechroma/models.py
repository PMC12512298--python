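"""Seasonal, thermal and background-matching models of color morph.

Three model families are fit to green(1)/brown(0) observation records and
compared by AIC (deviance + 2 * effective degrees of freedom):

* penalized binomial GAMs of week-of-year (cyclic cubic spline, period 52)
  and latitude, including a tensor-product interaction variant;
* binomial logistic regressions of hourly temperature with a breeding /
  non-breeding season term, including a temperature-by-season interaction;
* ordinary least squares of organism greenness on background greenness,
  with a temperature-confounder check.

Predictions are formed on the logit scale with +/- z * SE bands and
back-transformed to probabilities.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.special import expit, logit
from scipy.stats import linregress, norm, pearsonr
import statsmodels.api as sm

from anolechroma.errors import (
    ConvergenceError,
    InvalidComparisonError,
    InvalidInputError,
)
from anolechroma.splines import CyclicCubicBasis

__all__ = [
    "ModelFitResult",
    "AICComparison",
    "BackgroundLMResult",
    "assign_season",
    "week_of_year",
    "fit_logistic",
    "fit_cyclic_gam",
    "aic_compare",
    "predict_with_ci",
    "fit_background_lm",
    "LOGISTIC_VARIANTS",
    "GAM_VARIANTS",
]

WEEKS_PER_YEAR = 52.0
BREEDING_MONTHS = range(4, 10)  # April through September, inclusive

LOGISTIC_VARIANTS = ("temp_only", "temp_plus_season", "temp_by_season_interaction")
GAM_VARIANTS = ("week_only", "week_plus_lat", "week_by_lat_interaction")

_COEF_BLOWUP = 30.0  # |logit coefficient| beyond this signals separation


# ---------------------------------------------------------------------------
# record-level derived covariates


def assign_season(date) -> str:
    """``breeding`` for dates from 1 April through 30 September, else
    ``nonbreeding``.  Accepts anything pandas can parse as a timestamp."""
    ts = pd.Timestamp(date)
    return "breeding" if ts.month in BREEDING_MONTHS else "nonbreeding"


def week_of_year(dates) -> np.ndarray:
    """Continuous week in [0, 52): (day_of_year - 1)/7, wrapped modulo 52
    (day 365 folds onto week 0 so the cycle closes; day 366 maps to 365)."""
    idx = pd.DatetimeIndex(np.atleast_1d(pd.to_datetime(dates)))
    doy = np.minimum(idx.dayofyear.to_numpy(dtype=float), 365.0)
    return ((doy - 1.0) / 7.0) % WEEKS_PER_YEAR


def _green_indicator(records: pd.DataFrame) -> np.ndarray:
    labels = records["label"].to_numpy()
    bad = set(np.unique(labels)) - {"green", "brown"}
    if bad:
        raise InvalidInputError(f"unexpected labels {sorted(bad)}; expected green/brown")
    y = (labels == "green").astype(float)
    if y.min() == y.max():
        raise InvalidInputError("both labels must be present to fit a binomial model")
    return y


def _fingerprint(y: np.ndarray, index) -> str:
    h = hashlib.sha1()
    h.update(np.asarray(y, dtype=np.float64).tobytes())
    h.update(str(len(y)).encode())
    return h.hexdigest()


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))


def _null_deviance(y: np.ndarray) -> float:
    return _binomial_deviance(y, np.full_like(y, y.mean()))


# ---------------------------------------------------------------------------
# results


@dataclass
class ModelFitResult:
    """A fitted binomial model: parametric coefficients, fit statistics and
    a prediction closure returning (linear predictor, SE) for new data."""

    model_name: str
    coefficients: dict
    standard_errors: dict
    pvalues: dict
    deviance: float
    null_deviance: float
    effective_df: float
    aic: float
    deviance_explained: float
    predict: Callable[[pd.DataFrame], tuple[np.ndarray, np.ndarray]]
    n_obs: int
    data_fingerprint: str
    smoothing: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.deviance > self.null_deviance + 1e-8:
            raise InvalidInputError(
                f"{self.model_name}: deviance {self.deviance} exceeds null "
                f"deviance {self.null_deviance}"
            )

    @property
    def adjusted_pseudo_r2(self) -> float:
        """Approximate adjusted pseudo-R^2:
        1 - (deviance/(n - edf)) / (null_deviance/(n - 1))."""
        n = self.n_obs
        return 1.0 - (self.deviance / (n - self.effective_df)) / (
            self.null_deviance / (n - 1.0)
        )

    def summary_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "pvalues": self.pvalues,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "effective_df": self.effective_df,
            "aic": self.aic,
            "deviance_explained": self.deviance_explained,
            "adjusted_pseudo_r2_approx": self.adjusted_pseudo_r2,
            "smoothing": self.smoothing,
            "n_obs": self.n_obs,
            "extras": {
                k: v for k, v in self.extras.items() if not callable(v)
            },
        }


@dataclass
class AICComparison:
    """Result of comparing fits on the same records by AIC."""

    fits: list
    best: str
    delta_aic: float  # best minus runner-up, <= 0

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "model_name": f.model_name,
                "aic": f.aic,
                "effective_df": f.effective_df,
                "deviance": f.deviance,
                "deviance_explained": f.deviance_explained,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class BackgroundLMResult:
    """OLS of organism greenness on background greenness plus the
    temperature-confounder check."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_obs: int
    temp_correlation: float | None = None
    temp_correlation_p: float | None = None
    temp_regression_p: float | None = None

    def summary_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "temp_correlation": self.temp_correlation,
            "temp_correlation_p": self.temp_correlation_p,
            "temp_regression_p": self.temp_regression_p,
        }


# ---------------------------------------------------------------------------
# logistic regressions (temperature x season)


def _logistic_design(df: pd.DataFrame, variant: str) -> tuple[np.ndarray, list[str]]:
    temp = np.asarray(df["hourly_temp"], dtype=float)
    names = ["intercept", "hourly_temp"]
    cols = [np.ones_like(temp), temp]
    if variant != "temp_only":
        breeding = (df["season"].to_numpy() == "breeding").astype(float)
        names.append("breeding")
        cols.append(breeding)
        if variant == "temp_by_season_interaction":
            names.append("hourly_temp:breeding")
            cols.append(temp * breeding)
    return np.column_stack(cols), names


def fit_logistic(records: pd.DataFrame, formula_variant: str) -> ModelFitResult:
    """Maximum-likelihood binomial logistic regression of green(1)/brown(0).

    Variants: ``temp_only`` (intercept + hourly temperature),
    ``temp_plus_season`` (+ breeding indicator),
    ``temp_by_season_interaction`` (+ temperature x breeding).
    AIC = deviance + 2 * number of coefficients.
    """
    if formula_variant not in LOGISTIC_VARIANTS:
        raise InvalidInputError(f"unknown variant {formula_variant!r}")
    if formula_variant != "temp_only":
        counts = records["season"].value_counts()
        if counts.get("breeding", 0) < 10 or counts.get("nonbreeding", 0) < 10:
            raise InvalidInputError("need >= 10 records per season level")
    y = _green_indicator(records)
    X, names = _logistic_design(records, formula_variant)

    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    except PerfectSeparationError as exc:
        raise ConvergenceError(f"complete separation: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > _COEF_BLOWUP:
        worst = names[int(np.argmax(np.abs(params)))]
        raise ConvergenceError(
            f"non-convergence (suspected separation) on term {worst!r}"
        )

    cov = np.asarray(res.cov_params(), dtype=float)
    ses = np.sqrt(np.diag(cov))
    zs = params / ses
    pvals = 2.0 * norm.sf(np.abs(zs))
    deviance = float(res.deviance)
    p = len(names)
    aic = deviance + 2.0 * p
    nulldev = float(res.null_deviance)

    def predict(newdata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        needed = {"hourly_temp"} | (
            {"season"} if formula_variant != "temp_only" else set()
        )
        missing = needed - set(newdata.columns)
        if missing:
            raise InvalidInputError(f"newdata missing covariates: {sorted(missing)}")
        Xn, _ = _logistic_design(newdata, formula_variant)
        lp = Xn @ params
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xn, cov, Xn))
        return lp, se

    extras = {"season_slopes": _season_slopes(formula_variant, names, params, cov)}
    return ModelFitResult(
        model_name=formula_variant,
        coefficients=dict(zip(names, params.tolist())),
        standard_errors=dict(zip(names, ses.tolist())),
        pvalues=dict(zip(names, pvals.tolist())),
        deviance=deviance,
        null_deviance=nulldev,
        effective_df=float(p),
        aic=aic,
        deviance_explained=(nulldev - deviance) / nulldev,
        predict=predict,
        n_obs=len(y),
        data_fingerprint=_fingerprint(y, records.index),
        extras=extras,
    )


def _season_slopes(variant, names, params, cov) -> dict:
    """Per-season temperature slope, SE, z and p from the fitted terms."""
    idx = {n: i for i, n in enumerate(names)}
    i_t = idx["hourly_temp"]
    out = {}
    for season in ("nonbreeding", "breeding"):
        contrast = np.zeros(len(names))
        contrast[i_t] = 1.0
        if season == "breeding" and "hourly_temp:breeding" in idx:
            contrast[idx["hourly_temp:breeding"]] = 1.0
        est = float(contrast @ params)
        se = float(np.sqrt(contrast @ cov @ contrast))
        z = est / se if se > 0 else np.inf
        out[season] = {
            "slope": est,
            "se": se,
            "z": z,
            "p_value": float(2.0 * norm.sf(abs(z))),
        }
    return out


# ---------------------------------------------------------------------------
# penalized cyclic GAMs (week x latitude)

_GCV_GRID = np.logspace(-4.0, 7.0, 45)


def _pirls(X, y, S_pen, lam, eta0=None, max_iter=200, tol=1e-9):
    """Penalized IRLS for a binomial GLM with logit link.

    Minimizes deviance + lam * beta' S beta.  Returns (beta, eta, deviance,
    edf, cov) where cov is the Bayesian posterior covariance
    (X'WX + lam S)^-1 and edf = tr[(X'WX + lam S)^-1 X'WX].
    """
    n, p = X.shape
    P = lam * S_pen
    if eta0 is None:
        mu = (y + 0.5) / 2.0
        eta = logit(mu)
    else:
        eta = np.asarray(eta0, dtype=float).copy()
    dev = np.inf
    beta = np.zeros(p)
    H = None
    for _ in range(max_iter):
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw
        try:
            beta_new = np.linalg.solve(H + P, X.T @ (w * z))
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(H + P + 1e-8 * np.eye(p), X.T @ (w * z))
        eta_new = X @ beta_new
        dev_new = _binomial_deviance(y, expit(eta_new))
        # step-halve if the penalized objective worsens
        step = 1.0
        pen_old = dev + lam * float(beta @ S_pen @ beta)
        while (
            dev_new + lam * float(beta_new @ S_pen @ beta_new) > pen_old + 1e-10
            and step > 1e-4
            and np.isfinite(pen_old)
        ):
            step /= 2.0
            beta_new = beta + step * (beta_new - beta)
            eta_new = X @ beta_new
            dev_new = _binomial_deviance(y, expit(eta_new))
        converged = abs(dev_new - dev) < tol * (abs(dev_new) + 0.1)
        beta, eta, dev = beta_new, eta_new, dev_new
        if converged:
            break
    mu = np.clip(expit(eta), 1e-10, 1.0 - 1e-10)
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None])
    A = np.linalg.solve(H + P, H)
    edf = float(np.trace(A))
    cov = np.linalg.inv(H + P)
    return beta, eta, dev, edf, cov


class _LatTransform:
    """Centered/scaled latitude and an orthogonalized quadratic term."""

    def __init__(self, lat: np.ndarray):
        self.mean = float(np.mean(lat))
        self.sd = float(np.std(lat)) or 1.0
        l1 = (lat - self.mean) / self.sd
        l2 = l1**2
        A = np.column_stack([np.ones_like(l1), l1])
        self.proj, *_ = np.linalg.lstsq(A, l2, rcond=None)

    def columns(self, lat: np.ndarray) -> np.ndarray:
        l1 = (np.asarray(lat, dtype=float) - self.mean) / self.sd
        l2o = l1**2 - self.proj[0] - self.proj[1] * l1
        return np.column_stack([l1, l2o])


def _gam_design(week, lat_cols, basis, Z, variant):
    """Design matrix and penalty for a GAM variant.

    Layout: [intercept | lat columns (if any) | penalized smooth columns].
    """
    Xw = basis.design(week) @ Z  # constrained cyclic basis, sums to ~0
    n = Xw.shape[0]
    intercept = np.ones((n, 1))
    if variant == "week_only":
        X = np.hstack([intercept, Xw])
        n_unpen = 1
        blocks = [Xw.shape[1]]
    elif variant == "week_plus_lat":
        X = np.hstack([intercept, lat_cols, Xw])
        n_unpen = 1 + lat_cols.shape[1]
        blocks = [Xw.shape[1]]
    elif variant == "week_by_lat_interaction":
        tensor = [Xw, Xw * lat_cols[:, [0]], Xw * lat_cols[:, [1]]]
        X = np.hstack([intercept, lat_cols] + tensor)
        n_unpen = 1 + lat_cols.shape[1]
        blocks = [Xw.shape[1]] * 3
    else:
        raise InvalidInputError(f"unknown variant {variant!r}")
    return X, n_unpen, blocks


def _penalty_matrix(p, n_unpen, blocks, S_block):
    S = np.zeros((p, p))
    pos = n_unpen
    for width in blocks:
        S[pos : pos + width, pos : pos + width] = S_block
        pos += width
    return S


def fit_cyclic_gam(
    records: pd.DataFrame, variant: str, n_knots: int = 8
) -> ModelFitResult:
    """Penalized binomial GAM of green(1)/brown(0) on week (and latitude).

    The week effect is a cyclic cubic regression spline with period 52
    (predictions at week 0 and week 52 are identical); the latitude effect
    is a rank-3 polynomial smooth {1, lat, lat^2} (orthogonalized); the
    interaction variant uses the tensor product of the two marginal bases.
    A single smoothing parameter on the week-direction curvature is chosen
    by GCV over a fixed grid; effective df is the trace of the penalized
    hat matrix and AIC = deviance + 2 * edf.
    """
    if variant not in GAM_VARIANTS:
        raise InvalidInputError(f"unknown variant {variant!r}")
    y = _green_indicator(records)
    week = np.asarray(records["week"], dtype=float)
    if week.max() - week.min() < 0.8 * WEEKS_PER_YEAR:
        warnings.warn(
            "observed weeks span less than ~80% of the annual cycle; the "
            "cyclic fit may be poorly identified",
            stacklevel=2,
        )

    basis = CyclicCubicBasis(n_knots=n_knots, period=WEEKS_PER_YEAR)
    Xw_raw = basis.design(week)
    # sum-to-zero constraint over the observed data -> identifiable with intercept
    Z = null_space(Xw_raw.sum(axis=0, keepdims=True))
    S_block = Z.T @ basis.S @ Z

    lat = np.asarray(records["latitude"], dtype=float)
    lat_t = _LatTransform(lat)
    lat_cols = lat_t.columns(lat)

    X, n_unpen, blocks = _gam_design(week, lat_cols, basis, Z, variant)
    S_pen = _penalty_matrix(X.shape[1], n_unpen, blocks, S_block)

    best = None
    eta = None
    for lam in _GCV_GRID:
        beta, eta, dev, edf, cov = _pirls(X, y, S_pen, lam, eta0=eta)
        n = len(y)
        gcv = n * dev / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, dev, edf, cov)
    gcv, lam, beta, dev, edf, cov = best

    if np.max(np.abs(beta)) > _COEF_BLOWUP:
        raise ConvergenceError("non-convergence (suspected separation) in GAM fit")

    nulldev = _null_deviance(y)
    names = _gam_coef_names(variant, n_unpen, blocks)
    ses = np.sqrt(np.diag(cov))

    def predict(newdata: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        if "week" not in newdata.columns:
            raise InvalidInputError("newdata must have a 'week' column")
        wk = np.asarray(newdata["week"], dtype=float)
        if variant == "week_only":
            lc = np.zeros((len(wk), 2))
        else:
            if "latitude" not in newdata.columns:
                raise InvalidInputError("newdata must have a 'latitude' column")
            lc = lat_t.columns(np.asarray(newdata["latitude"], dtype=float))
        Xn, _, _ = _gam_design(wk, lc, basis, Z, variant)
        lp = Xn @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xn, cov, Xn))
        return lp, se

    return ModelFitResult(
        model_name=variant,
        coefficients=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, ses.tolist())),
        pvalues={},
        deviance=dev,
        null_deviance=nulldev,
        effective_df=edf,
        aic=dev + 2.0 * edf,
        deviance_explained=(nulldev - dev) / nulldev,
        predict=predict,
        n_obs=len(y),
        data_fingerprint=_fingerprint(y, records.index),
        smoothing={"lambda": float(lam), "gcv": float(gcv)},
        extras={"n_knots": n_knots},
    )


def _gam_coef_names(variant, n_unpen, blocks):
    names = ["intercept"]
    if n_unpen == 3:
        names += ["lat", "lat2"]
    prefixes = {1: ["s(week)"], 3: ["s(week)", "s(week):lat", "s(week):lat2"]}[
        len(blocks)
    ]
    for prefix, width in zip(prefixes, blocks):
        names += [f"{prefix}.{i}" for i in range(width)]
    return names


# ---------------------------------------------------------------------------
# model comparison and prediction


def aic_compare(fits: Sequence[ModelFitResult]) -> AICComparison:
    """Select the minimum-AIC fit; ties go to fewer effective df.

    ``delta_aic`` is best minus runner-up and therefore <= 0.  All fits
    must have been produced from the same records.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise InvalidInputError("need at least 2 fits to compare")
    prints = {f.data_fingerprint for f in fits}
    if len(prints) != 1:
        raise InvalidComparisonError("fits were produced from differing record sets")
    ranked = sorted(fits, key=lambda f: (f.aic, f.effective_df))
    return AICComparison(
        fits=fits,
        best=ranked[0].model_name,
        delta_aic=ranked[0].aic - ranked[1].aic,
    )


def predict_with_ci(
    fit: ModelFitResult, newdata: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Back-transformed probability with a confidence band.

    The linear predictor +/- z * SE is formed on the logit scale and all
    three values are inverse-logit transformed, guaranteeing bounds in
    (0, 1) and lower <= probability <= upper.
    """
    if not (0.0 < level < 1.0):
        raise InvalidInputError(f"level {level} outside (0, 1)")
    lp, se = fit.predict(newdata)
    z = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "probability": expit(lp),
            "lower": expit(lp - z * se),
            "upper": expit(lp + z * se),
        },
        index=newdata.index,
    )


# ---------------------------------------------------------------------------
# background matching


def fit_background_lm(records: pd.DataFrame) -> BackgroundLMResult:
    """OLS of organism greenness on background-ring greenness.

    Also reports the temperature-confounder check when ``hourly_temp`` is
    present: Pearson correlation of background greenness with temperature
    and the slope p-value of the reverse regression (temperature on
    background greenness).
    """
    x = np.asarray(records["bg_greenness"], dtype=float)
    y = np.asarray(records["greenness"], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise InvalidInputError("need >= 3 records with finite greenness indices")
    if np.ptp(x) == 0:
        raise InvalidInputError("background greenness has zero variance")
    res = linregress(x, y)

    temp_r = temp_r_p = temp_reg_p = None
    if "hourly_temp" in records.columns:
        t = np.asarray(records["hourly_temp"], dtype=float)[ok]
        if np.isfinite(t).all() and np.var(t) > 0:
            r, rp = pearsonr(x, t)
            temp_r, temp_r_p = float(r), float(rp)
            temp_reg_p = float(linregress(x, t).pvalue)

    return BackgroundLMResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_obs=len(x),
        temp_correlation=temp_r,
        temp_correlation_p=temp_r_p,
        temp_regression_p=temp_reg_p,
    )
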