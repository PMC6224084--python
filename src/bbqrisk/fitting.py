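"""Fitting of all input distributions.

* gamma amount-per-meal distributions per sex x weight class (ML),
* left-censored lognormal concentration distributions with sample-specific
  limits of detection (ML on the censored likelihood),
* censored two-component lognormal mixture (MAP via EM),
* the no-intercept sex/age bodyweight regression.

Censored records enter the likelihood through the lognormal CDF at their own
LOD — no substitution (LOD/2 and similar) is ever used, because a value
below the LOD is evidence of a low concentration, not of a zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import params as P
from .params import BodyweightRegression, GammaParams, LognormalParams, MixtureLognormalParams


class FittingError(RuntimeError):
    """Raised when a fit is impossible or fails to converge."""


class ConvergenceError(FittingError):
    """EM failed to converge; ``best`` carries the best-so-far estimate."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


# --------------------------------------------------------------------------
# censored data container
# --------------------------------------------------------------------------


@dataclass
class CensoredConcentrationSet:
    """Concentration measurements for one meat type.

    ``values`` holds detected concentrations only; ``lods`` holds the limit
    of detection of every *censored* record.  A censored record carries no
    numeric concentration.
    """

    meat_type: str
    values: np.ndarray
    lods: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.lods = np.asarray(self.lods, dtype=float)
        if self.values.size and np.any(self.values <= 0):
            raise ValueError("detected concentrations must be positive")
        if self.lods.size and np.any(self.lods <= 0):
            raise ValueError("LODs must be positive")

    @property
    def n_detected(self) -> int:
        return int(self.values.size)

    @property
    def n_censored(self) -> int:
        return int(self.lods.size)

    @property
    def n(self) -> int:
        return self.n_detected + self.n_censored

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meat_type: str | None = None):
        """Build from rows with columns value / lod / censored (the
        synthetic-survey CSV layout), optionally filtering one meat type."""
        if meat_type is not None:
            df = df[df["meat_type"] == meat_type]
        cens = df["censored"].astype(bool).to_numpy()
        return cls(
            meat_type=meat_type or str(df["meat_type"].iloc[0]),
            values=df.loc[~cens, "value"].to_numpy(dtype=float),
            lods=df.loc[cens, "lod"].to_numpy(dtype=float),
        )


# --------------------------------------------------------------------------
# gamma consumption
# --------------------------------------------------------------------------


def fit_gamma_consumption(amounts, group=None) -> GammaParams:
    """Maximum-likelihood gamma fit (shape/rate) of per-meal amounts."""
    amounts = np.asarray(amounts, dtype=float)
    if amounts.size < 10:
        raise FittingError("need at least 10 amounts to fit a gamma")
    if np.any(amounts <= 0):
        raise FittingError("amounts must be strictly positive")
    if np.ptp(amounts) == 0:
        raise FittingError("degenerate (constant) amounts cannot be fit")
    shape, _, scale = stats.gamma.fit(amounts, floc=0)
    if not np.isfinite(shape) or shape <= 0 or scale <= 0:
        raise FittingError("gamma ML fit did not converge")
    return GammaParams(shape=float(shape), rate=float(1.0 / scale))


# --------------------------------------------------------------------------
# censored lognormal
# --------------------------------------------------------------------------


def censored_lognormal_loglik(
    params: LognormalParams | tuple, data: CensoredConcentrationSet
) -> float:
    """Log-likelihood of a lognormal under left censoring.

    Detected records contribute the lognormal log-density; each censored
    record contributes the log-CDF at its own LOD.
    """
    if isinstance(params, LognormalParams):
        mu, sigma = params.meanlog, params.sdlog
    else:
        mu, sigma = params
    if sigma <= 0:
        return -np.inf
    ll = 0.0
    if data.n_detected:
        y = np.log(data.values)
        ll += np.sum(stats.norm.logpdf(y, mu, sigma) - y)
    if data.n_censored:
        ll += np.sum(stats.norm.logcdf(np.log(data.lods), mu, sigma))
    return float(ll)


def fit_censored_lognormal(data: CensoredConcentrationSet) -> LognormalParams:
    """ML fit of (meanlog, sdlog) maximising the censored likelihood.

    Multistart Nelder-Mead from moment estimates of the detected values;
    with zero censoring this agrees with the closed-form MLE of the logs.
    """
    if data.n_detected < 1:
        raise FittingError(
            "all records censored: the censored likelihood is unbounded in meanlog"
        )
    if data.n < 5:
        raise FittingError("need at least 5 records in total")

    y = np.log(data.values)
    mu0 = float(np.mean(y))
    s0 = float(np.std(y)) if data.n_detected > 1 else 1.0
    s0 = max(s0, 0.05)

    def nll(theta):
        mu, logsig = theta
        return -censored_lognormal_loglik((mu, np.exp(logsig)), data)

    best = None
    for mu_start, s_start in [
        (mu0, s0),
        (mu0 - s0, 1.5 * s0),
        (mu0, 2.0 * s0),
    ]:
        res = optimize.minimize(
            nll,
            x0=[mu_start, np.log(s_start)],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise FittingError("censored lognormal fit did not converge")
    return LognormalParams(meanlog=float(best.x[0]), sdlog=float(np.exp(best.x[1])))


# --------------------------------------------------------------------------
# censored 2-component lognormal mixture (MAP by EM)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MixturePriors:
    """Priors of the MAP mixture fit.

    Weakly informative by default: uniform Beta(1,1) on the weight, a wide
    normal on each meanlog, and a weak inverse-gamma on each squared sdlog
    (the conjugate analogue of a half-normal scale prior, which keeps every
    EM update in closed form).
    """

    w_a: float = 1.0
    w_b: float = 1.0
    mu_mean: float = 0.0
    mu_sd: float = 10.0
    sigma2_shape: float = 1.0
    sigma2_scale: float = 0.5


@dataclass
class MixtureFitResult:
    params: MixtureLognormalParams
    log_posterior_trace: np.ndarray
    converged: bool
    n_iter: int


def _mixture_log_posterior(w, mu, sig, data, priors):
    """Observed-data log posterior (up to a constant)."""
    lp = 0.0
    logw = np.log([w, 1.0 - w])
    if data.n_detected:
        y = np.log(data.values)[:, None]
        comp = stats.norm.logpdf(y, mu[None, :], sig[None, :]) + logw[None, :]
        lp += np.sum(_logsumexp2(comp)) - np.sum(np.log(data.values))
    if data.n_censored:
        u = np.log(data.lods)[:, None]
        comp = stats.norm.logcdf((u - mu[None, :]) / sig[None, :]) + logw[None, :]
        lp += np.sum(_logsumexp2(comp))
    lp += (priors.w_a - 1) * np.log(w) + (priors.w_b - 1) * np.log(1 - w)
    lp += np.sum(stats.norm.logpdf(mu, priors.mu_mean, priors.mu_sd))
    lp += np.sum(
        -(priors.sigma2_shape + 1) * np.log(sig**2) - priors.sigma2_scale / sig**2
    )
    return float(lp)


def _logsumexp2(a):
    m = np.max(a, axis=1, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=1, keepdims=True)))[:, 0]


def fit_censored_lognormal_mixture_map(
    data: CensoredConcentrationSet,
    priors: MixturePriors | None = None,
    max_iter: int = 500,
    tol: float = 1e-9,
    init: tuple | None = None,
) -> MixtureFitResult:
    """MAP estimate of a censored two-component lognormal mixture by EM.

    The E-step uses exact truncated-normal moments for the latent log-value
    of each censored record; the M-step is conditional maximisation (means
    given old variances, then variances), so the penalised log-posterior is
    non-decreasing over iterations.  Components are returned in ascending
    meanlog order.
    """
    priors = priors or MixturePriors()
    if data.n < 30:
        raise FittingError("need at least 30 records for a mixture fit")
    if data.n_detected < 10:
        raise FittingError("need at least 10 detected records for a mixture fit")

    y = np.log(data.values)
    u = np.log(data.lods) if data.n_censored else np.empty(0)

    if init is None:
        lo, hi = np.quantile(y, [0.25, 0.75])
        mu = np.array([lo, hi])
        s = max(float(np.std(y)) / 2.0, 0.05)
        sig = np.array([s, s])
        w = 0.5
    else:
        w, mu, sig = init
        mu = np.asarray(mu, dtype=float).copy()
        sig = np.asarray(sig, dtype=float).copy()

    eps = 1e-12
    trace = []
    converged = False
    for it in range(max_iter):
        logw = np.log([max(w, eps), max(1 - w, eps)])

        # ---- E-step -----------------------------------------------------
        # detected records: responsibilities and first/second moments (=data)
        if data.n_detected:
            lc = stats.norm.logpdf(y[:, None], mu[None, :], sig[None, :]) + logw
            r_det = np.exp(lc - _logsumexp2(lc)[:, None])
            m1_det = np.broadcast_to(y[:, None], (y.size, 2))
            m2_det = m1_det**2
        # censored records: responsibilities via component CDFs, moments of
        # the latent log-value truncated above at the record's log-LOD
        if data.n_censored:
            alpha = (u[:, None] - mu[None, :]) / sig[None, :]
            logPhi = stats.norm.logcdf(alpha)
            lc = logPhi + logw
            r_cen = np.exp(lc - _logsumexp2(lc)[:, None])
            lam = -np.exp(stats.norm.logpdf(alpha) - logPhi)  # E[Z | Z < alpha]
            ez2 = 1.0 + alpha * lam  # E[Z^2 | Z < alpha]
            m1_cen = mu[None, :] + sig[None, :] * lam
            m2_cen = mu[None, :] ** 2 + 2 * mu[None, :] * sig[None, :] * lam + sig[None, :] ** 2 * ez2

        def stacked(det, cen):
            parts = []
            if data.n_detected:
                parts.append(det)
            if data.n_censored:
                parts.append(cen)
            return np.vstack(parts)

        r = stacked(r_det if data.n_detected else None, r_cen if data.n_censored else None)
        m1 = stacked(m1_det if data.n_detected else None, m1_cen if data.n_censored else None)
        m2 = stacked(m2_det if data.n_detected else None, m2_cen if data.n_censored else None)

        # ---- M-step (conditional) --------------------------------------
        nj = r.sum(axis=0)
        w = (nj[0] + priors.w_a - 1.0) / (data.n + priors.w_a + priors.w_b - 2.0)
        w = float(np.clip(w, eps, 1 - eps))
        # means given current variances (normal prior)
        prec_prior = 1.0 / priors.mu_sd**2
        mu = (np.sum(r * m1, axis=0) / sig**2 + priors.mu_mean * prec_prior) / (
            nj / sig**2 + prec_prior
        )
        # variances given new means (inverse-gamma prior on sigma^2)
        S = np.sum(r * (m2 - 2 * mu[None, :] * m1 + mu[None, :] ** 2), axis=0)
        sig = np.sqrt(
            (S + 2 * priors.sigma2_scale) / (nj + 2 * priors.sigma2_shape + 2)
        )
        sig = np.maximum(sig, 1e-6)

        trace.append(_mixture_log_posterior(w, mu, sig, data, priors))
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            converged = True
            break

    order = np.argsort(mu)
    mu, sig = mu[order], sig[order]
    if order[0] == 1:
        w = 1.0 - w
    result = MixtureFitResult(
        params=MixtureLognormalParams(
            w=float(np.clip(w, eps, 1 - eps)),
            component1=LognormalParams(float(mu[0]), float(sig[0])),
            component2=LognormalParams(float(mu[1]), float(sig[1])),
        ),
        log_posterior_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
    )
    if not converged:
        raise ConvergenceError(
            f"mixture EM did not converge within {max_iter} iterations", best=result
        )
    return result


# --------------------------------------------------------------------------
# bodyweight regression and weight classes
# --------------------------------------------------------------------------


def fit_bodyweight_regression(records: pd.DataFrame) -> BodyweightRegression:
    """Least-squares fit of weight = b1*sex + b2*age + b3*ln(age), no
    intercept; the residual standard error estimates the noise SD.

    ``records`` needs columns sex, age, bodyweight; duplicate rows per
    person (dinner-level surveys) are collapsed on person_id if present.
    """
    df = records
    if "person_id" in df.columns:
        df = df.drop_duplicates("person_id")
    if len(df) < 50:
        raise FittingError("need at least 50 individuals")
    sexes = set(df["sex"].unique())
    if not sexes <= {P.MALE, P.FEMALE}:
        raise FittingError(f"unknown sex codes {sexes - {P.MALE, P.FEMALE}}")
    if len(sexes) < 2:
        warnings.warn(
            "single-sex data: coefficients estimable but the sex effect is "
            "confounded with the overall level",
            stacklevel=2,
        )
    sex = df["sex"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    wt = df["bodyweight"].to_numpy(dtype=float)
    X = np.column_stack([sex, age, np.log(age)])
    if np.linalg.matrix_rank(X) < 3:
        raise FittingError("singular design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, wt, rcond=None)
    resid = wt - X @ beta
    dof = max(len(df) - 3, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    return BodyweightRegression(
        beta_sex=float(beta[0]),
        beta_age=float(beta[1]),
        beta_logage=float(beta[2]),
        residual_sd=max(residual_sd, 1e-12),
    )


def predict_bodyweight(reg: BodyweightRegression, sex, age, noise_draw=0.0):
    """Bodyweight prediction for a given standard-normal noise draw."""
    if np.any(np.asarray(age) < 1):
        raise ValueError("age must be >= 1")
    return reg.mean(sex, age) + reg.residual_sd * np.asarray(noise_draw)


def assign_weight_class(sex: int, bodyweight: float, cutoffs=None) -> str:
    """Sex-specific low/medium/high weight class.

    Continuous weights are rounded to integer kg first, so the integer band
    edges (e.g. men: <=76 | 77-87 | >=88) are exhaustive.
    """
    if bodyweight <= 0:
        raise ValueError("bodyweight must be positive")
    cutoffs = cutoffs or P.WEIGHT_CLASS_CUTOFFS
    low_max, med_max = cutoffs[int(sex)]
    w = int(np.floor(bodyweight + 0.5))  # round half up
    if w <= low_max:
        return "low"
    if w <= med_max:
        return "medium"
    return "high"
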