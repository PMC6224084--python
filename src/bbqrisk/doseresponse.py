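"""Two-stage quantal dose-response model.

Extra risk of a tumour at dose d is

    ER(d) = 1 - exp(-(d/b) - c (d/b)^2)

with potency b (dose units) and dimensionless shape c >= 0.  Observed
incidence allows a background a: p(d) = a + (1 - a) ER(d).  The module
provides ML fitting to quantal data, parametric-bootstrap parameter
uncertainty, benchmark-dose computation (BMD and BMDL), a percentile-matched
two-piece lognormal sampler for published (2.5th, median, 97.5th) parameter
summaries, and the linear-extrapolation / margin-of-exposure comparators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .fitting import FittingError
from .params import PercentileSummary


@dataclass(frozen=True)
class TwoStageParams:
    b: float
    c: float
    a: float = 0.0  # background incidence

    def __post_init__(self):
        if not self.b > 0:
            raise ValueError("potency b must be positive")
        if self.c < 0:
            raise ValueError("shape c must be non-negative")
        if not 0.0 <= self.a < 1.0:
            raise ValueError("background must lie in [0, 1)")


@dataclass
class ParamUncertainty:
    """Empirical uncertainty of (b, c): paired bootstrap draws."""

    b: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.b.shape != self.c.shape:
            raise ValueError("b and c draws must be paired")
        if np.any(self.b <= 0) or np.any(self.c < 0):
            raise ValueError("invalid parameter draws")

    @property
    def n(self) -> int:
        return int(self.b.size)


def two_stage_extra_risk(dose, params: TwoStageParams):
    """Extra risk ER(d) in [0, 1), strictly increasing in dose."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    q = d / params.b
    er = -np.expm1(-(q + params.c * q**2))
    return er if er.ndim else float(er)


def _incidence(dose, a, b, c):
    er = -np.expm1(-(dose / b + c * (dose / b) ** 2))
    return a + (1.0 - a) * er


def _binom_negloglik(theta, dose, n, k, fix_a):
    if fix_a is None:
        logit_a, logb, logc = theta
        a = special.expit(logit_a)
    else:
        logb, logc = theta
        a = fix_a
    p = _incidence(dose, a, np.exp(logb), np.exp(logc))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))


def validate_study(data: pd.DataFrame) -> pd.DataFrame:
    data = data[["dose", "n", "n_tumor"]].astype(float)
    if len(data) < 3 or not (data["dose"] == 0).any():
        raise FittingError("need >= 3 dose groups including a control")
    if (data["dose"] < 0).any():
        raise FittingError("doses must be non-negative")
    if ((data["n_tumor"] < 0) | (data["n_tumor"] > data["n"])).any():
        raise FittingError("tumour counts must lie in [0, n]")
    return data


def fit_two_stage_ml(
    data: pd.DataFrame,
    fix_background: bool = True,
    fix_c: float | None = None,
    x0: TwoStageParams | None = None,
) -> TwoStageParams:
    """Binomial ML fit of the two-stage model.

    With ``fix_background`` (default) the background a is pinned at the
    observed control incidence and only (b, c) are optimised by multistart
    Nelder-Mead over (log b, log c).  ``fix_c`` pins the shape (c = 0 gives
    the one-hit model); ``x0`` warm-starts from a previous fit (used by the
    bootstrap).
    """
    data = validate_study(data)
    dose, n, k = (data[c].to_numpy() for c in ("dose", "n", "n_tumor"))
    if k.sum() == 0:
        raise FittingError("no tumours observed: dose-response uninformative")
    control = data["dose"] == 0
    a0 = float(k[control].sum() / n[control].sum())
    fix_a = a0 if fix_background else None

    if fix_c is not None:
        # 1-D problem in log b
        def nll_b(theta):
            p = _incidence(dose, a0 if fix_a is not None else 0.0, np.exp(theta[0]), fix_c)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p))

        best = None
        for b0 in (dose.max(), 5 * dose.max(), 0.2 * dose.max()):
            res = optimize.minimize(
                nll_b, x0=[np.log(b0)], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        return TwoStageParams(b=float(np.exp(best.x[0])), c=float(fix_c), a=a0)

    dmax = dose.max()
    if x0 is not None:
        starts = [(np.log(x0.b), np.log(max(x0.c, 1e-8)))]
    else:
        starts = [
            (np.log(b0), np.log(c0))
            for b0 in (dmax, 5 * dmax, 0.2 * dmax)
            for c0 in (0.1, 1.0, 10.0)
        ]

    best = None
    for s in starts:
        start = s if fix_background else (special.logit(max(a0, 1e-3)),) + s
        res = optimize.minimize(
            _binom_negloglik,
            x0=np.asarray(start),
            args=(dose, n, k, fix_a),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FittingError("two-stage ML fit did not converge")
    if fix_background:
        logb, logc = best.x
        a = a0
    else:
        logit_a, logb, logc = best.x
        a = float(special.expit(logit_a))
    return TwoStageParams(b=float(np.exp(logb)), c=float(np.exp(logc)), a=a)


def bootstrap_two_stage(
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    fix_background: bool = True,
    max_failure_fraction: float = 0.2,
) -> ParamUncertainty:
    """Parametric bootstrap of (b, c): resample tumour counts from the
    fitted binomials and refit; the joint draws preserve the b-c
    correlation."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    data = validate_study(data)
    fitted = fit_two_stage_ml(data, fix_background=fix_background)
    dose = data["dose"].to_numpy()
    n = data["n"].to_numpy().astype(int)
    p = np.clip(_incidence(dose, fitted.a, fitted.b, fitted.c), 0.0, 1.0)
    rng = np.random.default_rng(seed)

    bs, cs, failures = [], [], 0
    for _ in range(n_boot):
        kb = rng.binomial(n, p)
        boot = pd.DataFrame({"dose": dose, "n": n, "n_tumor": kb})
        try:
            est = fit_two_stage_ml(boot, fix_background=fix_background, x0=fitted)
        except FittingError:
            failures += 1
            continue
        bs.append(est.b)
        cs.append(est.c)
    if failures > max_failure_fraction * n_boot:
        raise FittingError(f"{failures}/{n_boot} bootstrap refits failed")
    return ParamUncertainty(b=np.asarray(bs), c=np.asarray(cs))


def bmd(params: TwoStageParams, bmr: float = 0.10) -> float:
    """Benchmark dose: ER(BMD) = bmr, closed form via the quadratic in d/b."""
    if not 0.0 < bmr < 1.0:
        raise ValueError("bmr must lie in (0, 1)")
    t = -np.log1p(-bmr)
    if params.c == 0:
        q = t
    else:
        q = (-1.0 + np.sqrt(1.0 + 4.0 * params.c * t)) / (2.0 * params.c)
    return float(q * params.b)


def bmd_array(b, c, bmr: float = 0.10) -> np.ndarray:
    """Vectorised BMD over paired parameter draws."""
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    t = -np.log1p(-bmr)
    q = np.where(c > 0, (-1.0 + np.sqrt(1.0 + 4.0 * c * t)) / np.where(c > 0, 2.0 * c, 1.0), t)
    return q * b


def bmdl(uncertainty: ParamUncertainty, bmr: float = 0.10, quantile: float = 0.05) -> float:
    """Lower confidence bound of the BMD: the ``quantile`` of per-draw BMDs."""
    if uncertainty.n < 100:
        raise ValueError("need at least 100 uncertainty samples")
    return float(np.quantile(bmd_array(uncertainty.b, uncertainty.c, bmr), quantile))


# --------------------------------------------------------------------------
# percentile-matched sampler for published parameter summaries
# --------------------------------------------------------------------------

_Z975 = stats.norm.ppf(0.975)


def two_piece_sigmas(summary: PercentileSummary) -> tuple[float, float, float]:
    """Log-scale location and the lower/upper sigmas of the two-piece
    lognormal that matches all three printed percentiles exactly."""
    mu = np.log(summary.median)
    sig_lo = (mu - np.log(summary.p2_5)) / _Z975
    sig_hi = (np.log(summary.p97_5) - mu) / _Z975
    return float(mu), float(sig_lo), float(sig_hi)


def sample_from_percentiles(
    summary: PercentileSummary, n: int, seed_or_rng
) -> np.ndarray:
    """Draws from the two-piece lognormal fitted to (p2.5, median, p97.5).

    A standard-normal z is scaled by the lower sigma when negative and the
    upper sigma when positive, so the three printed percentiles are matched
    exactly; equal sigmas reduce to a single lognormal.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    mu, sig_lo, sig_hi = two_piece_sigmas(summary)
    z = rng.standard_normal(n)
    return np.exp(mu + np.where(z < 0, sig_lo, sig_hi) * z)


# --------------------------------------------------------------------------
# discussion comparators
# --------------------------------------------------------------------------


def linear_extrapolation_risk(daily_dose: float, bmdl10: float) -> float:
    """Risk under linear low-dose extrapolation: 0.10 x dose / BMDL10
    (both per day)."""
    if daily_dose < 0 or bmdl10 <= 0:
        raise ValueError("doses must be positive (daily dose may be zero)")
    return 0.10 * daily_dose / bmdl10


def margin_of_exposure(bmdl10: float, daily_dose: float) -> float:
    """MOE = BMDL10 / exposure, both per day; values below ~10,000 flag a
    health concern for genotoxic carcinogens."""
    if daily_dose <= 0 or bmdl10 <= 0:
        raise ValueError("doses must be strictly positive")
    return bmdl10 / daily_dose
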