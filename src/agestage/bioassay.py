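"""Virulence-bioassay statistics.

Covers the standard toolkit of an insect-pathology screening study:

* Abbott's correction of treatment mortality for control mortality,
* the three-parameter logistic time-mortality curve
  ``Y = K / (1 + exp(a - b X))`` with the median lethal time LT50
  (defined only when the mortality asymptote K exceeds 50%),
* maximum-likelihood probit dose-response regression on log10 concentration
  with the median lethal concentration LC50 and its Fieller 95% CI,
* endophytic colonization rates, and
* arcsine-square-root ANOVA with LSD pairwise tests, Holm correction and a
  compact letter display for comparing mortality percentages across strains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .bootstrap import compact_letter_display

__all__ = [
    "FitFailureError",
    "SeparationError",
    "TimeMortalityFit",
    "LT50Result",
    "DoseResponseFit",
    "GroupComparison",
    "abbott_correction",
    "fit_time_mortality",
    "lt50",
    "fit_dose_response",
    "colonization_rate",
    "compare_groups",
]


class FitFailureError(RuntimeError):
    """A regression model could not be fitted to the data."""


class SeparationError(FitFailureError):
    """Dose-response data show no graded response (all-or-nothing at every dose)."""


# ---------------------------------------------------------------------------
# Abbott's correction and colonization
# ---------------------------------------------------------------------------


def abbott_correction(p_treat: float, p_control: float) -> float:
    """Corrected mortality % = 100 * (p_treat - p_control) / (1 - p_control).

    Both arguments are proportions in [0, 1].  A treatment mortality below the
    control gives a negative corrected value, reported as-is with a warning.
    """
    if not (0 <= p_treat <= 1 and 0 <= p_control <= 1):
        raise ValueError("mortality proportions must lie in [0, 1]")
    if p_control >= 1:
        raise ValueError("Abbott correction undefined for 100% control mortality")
    corrected = 100.0 * (p_treat - p_control) / (1.0 - p_control)
    if corrected < 0:
        warnings.warn(
            f"treatment mortality below control: corrected mortality {corrected:.2f}%",
            stacklevel=2,
        )
    return corrected


def colonization_rate(positives: int, total: int) -> float:
    """Percentage of tested plants from which the fungus was re-isolated."""
    if total <= 0:
        raise ValueError("total plants tested must be positive")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    return 100.0 * positives / total


# ---------------------------------------------------------------------------
# Time-mortality logistic and LT50
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeMortalityFit:
    """Least-squares fit of ``Y = K / (1 + exp(a - b X))`` to cumulative mortality %."""

    K: float  # upper asymptote, % mortality in (0, 100]
    a: float  # intercept
    b: float  # slope per day (> 0 for a valid fit)
    r2: float
    cov: np.ndarray  # 3x3 covariance of (K, a, b)
    days: np.ndarray
    mortality: np.ndarray

    @property
    def valid(self) -> bool:
        return 0 < self.K <= 100 and self.b > 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.K / (1.0 + np.exp(self.a - self.b * x))


@dataclass(frozen=True)
class LT50Result:
    """Median lethal time in days, or the reason it is undefined."""

    value: float | None
    ci: tuple[float, float] | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


def _logistic(x, K, a, b):
    return K / (1.0 + np.exp(a - b * x))


def fit_time_mortality(days, mortality) -> TimeMortalityFit:
    """Fit the three-parameter logistic time-mortality curve.

    ``days`` and ``mortality`` (cumulative %, 0-100) must hold at least four
    time points.  Initialisation: K0 = max observed mortality, (a0, b0) from a
    log-linearised regression of ``ln(K0/Y - 1)`` on the interior points; the
    optimisation bounds keep K in (0, 100].
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(mortality, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (day, mortality) pairs")
    if np.any(np.diff(y[np.argsort(x)]) < -1e-9):
        raise ValueError("cumulative mortality must be non-decreasing in time")
    if np.any((y < 0) | (y > 100)):
        raise ValueError("mortality must be a percentage in [0, 100]")
    if y.max() <= 0:
        raise FitFailureError("flat series at 0% mortality: no curve to fit")

    K0 = float(np.clip(y.max(), 1e-3, 100.0))
    interior = (y > 0.005 * K0) & (y < 0.995 * K0)
    if interior.sum() >= 2:
        z = np.log(K0 / y[interior] - 1.0)
        slope, intercept = np.polyfit(x[interior], z, 1)
        b0 = max(1e-3, -slope)
        a0 = intercept
    else:
        b0, a0 = 0.5, 0.5 * float(np.median(x))
    try:
        popt, pcov = optimize.curve_fit(
            _logistic,
            x,
            y,
            p0=(min(K0 * 1.02, 100.0), a0, b0),
            bounds=([1e-6, -np.inf, 1e-9], [100.0, np.inf, np.inf]),
            maxfev=20_000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitFailureError(f"time-mortality fit did not converge: {exc}") from exc
    K, a, b = (float(v) for v in popt)
    resid = y - _logistic(x, K, a, b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return TimeMortalityFit(K, a, b, r2, np.asarray(pcov), x, y)


def lt50(fit: TimeMortalityFit, z: float = 1.959963984540054) -> LT50Result:
    """LT50 = (a - ln(K/50 - 1)) / b, defined only when the asymptote K > 50%.

    A fit whose asymptote never crosses 50% mortality has no median lethal
    time; such fits are reported as undefined with the reason recorded (the
    dash convention of bioassay tables).  The CI is a delta-method interval on
    the (K, a, b) covariance.
    """
    if not fit.valid:
        return LT50Result(None, reason="invalid fit (K outside (0, 100] or slope <= 0)")
    if fit.K <= 50.0:
        return LT50Result(None, reason="asymptote <= 50%")
    K, a, b = fit.K, fit.a, fit.b
    value = (a - math.log(K / 50.0 - 1.0)) / b
    grad = np.array([-1.0 / (b * (K - 50.0)), 1.0 / b, -value / b])
    var = float(grad @ fit.cov @ grad)
    ci = None
    if np.isfinite(var) and var >= 0:
        half = z * math.sqrt(var)
        ci = (value - half, value + half)
    return LT50Result(float(value), ci=ci)


# ---------------------------------------------------------------------------
# Probit dose-response and LC50
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseFit:
    """ML probit regression of mortality on log10(concentration)."""

    intercept: float
    slope: float  # probits per log10 concentration
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    lc50: float
    lc50_ci: tuple[float, float] | None
    chi2_gof: float
    df_gof: int
    converged: bool

    @property
    def valid(self) -> bool:
        return self.converged and self.slope > 0


def _fieller_ci(alpha_hat, beta_hat, cov, z=1.959963984540054):
    """Fieller interval for the ratio -alpha/beta (log10 LC50)."""
    vaa, vab, vbb = cov[0, 0], cov[0, 1], cov[1, 1]
    A = beta_hat**2 - z**2 * vbb
    B = 2.0 * (alpha_hat * beta_hat - z**2 * vab)
    C = alpha_hat**2 - z**2 * vaa
    if A <= 0:
        return None  # slope not distinguishable from 0: unbounded interval
    disc = B**2 - 4 * A * C
    if disc < 0:
        return None
    root = math.sqrt(disc)
    lo, hi = (-B - root) / (2 * A), (-B + root) / (2 * A)
    return (10.0**lo, 10.0**hi)


def fit_dose_response(concentrations, n_total, n_dead) -> DoseResponseFit:
    """Probit regression on x = log10(concentration); LC50 = 10^(-a/b).

    Raises :class:`SeparationError` when every dose responds all-or-nothing
    (the likelihood has no finite maximum); a non-positive fitted slope is
    returned flagged invalid rather than raised.
    """
    conc = np.asarray(concentrations, dtype=float)
    n = np.asarray(n_total, dtype=float)
    d = np.asarray(n_dead, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any((d < 0) | (d > n)) or np.any(n <= 0):
        raise ValueError("invalid counts")
    if np.all((d == 0) | (d == n)):
        raise SeparationError(
            "all-or-nothing response at every dose: probit likelihood unbounded"
        )

    x = np.log10(conc)
    exog = sm.add_constant(x)
    model = sm.GLM(
        np.column_stack([d, n - d]),
        exog,
        family=sm.families.Binomial(link=sm.families.links.Probit()),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
    intercept, slope = (float(v) for v in res.params)
    cov = np.asarray(res.cov_params())
    converged = bool(res.converged)

    if slope <= 0 or not converged:
        return DoseResponseFit(
            intercept, slope, cov, math.nan, None, math.nan, 0, converged
        )
    lc50 = 10.0 ** (-intercept / slope)
    ci = _fieller_ci(intercept, slope, cov)
    mu = res.fittedvalues
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = np.nansum((d - n * mu) ** 2 / (n * mu * (1 - mu)))
    return DoseResponseFit(
        intercept,
        slope,
        cov,
        float(lc50),
        ci,
        float(pearson),
        int(conc.size - 2),
        converged,
    )


# ---------------------------------------------------------------------------
# Group comparison: arcsine-sqrt ANOVA + LSD + Holm letters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with LSD pairwise tests, Holm correction, and letters."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, t, p_raw, p_holm, significant
    letters: dict[str, str]


def _arcsine_sqrt(pct: np.ndarray) -> np.ndarray:
    """arcsin(sqrt(p)) on percentages; 0% -> 0 and 100% -> pi/2 exactly."""
    p = np.clip(np.asarray(pct, dtype=float) / 100.0, 0.0, 1.0)
    return np.arcsin(np.sqrt(p))


def compare_groups(groups: dict, transform: bool = True, alpha: float = 0.05) -> GroupComparison:
    """Compare per-replicate percentages across >= 2 groups.

    With ``transform`` the arcsine-square-root variance-stabilising transform
    is applied before the ANOVA and all pairwise LSD t-tests (performed on the
    transformed scale, Holm-adjusted at level ``alpha``); reported differences
    are on the transformed scale, letters on the groups.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {}
    for g in names:
        v = np.asarray(groups[g], dtype=float)
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
        data[g] = _arcsine_sqrt(v) if transform else v

    allv = np.concatenate([data[g] for g in names])
    n_tot = allv.size
    k = len(names)
    grand = allv.mean()
    ss_between = sum(data[g].size * (data[g].mean() - grand) ** 2 for g in names)
    ss_within = sum(float(np.sum((data[g] - data[g].mean()) ** 2)) for g in names)
    df_b, df_w = k - 1, n_tot - k
    if ss_within <= 0:
        raise FitFailureError(
            "zero within-group variance in every group: ANOVA degenerate"
        )
    msb, mse = ss_between / df_b, ss_within / df_w
    f_stat = msb / mse
    p_val = float(stats.f.sf(f_stat, df_b, df_w))

    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            na, nb = data[ga].size, data[gb].size
            diff = data[ga].mean() - data[gb].mean()
            se = math.sqrt(mse * (1.0 / na + 1.0 / nb))
            t = diff / se
            p = 2.0 * float(stats.t.sf(abs(t), df_w))
            rows.append({"group_a": ga, "group_b": gb, "diff": diff, "t": t, "p_raw": p})
    pw = pd.DataFrame(rows)
    pw["p_holm"], pw["significant"] = np.nan, False
    rej, p_adj, *_ = multipletests(pw["p_raw"].to_numpy(), alpha=alpha, method="holm")
    pw["p_holm"] = p_adj
    pw["significant"] = rej

    means = {g: float(data[g].mean()) for g in names}
    sig = {
        (row.group_a, row.group_b): bool(row.significant) for row in pw.itertuples()
    }
    letters = compact_letter_display(names, means, sig)
    return GroupComparison(float(f_stat), p_val, df_b, df_w, float(mse), pw, letters)
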