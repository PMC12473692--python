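"""Age-stage, two-sex life-table engine.

Implements the Chi & Liu age-stage two-sex framework for daily-census cohort
data.  All quantities are functions of the age-stage survival proportions
``s_xj = n_xj / N`` (probability a newborn is alive and in stage j at age x,
with the adult stage split by sex) and the age-stage fecundity ``f_xj``:

* ``l_x = sum_j s_xj``                     — age-specific survival
* ``m_x = sum_j s_xj f_xj / sum_j s_xj``   — age-specific fecundity
* ``R0  = sum_x l_x m_x``                  — net reproductive rate
* ``r`` solves ``sum_x exp(-r (x+1)) l_x m_x = 1`` (Euler-Lotka, age indexed
  from 0, end-of-day census — the Goodman/Chi exponent convention)
* ``lambda = exp(r)``, ``T = ln(R0) / r``
* ``e_xj`` (life expectancy) and ``v_xj`` (reproductive value) via forward
  propagation of the empirical age-stage transition frequencies.

Day counting: an individual observed alive at age x contributes that day to
its lifespan, so ``e_xj`` counts the current day plus expected future days and
``e_{0, first stage}`` equals the mean observed lifespan exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .cohort import AgeStageCounts, Cohort, build_age_stage_counts, cohort_arrays

__all__ = [
    "AgeStageSurvivalMatrix",
    "FecunditySchedule",
    "TransitionModel",
    "DemographicParams",
    "UndefinedParameterError",
    "survival_matrix",
    "age_specific_survival",
    "fecundity_schedule",
    "net_reproductive_rate",
    "intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "preadult_survival",
    "transition_model",
    "life_expectancy",
    "reproductive_value",
    "compute_demography",
    "solve_euler",
]


class UndefinedParameterError(ValueError):
    """A demographic parameter is undefined for this schedule (e.g. r when R0=0)."""


@dataclass(frozen=True)
class AgeStageSurvivalMatrix:
    """``s_xj`` proportions (rows: age, columns: states incl. sexed adults)."""

    s: np.ndarray  # (n_ages, n_states) float
    states: tuple[str, ...]
    N: int

    def __post_init__(self):
        s = self.s
        if np.any(s < 0) or np.any(s > 1 + 1e-12):
            raise ValueError("s_xj proportions must lie in [0, 1]")


@dataclass(frozen=True)
class FecunditySchedule:
    """Age-stage fecundity ``f_xj`` with the derived ``l_x`` and ``m_x`` vectors."""

    f: np.ndarray  # (n_ages, n_states)
    l: np.ndarray  # (n_ages,)
    m: np.ndarray  # (n_ages,)


@dataclass(frozen=True)
class TransitionModel:
    """Empirical per-(age, state) transition frequencies.

    ``p[x, j, k]`` is the fraction of individuals in state j at age x that are
    in state k at age x+1; the residual ``1 - sum_k p[x, j, :]`` died.  Only
    estimated where ``n[x, j] > 0`` (masked elsewhere).
    """

    p: np.ndarray  # (n_ages, n_states, n_states); rows with n=0 are all-zero
    n: np.ndarray  # (n_ages, n_states) occupancy counts
    states: tuple[str, ...]


@dataclass(frozen=True)
class DemographicParams:
    """Point estimates of the population parameters (None where undefined)."""

    R0: float
    r: float | None
    lam: float | None
    T: float | None
    preadult_survival: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "R0": self.R0,
            "r": self.r,
            "lambda": self.lam,
            "T": self.T,
            "preadult_survival": self.preadult_survival,
        }


# ---------------------------------------------------------------------------
# Survival and fecundity schedules
# ---------------------------------------------------------------------------


def survival_matrix(counts: AgeStageCounts, N: int | None = None) -> AgeStageSurvivalMatrix:
    """``s_xj = n_xj / N``."""
    N = counts.N if N is None else N
    if N <= 0:
        raise ValueError("cohort size N must be positive")
    return AgeStageSurvivalMatrix(counts.counts / float(N), counts.states, N)


def age_specific_survival(s: AgeStageSurvivalMatrix) -> np.ndarray:
    """``l_x = sum_j s_xj``."""
    return s.s.sum(axis=1)


def fecundity_schedule(cohort: Cohort, s: AgeStageSurvivalMatrix) -> FecunditySchedule:
    """Build ``f_xj`` (mean eggs per individual in (x, j)) plus ``l_x``/``m_x``.

    ``f_xj`` is nonzero only for the adult-female column; ``m_x`` is zero where
    nobody is alive.
    """
    arrs = cohort_arrays(cohort)
    n_ages, n_states = s.s.shape
    eggs_by = np.zeros((n_ages, n_states))
    occ = np.zeros((n_ages, n_states))
    for x in range(n_ages):
        col = arrs.state[:, x]
        for j in range(n_states):
            in_state = col == j
            occ[x, j] = in_state.sum()
            if occ[x, j]:
                eggs_by[x, j] = arrs.eggs[in_state, x].sum()
    with np.errstate(invalid="ignore"):
        f = np.where(occ > 0, eggs_by / np.maximum(occ, 1), 0.0)
    l = age_specific_survival(s)
    weighted = (s.s * f).sum(axis=1)
    m = np.divide(weighted, l, out=np.zeros_like(l), where=l > 0)
    return FecunditySchedule(f, l, m)


def net_reproductive_rate(fs: FecunditySchedule) -> float:
    """``R0 = sum_x l_x m_x``."""
    return float(np.sum(fs.l * fs.m))


# ---------------------------------------------------------------------------
# Euler-Lotka solution
# ---------------------------------------------------------------------------


def _log_euler(r: float, ages1: np.ndarray, logphi: np.ndarray) -> float:
    """log of the Euler-Lotka left-hand side; strictly decreasing in r."""
    t = -r * ages1 + logphi
    m = t.max()
    return float(m + math.log(np.exp(t - m).sum()))


def solve_euler(lxmx: np.ndarray, tol: float = 1e-10) -> float:
    """Solve ``sum_x exp(-r (x+1)) l_x m_x = 1`` for r.

    Works on the log of the (all-positive) sum so the left-hand side never
    overflows; the root is bracketed by doubling and polished with Brent's
    method.  Raises :class:`UndefinedParameterError` when the schedule has no
    reproduction (R0 = 0).
    """
    phi = np.asarray(lxmx, dtype=float)
    if not np.all(np.isfinite(phi)) or np.any(phi < 0):
        raise ValueError("l_x m_x schedule must be finite and non-negative")
    pos = phi > 0
    if not pos.any():
        raise UndefinedParameterError("R0 = 0: intrinsic rate undefined")
    ages1 = np.nonzero(pos)[0] + 1.0  # Euler exponent (x + 1), age indexed from 0
    logphi = np.log(phi[pos])

    hi = 1.0
    while _log_euler(hi, ages1, logphi) > 0:
        hi *= 2
        if hi > 1e6:  # pragma: no cover - unreachable for finite schedules
            raise RuntimeError("failed to bracket the Euler root from above")
    lo = -1.0
    while _log_euler(lo, ages1, logphi) < 0:
        lo *= 2
        if lo < -1e6:  # pragma: no cover
            raise RuntimeError("failed to bracket the Euler root from below")
    r = brentq(_log_euler, lo, hi, args=(ages1, logphi), xtol=1e-14, rtol=8.9e-16)
    if abs(math.exp(_log_euler(r, ages1, logphi)) - 1.0) > tol:
        raise RuntimeError("Euler residual above tolerance after root finding")
    return float(r)


def intrinsic_rate(fs: FecunditySchedule, tol: float = 1e-10) -> float:
    """Intrinsic rate of increase r (per day) from the fitted schedule."""
    return solve_euler(fs.l * fs.m, tol=tol)


def finite_rate(r: float) -> float:
    """``lambda = exp(r)`` (per-day finite rate of increase)."""
    return float(math.exp(r))


def mean_generation_time(R0: float, r: float) -> float:
    """``T = ln(R0) / r`` in days.

    Raises :class:`UndefinedParameterError` when r = 0 (R0 = 1: no unique
    generation time) and ``ValueError`` for non-positive R0.
    """
    if R0 <= 0:
        raise ValueError("mean generation time needs R0 > 0")
    if r == 0:
        raise UndefinedParameterError("r = 0: mean generation time undefined")
    return float(math.log(R0) / r)


def preadult_survival(cohort: Cohort) -> float:
    """Fraction of the N individuals that ever occupy an adult column."""
    arrs = cohort_arrays(cohort)
    return float(arrs.reached_adult.mean())


# ---------------------------------------------------------------------------
# Transition model, life expectancy, reproductive value
# ---------------------------------------------------------------------------


def transition_model(cohort: Cohort) -> TransitionModel:
    """Tally empirical (age, state) -> (age+1, state') transition frequencies.

    Death is the complement of the row sum.  Sexed adult columns are distinct
    states, so the pupa -> adult transition branches by sex.
    """
    arrs = cohort_arrays(cohort)
    N, n_ages = arrs.state.shape
    n_states = len(arrs.states)
    trans = np.zeros((n_ages, n_states, n_states))
    occ = np.zeros((n_ages, n_states))
    for x in range(n_ages):
        col = arrs.state[:, x]
        nxt = arrs.state[:, x + 1] if x + 1 < n_ages else np.full(N, -1, dtype=np.int16)
        for j in range(n_states):
            here = col == j
            nj = int(here.sum())
            if nj == 0:
                continue
            occ[x, j] = nj
            dest = nxt[here]
            for k in range(n_states):
                trans[x, j, k] = np.sum(dest == k) / nj
    return TransitionModel(trans, occ, arrs.states)


def life_expectancy(tm: TransitionModel) -> np.ma.MaskedArray:
    """``e_xj``: expected remaining days (current day included) at (x, j).

    Propagates a unit of survival mass forward from (x, j) through the
    empirical transition frequencies; cells never occupied are masked.
    """
    n_ages, n_states, _ = tm.p.shape
    e = np.ma.masked_all((n_ages, n_states))
    for x in range(n_ages):
        for j in range(n_states):
            if tm.n[x, j] == 0:
                continue
            mass = np.zeros(n_states)
            mass[j] = 1.0
            total = 1.0
            for i in range(x, n_ages - 1):
                mass = mass @ tm.p[i]
                total += mass.sum()
                if not mass.any():
                    break
            e[x, j] = total
    return e


def reproductive_value(
    tm: TransitionModel, fs: FecunditySchedule, r: float
) -> np.ma.MaskedArray:
    """``v_xj``: expected contribution of an individual at (x, j) to future
    population growth, discounted at the intrinsic rate r.

    ``v_xj = exp(r (x+1)) * sum_{i>=x} exp(-r (i+1)) sum_y s'_iy f_iy`` with
    the conditional occupancy ``s'`` propagated forward from a unit mass at
    (x, j).  Unoccupied cells are masked.  By construction
    ``v_{0, first stage} = lambda`` whenever all individuals start in the first
    stage at age 0.
    """
    n_ages, n_states, _ = tm.p.shape
    v = np.ma.masked_all((n_ages, n_states))
    for x in range(n_ages):
        for j in range(n_states):
            if tm.n[x, j] == 0:
                continue
            mass = np.zeros(n_states)
            mass[j] = 1.0
            acc = math.exp(-r * (x + 1)) * float(mass @ fs.f[x])
            for i in range(x, n_ages - 1):
                mass = mass @ tm.p[i]
                if not mass.any():
                    break
                acc += math.exp(-r * (i + 2)) * float(mass @ fs.f[i + 1])
            v[x, j] = math.exp(r * (x + 1)) * acc
    return v


# ---------------------------------------------------------------------------
# Convenience front door
# ---------------------------------------------------------------------------


def compute_demography(cohort: Cohort, tol: float = 1e-10) -> DemographicParams:
    """All population parameters of a cohort in one call.

    r, lambda and T are ``None`` when undefined (R0 = 0, or r = 0 for T).
    """
    counts = build_age_stage_counts(cohort)
    s = survival_matrix(counts)
    fs = fecundity_schedule(cohort, s)
    R0 = net_reproductive_rate(fs)
    r = lam = T = None
    if R0 > 0:
        r = intrinsic_rate(fs, tol=tol)
        lam = finite_rate(r)
        if r != 0:
            T = mean_generation_time(R0, r)
    return DemographicParams(R0, r, lam, T, preadult_survival(cohort))


def demography_from_phi(phi: np.ndarray, tol: float = 1e-10):
    """Fast path used by the bootstrap: (R0, r, lambda, T) from ``l_x m_x``.

    Undefined entries come back as NaN rather than raising, since bootstrap
    replicates with no surviving females are legitimate draws.
    """
    R0 = float(np.sum(phi))
    if R0 <= 0:
        return R0, math.nan, math.nan, math.nan
    r = solve_euler(phi, tol=tol)
    lam = math.exp(r)
    T = math.log(R0) / r if r != 0 else math.nan
    return R0, r, lam, T
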