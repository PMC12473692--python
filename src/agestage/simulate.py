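"""Individual-based synthetic cohorts and bioassays.

The generator emulates a laboratory rearing study of a holometabolous insect
(egg -> four larval instars -> pupa -> sexed adult) followed by a daily census:
each egg draws integer stage durations from a discretized gamma law, survives
each pre-adult day with a stage-specific probability, is sexed at pupation
(Bernoulli sex ratio), and — if female — allocates a negative-binomial lifetime
egg total across her adult days along a triangular daily profile.  Shipped
presets reproduce the published developmental-duration, longevity, fecundity
and pre-adult-survival magnitudes of *Tuta absoluta* on control tomato plants
and on plants endophytically colonized by *Beauveria bassiana* (foliar-spray
and root-irrigation inoculation).

Because a female lays her entire drawn total before death, the generative net
reproductive rate has the closed form

    R0 = P(female) * E[eggs per female] * prod_s E[p_s ** D_s],

which :func:`analytic_r0` evaluates exactly from the discretized duration
distributions; it is the ground truth for bootstrap-coverage checks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (
    BioassayTable,
    Cohort,
    DEFAULT_STAGE_ORDER,
    FEMALE,
    IndividualRecord,
    MALE,
    Observation,
    UNDETERMINED,
)

__all__ = [
    "DurationLaw",
    "FecundityLaw",
    "SimulationParams",
    "simulate_cohort",
    "simulate_bioassay",
    "analytic_r0",
    "load_preset",
    "available_presets",
]


@dataclass(frozen=True)
class DurationLaw:
    """Discretized gamma duration: round to nearest day, floor 1 day.

    ``cv = 0`` collapses to the deterministic ``max(1, round(mean))`` days.
    """

    mean: float
    cv: float = 0.2

    def __post_init__(self):
        if self.mean <= 0 or self.cv < 0:
            raise ValueError("duration law needs mean > 0 and cv >= 0")

    def _gamma(self):
        shape = 1.0 / self.cv**2
        return stats.gamma(shape, scale=self.mean / shape)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        if self.cv == 0:
            return np.full(size, max(1, round(self.mean)), dtype=int)
        shape = 1.0 / self.cv**2
        x = rng.gamma(shape, self.mean / shape, size=size)
        return np.maximum(1, np.rint(x)).astype(int)

    def pmf(self, eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
        """Exact pmf of the discretized duration (days, probabilities)."""
        if self.cv == 0:
            return np.array([max(1, round(self.mean))]), np.array([1.0])
        g = self._gamma()
        kmax = max(2, int(np.ceil(g.ppf(1 - eps))) + 1)
        ks = np.arange(1, kmax + 1)
        upper = g.cdf(ks + 0.5)
        lower = g.cdf(ks - 0.5)
        p = upper - lower
        p[0] = upper[0]  # all mass below 1.5 days rounds to 1
        return ks, p / p.sum()

    def mean_discrete(self) -> float:
        ks, p = self.pmf()
        return float(np.sum(ks * p))


@dataclass(frozen=True)
class FecundityLaw:
    """Lifetime eggs per adult female and their daily allocation.

    ``dispersion`` is the negative-binomial size parameter k (variance
    ``mu + mu^2/k``); ``None`` means every female lays exactly
    ``round(mean_eggs)``.  Oviposition starts ``preoviposition_days`` after
    adult emergence and the daily allocation follows a triangular profile
    peaking ``peak_day`` days after emergence, declining until death.
    """

    mean_eggs: float
    dispersion: float | None = 35.0
    preoviposition_days: int = 1
    peak_day: int = 3
    tail_days: int = 8

    def sample_total(self, rng: np.random.Generator) -> int:
        if self.mean_eggs < 0:
            raise ValueError("mean_eggs must be non-negative")
        if self.dispersion is None:
            return int(round(self.mean_eggs))
        k = self.dispersion
        return int(rng.negative_binomial(k, k / (k + self.mean_eggs)))


@dataclass(frozen=True)
class SimulationParams:
    """Generative description of one treatment cohort."""

    n: int = 100
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    durations: dict[str, DurationLaw] = field(default_factory=dict)
    daily_survival: dict[str, float] = field(default_factory=dict)
    p_female: float = 0.5
    fecundity: FecundityLaw = FecundityLaw(100.0)
    adult_longevity: dict[str, DurationLaw] = field(default_factory=dict)
    label: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not 0 <= self.p_female <= 1:
            raise ValueError("sex ratio must be a probability")
        preadult = self.stage_order[:-1]
        missing = [s for s in preadult if s not in self.durations]
        if missing:
            raise ValueError(f"missing duration laws for stages {missing}")
        for s in preadult:
            p = self.daily_survival.get(s, 1.0)
            if not 0 <= p <= 1:
                raise ValueError(f"daily survival for {s!r} outside [0, 1]")
        for sex in (FEMALE, MALE):
            if sex not in self.adult_longevity:
                raise ValueError(f"missing adult longevity law for {sex}")


def _triangular_weights(days: np.ndarray, peak: int, tail_end: int) -> np.ndarray:
    """Triangular daily profile: linear rise to ``peak``, linear fall hitting
    zero one day past ``tail_end``; strictly positive on ``days``."""
    start = int(days[0])
    peak = int(np.clip(peak, start, days[-1]))
    w = np.where(
        days <= peak,
        (days - start + 1.0) / (peak - start + 1.0),
        (tail_end + 1.0 - days) / (tail_end + 1.0 - peak),
    )
    return w / w.sum()


def simulate_cohort(params: SimulationParams, seed: int | None = None) -> Cohort:
    """Forward-simulate a cohort of ``params.n`` eggs; reproducible by seed."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    preadult = params.stage_order[:-1]
    adult = params.stage_order[-1]
    n = params.n
    dur_draws = {s: params.durations[s].sample(rng, n) for s in preadult}
    sex_draws = rng.random(n) < params.p_female
    longevity_f = params.adult_longevity[FEMALE].sample(rng, n)
    longevity_m = params.adult_longevity[MALE].sample(rng, n)
    individuals = []
    for i in range(n):
        durs = {s: int(dur_draws[s][i]) for s in preadult}
        sex_draw = FEMALE if sex_draws[i] else MALE
        longevity = int(longevity_f[i] if sex_draws[i] else longevity_m[i])

        # pre-adult daily survival trial for the transition age x -> x+1
        stage_of_age: list[str] = []
        for s in preadult:
            stage_of_age.extend([s] * durs[s])
        emergence = len(stage_of_age)

        death_age = None  # first age at which the individual is no longer alive
        for x, s in enumerate(stage_of_age):
            if rng.random() > params.daily_survival.get(s, 1.0):
                death_age = x + 1
                break
        if death_age is None:
            death_age = emergence + longevity

        last_alive = death_age - 1
        pupal_start = emergence - durs[preadult[-1]]
        reached_pupa = last_alive >= pupal_start
        sex = sex_draw if reached_pupa else UNDETERMINED

        eggs_by_age = np.zeros(death_age, dtype=int)
        if sex == FEMALE and last_alive >= emergence:
            fec = params.fecundity
            total = fec.sample_total(rng)
            start = emergence + fec.preoviposition_days
            tail_end = emergence + fec.peak_day + fec.tail_days
            stop = min(last_alive, tail_end)
            if start > stop:
                eggs_by_age[last_alive] = total  # window shorter than pre-oviposition
            else:
                days = np.arange(start, stop + 1)
                w = _triangular_weights(days, emergence + fec.peak_day, tail_end)
                eggs_by_age[days] = rng.multinomial(total, w)

        obs = []
        for x in range(death_age):
            stage = stage_of_age[x] if x < emergence else adult
            obs.append(Observation(x, stage, True, int(eggs_by_age[x])))
        obs.append(Observation(death_age, obs[-1].stage, False, 0))
        individuals.append(IndividualRecord(f"{params.label or 'ind'}-{i:04d}", sex, tuple(obs)))
    return Cohort(tuple(individuals), params.stage_order, params.label)


def analytic_r0(params: SimulationParams) -> float:
    """Exact generative net reproductive rate of the simulation process."""
    surv = 1.0
    for s in params.stage_order[:-1]:
        ks, p = params.durations[s].pmf()
        surv *= float(np.sum(p * params.daily_survival.get(s, 1.0) ** ks))
    return params.p_female * params.fecundity.mean_eggs * surv


def analytic_preadult_survival(params: SimulationParams) -> float:
    """Exact generative probability of reaching the adult stage."""
    surv = 1.0
    for s in params.stage_order[:-1]:
        ks, p = params.durations[s].pmf()
        surv *= float(np.sum(p * params.daily_survival.get(s, 1.0) ** ks))
    return surv


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _preset_data() -> dict:
    text = importlib.resources.files("agestage").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> tuple[str, ...]:
    return tuple(_preset_data())


def load_preset(name: str, n: int | None = None, seed: int | None = None) -> SimulationParams:
    """Load a shipped treatment preset (``control``, ``bbfs``, ``bbri``)."""
    data = _preset_data()
    if name not in data:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(data)}")
    cfg = data[name]
    fec = cfg["fecundity"]
    params = SimulationParams(
        n=int(cfg.get("n", 100)),
        stage_order=tuple(cfg.get("stage_order", DEFAULT_STAGE_ORDER)),
        durations={k: DurationLaw(**v) for k, v in cfg["durations"].items()},
        daily_survival={k: float(v) for k, v in cfg["daily_survival"].items()},
        p_female=float(cfg.get("p_female", 0.5)),
        fecundity=FecundityLaw(
            mean_eggs=float(fec["mean_eggs"]),
            dispersion=fec.get("dispersion"),
            preoviposition_days=int(fec.get("preoviposition_days", 1)),
            peak_day=int(fec.get("peak_day", 3)),
            tail_days=int(fec.get("tail_days", 8)),
        ),
        adult_longevity={k: DurationLaw(**v) for k, v in cfg["adult_longevity"].items()},
        label=name,
    )
    if n is not None:
        params = replace(params, n=n)
    if seed is not None:
        params = replace(params, seed=seed)
    return params


# ---------------------------------------------------------------------------
# Bioassay simulation
# ---------------------------------------------------------------------------


def simulate_bioassay(
    lc50: float,
    slope: float,
    n_per_dose: int,
    doses,
    control_mortality: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
    days: int = 14,
    time_a: float = 3.1,
    time_b: float = 0.56,
    strain: str = "sim",
) -> BioassayTable:
    """Binomial dose-response deaths with a logistic daily time course.

    Final mortality at dose d follows the probit model
    ``Phi(slope * (log10 d - log10 lc50))`` combined independently with the
    control mortality; daily cumulative deaths spread each replicate's final
    total along a logistic-in-time CDF.  Control replicates are emitted with
    ``concentration = 0``.
    """
    if not 0 <= control_mortality < 1:
        raise ValueError("control mortality must be in [0, 1)")
    rng = np.random.default_rng(seed)
    tgrid = np.arange(1, days + 1)
    cdf = 1.0 / (1.0 + np.exp(time_a - time_b * tgrid))
    cdf = cdf / cdf[-1]
    increments = np.diff(np.concatenate([[0.0], cdf]))

    rows = []

    def emit(conc: float, p_final: float):
        for rep in range(1, n_replicates + 1):
            dead = rng.binomial(n_per_dose, p_final)
            daily = rng.multinomial(dead, increments)
            cum = np.cumsum(daily)
            for day, c in zip(tgrid, cum):
                rows.append((strain, conc, rep, int(day), n_per_dose, int(c)))

    for d in doses:
        if np.isinf(slope):
            p = 0.5 if d == lc50 else float(d > lc50)
        else:
            p = float(stats.norm.cdf(slope * (np.log10(d) - np.log10(lc50))))
        emit(float(d), control_mortality + (1 - control_mortality) * p)
    emit(0.0, control_mortality)

    df = pd.DataFrame(
        rows, columns=["strain", "concentration", "replicate", "day", "n_total", "n_dead_cum"]
    )
    return BioassayTable(df)
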