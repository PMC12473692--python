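"""Individual-level cohort life histories and bioassay tables.

The raw input of an age-stage, two-sex life-table study is a daily census of
every individual in a cohort followed from oviposition (age 0) to death: which
developmental stage it occupies, whether it is alive, its sex (determined
morphologically at pupation), and — for adult females — the number of eggs laid
that day.  This module holds the validated in-memory model of those records,
reads and writes them as plain long-format CSV, and tallies the age × stage
count matrix ``n_xj`` that every downstream life-table quantity is built from.

Conventions
-----------
* Ages are integer days, 0-based; age 0 is the day the egg was laid, and each
  observation represents the end-of-day census.
* An individual's record consists of one row per day while alive, optionally
  followed by a single ``alive = False`` row on the day it was found dead.
* The last entry of ``stage_order`` is the sexed adult stage: in the count
  matrix it is split into ``<adult>_female`` and ``<adult>_male`` columns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_STAGE_ORDER: tuple[str, ...] = ("egg", "L1", "L2", "L3", "L4", "pupa", "adult")

FEMALE = "female"
MALE = "male"
UNDETERMINED = "undetermined"
SEXES = (FEMALE, MALE, UNDETERMINED)

COHORT_COLUMNS = ("individual_id", "sex", "age", "stage", "alive", "eggs")
BIOASSAY_COLUMNS = ("strain", "concentration", "replicate", "day", "n_total", "n_dead_cum")


class CohortError(ValueError):
    """Base class for cohort data errors."""


class CohortParseError(CohortError):
    """A malformed row in an input file (carries the offending line number)."""


class CohortValidationError(CohortError):
    """An invariant violation, naming the individual and the rule broken."""

    def __init__(self, individual_id: str, rule: str):
        self.individual_id = individual_id
        self.rule = rule
        super().__init__(f"individual {individual_id!r}: {rule}")


class BioassayValidationError(CohortError):
    """Invariant violation in a cumulative-mortality bioassay table."""


@dataclass(frozen=True)
class Observation:
    """One end-of-day census row: (age, stage, alive, eggs laid that day)."""

    age: int
    stage: str
    alive: bool
    eggs: int = 0


@dataclass(frozen=True)
class IndividualRecord:
    """Complete daily life history of one individual, from oviposition to death."""

    id: str
    sex: str
    observations: tuple[Observation, ...]

    @property
    def lifespan(self) -> int:
        """Number of days observed alive."""
        return sum(1 for o in self.observations if o.alive)

    def stages_visited(self) -> list[str]:
        seen: list[str] = []
        for o in self.observations:
            if o.alive and (not seen or seen[-1] != o.stage):
                seen.append(o.stage)
        return seen

    def reached(self, stage: str) -> bool:
        return any(o.alive and o.stage == stage for o in self.observations)

    @property
    def total_eggs(self) -> int:
        return sum(o.eggs for o in self.observations)


def _validate_individual(
    ind: IndividualRecord, stage_order: tuple[str, ...], allow_stage_skip: bool
) -> None:
    sid = ind.id
    if ind.sex not in SEXES:
        raise CohortValidationError(sid, f"unknown sex {ind.sex!r}")
    obs = ind.observations
    if not obs:
        raise CohortValidationError(sid, "no observations")
    stage_idx = {s: i for i, s in enumerate(stage_order)}
    adult = stage_order[-1]
    # Sexing happens at pupation; with collapsed stage lists that lack an
    # explicit pupal stage, sex can only be demanded once the adult stage is
    # reached.
    sexing_stage = "pupa" if "pupa" in stage_idx else adult
    sexed_from = {s for s in stage_order if stage_idx[s] >= stage_idx[sexing_stage]}

    ages = [o.age for o in obs]
    if ages != list(range(len(obs))):
        raise CohortValidationError(sid, "ages must be consecutive integers starting at 0")
    n_alive = sum(o.alive for o in obs)
    if n_alive == 0:
        raise CohortValidationError(sid, "never observed alive")
    if any(o.alive for o in obs[n_alive:]) or not all(o.alive for o in obs[:n_alive]):
        raise CohortValidationError(sid, "alive rows must precede the death row (no resurrection)")
    if len(obs) > n_alive + 1:
        raise CohortValidationError(sid, "at most one observation after death")

    prev = None
    for o in obs:
        if o.stage not in stage_idx:
            raise CohortValidationError(sid, f"stage {o.stage!r} not in stage order")
        if o.eggs < 0:
            raise CohortValidationError(sid, "negative egg count")
        if o.eggs > 0 and not (ind.sex == FEMALE and o.stage == adult and o.alive):
            raise CohortValidationError(
                sid, "eggs recorded outside a live adult-female observation"
            )
        if prev is not None:
            step = stage_idx[o.stage] - stage_idx[prev]
            if step < 0:
                raise CohortValidationError(sid, f"stage regression {prev} -> {o.stage}")
            if step > 1 and not allow_stage_skip:
                raise CohortValidationError(sid, f"stage skip {prev} -> {o.stage}")
        prev = o.stage

    if ind.sex == UNDETERMINED and any(o.alive and o.stage in sexed_from for o in obs):
        raise CohortValidationError(sid, "sex undetermined but individual reached pupation")
    if ind.sex == UNDETERMINED and any(o.alive and o.stage == adult for o in obs):
        raise CohortValidationError(sid, "adult of undetermined sex")


@dataclass(frozen=True)
class Cohort:
    """A treatment cohort: validated individual records plus the stage ordering."""

    individuals: tuple[IndividualRecord, ...]
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    label: str = ""
    allow_stage_skip: bool = False

    def __post_init__(self):
        if len(self.individuals) < 1:
            raise CohortError("a cohort needs at least one individual")
        if len(self.stage_order) < 2:
            raise CohortError("stage order needs at least a juvenile and an adult stage")
        ids = [i.id for i in self.individuals]
        if len(set(ids)) != len(ids):
            raise CohortError("duplicate individual ids")
        for ind in self.individuals:
            _validate_individual(ind, tuple(self.stage_order), self.allow_stage_skip)

    @property
    def N(self) -> int:
        return len(self.individuals)

    @property
    def adult_stage(self) -> str:
        return self.stage_order[-1]

    @property
    def states(self) -> tuple[str, ...]:
        """Stage columns with the adult stage split by sex."""
        adult = self.adult_stage
        return tuple(self.stage_order[:-1]) + (f"{adult}_female", f"{adult}_male")

    def max_age(self) -> int:
        return max(o.age for ind in self.individuals for o in ind.observations if o.alive)


def read_cohort(
    path,
    stage_order=DEFAULT_STAGE_ORDER,
    allow_stage_skip: bool = False,
    label: str | None = None,
) -> Cohort:
    """Read a long-format cohort CSV (one row per individual-day) and validate it.

    Expected header: ``individual_id,sex,age,stage,alive,eggs``.  ``alive`` is
    ``1``/``0`` (``true``/``false`` accepted).  Raises :class:`CohortParseError`
    with the line number on malformed rows and :class:`CohortValidationError`
    naming the individual and rule on invariant violations.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")

    truthy = {"1": True, "true": True, "0": False, "false": False}
    rows = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            age = int(row.age)
            eggs = int(row.eggs)
            alive = truthy[str(row.alive).strip().lower()]
        except (ValueError, KeyError, TypeError):
            raise CohortParseError(f"{path} line {line}: malformed row {tuple(row)!r}") from None
        if age < 0:
            raise CohortParseError(f"{path} line {line}: negative age")
        rows.append((str(row.individual_id), str(row.sex), age, str(row.stage), alive, eggs))

    by_id: dict[str, list] = {}
    sex_of: dict[str, str] = {}
    for iid, sex, age, stage, alive, eggs in rows:
        by_id.setdefault(iid, []).append(Observation(age, stage, alive, eggs))
        sex_of.setdefault(iid, sex)
        if sex_of[iid] != sex:
            raise CohortValidationError(iid, "inconsistent sex across rows")

    individuals = tuple(
        IndividualRecord(iid, sex_of[iid], tuple(sorted(obs, key=lambda o: o.age)))
        for iid, obs in by_id.items()
    )
    return Cohort(
        individuals,
        tuple(stage_order),
        label if label is not None else "",
        allow_stage_skip,
    )


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical long-format CSV; ``read_cohort(write_cohort(c)) == c``."""
    buf = io.StringIO()
    buf.write(",".join(COHORT_COLUMNS) + "\n")
    for ind in cohort.individuals:
        for o in ind.observations:
            buf.write(
                f"{ind.id},{ind.sex},{o.age},{o.stage},{int(o.alive)},{o.eggs}\n"
            )
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)


def collapse_stages(
    cohort: Cohort, mapping: dict[str, str], new_stage_order: tuple[str, ...]
) -> Cohort:
    """Relabel stages (e.g. merge larval instars into one ``larva`` stage).

    ``mapping`` sends old stage codes to new ones; codes absent from the mapping
    are kept.  Aggregate quantities that depend only on ``l_x`` and ``m_x``
    (R0, r, lambda, T) are invariant under such a collapse.
    """
    new_inds = []
    for ind in cohort.individuals:
        obs = tuple(
            replace(o, stage=mapping.get(o.stage, o.stage)) for o in ind.observations
        )
        new_inds.append(replace(ind, observations=obs))
    return Cohort(tuple(new_inds), tuple(new_stage_order), cohort.label, cohort.allow_stage_skip)


# ---------------------------------------------------------------------------
# Count matrices and dense per-individual arrays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeStageCounts:
    """``n_xj``: individuals alive in state j at age x (adult split by sex)."""

    counts: np.ndarray  # (n_ages, n_states) int
    states: tuple[str, ...]
    N: int


def _state_index(cohort: Cohort) -> dict[tuple[str, str], int]:
    """Map (stage, sex) to a state column, splitting the adult stage by sex."""
    states = cohort.states
    idx = {}
    adult = cohort.adult_stage
    for j, s in enumerate(cohort.stage_order[:-1]):
        for sex in SEXES:
            idx[(s, sex)] = j
    idx[(adult, FEMALE)] = states.index(f"{adult}_female")
    idx[(adult, MALE)] = states.index(f"{adult}_male")
    return idx


def build_age_stage_counts(cohort: Cohort) -> AgeStageCounts:
    """Tally ``n_xj`` from the raw records.

    The adult stage is split into female and male columns; all pre-adult
    states pool the sexes (individuals dying before pupation are retained with
    sex *undetermined*, the standard two-sex treatment).
    """
    arrs = cohort_arrays(cohort)
    _, n_ages = arrs.state.shape
    counts = np.zeros((n_ages, len(arrs.states)), dtype=int)
    for x in range(n_ages):
        col = arrs.state[:, x]
        for j in range(len(arrs.states)):
            counts[x, j] = int(np.sum(col == j))
    return AgeStageCounts(counts, arrs.states, cohort.N)


@dataclass(frozen=True)
class CohortArrays:
    """Dense per-individual arrays backing the engine and the bootstrap.

    ``state[i, x]`` is the state index of individual i at age x (-1 when not
    alive), ``eggs[i, x]`` the eggs it laid that day, ``reached_adult[i]``
    whether it ever occupied an adult column.
    """

    state: np.ndarray  # (N, n_ages) int16, -1 = not alive
    eggs: np.ndarray  # (N, n_ages) float64
    reached_adult: np.ndarray  # (N,) bool
    is_adult_female: np.ndarray  # (N,) bool
    states: tuple[str, ...]
    N: int


def cohort_arrays(cohort: Cohort) -> CohortArrays:
    n_ages = cohort.max_age() + 1
    N = cohort.N
    state = np.full((N, n_ages), -1, dtype=np.int16)
    eggs = np.zeros((N, n_ages), dtype=float)
    sidx = _state_index(cohort)
    adult_cols = {len(cohort.stage_order) - 1, len(cohort.stage_order)}
    reached = np.zeros(N, dtype=bool)
    fem = np.zeros(N, dtype=bool)
    adult_f = cohort.states.index(f"{cohort.adult_stage}_female")
    for i, ind in enumerate(cohort.individuals):
        for o in ind.observations:
            if not o.alive:
                continue
            j = sidx[(o.stage, ind.sex)]
            state[i, o.age] = j
            eggs[i, o.age] = o.eggs
            if j in adult_cols:
                reached[i] = True
            if j == adult_f:
                fem[i] = True
    return CohortArrays(state, eggs, reached, fem, cohort.states, N)


# ---------------------------------------------------------------------------
# Bioassay tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BioassayTable:
    """Cumulative daily mortality counts by strain x concentration x replicate."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in BIOASSAY_COLUMNS if c not in df.columns]
        if missing:
            raise BioassayValidationError(f"missing columns {missing}")
        if (df["n_dead_cum"] > df["n_total"]).any():
            bad = df[df["n_dead_cum"] > df["n_total"]].iloc[0]
            raise BioassayValidationError(
                f"n_dead_cum {int(bad.n_dead_cum)} exceeds n_total {int(bad.n_total)}"
            )
        if (df["n_dead_cum"] < 0).any() or (df["day"] < 1).any():
            raise BioassayValidationError("negative counts or day < 1")
        for key, grp in df.groupby(["strain", "concentration", "replicate"]):
            g = grp.sort_values("day")
            if g["day"].duplicated().any():
                raise BioassayValidationError(f"duplicate day within series {key}")
            if (np.diff(g["n_dead_cum"].to_numpy()) < 0).any():
                raise BioassayValidationError(
                    f"cumulative deaths decrease within series {key}"
                )

    def series(self, strain: str, concentration: float, replicate: int) -> pd.DataFrame:
        df = self.data
        m = (
            (df["strain"] == strain)
            & (df["concentration"] == concentration)
            & (df["replicate"] == replicate)
        )
        return df[m].sort_values("day").reset_index(drop=True)


def read_bioassay(path) -> BioassayTable:
    """Read and validate a bioassay CSV (``strain,concentration,replicate,day,n_total,n_dead_cum``)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in BIOASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(f"{path}: missing columns {missing}")
    try:
        df = df.astype(
            {
                "strain": str,
                "concentration": float,
                "replicate": int,
                "day": int,
                "n_total": int,
                "n_dead_cum": int,
            }
        )
    except ValueError as exc:
        raise CohortParseError(f"{path}: malformed value ({exc})") from None
    return BioassayTable(df.reset_index(drop=True))


def write_bioassay(table: BioassayTable, path) -> None:
    table.data.to_csv(path, index=False, columns=list(BIOASSAY_COLUMNS))
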