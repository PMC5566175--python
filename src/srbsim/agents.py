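"""Agent state, behavioral parameters, and demographic primitives.

Each individual carries the state record of the microsimulation: sex,
birth year, completed age, son preference, parity, number of living
sons, access to prenatal sex-determination technology, abortions, and a
link to the mother.  Two representations are provided: ``AgentState``, a
per-individual record used by the scalar contract functions and for CSV
export, and ``Population``, a struct-of-arrays container the engine
iterates on.

The demographic primitives are discrete-time: hazards are per-year
conception probabilities (one tick = one year), and mortality is a
per-year death probability q(x, sex, year).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .rates import (
    FERTILITY_AGE_HI,
    FERTILITY_AGE_LO,
    MAX_AGE,
    P_MALE_DEFAULT,
    InitialPopulation,
    RateSchedule,
)

FEMALE = 0
MALE = 1
SP_UNSET = -1  # son preference not yet assigned (children, burn-in)

# (name, lo, hi): the theoretically plausible box over which the six
# behavioral parameters are explored during calibration.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "gamma": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "sigma": (0.0, 2.5),
    "beta": (0.0, 0.5),
    "rho": (0.0, 2.0),
    "phi": (0.0, 20.0),
}


@dataclass(frozen=True)
class ParameterSet:
    """The six behavioral parameters plus the natural male-conception odds.

    gamma : son-preference intensity — proportional expansion of the
        birth hazard while son preference is unmet.
    alpha : birth-risk reduction once son preference is met.
    sigma : fertility-squeeze scale for abortion at parity >= 1.
    beta : fertility-squeeze scale for abortion at parity 0.
    rho : slope of the logistic technology-diffusion curve (per year).
    phi : inflection time-step of the diffusion curve (years since
        simulation start).
    p_male : probability a conception is male; 0.5122 implies a natural
        sex ratio at birth of 105.
    """

    gamma: float = 0.20
    alpha: float = 0.075
    sigma: float = 1.7
    beta: float = 0.2
    rho: float = 0.5
    phi: float = 7.0
    p_male: float = P_MALE_DEFAULT

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAMETER_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside plausible range [{lo}, {hi}]")
        if not 0.0 < self.p_male < 1.0:
            raise ValueError("p_male must lie strictly between 0 and 1")

    def with_values(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass
class AgentState:
    """One individual's record.

    ``sp``, ``parity``, ``sons`` and ``abortions`` are meaningful only
    for females; ``sp`` is ``SP_UNSET`` until assigned at reproductive
    age.
    """

    id: int
    sex: int
    birth_year: int
    age: int
    sp: int = SP_UNSET
    parity: int = 0
    sons: int = 0
    tech_access: bool = False
    abortions: int = 0
    mother_id: int = -1

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError("sex must be FEMALE (0) or MALE (1)")
        if not 0 <= self.age <= MAX_AGE:
            raise ValueError(f"age {self.age} outside 0-{MAX_AGE}")
        if self.sons > self.parity:
            raise ValueError("living sons cannot exceed parity")


# ---------------------------------------------------------------------------
# Scalar contract functions
# ---------------------------------------------------------------------------

def fertility_hazard(agent: AgentState, base_rate: float, params: ParameterSet) -> float:
    """Per-year conception probability under differential stopping behavior.

    The standard period age-specific rate applies when the woman holds no
    son preference.  While her son preference is unmet (fewer living sons
    than desired) the rate expands by (1 + gamma), capped at 1; once met
    it contracts by (1 - alpha).
    """
    if agent.sex != FEMALE:
        raise ValueError("fertility hazard is defined for female agents only")
    if not FERTILITY_AGE_LO <= agent.age <= FERTILITY_AGE_HI:
        raise ValueError(
            f"agent age {agent.age} outside reproductive span "
            f"{FERTILITY_AGE_LO}-{FERTILITY_AGE_HI}"
        )
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base rate must lie in [0, 1]")
    sp = max(agent.sp, 0)  # unset preference behaves as none
    if sp == 0:
        return base_rate
    if agent.sons < sp:
        return min(1.0, base_rate * (1.0 + params.gamma))
    return base_rate * (1.0 - params.alpha)


def fertility_hazard_vector(
    base: np.ndarray, sp: np.ndarray, sons: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """Vectorized DSB hazard over aligned arrays (engine fast path)."""
    sp_eff = np.maximum(sp, 0)
    unmet = sons < sp_eff
    met = (sons >= sp_eff) & (sp_eff > 0)
    h = base.astype(np.float64).copy()
    h[unmet] = np.minimum(1.0, h[unmet] * (1.0 + params.gamma))
    h[met] = h[met] * (1.0 - params.alpha)
    return h


def draw_sex(rng: np.random.Generator, params: ParameterSet) -> int:
    """Bernoulli sex-at-conception draw: MALE with probability p_male."""
    return MALE if rng.random() < params.p_male else FEMALE


# ---------------------------------------------------------------------------
# Population container
# ---------------------------------------------------------------------------

class Population:
    """Struct-of-arrays population; ids are strictly increasing.

    Keeping ids sorted lets the engine resolve mother links with a
    binary search instead of a hash map.
    """

    __slots__ = (
        "id",
        "sex",
        "birth_year",
        "age",
        "sp",
        "parity",
        "sons",
        "tech",
        "abortions",
        "mother_id",
        "next_id",
    )

    def __init__(self, next_id: int = 1, **arrays) -> None:
        n = len(arrays.get("id", ()))
        self.id = np.asarray(arrays.get("id", np.empty(0)), dtype=np.int64)
        self.sex = np.asarray(arrays.get("sex", np.empty(0)), dtype=np.int8)
        self.birth_year = np.asarray(
            arrays.get("birth_year", np.empty(0)), dtype=np.int32
        )
        self.age = np.asarray(arrays.get("age", np.empty(0)), dtype=np.int16)
        self.sp = np.asarray(arrays.get("sp", np.full(n, SP_UNSET)), dtype=np.int8)
        self.parity = np.asarray(arrays.get("parity", np.zeros(n)), dtype=np.int16)
        self.sons = np.asarray(arrays.get("sons", np.zeros(n)), dtype=np.int16)
        self.tech = np.asarray(arrays.get("tech", np.zeros(n)), dtype=bool)
        self.abortions = np.asarray(arrays.get("abortions", np.zeros(n)), dtype=np.int16)
        self.mother_id = np.asarray(
            arrays.get("mother_id", np.full(n, -1)), dtype=np.int64
        )
        self.next_id = int(next_id)

    _FIELDS = (
        "id",
        "sex",
        "birth_year",
        "age",
        "sp",
        "parity",
        "sons",
        "tech",
        "abortions",
        "mother_id",
    )

    def __len__(self) -> int:
        return self.id.size

    def keep(self, mask: np.ndarray) -> None:
        """Retain only the agents where ``mask`` is true (order preserved)."""
        for f in self._FIELDS:
            setattr(self, f, getattr(self, f)[mask])

    def add_newborns(self, n: int, sexes: np.ndarray, year: int, mother_ids: np.ndarray) -> None:
        if n == 0:
            return
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        self.id = np.concatenate([self.id, ids])
        self.sex = np.concatenate([self.sex, sexes.astype(np.int8)])
        self.birth_year = np.concatenate(
            [self.birth_year, np.full(n, year, dtype=np.int32)]
        )
        self.age = np.concatenate([self.age, np.zeros(n, dtype=np.int16)])
        self.sp = np.concatenate([self.sp, np.full(n, SP_UNSET, dtype=np.int8)])
        self.parity = np.concatenate([self.parity, np.zeros(n, dtype=np.int16)])
        self.sons = np.concatenate([self.sons, np.zeros(n, dtype=np.int16)])
        self.tech = np.concatenate([self.tech, np.zeros(n, dtype=bool)])
        self.abortions = np.concatenate([self.abortions, np.zeros(n, dtype=np.int16)])
        self.mother_id = np.concatenate([self.mother_id, mother_ids.astype(np.int64)])

    def index_of_ids(self, ids: np.ndarray) -> np.ndarray:
        """Indices of the given ids; -1 where the id is no longer present."""
        pos = np.searchsorted(self.id, ids)
        pos = np.clip(pos, 0, max(len(self) - 1, 0))
        found = np.empty(ids.size, dtype=np.int64)
        if len(self) == 0:
            found.fill(-1)
            return found
        ok = self.id[pos] == ids
        found[:] = np.where(ok, pos, -1)
        return found

    def women_mask(self) -> np.ndarray:
        return (
            (self.sex == FEMALE)
            & (self.age >= FERTILITY_AGE_LO)
            & (self.age <= FERTILITY_AGE_HI)
        )

    # -- conversion -------------------------------------------------------

    @classmethod
    def from_initial(
        cls, initial: InitialPopulation, start_year: int
    ) -> "Population":
        ages, sexes = [], []
        for a in range(initial.counts.shape[0]):
            for s in (FEMALE, MALE):
                c = int(initial.counts[a, s])
                ages.extend([a] * c)
                sexes.extend([s] * c)
        n = len(ages)
        ages = np.array(ages, dtype=np.int16)
        sexes = np.array(sexes, dtype=np.int8)
        return cls(
            next_id=n + 1,
            id=np.arange(1, n + 1),
            sex=sexes,
            birth_year=start_year - ages.astype(np.int32),
            age=ages,
        )

    def to_frame(self) -> pd.DataFrame:
        """Snapshot as a tidy table (id,sex,birth_year,age,sp,p,so,tech,ab,mother_id)."""
        return pd.DataFrame(
            {
                "id": self.id,
                "sex": np.where(self.sex == FEMALE, "female", "male"),
                "birth_year": self.birth_year,
                "age": self.age,
                "sp": self.sp,
                "p": self.parity,
                "so": self.sons,
                "tech": self.tech.astype(int),
                "ab": self.abortions,
                "mother_id": self.mother_id,
            }
        )

    def get_agent(self, i: int) -> AgentState:
        return AgentState(
            id=int(self.id[i]),
            sex=int(self.sex[i]),
            birth_year=int(self.birth_year[i]),
            age=int(self.age[i]),
            sp=int(self.sp[i]),
            parity=int(self.parity[i]),
            sons=int(self.sons[i]),
            tech_access=bool(self.tech[i]),
            abortions=int(self.abortions[i]),
            mother_id=int(self.mother_id[i]),
        )


@dataclass
class DeathNotice:
    """Record of a death the engine may need to act on (son-loss feedback)."""

    agent_id: int
    sex: int
    mother_id: int


def apply_mortality(
    pop: Population,
    schedule: RateSchedule,
    year: int,
    rng: np.random.Generator,
) -> list[DeathNotice]:
    """Kill agents independently with probability q(age, sex, year).

    Dead sons are reported back so that their mothers — if still alive,
    female, and under the retirement age — have their count of living
    sons decremented, reopening differential stopping behavior for them.
    Mutates ``pop`` in place and returns the death notices.
    """
    q_table = schedule.mortality_at(year)  # (51, 2)
    if len(pop) == 0:
        return []
    q = q_table[pop.age, pop.sex]
    dead = rng.random(len(pop)) < q
    notices = [
        DeathNotice(agent_id=int(i), sex=int(s), mother_id=int(m))
        for i, s, m in zip(pop.id[dead], pop.sex[dead], pop.mother_id[dead])
    ]

    dead_sons_mothers = pop.mother_id[dead & (pop.sex == MALE) & (pop.mother_id >= 0)]
    pop.keep(~dead)

    if dead_sons_mothers.size:
        idx = pop.index_of_ids(np.sort(dead_sons_mothers))
        idx = idx[idx >= 0]
        if idx.size:
            eligible = (pop.sex[idx] == FEMALE) & (pop.age[idx] < MAX_AGE)
            idx = idx[eligible]
            np.subtract.at(pop.sons, idx, 1)
            np.maximum(pop.sons, 0, out=pop.sons)
    return notices


def retire_at_50(pop: Population) -> int:
    """Remove agents aged 50 or older; returns the number removed."""
    mask = pop.age < MAX_AGE
    removed = int(len(pop) - mask.sum())
    pop.keep(mask)
    return removed
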