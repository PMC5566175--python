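"""Ready-willing-able behavior: the three preconditions for sex selection.

A woman sex-selectively aborts a female conception only when three
conditions hold at once:

* willing — she holds an unmet son preference (sp > so), where the
  population proportion willing follows a fitted logistic time trend;
* able — she has access to prenatal sex-determination technology, whose
  availability follows a logistic diffusion curve in model time;
* ready — the fertility squeeze, the ratio of her parity to prevailing
  fertility levels, makes abortion preferable to another birth.

``conception_step`` composes the pieces into the per-woman per-year
decision flow: conception, sex at conception, and — for female fetuses
of willing and able women — a readiness-weighted abortion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .agents import FEMALE, AgentState, ParameterSet, fertility_hazard


def _logistic(z: float) -> float:
    if z >= 0:
        e = math.exp(-z)
        return 1.0 / (1.0 + e)
    e = math.exp(z)
    return e / (1.0 + e)


def _logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError("proportions must lie strictly inside (0, 1)")
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class SonPreferenceCurve:
    """Logistic time trend for the probability of stating son preference.

    ``delta0`` is the log-odds at ``reference_year``; ``delta1`` the
    per-year log-odds slope.  The default is anchored on South-Korean
    style survey trends: 48 % stating a son is a must in 1985, falling
    to 26 % by 1994.
    """

    delta0: float
    delta1: float
    reference_year: int = 1980

    @classmethod
    def from_anchors(
        cls,
        year_a: int,
        prop_a: float,
        year_b: int,
        prop_b: float,
        reference_year: int = 1980,
    ) -> "SonPreferenceCurve":
        """Exact two-point solution of the logistic through both anchors."""
        if year_a == year_b:
            raise ValueError("anchor years must differ")
        la, lb = _logit(prop_a), _logit(prop_b)
        delta1 = (lb - la) / (year_b - year_a)
        delta0 = la - delta1 * (year_a - reference_year)
        return cls(delta0=delta0, delta1=delta1, reference_year=reference_year)


#: Curve through the survey anchors (1985, 48 %) and (1994, 26 %).
DEFAULT_SON_PREFERENCE_CURVE = SonPreferenceCurve.from_anchors(1985, 0.48, 1994, 0.26)


def son_preference_probability(curve: SonPreferenceCurve, year: int | float) -> float:
    """Probability a woman states son preference in a calendar year."""
    return _logistic(curve.delta0 + curve.delta1 * (year - curve.reference_year))


def fit_son_preference(
    observations: list[tuple[int, float]], reference_year: int = 1980
) -> SonPreferenceCurve:
    """Fit the logistic son-preference trend to (year, proportion) data.

    With exactly two observations the curve is solved in closed form
    through both points; with more, a least-squares line is fitted on
    the logit scale (exact whenever the data are collinear on logits).
    """
    if len(observations) < 2:
        raise ValueError("need at least two (year, proportion) observations")
    years = np.array([y for y, _ in observations], dtype=float)
    logits = np.array([_logit(p) for _, p in observations])
    if len(observations) == 2:
        return SonPreferenceCurve.from_anchors(
            int(years[0]), observations[0][1], int(years[1]), observations[1][1],
            reference_year=reference_year,
        )
    x = years - reference_year
    delta1, delta0 = np.polyfit(x, logits, 1)
    return SonPreferenceCurve(
        delta0=float(delta0), delta1=float(delta1), reference_year=reference_year
    )


@dataclass(frozen=True)
class DiffusionCurve:
    """Logistic diffusion of prenatal sex-determination technology.

    ``rho`` is the diffusion rate (slope), ``phi`` the inflection
    time-step in model time (t = 0 at simulation start); Ability(phi)
    is exactly one half.
    """

    rho: float
    phi: float

    @classmethod
    def from_params(cls, params: ParameterSet) -> "DiffusionCurve":
        return cls(rho=params.rho, phi=params.phi)


def ability_probability(curve: DiffusionCurve, t: float) -> float:
    """Proportion of the population with technology access at time-step t."""
    return _logistic(curve.rho * (t - curve.phi))


def update_tech_access(
    agent: AgentState,
    curve: DiffusionCurve,
    t: float,
    rng: np.random.Generator,
    absorbing: bool = True,
) -> AgentState:
    """Redraw one woman's technology access against Ability(t).

    In the default absorbing mode access, once gained, persists; in
    redraw mode the state is drawn fresh every tick so the population
    share tracks Ability(t) exactly.
    """
    if agent.sex != FEMALE:
        raise ValueError("technology access is tracked for female agents")
    p = ability_probability(curve, t)
    gained = rng.random() < p
    if absorbing:
        tech = agent.tech_access or gained
    else:
        tech = gained
    if tech == agent.tech_access:
        return agent
    return AgentState(
        id=agent.id,
        sex=agent.sex,
        birth_year=agent.birth_year,
        age=agent.age,
        sp=agent.sp,
        parity=agent.parity,
        sons=agent.sons,
        tech_access=tech,
        abortions=agent.abortions,
        mother_id=agent.mother_id,
    )


def readiness_probability(parity: int, tfr_prev: float, params: ParameterSet) -> float:
    """Probability of aborting a female conception given willing and able.

    The fertility squeeze is the ratio of parity to prevailing fertility
    TFR(t-1); it is scaled by sigma at parity >= 1 and by beta at
    parity 0, and capped at 1.
    """
    if tfr_prev <= 0:
        raise ValueError("prevailing TFR must be positive")
    if parity < 0:
        raise ValueError("parity must be non-negative")
    if parity == 0:
        return min(1.0, params.beta / tfr_prev)
    return min(1.0, parity * params.sigma / tfr_prev)


class ConceptionEvent(enum.Enum):
    NO_CONCEPTION = "no_conception"
    FEMALE_BIRTH = "female_birth"
    MALE_BIRTH = "male_birth"
    SEX_SELECTIVE_ABORTION = "sex_selective_abortion"


def conception_event_distribution(
    agent: AgentState, base_rate: float, tfr_prev: float, params: ParameterSet
) -> dict[ConceptionEvent, float]:
    """Closed-form event probabilities for one woman-year.

    The decision flow is a product of Bernoulli stages, so the exact
    distribution is available in closed form; it serves as the oracle
    for the sampling path.
    """
    h = fertility_hazard(agent, base_rate, params)
    willing = max(agent.sp, 0) > agent.sons
    able = agent.tech_access
    r = (
        readiness_probability(agent.parity, tfr_prev, params)
        if (willing and able)
        else 0.0
    )
    pm = params.p_male
    return {
        ConceptionEvent.NO_CONCEPTION: 1.0 - h,
        ConceptionEvent.MALE_BIRTH: h * pm,
        ConceptionEvent.FEMALE_BIRTH: h * (1.0 - pm) * (1.0 - r),
        ConceptionEvent.SEX_SELECTIVE_ABORTION: h * (1.0 - pm) * r,
    }


def conception_step(
    agent: AgentState,
    base_rate: float,
    tfr_prev: float,
    params: ParameterSet,
    rng: np.random.Generator,
) -> tuple[ConceptionEvent, AgentState]:
    """One woman's reproduction step for one tick.

    Conception is Bernoulli in the DSB-modified hazard; the fetal sex is
    drawn at conception; a female fetus is aborted when the woman is
    willing (sp > so), able (tech access), and a uniform draw falls
    under her readiness.  Male fetuses are never aborted.  Returns the
    event and the updated agent (parity/sons on birth, abortions on
    abortion).
    """
    h = fertility_hazard(agent, base_rate, params)
    if rng.random() >= h:
        return ConceptionEvent.NO_CONCEPTION, agent
    male = rng.random() < params.p_male
    if male:
        return ConceptionEvent.MALE_BIRTH, AgentState(
            id=agent.id, sex=agent.sex, birth_year=agent.birth_year, age=agent.age,
            sp=agent.sp, parity=agent.parity + 1, sons=agent.sons + 1,
            tech_access=agent.tech_access, abortions=agent.abortions,
            mother_id=agent.mother_id,
        )
    willing = max(agent.sp, 0) > agent.sons
    if willing and agent.tech_access:
        r = readiness_probability(agent.parity, tfr_prev, params)
        if rng.random() < r:
            return ConceptionEvent.SEX_SELECTIVE_ABORTION, AgentState(
                id=agent.id, sex=agent.sex, birth_year=agent.birth_year,
                age=agent.age, sp=agent.sp, parity=agent.parity, sons=agent.sons,
                tech_access=agent.tech_access, abortions=agent.abortions + 1,
                mother_id=agent.mother_id,
            )
    return ConceptionEvent.FEMALE_BIRTH, AgentState(
        id=agent.id, sex=agent.sex, birth_year=agent.birth_year, age=agent.age,
        sp=agent.sp, parity=agent.parity + 1, sons=agent.sons,
        tech_access=agent.tech_access, abortions=agent.abortions,
        mother_id=agent.mother_id,
    )
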