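"""Simulation engine: burn-in, the yearly tick loop, and replicate ensembles.

One tick is one calendar year.  Within a tick the order of operations
is: willingness and ability updates (with readiness inputs frozen at the
previous year's model-generated TFR), mortality (so a woman who loses a
son may respond the same year), conception / abortion / birth, then
aging and retirement at age 50.  The burn-in evolves the starting
pyramid under plain fertility and mortality — no differential stopping,
no abortion — so that women alive at the scenario start carry realistic
parity histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import (
    FEMALE,
    MALE,
    SP_UNSET,
    ParameterSet,
    Population,
    apply_mortality,
    fertility_hazard_vector,
    retire_at_50,
)
from .behavior import (
    DEFAULT_SON_PREFERENCE_CURVE,
    DiffusionCurve,
    SonPreferenceCurve,
    ability_probability,
    son_preference_probability,
)
from .rates import FERTILITY_AGE_LO, RateSchedule, synthesize_initial_population


@dataclass
class ScenarioConfig:
    """Everything needed to reproduce a simulation run.

    ``sp_override`` / ``ability_override`` freeze the willing / able
    proportions at a constant value (counterfactual scenarios); when an
    ability override is set, access is redrawn every tick so the
    population share stays at the override.
    """

    start_year: int = 1980
    end_year: int = 2030
    burnin_years: int = 35
    population_size: int = 20_000
    params: ParameterSet = field(default_factory=ParameterSet)
    sp_curve: SonPreferenceCurve = DEFAULT_SON_PREFERENCE_CURVE
    sp_mode: str = "annual_redraw"      # or "cohort_fixed"
    sp_override: float | None = None
    ability_override: float | None = None
    tech_absorbing: bool = True
    dsb_in_burnin: bool = False
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.burnin_years < 0:
            raise ValueError("burnin_years must be non-negative")
        if self.sp_mode not in ("annual_redraw", "cohort_fixed"):
            raise ValueError(f"unknown sp_mode {self.sp_mode!r}")

    def with_values(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class YearlyOutput:
    """Aggregate outcomes of one simulated year."""

    year: int
    conceptions: int
    male_births: int
    female_births: int
    abortions_p0: int
    abortions_p1: int
    abortions_p2: int
    abortions_p3plus: int
    realized_tfr: float
    prop_willing: float
    prop_able: float

    @property
    def births(self) -> int:
        return self.male_births + self.female_births

    @property
    def abortions(self) -> int:
        return (
            self.abortions_p0
            + self.abortions_p1
            + self.abortions_p2
            + self.abortions_p3plus
        )

    @property
    def srb(self) -> float:
        """Male births per 100 female births; NaN when no female births."""
        if self.female_births == 0:
            return float("nan")
        return 100.0 * self.male_births / self.female_births

    def as_row(self) -> dict:
        return {
            "year": self.year,
            "conceptions": self.conceptions,
            "male_births": self.male_births,
            "female_births": self.female_births,
            "srb": self.srb,
            "tfr": self.realized_tfr,
            "abortions_p0": self.abortions_p0,
            "abortions_p1": self.abortions_p1,
            "abortions_p2": self.abortions_p2,
            "abortions_p3plus": self.abortions_p3plus,
            "prop_willing": self.prop_willing,
            "prop_able": self.prop_able,
        }


def step_year(
    pop: Population,
    schedule: RateSchedule,
    params: ParameterSet,
    tfr_prev: float,
    year: int,
    t: int,
    rng: np.random.Generator,
    *,
    sp_curve: SonPreferenceCurve = DEFAULT_SON_PREFERENCE_CURVE,
    diffusion: DiffusionCurve | None = None,
    sp_mode: str = "annual_redraw",
    sp_override: float | None = None,
    ability_override: float | None = None,
    tech_absorbing: bool = True,
    dsb: bool = True,
    abortion: bool = True,
) -> tuple[Population, YearlyOutput]:
    """Advance the population by one year and collect aggregate outcomes.

    Mutates ``pop`` in place (and returns it alongside the outputs).
    ``tfr_prev`` is the prevailing fertility level entering the
    readiness condition; ``t`` is model time for the diffusion curve.
    """
    if tfr_prev <= 0:
        raise ValueError("previous-year TFR must be positive")
    if diffusion is None:
        diffusion = DiffusionCurve.from_params(params)

    widx = np.flatnonzero(pop.women_mask())

    # willingness: annual redraw tracks the fitted period trend; cohort
    # mode assigns once on entry to reproductive age
    if dsb or abortion:
        p_sp = (
            sp_override
            if sp_override is not None
            else son_preference_probability(sp_curve, year)
        )
        if sp_mode == "annual_redraw":
            pop.sp[widx] = (rng.random(widx.size) < p_sp).astype(np.int8)
        elif sp_mode == "cohort_fixed":
            unset = widx[pop.sp[widx] == SP_UNSET]
            pop.sp[unset] = (rng.random(unset.size) < p_sp).astype(np.int8)
        else:
            raise ValueError(f"unknown sp_mode {sp_mode!r}")

    # ability: logistic diffusion (absorbing by default), or a constant
    # override redrawn each tick
    if abortion:
        if ability_override is not None:
            pop.tech[widx] = rng.random(widx.size) < ability_override
        else:
            a = ability_probability(diffusion, t)
            gained = rng.random(widx.size) < a
            if tech_absorbing:
                pop.tech[widx] |= gained
            else:
                pop.tech[widx] = gained

    # deaths before conceptions: son loss can reopen DSB this same year
    apply_mortality(pop, schedule, year, rng)

    widx = np.flatnonzero(pop.women_mask())
    base = schedule.fertility_at(year)[pop.age[widx] - FERTILITY_AGE_LO]
    if dsb:
        hazard = fertility_hazard_vector(base, pop.sp[widx], pop.sons[widx], params)
    else:
        hazard = base
    conceived = rng.random(widx.size) < hazard
    cidx = widx[conceived]
    male = rng.random(cidx.size) < params.p_male

    sp_eff = np.maximum(pop.sp[cidx], 0)
    willing = sp_eff > pop.sons[cidx]
    candidates = (~male) & willing & pop.tech[cidx] if abortion else np.zeros(
        cidx.size, dtype=bool
    )
    parities = pop.parity[cidx].astype(np.int64)
    readiness = np.zeros(cidx.size)
    if candidates.any():
        pc = parities[candidates]
        readiness[candidates] = np.where(
            pc == 0,
            min(1.0, params.beta / tfr_prev),
            np.minimum(1.0, pc * params.sigma / tfr_prev),
        )
    aborted = np.zeros(cidx.size, dtype=bool)
    ncand = int(candidates.sum())
    if ncand:
        aborted[np.flatnonzero(candidates)] = rng.random(ncand) < readiness[candidates]

    born = ~aborted
    mothers = cidx[born]
    born_male = male[born]
    pop.parity[mothers] += 1
    pop.sons[mothers[born_male]] += 1
    pop.abortions[cidx[aborted]] += 1

    # aggregates (women at risk measured after mortality, before aging)
    male_births = int(born_male.sum())
    female_births = int(born.sum()) - male_births
    ab_par = parities[aborted]
    women_by_age = np.bincount(pop.age[widx], minlength=FERTILITY_AGE_LO + 36)
    births_by_age = np.bincount(pop.age[mothers], minlength=FERTILITY_AGE_LO + 36)
    with np.errstate(divide="ignore", invalid="ignore"):
        asfr = np.where(women_by_age > 0, births_by_age / women_by_age, 0.0)
    realized_tfr = float(asfr.sum())
    prop_willing = float((np.maximum(pop.sp[widx], 0) == 1).mean()) if widx.size else 0.0
    prop_able = float(pop.tech[widx].mean()) if widx.size else 0.0

    out = YearlyOutput(
        year=year,
        conceptions=int(cidx.size),
        male_births=male_births,
        female_births=female_births,
        abortions_p0=int((ab_par == 0).sum()),
        abortions_p1=int((ab_par == 1).sum()),
        abortions_p2=int((ab_par == 2).sum()),
        abortions_p3plus=int((ab_par >= 3).sum()),
        realized_tfr=realized_tfr,
        prop_willing=prop_willing,
        prop_able=prop_able,
    )

    # aging last; newborns enter at age 0 and age from next tick
    mother_ids = pop.id[mothers].copy()
    pop.age += 1
    n_new = int(born.sum())
    pop.add_newborns(n_new, np.where(born_male, MALE, FEMALE), year, mother_ids)
    retire_at_50(pop)
    return pop, out


def run_burnin(
    config: ScenarioConfig, schedule: RateSchedule, rng: np.random.Generator
) -> Population:
    """Evolve a synthetic starting pyramid up to the scenario start year.

    Individuals die and reproduce according to the schedule rates alone;
    the abortion pathway is off, and differential stopping is off unless
    ``config.dsb_in_burnin`` is set.
    """
    burn_start = config.start_year - config.burnin_years
    initial = synthesize_initial_population(
        schedule, config.population_size, seed=rng, p_male=config.params.p_male
    )
    pop = Population.from_initial(initial, burn_start)
    for year in range(burn_start, config.start_year):
        tfr_prev = max(schedule.schedule_tfr(year), 1e-6)
        step_year(
            pop,
            schedule,
            config.params,
            tfr_prev,
            year,
            t=year - config.start_year,
            rng=rng,
            sp_curve=config.sp_curve,
            sp_mode=config.sp_mode,
            sp_override=config.sp_override,
            dsb=config.dsb_in_burnin,
            abortion=False,
        )
    return pop


def run_replicate(
    config: ScenarioConfig, schedule: RateSchedule, replicate: int
) -> pd.DataFrame:
    """One full run (burn-in + scenario years) with the replicate's seed."""
    rng = np.random.default_rng(config.seed + replicate)
    pop = run_burnin(config, schedule, rng)
    prev = config.start_year - 1
    tfr_prev = schedule.schedule_tfr(prev if schedule.covers(prev) else config.start_year)
    tfr_prev = max(tfr_prev, 1e-6)
    rows = []
    for year in range(config.start_year, config.end_year + 1):
        _, out = step_year(
            pop,
            schedule,
            config.params,
            tfr_prev,
            year,
            t=year - config.start_year,
            rng=rng,
            sp_curve=config.sp_curve,
            sp_mode=config.sp_mode,
            sp_override=config.sp_override,
            ability_override=config.ability_override,
            tech_absorbing=config.tech_absorbing,
        )
        rows.append(out.as_row())
        # model-generated prevailing fertility; schedule fallback guards
        # against degenerate tiny populations
        tfr_prev = out.realized_tfr if out.realized_tfr > 0.05 else max(
            schedule.schedule_tfr(year), 1e-6
        )
    df = pd.DataFrame(rows)
    df.insert(0, "replicate", replicate)
    return df


@dataclass
class TrajectoryEnsemble:
    """Per-replicate yearly series with pointwise summaries.

    ``summary`` holds per-year across-replicate means and empirical
    2.5/5/95/97.5 percentiles of SRB and TFR; ``smoothed`` applies a
    centered five-year moving average to each summary column.
    """

    replicates: list[pd.DataFrame]
    summary: pd.DataFrame
    smoothed: pd.DataFrame

    @classmethod
    def from_replicates(
        cls, frames: list[pd.DataFrame], window: int = 5
    ) -> "TrajectoryEnsemble":
        years = frames[0]["year"].values
        for f in frames[1:]:
            if not np.array_equal(f["year"].values, years):
                raise ValueError("replicates cover different years")
        summary = {"year": years}
        for var in ("srb", "tfr"):
            stack = np.vstack([f[var].values for f in frames])
            summary[f"{var}_mean"] = np.nanmean(stack, axis=0)
            for q, tag in ((2.5, "p2_5"), (5, "p5"), (95, "p95"), (97.5, "p97_5")):
                summary[f"{var}_{tag}"] = np.nanpercentile(stack, q, axis=0)
        summary = pd.DataFrame(summary)
        smoothed = summary.copy()
        for col in smoothed.columns:
            if col != "year":
                smoothed[col] = moving_average(smoothed[col].values, window)
        return cls(replicates=frames, summary=summary, smoothed=smoothed)

    @property
    def years(self) -> np.ndarray:
        return self.summary["year"].values

    def tidy(self) -> pd.DataFrame:
        """All replicates stacked as one tidy table."""
        return pd.concat(self.replicates, ignore_index=True)


def run_scenario(config: ScenarioConfig, schedule: RateSchedule) -> TrajectoryEnsemble:
    """Run ``n_replicates`` independent replicates (seeds ``seed + r``)."""
    burn_start = config.start_year - config.burnin_years
    for y in (burn_start, config.end_year):
        if not schedule.covers(y):
            raise ValueError(
                f"schedule [{schedule.start_year}, {schedule.end_year}] does not "
                f"cover simulated year {y}"
            )
    frames = [
        run_replicate(config, schedule, r) for r in range(config.n_replicates)
    ]
    return TrajectoryEnsemble.from_replicates(frames)


def moving_average(series, window: int = 5) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    NaN entries (years with undefined SRB) are skipped within each
    window; a window with no defined values yields NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot smooth an empty series")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        w = x[lo:hi]
        w = w[~np.isnan(w)]
        out[i] = w.mean() if w.size else np.nan
    return out


def counterfactual_tfr_gap(
    with_abortion: TrajectoryEnsemble, without: TrajectoryEnsemble
) -> pd.DataFrame:
    """Per-year fertility cost of sex-selective abortion.

    Returns the ensemble-mean TFR under both regimes, their difference
    (TFR without abortion minus TFR with), and the difference as a
    percentage of the with-abortion level.
    """
    if not np.array_equal(with_abortion.years, without.years):
        raise ValueError("ensembles cover different years")
    tfr_w = with_abortion.summary["tfr_mean"].values
    tfr_o = without.summary["tfr_mean"].values
    gap = tfr_o - tfr_w
    return pd.DataFrame(
        {
            "year": with_abortion.years,
            "tfr_with": tfr_w,
            "tfr_without": tfr_o,
            "gap": gap,
            "gap_pct": 100.0 * gap / tfr_w,
        }
    )


def scenario_suite(config: ScenarioConfig) -> dict[str, ScenarioConfig]:
    """The standard counterfactual batch derived from a baseline config.

    Alongside the baseline: willingness frozen at 50 % and at 100 %,
    technology availability held constant at 50 %, and a weakened
    fertility squeeze (sigma 1.0, no parity-0 abortion).
    """
    out = {"baseline": config}
    out["frozen_sp_50"] = config.with_values(sp_override=0.5)
    out["frozen_sp_100"] = config.with_values(sp_override=1.0)
    out["constant_ability_50"] = config.with_values(
        ability_override=0.5, params=config.params.with_values(rho=0.0, phi=0.0)
    )
    out["weak_readiness"] = config.with_values(
        params=config.params.with_values(sigma=1.0, beta=0.0)
    )
    return out
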