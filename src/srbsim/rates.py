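"""Demographic rate schedules and synthetic-data generation.

The simulation consumes period rate schedules in the layout of the UN
World Population Prospects: age-specific fertility rates for single ages
15-49 and sex- and age-specific one-year death probabilities for single
ages 0-50, both indexed by calendar year.  This module reads and writes
those schedules as tidy CSV tables, validates their invariants, and can
synthesize realistic schedules (declining fertility, declining
Gompertz-like mortality) so that every downstream module is testable
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FERTILITY_AGE_LO = 15
FERTILITY_AGE_HI = 49          # inclusive
MAX_AGE = 50                   # agents leave the simulation at 50
N_FERT_AGES = FERTILITY_AGE_HI - FERTILITY_AGE_LO + 1
SEXES = ("female", "male")

# Natural probability that a conception is male; implies an SRB of
# 100 * 0.5122 / 0.4878 = 105.
P_MALE_DEFAULT = 0.5122


class ScheduleError(ValueError):
    """Raised when a rate table violates the schedule contract."""


@dataclass
class RateSchedule:
    """Period fertility and mortality surfaces over contiguous years.

    Parameters
    ----------
    years:
        Contiguous calendar years covered by the schedule.
    fertility:
        Array of shape ``(n_years, 35)``: births per woman-year at single
        ages 15-49.
    mortality:
        Array of shape ``(n_years, 51, 2)``: probability of dying within
        the year at single ages 0-50, last axis ordered (female, male).
    """

    years: np.ndarray
    fertility: np.ndarray
    mortality: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.fertility = np.asarray(self.fertility, dtype=np.float64)
        self.mortality = np.asarray(self.mortality, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.years.size == 0:
            raise ScheduleError("schedule covers no years")
        if not np.all(np.diff(self.years) == 1):
            raise ScheduleError("years must be contiguous and increasing")
        n = self.years.size
        if self.fertility.shape != (n, N_FERT_AGES):
            raise ScheduleError(
                f"fertility must have shape ({n}, {N_FERT_AGES}), "
                f"got {self.fertility.shape}"
            )
        if self.mortality.shape != (n, MAX_AGE + 1, 2):
            raise ScheduleError(
                f"mortality must have shape ({n}, {MAX_AGE + 1}, 2), "
                f"got {self.mortality.shape}"
            )
        for name, arr in (("fertility", self.fertility), ("mortality", self.mortality)):
            if not np.all(np.isfinite(arr)):
                raise ScheduleError(f"{name} contains non-finite rates")
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ScheduleError(f"{name} rates must lie in [0, 1]")

    # -- indexing ---------------------------------------------------------

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def covers(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year

    def _yi(self, year: int) -> int:
        if not self.covers(year):
            raise ScheduleError(
                f"year {year} outside schedule coverage "
                f"[{self.start_year}, {self.end_year}]"
            )
        return int(year - self.start_year)

    def fertility_at(self, year: int) -> np.ndarray:
        """ASFR vector over ages 15-49 for a calendar year."""
        return self.fertility[self._yi(year)]

    def mortality_at(self, year: int) -> np.ndarray:
        """Death probabilities, shape (51, 2), for a calendar year."""
        return self.mortality[self._yi(year)]

    def schedule_tfr(self, year: int | None = None):
        """Sum of single-age fertility rates: the period TFR of the table."""
        if year is None:
            return self.fertility.sum(axis=1)
        return float(self.fertility[self._yi(year)].sum())


@dataclass
class InitialPopulation:
    """Counts by single age 0-50 and sex at the burn-in start year.

    ``counts`` has shape ``(51, 2)``, last axis (female, male).
    """

    counts: np.ndarray = field()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (MAX_AGE + 1, 2):
            raise ScheduleError(
                f"counts must have shape ({MAX_AGE + 1}, 2), got {self.counts.shape}"
            )
        if self.counts.min() < 0:
            raise ScheduleError("population counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ScheduleError("population must contain at least one individual")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# CSV input/output
# ---------------------------------------------------------------------------

def _expand_age_groups(df: pd.DataFrame, linear: bool = False) -> pd.DataFrame:
    """Expand age-group rows (age column like '15-19') to single ages.

    Default is constant-within-group, which preserves the group mean
    exactly.  ``linear=True`` adds a within-group linear gradient whose
    slope is the central difference of neighbouring group rates; because
    the gradient is centred on the group midpoint the group mean is still
    preserved exactly.
    """
    if df["age"].dtype.kind in "iu":
        return df

    singles = []
    grouped = []
    for _, row in df.iterrows():
        age = row["age"]
        if isinstance(age, str) and "-" in age:
            lo, hi = (int(a) for a in age.split("-"))
            grouped.append((lo, hi, row))
        else:
            r = row.copy()
            r["age"] = int(age)
            singles.append(r)
    if not grouped:
        out = pd.DataFrame(singles)
        out["age"] = out["age"].astype(int)
        return out

    keycols = [c for c in ("year", "sex") if c in df.columns]
    rows = list(singles)
    gdf = pd.DataFrame(
        [
            {**{k: row[k] for k in keycols}, "lo": lo, "hi": hi, "rate": row["rate"]}
            for lo, hi, row in grouped
        ]
    )
    for _, block in gdf.groupby(keycols) if keycols else [((), gdf)]:
        block = block.sort_values("lo").reset_index(drop=True)
        rates = block["rate"].values.astype(float)
        for i, brow in block.iterrows():
            lo, hi = int(brow["lo"]), int(brow["hi"])
            width = hi - lo + 1
            if linear and len(rates) > 1:
                left = rates[i - 1] if i > 0 else rates[i]
                right = rates[i + 1] if i < len(rates) - 1 else rates[i]
                span = (
                    (block.loc[min(i + 1, len(rates) - 1), "lo"] + 0.0)
                    - block.loc[max(i - 1, 0), "lo"]
                )
                slope = (right - left) / span if span > 0 else 0.0
                # keep single-age rates non-negative; symmetric clamping
                # still preserves the group mean
                half = (hi - lo) / 2.0
                if half > 0 and rates[i] >= 0:
                    limit = rates[i] / half
                    slope = float(np.clip(slope, -limit, limit))
            else:
                slope = 0.0
            mid = (lo + hi) / 2.0
            for a in range(lo, hi + 1):
                r = {k: brow[k] for k in keycols}
                r["age"] = a
                r["rate"] = rates[i] + slope * (a - mid)
                rows.append(pd.Series(r))
    out = pd.DataFrame(rows)
    out["age"] = out["age"].astype(int)
    return out


def read_rate_schedule(
    fertility_path,
    mortality_path,
    dialect: str = "tidy",
    graduation: str = "constant",
) -> RateSchedule:
    """Read a schedule from CSV rate tables.

    The fertility table has columns ``year,age,rate``; the mortality
    table ``year,age,sex,rate`` with ``sex`` in {female, male}.  Ages may
    be 5-year groups written ``lo-hi``; they are expanded to single ages
    as constant within the group.

    Parameters
    ----------
    dialect:
        Table-layout tag; only ``"tidy"`` (one record per row) is
        currently defined.
    """
    if dialect != "tidy":
        raise ScheduleError(f"unknown table dialect {dialect!r}")
    if graduation not in ("constant", "linear"):
        raise ScheduleError(f"unknown graduation rule {graduation!r}")
    linear = graduation == "linear"
    fert = pd.read_csv(fertility_path, dtype={"rate": float})
    mort = pd.read_csv(mortality_path, dtype={"rate": float})
    for name, df, cols in (
        ("fertility", fert, {"year", "age", "rate"}),
        ("mortality", mort, {"year", "age", "sex", "rate"}),
    ):
        missing = cols - set(df.columns)
        if missing:
            raise ScheduleError(f"{name} table missing columns {sorted(missing)}")
        if (df["rate"] < 0).any() or (df["rate"] > 1).any():
            bad = df.loc[(df["rate"] < 0) | (df["rate"] > 1)].iloc[0]
            raise ScheduleError(
                f"{name} rate {bad['rate']} at year {bad['year']} outside [0, 1]"
            )
    fert = _expand_age_groups(fert, linear=linear)
    mort = _expand_age_groups(mort, linear=linear)

    years = np.unique(np.concatenate([fert["year"].values, mort["year"].values]))
    years = np.arange(years.min(), years.max() + 1)

    fertility = np.zeros((years.size, N_FERT_AGES))
    fgrid = fert.pivot_table(index="year", columns="age", values="rate")
    for y in years:
        if y not in fgrid.index:
            raise ScheduleError(f"fertility table missing year {y}")
    want_ages = set(range(FERTILITY_AGE_LO, FERTILITY_AGE_HI + 1))
    have_ages = set(int(a) for a in fgrid.columns)
    if not want_ages <= have_ages:
        raise ScheduleError(
            f"fertility table missing ages {sorted(want_ages - have_ages)}"
        )
    for j, a in enumerate(range(FERTILITY_AGE_LO, FERTILITY_AGE_HI + 1)):
        fertility[:, j] = fgrid.loc[years, a].values

    mortality = np.zeros((years.size, MAX_AGE + 1, 2))
    for k, sex in enumerate(SEXES):
        sub = mort[mort["sex"] == sex]
        if sub.empty:
            raise ScheduleError(f"mortality table has no rows for sex={sex!r}")
        mgrid = sub.pivot_table(index="year", columns="age", values="rate")
        for y in years:
            if y not in mgrid.index:
                raise ScheduleError(f"mortality table ({sex}) missing year {y}")
        have = set(int(a) for a in mgrid.columns)
        need = set(range(0, MAX_AGE + 1))
        if not need <= have:
            raise ScheduleError(
                f"mortality table ({sex}) missing ages {sorted(need - have)}"
            )
        for a in range(0, MAX_AGE + 1):
            mortality[:, a, k] = mgrid.loc[years, a].values

    return RateSchedule(years=years, fertility=fertility, mortality=mortality)


def write_rate_schedule(schedule: RateSchedule, fertility_path, mortality_path) -> None:
    """Write a schedule as the two tidy CSV tables read_rate_schedule expects."""
    schedule.validate()
    frows = []
    for i, y in enumerate(schedule.years):
        for j, a in enumerate(range(FERTILITY_AGE_LO, FERTILITY_AGE_HI + 1)):
            frows.append((int(y), a, repr(float(schedule.fertility[i, j]))))
    pd.DataFrame(frows, columns=["year", "age", "rate"]).to_csv(
        fertility_path, index=False
    )
    mrows = []
    for i, y in enumerate(schedule.years):
        for a in range(0, MAX_AGE + 1):
            for k, sex in enumerate(SEXES):
                mrows.append((int(y), a, sex, repr(float(schedule.mortality[i, a, k]))))
    pd.DataFrame(mrows, columns=["year", "age", "sex", "rate"]).to_csv(
        mortality_path, index=False
    )


def read_initial_population(path) -> InitialPopulation:
    """Read an age/sex count table with columns ``age,sex,count``."""
    df = pd.read_csv(path)
    missing = {"age", "sex", "count"} - set(df.columns)
    if missing:
        raise ScheduleError(f"population table missing columns {sorted(missing)}")
    counts = np.zeros((MAX_AGE + 1, 2), dtype=np.int64)
    for _, row in df.iterrows():
        a = int(row["age"])
        if not 0 <= a <= MAX_AGE:
            raise ScheduleError(f"population age {a} outside 0-{MAX_AGE}")
        counts[a, SEXES.index(row["sex"])] += int(row["count"])
    return InitialPopulation(counts=counts)


def write_initial_population(pop: InitialPopulation, path) -> None:
    rows = [
        (a, sex, int(pop.counts[a, k]))
        for a in range(0, MAX_AGE + 1)
        for k, sex in enumerate(SEXES)
    ]
    pd.DataFrame(rows, columns=["age", "sex", "count"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic schedules
# ---------------------------------------------------------------------------

# Fixed unimodal fertility age shape over 15-49: a discretized Beta(2.5, 4.5)
# density on [15, 50], which peaks near age 25-26.  Packaged as a constant so
# synthetic schedules are deterministic.
def _fertility_age_shape() -> np.ndarray:
    from scipy.stats import beta as beta_dist

    ages = np.arange(FERTILITY_AGE_LO, FERTILITY_AGE_HI + 1)
    x = (ages + 0.5 - FERTILITY_AGE_LO) / (MAX_AGE - FERTILITY_AGE_LO)
    w = beta_dist.pdf(x, 2.5, 4.5)
    return w / w.sum()


FERTILITY_AGE_SHAPE = _fertility_age_shape()


def synthesize_schedule(
    start_year: int,
    n_years: int,
    tfr_start: float,
    tfr_end: float,
    e0_proxy: float = 1.0,
    seed: int | None = None,
    tfr_anchors: list[tuple[int, float]] | None = None,
) -> RateSchedule:
    """Generate a synthetic declining-fertility, declining-mortality schedule.

    Fertility uses a fixed unimodal age shape scaled so the period TFR
    interpolates log-linearly from ``tfr_start`` to ``tfr_end`` across the
    span (or piecewise log-linearly through ``tfr_anchors`` when given,
    holding constant beyond the last anchor).  Mortality is a child
    (exponentially decaying in age) plus Gompertz adult hazard whose
    overall level declines monotonically over calendar time; ``e0_proxy``
    scales the starting level (1.0 corresponds to a mid-transition
    mortality regime with infant death probability around 0.09).

    The output is deterministic given the arguments; ``seed`` is accepted
    for interface symmetry with the other generators.
    """
    del seed  # deterministic surface by construction
    if n_years < 1:
        raise ScheduleError("n_years must be at least 1")
    if tfr_start <= 0 or tfr_end <= 0:
        raise ScheduleError("TFR anchors must be positive")
    if e0_proxy <= 0:
        raise ScheduleError("e0_proxy must be positive")
    years = np.arange(start_year, start_year + n_years)

    if tfr_anchors is None:
        tfr_anchors = [(start_year, tfr_start), (start_year + n_years - 1, tfr_end)]
    ay = np.array([a[0] for a in tfr_anchors], dtype=float)
    av = np.array([a[1] for a in tfr_anchors], dtype=float)
    if np.any(av <= 0):
        raise ScheduleError("TFR anchors must be positive")
    log_tfr = np.interp(years.astype(float), ay, np.log(av))
    tfr = np.exp(log_tfr)

    fertility = tfr[:, None] * FERTILITY_AGE_SHAPE[None, :]
    if fertility.max() > 1.0:
        raise ScheduleError("TFR too high for a per-year probability schedule")

    ages = np.arange(0, MAX_AGE + 1, dtype=float)
    child = 0.09 * np.exp(-ages / 2.0)
    adult = 2.0e-4 * np.exp(0.07 * ages)
    base = child + adult + 5.0e-4
    # mortality level halves roughly every 35 years
    level = e0_proxy * np.exp(-np.log(2.0) / 35.0 * np.arange(n_years, dtype=float))
    mortality = np.zeros((n_years, MAX_AGE + 1, 2))
    mortality[:, :, 0] = level[:, None] * base[None, :]
    mortality[:, :, 1] = level[:, None] * base[None, :] * 1.15  # excess male risk
    np.clip(mortality, 0.0, 1.0, out=mortality)

    return RateSchedule(years=years, fertility=fertility, mortality=mortality)


def demo_schedule(
    start_year: int = 1945, end_year: int = 2045, seed: int | None = None
) -> RateSchedule:
    """Bundled synthetic analog of a fast fertility transition.

    TFR falls from 5.0 at the burn-in start through 2.8 thirty-five years
    later down to 1.2 another thirty years on, then stays constant —
    the classic declining-family-size profile over which SRB distortions
    emerge.
    """
    mid = start_year + 35
    late = mid + 30
    return synthesize_schedule(
        start_year,
        end_year - start_year + 1,
        tfr_start=5.0,
        tfr_end=1.2,
        seed=seed,
        tfr_anchors=[(start_year, 5.0), (mid, 2.8), (late, 1.2), (end_year, 1.2)],
    )


def synthesize_initial_population(
    schedule: RateSchedule,
    size: int,
    seed: int | None = None,
    p_male: float = P_MALE_DEFAULT,
) -> InitialPopulation:
    """Draw an initial age/sex pyramid near the stable population.

    The female stable age distribution is the leading eigenvector of the
    Leslie matrix built from the schedule's first-year rates; male counts
    follow from the natural sex ratio at conception and relative male
    survival.  The requested ``size`` is allocated by a multinomial draw
    over the (age, sex) cells, so the newborn slice carries a sex ratio
    of about 105 males per 100 females up to binomial noise.
    """
    if size <= 0:
        raise ScheduleError("population size must be positive")
    rng = np.random.default_rng(seed)
    q = schedule.mortality[0]          # (51, 2)
    f = schedule.fertility[0]          # ages 15-49

    n = MAX_AGE + 1
    leslie = np.zeros((n, n))
    surv_f = 1.0 - q[:, 0]
    for a in range(n - 1):
        leslie[a + 1, a] = surv_f[a]
    for j, a in enumerate(range(FERTILITY_AGE_LO, FERTILITY_AGE_HI + 1)):
        leslie[0, a] = f[j] * (1.0 - p_male)
    vals, vecs = np.linalg.eig(leslie)
    i = int(np.argmax(vals.real))
    stable_f = np.abs(vecs[:, i].real)
    stable_f /= stable_f.sum()

    # male profile: same shape scaled by conception sex ratio and the
    # ratio of male to female survivorship to each age
    lf = np.concatenate([[1.0], np.cumprod(surv_f[:-1])])
    lm = np.concatenate([[1.0], np.cumprod(1.0 - q[:-1, 1])])
    stable_m = stable_f * (p_male / (1.0 - p_male)) * (lm / np.maximum(lf, 1e-12))

    probs = np.concatenate([stable_f, stable_m])
    probs /= probs.sum()
    draw = rng.multinomial(size, probs)
    counts = np.stack([draw[:n], draw[n:]], axis=1)
    return InitialPopulation(counts=counts)
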