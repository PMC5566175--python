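"""Calibration and sensitivity machinery.

The simulator is fitted to a reference sex-ratio-at-birth series by
minimizing a root-mean-squared yearly error over a Latin hypercube
sample of the six behavioral parameters.  A polynomial regression
metamodel (linear + quadratic + pairwise interaction terms) is fitted
over the design points, supports dense interpolation of the fit surface,
and its sequential ANOVA decomposition attributes response variance to
individual parameters, their squares, and their interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import qmc
from statsmodels.stats.anova import anova_lm

from .agents import PARAMETER_RANGES, ParameterSet
from .engine import ScenarioConfig, run_scenario

PARAM_NAMES = tuple(PARAMETER_RANGES)  # gamma, alpha, sigma, beta, rho, phi


def model_fit_rmse(
    simulated: pd.Series | dict,
    reference: pd.Series | dict,
    start_year: int,
    end_year: int,
) -> float:
    """Average yearly error between simulated and reference SRB series.

    Sums squared errors over every year from ``start_year`` through
    ``end_year`` inclusive and divides by ``end_year - start_year``
    (the printed convention: 30 for a 1980-2010 window, although 31
    yearly terms enter the sum).
    """
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    sim = pd.Series(simulated)
    ref = pd.Series(reference)
    years = range(start_year, end_year + 1)
    for name, s in (("simulated", sim), ("reference", ref)):
        missing = [y for y in years if y not in s.index or pd.isna(s.get(y))]
        if missing:
            raise ValueError(f"{name} series missing years {missing[:5]}")
    sq = sum((ref[y] - sim[y]) ** 2 for y in years)
    return float(np.sqrt(sq / (end_year - start_year)))


@dataclass
class DesignTable:
    """Latin hypercube design points with attached model-fit outcomes.

    ``design`` has one row per point: ``point_id``, the six parameters,
    and ``n_reps`` (replicated points get several simulation runs).
    ``outcomes`` is a long table (``point_id``, ``replicate``, outcome
    columns) filled in by :func:`evaluate_design`.
    """

    design: pd.DataFrame
    outcomes: pd.DataFrame | None = None

    @property
    def n_points(self) -> int:
        return len(self.design)

    @property
    def planned_runs(self) -> int:
        return int(self.design["n_reps"].sum())

    def mean_outcomes(self) -> pd.DataFrame:
        if self.outcomes is None:
            raise ValueError("design has no outcomes yet")
        means = self.outcomes.groupby("point_id").mean(numeric_only=True)
        means = means.drop(columns=["replicate"], errors="ignore")
        return self.design.merge(means, on="point_id")

    def to_csv(self, design_path, outcomes_path=None) -> None:
        self.design.to_csv(design_path, index=False)
        if outcomes_path is not None and self.outcomes is not None:
            self.outcomes.to_csv(outcomes_path, index=False)

    @classmethod
    def from_csv(cls, design_path, outcomes_path=None) -> "DesignTable":
        design = pd.read_csv(design_path)
        outcomes = pd.read_csv(outcomes_path) if outcomes_path else None
        return cls(design=design, outcomes=outcomes)


def latin_hypercube_design(
    ranges: dict[str, tuple[float, float]] | None = None,
    n_points: int = 224,
    n_replicated: int = 44,
    reps: int = 5,
    seed: int | None = None,
) -> DesignTable:
    """Space-filling Latin hypercube over the behavioral-parameter box.

    ``n_replicated`` randomly chosen points are flagged for ``reps``
    repeated simulation runs each (the rest get one run), so the default
    224-point design plans (224 - 44) x 1 + 44 x 5 = 400 runs.
    """
    if ranges is None:
        ranges = dict(PARAMETER_RANGES)
    if n_replicated > n_points:
        raise ValueError("cannot replicate more points than the design holds")
    if reps < 1:
        raise ValueError("reps must be at least 1")
    names = list(ranges)
    lo = np.array([ranges[k][0] for k in names], dtype=float)
    hi = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("each parameter range must have max > min")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(names), rng=rng)
    unit = sampler.random(n_points)
    points = qmc.scale(unit, lo, hi)
    design = pd.DataFrame(points, columns=names)
    design.insert(0, "point_id", np.arange(n_points))
    n_reps = np.ones(n_points, dtype=int)
    replicated = rng.choice(n_points, size=n_replicated, replace=False)
    n_reps[replicated] = reps
    design["n_reps"] = n_reps
    return DesignTable(design=design)


def evaluate_design(
    design: DesignTable,
    schedule,
    reference: pd.Series,
    config_template: ScenarioConfig,
    fit_window: tuple[int, int] | None = None,
) -> DesignTable:
    """Run the simulator at every design point and score the SRB fit.

    Each point runs ``n_reps`` replicates (common base seed, replicate
    offsets) and records per-replicate RMSE against the reference
    series plus the SRB summaries used as sensitivity outcomes.
    """
    if fit_window is None:
        fit_window = (config_template.start_year, config_template.end_year)
    start, end = fit_window
    rows = []
    for rec in design.design.itertuples(index=False):
        params = ParameterSet(
            **{k: getattr(rec, k) for k in PARAM_NAMES},
            p_male=config_template.params.p_male,
        )
        cfg = config_template.with_values(params=params, n_replicates=int(rec.n_reps))
        ens = run_scenario(cfg, schedule)
        for r, frame in enumerate(ens.replicates):
            srb = frame.set_index("year")["srb"]
            rows.append(
                {
                    "point_id": rec.point_id,
                    "replicate": r,
                    "fit": model_fit_rmse(srb, reference, start, end),
                    "srb_mid": float(srb.get(start + (end - start) // 3, np.nan)),
                    "max_srb": float(srb.max()),
                }
            )
    return DesignTable(design=design.design, outcomes=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Regression metamodel and ANOVA decomposition
# ---------------------------------------------------------------------------

@dataclass
class MetamodelResult:
    """Fitted response-surface regression with its variance decomposition.

    ``variance_shares`` maps each term to its sequential (type-I) share
    of the total response variance in percent; shares plus
    ``residual_share`` sum to 100 within rounding.
    """

    outcome: str
    terms: list[str]
    centers: dict[str, float]
    results: object  # statsmodels RegressionResults
    r_squared: float
    variance_shares: pd.Series
    residual_share: float
    ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(PARAMETER_RANGES))

    def predict(self, points: pd.DataFrame) -> np.ndarray:
        df = points.copy()
        for k, c in self.centers.items():
            df[k] = df[k] - c
        return np.asarray(self.results.predict(df))


def _term_formula(term_set: str) -> tuple[list[str], str]:
    """Fixed, documented term order: mains, then squares, then pairs."""
    names = list(PARAM_NAMES)
    terms = list(names)
    if term_set in ("+quadratic", "+interactions"):
        terms += [f"I({k} ** 2)" for k in names]
    if term_set == "+interactions":
        terms += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    if term_set not in ("linear", "+quadratic", "+interactions"):
        raise ValueError(f"unknown term set {term_set!r}")
    return terms, "y ~ " + " + ".join(terms)


def fit_metamodel(
    design: DesignTable,
    outcome: str = "fit",
    terms: str = "+interactions",
    log_scale: bool = False,
) -> MetamodelResult:
    """Least-squares polynomial metamodel with sequential ANOVA shares.

    Parameters are centered at their design means before the quadratic
    and interaction terms are formed, which reduces the order
    sensitivity of the sequential decomposition; the entry order (main
    effects first, then squares, then pairwise interactions) is fixed.
    """
    data = design.mean_outcomes()
    if outcome not in data.columns:
        raise ValueError(f"outcome {outcome!r} not in design outcomes")
    term_list, formula = _term_formula(terms)
    n_terms = len(term_list)
    if len(data) < 2 * n_terms:
        raise ValueError(
            f"need at least {2 * n_terms} design points for {n_terms} terms, "
            f"have {len(data)}"
        )
    df = data.copy()
    y = df[outcome].astype(float)
    if log_scale:
        y = np.log(y)
    df["y"] = y
    centers = {k: float(df[k].mean()) for k in PARAM_NAMES}
    for k, c in centers.items():
        df[k] = df[k] - c
    model = smf.ols(formula, data=df).fit()
    table = anova_lm(model, typ=1)
    ss = table["sum_sq"]
    total = float(ss.sum())
    shares = 100.0 * ss.drop("Residual") / total
    residual = 100.0 * float(ss["Residual"]) / total
    return MetamodelResult(
        outcome=outcome,
        terms=term_list,
        centers=centers,
        results=model,
        r_squared=float(model.rsquared),
        variance_shares=shares,
        residual_share=residual,
    )


def interpolate_fit_surface(
    metamodel: MetamodelResult,
    grid: dict[str, np.ndarray] | None = None,
    levels: int = 7,
) -> pd.DataFrame:
    """Metamodel prediction over a dense factorial grid of the box.

    ``grid`` maps each parameter to its value levels (defaults to
    ``levels`` equally spaced values across the plausible range).  The
    returned frame has one row per grid point with a ``predicted``
    column; the argmin row is the metamodel's best-fit candidate.
    """
    if grid is None:
        grid = {
            k: np.linspace(lo, hi, levels)
            for k, (lo, hi) in metamodel.ranges.items()
        }
    for k, values in grid.items():
        lo, hi = metamodel.ranges[k]
        v = np.asarray(values, dtype=float)
        if v.min() < lo - 1e-12 or v.max() > hi + 1e-12:
            raise ValueError(f"grid for {k} leaves the plausible range [{lo}, {hi}]")
    names = list(grid)
    mesh = np.meshgrid(*[grid[k] for k in names], indexing="ij")
    points = pd.DataFrame({k: m.ravel() for k, m in zip(names, mesh)})
    points["predicted"] = metamodel.predict(points)
    return points


def argmin_surface(surface: pd.DataFrame) -> pd.Series:
    """The grid point with the smallest predicted outcome."""
    return surface.loc[surface["predicted"].idxmin()]


def best_fit_search(
    schedule,
    reference: pd.Series,
    config_template: ScenarioConfig,
    design: DesignTable,
    fit_window: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, DesignTable]:
    """Rank design points by mean RMSE against the reference series.

    Returns the ranked table (best first, with a ``rank`` column) and
    the evaluated design.  Use :func:`fit_metamodel` +
    :func:`interpolate_fit_surface` on the result for metamodel-based
    refinement between design points.
    """
    evaluated = (
        design
        if design.outcomes is not None
        else evaluate_design(design, schedule, reference, config_template, fit_window)
    )
    ranked = evaluated.mean_outcomes().sort_values("fit").reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked, evaluated
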