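"""Scenario definitions, probabilistic sensitivity analysis, tornado and grids.

A :class:`ScenarioSpec` fixes one analysis: the eligible population (an
incidence stratum), screening start age, screening interval, horizon,
discount rate and the structural variants examined in sensitivity analyses
(false-positive rate, stage-shift source, overdiagnosis rate, false-positive
disutility).  Deterministic runs use every parameter at its point value; the
PSA redraws costs (gamma), utilities (beta) and stage fractions (normal,
renormalized per arm) 10,000 times and summarizes the incremental results
with both interval conventions: the min-max of the draws (the convention
used for the published uncertainty intervals) and 2.5/97.5 percentiles.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .health_economics import Accumulation, CeaResult, accumulate, ceac, compare
from .life_tables import LifeTable
from .markov_engine import StrategySpec, run_blended_trace
from .parameters import ParameterSet, DistributionSpec, draw_parameters
from .synthetic_cohort import SubgroupSpec, default_subgroups

__all__ = [
    "ScenarioSpec",
    "run_cea",
    "PsaRun",
    "run_psa",
    "tornado",
    "scenario_grid",
    "COHORT_SIZE",
]

#: reference cohort size used to scale per-person event flows to counts
COHORT_SIZE = 14_218

#: stage split observed with volumetry-based (NELSON-style) screening,
#: used by the stage-shift structural scenario
NELSON_STAGE_SPLIT = (0.512, 0.488)

#: per-screen false-positive rate of the NLST work-up algorithm (scenario)
NLST_FP_RATE = 0.233


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One analysis scenario (population, strategy settings, variants)."""

    population: str = "total_population"
    start_age: int = 55
    interval: int = 1
    horizon_years: int | None = None
    discount_rate: float | None = None  # None = parameter-set default
    fp_rate: float | None = None
    nelson_stage_shift: bool = False
    hr_overdiagnosis: float | None = None
    fp_disutility: float | None = None  # e.g. 0.10 -> FP-cycle utility 0.90
    male_fraction: float = 0.948
    biennial_mode: str = "compartment"

    def __post_init__(self) -> None:
        if self.interval not in (1, 2):
            raise ValueError("interval must be 1 or 2")
        if self.start_age not in (50, 55, 60):
            raise ValueError("start_age must be one of 50, 55, 60")

    def apply(self, params: ParameterSet) -> ParameterSet:
        """Parameter set with this scenario's variants applied."""
        overrides: dict[str, object] = {}
        if self.discount_rate is not None:
            overrides["discount_rate_annual"] = self.discount_rate
        if self.fp_rate is not None:
            overrides["fp_rate_per_screen"] = self.fp_rate
        if self.hr_overdiagnosis is not None:
            overrides["hr_overdiagnosis"] = self.hr_overdiagnosis
        if self.nelson_stage_shift:
            loc, dis = NELSON_STAGE_SPLIT
            overrides["stage_frac_localized_screen"] = DistributionSpec.fixed(loc)
            overrides["stage_frac_disseminated_screen"] = DistributionSpec.fixed(dis)
        if self.fp_disutility is not None:
            overrides["utility_false_positive"] = DistributionSpec.fixed(
                1.0 - self.fp_disutility
            )
        return params.replace(**overrides) if overrides else params

    def strategies(self) -> tuple[StrategySpec, StrategySpec]:
        usual = StrategySpec.usual_care(self.start_age, self.horizon_years)
        screen = StrategySpec.screening(
            self.interval, self.start_age, self.horizon_years, self.biennial_mode
        )
        return usual, screen

    def stratum(self, subgroups: dict[str, SubgroupSpec] | None = None) -> SubgroupSpec:
        groups = subgroups or default_subgroups()
        if self.population not in groups:
            raise KeyError(
                f"no incidence stratum {self.population!r}; "
                f"available: {sorted(groups)}"
            )
        return groups[self.population]


def _arm_accumulations(
    scenario: ScenarioSpec,
    params: ParameterSet,
    life: LifeTable,
    subgroups: dict[str, SubgroupSpec] | None = None,
    collect_events: bool = True,
) -> tuple[Accumulation, Accumulation, dict | None]:
    p = scenario.apply(params)
    stratum = scenario.stratum(subgroups)
    usual_strategy, screen_strategy = scenario.strategies()
    t_usual = run_blended_trace(
        scenario.start_age, stratum, p, usual_strategy, life, scenario.male_fraction
    )
    t_screen = run_blended_trace(
        scenario.start_age, stratum, p, screen_strategy, life, scenario.male_fraction
    )
    events = None
    if collect_events:
        events = {
            "localized_usual": t_usual.total("new_localized") * COHORT_SIZE,
            "disseminated_usual": t_usual.total("new_disseminated") * COHORT_SIZE,
            "localized_screen": t_screen.total("new_localized") * COHORT_SIZE,
            "disseminated_screen": t_screen.total("new_disseminated") * COHORT_SIZE,
            "false_positives": t_screen.total("new_fp") * COHORT_SIZE,
            "screens": t_screen.total("screens") * COHORT_SIZE,
        }
    return (
        accumulate(t_usual, p, usual_strategy),
        accumulate(t_screen, p, screen_strategy),
        events,
    )


def run_cea(
    scenario: ScenarioSpec,
    params: ParameterSet,
    life: LifeTable,
    subgroups: dict[str, SubgroupSpec] | None = None,
) -> CeaResult:
    """Deterministic cost-effectiveness comparison for one scenario."""
    usual, screen, events = _arm_accumulations(scenario, params, life, subgroups)
    result = compare(usual, screen)
    return dataclasses.replace(result, events=events)


@dataclasses.dataclass(frozen=True)
class PsaRun:
    """Results of a probabilistic sensitivity analysis.

    ``point`` is the all-deterministic run (not the mean of the draws).
    ``delta_costs``/``delta_qalys``/``icers`` hold one entry per draw; draws
    with a non-positive QALY increment are retained and counted in
    ``n_nonpositive_dq`` (their ICER entry is NaN).
    """

    scenario: ScenarioSpec
    n_draws: int
    seed: int
    point: CeaResult
    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    icers: np.ndarray
    n_nonpositive_dq: int

    def interval(self, quantity: str, method: str = "minmax") -> tuple[float, float]:
        """Uncertainty interval for ``delta_cost``, ``delta_qalys`` or ``icer``.

        ``minmax`` spans the extreme draws (the published convention);
        ``percentile`` spans the central 95%.
        """
        values = {
            "delta_cost": self.delta_costs,
            "delta_qalys": self.delta_qalys,
            "icer": self.icers[np.isfinite(self.icers)],
        }[quantity]
        if method == "minmax":
            return float(np.min(values)), float(np.max(values))
        if method == "percentile":
            lo, hi = np.percentile(values, [2.5, 97.5])
            return float(lo), float(hi)
        raise ValueError(f"unknown interval method {method!r}")

    def fraction_cost_effective(self, threshold: float) -> float:
        """Share of draws with positive net monetary benefit at ``threshold``."""
        return float(ceac(self.delta_costs, self.delta_qalys, [threshold])[0])

    def acceptability_curve(self, thresholds) -> pd.DataFrame:
        frac = ceac(self.delta_costs, self.delta_qalys, thresholds)
        return pd.DataFrame({"threshold": thresholds, "fraction_cost_effective": frac})


def run_psa(
    scenario: ScenarioSpec,
    params: ParameterSet,
    life: LifeTable,
    n_draws: int = 10_000,
    seed: int = 0,
    subgroups: dict[str, SubgroupSpec] | None = None,
) -> PsaRun:
    """Monte Carlo propagation of parameter uncertainty for one scenario.

    Every draw re-samples the full parameter set once and reruns both arms
    under the identical draw, so the increments are internally consistent.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    point = run_cea(scenario, params, life, subgroups)
    rng = np.random.default_rng(seed)
    dc = np.empty(n_draws)
    dq = np.empty(n_draws)
    for i in range(n_draws):
        drawn = draw_parameters(params, rng)
        usual, screen, _ = _arm_accumulations(
            scenario, drawn, life, subgroups, collect_events=False
        )
        dc[i] = screen.cost - usual.cost
        dq[i] = screen.qalys - usual.qalys
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(np.abs(dq) > 1e-9, dc / dq, np.nan)
    icers = np.where(dq > 1e-9, icers, np.nan)  # flagged draws: no meaningful ICER
    return PsaRun(
        scenario=scenario,
        n_draws=n_draws,
        seed=seed,
        point=point,
        delta_costs=dc,
        delta_qalys=dq,
        icers=icers,
        n_nonpositive_dq=int(np.sum(dq <= 1e-9)),
    )


# ---------------------------------------------------------------------------
# one-way (tornado) sensitivity analysis
# ---------------------------------------------------------------------------

# parameter sweeps: name -> list of (field, low value, high value) applied
# jointly; stage fractions move in complementary pairs so each arm's split
# keeps summing to one
def _tornado_sweeps(params: ParameterSet) -> dict[str, list[tuple[str, float, float]]]:
    sweeps: dict[str, list[tuple[str, float, float]]] = {}
    for name, spec in params.spec_fields():
        if spec.family == "fixed" or spec.low == spec.high:
            sweeps[name] = [(name, spec.deterministic, spec.deterministic)]
        else:
            sweeps[name] = [(name, spec.low, spec.high)]
    # complementary pairing for the stage splits
    u_loc = params.stage_frac_localized_usual
    u_dis = params.stage_frac_disseminated_usual
    s_loc = params.stage_frac_localized_screen
    s_dis = params.stage_frac_disseminated_screen
    sweeps["stage_split_usual"] = [
        ("stage_frac_localized_usual", u_loc.low, u_loc.high),
        ("stage_frac_disseminated_usual", u_dis.high, u_dis.low),
    ]
    sweeps["stage_split_screen"] = [
        ("stage_frac_localized_screen", s_loc.low, s_loc.high),
        ("stage_frac_disseminated_screen", s_dis.high, s_dis.low),
    ]
    for pair in (
        "stage_frac_localized_usual",
        "stage_frac_disseminated_usual",
        "stage_frac_localized_screen",
        "stage_frac_disseminated_screen",
    ):
        del sweeps[pair]
    # structural scalars examined one-way in the published analysis
    sweeps["fp_rate_per_screen"] = [
        ("fp_rate_per_screen", params.fp_rate_per_screen, NLST_FP_RATE)
    ]
    sweeps["hr_overdiagnosis"] = [("hr_overdiagnosis", 1.03, 1.23)]
    sweeps["discount_rate_annual"] = [("discount_rate_annual", 0.02, 0.06)]
    return sweeps


def tornado(
    scenario: ScenarioSpec,
    params: ParameterSet,
    life: LifeTable,
    subgroups: dict[str, SubgroupSpec] | None = None,
) -> pd.DataFrame:
    """One-way sweeps of each parameter to its low and high bound.

    All other parameters stay at their deterministic values.  Returns a
    table (parameter, icer_low, icer_high, span) sorted widest span first;
    ``icer_low`` is the ICER with the parameter at its low bound.
    """
    base = run_cea(scenario, params, life, subgroups)
    rows = []
    for label, moves in _tornado_sweeps(params).items():
        icer_lh = []
        for bound_idx in (1, 2):  # low values, then high values
            swept = params.replace(**{mv[0]: mv[bound_idx] for mv in moves})
            res = run_cea(scenario, swept, life, subgroups)
            icer_lh.append(res.icer if res.icer_defined else np.nan)
        rows.append(
            {
                "parameter": label,
                "icer_low": icer_lh[0],
                "icer_high": icer_lh[1],
                "span": abs(icer_lh[1] - icer_lh[0]),
            }
        )
    out = pd.DataFrame(rows).sort_values("span", ascending=False, ignore_index=True)
    out.attrs["baseline_icer"] = base.icer
    return out


DEFAULT_GRID_POPULATIONS = (
    "total_population",
    "high_exposure",
    "intermediate_exposure",
    "smokers",
    "high_exposure_smokers",
    "pleural_plaques",
    "asbestosis",
)


def scenario_grid(
    params: ParameterSet,
    life: LifeTable,
    populations=DEFAULT_GRID_POPULATIONS,
    start_ages=(50, 55, 60),
    intervals=(1, 2),
    subgroups: dict[str, SubgroupSpec] | None = None,
) -> pd.DataFrame:
    """Deterministic ICER table over population x start age x interval.

    Raises a gap report if a requested population has no incidence stratum.
    """
    groups = subgroups or default_subgroups()
    missing = [p for p in populations if p not in groups]
    if missing:
        raise KeyError(f"no incidence row for population(s): {missing}")
    rows = []
    for pop in populations:
        for age in start_ages:
            for interval in intervals:
                res = run_cea(
                    ScenarioSpec(population=pop, start_age=age, interval=interval),
                    params,
                    life,
                    groups,
                )
                rows.append(
                    {
                        "population": pop,
                        "start_age": age,
                        "interval": interval,
                        "icer": res.icer,
                        "delta_cost": res.delta_cost,
                        "delta_qalys": res.delta_qalys,
                        "incidence_all_ages": groups[pop].rate_all,
                    }
                )
    return pd.DataFrame(rows)
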