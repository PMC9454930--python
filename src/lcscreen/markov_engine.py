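"""Five-state annual-cycle Markov cohort engine for the screening comparison.

States: HEALTHY, LOCALIZED_LC, DISSEMINATED_LC, FALSE_POSITIVE, DEAD.
One cycle is one year; the horizon runs to age 110 (where the life table
closes) unless a shorter horizon is requested.

Within a cycle, competing events from HEALTHY are ordered and mutually
exclusive: background death first, then lung-cancer diagnosis, then a
false-positive screen among the remaining subjects, so every transition row
sums to one by construction.  Diagnosed states are exit-only-to-death (the
heterogeneous clinical courses after a localized diagnosis — cure,
progression, death — are folded into a single stage-specific death hazard
ratio).  A false positive returns to HEALTHY after one cycle; during the
work-up year the subject still faces background death and the same
lung-cancer incidence as a healthy subject (the work-up does not shield
against diagnosis).  Screening, its false-positive risk and its cost recur
at every screening interval from the start age for as long as the subject
is healthy, with no upper age cap.

Biennial screening keeps the annual cycle but screens every second year.
Its diagnoses split into a screen-detected compartment (carrying the
screening stage fractions) and an interval-cancer compartment (carrying the
usual-care stage fractions) at the 2.8:1 ratio observed with a two-year
screening round; see :func:`biennial_stage_mix` for the conventions.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .life_tables import LifeTable, lc_death_prob
from .parameters import ParameterSet
from .synthetic_cohort import SubgroupSpec

__all__ = [
    "HealthState",
    "StrategySpec",
    "CohortTrace",
    "transition_probs",
    "run_trace",
    "run_blended_trace",
    "biennial_adapt",
    "biennial_stage_mix",
]

MAX_AGE = 110
_SUM_TOL = 1e-9
_DRIFT_TOL = 1e-6


class HealthState(enum.IntEnum):
    HEALTHY = 0
    LOCALIZED_LC = 1
    DISSEMINATED_LC = 2
    FALSE_POSITIVE = 3
    DEAD = 4


N_STATES = len(HealthState)


@dataclasses.dataclass(frozen=True)
class StrategySpec:
    """One comparator arm.

    ``usual_care`` never screens; ``screening`` screens every
    ``screen_interval`` years (1 or 2) from ``start_age`` until death.
    ``horizon_years=None`` runs a lifetime horizon (to age 110).
    ``biennial_mode`` selects the diagnosis-mix convention for interval 2.
    """

    arm: str
    screen_interval: int | None = None
    start_age: int = 55
    horizon_years: int | None = None
    biennial_mode: str = "compartment"

    def __post_init__(self) -> None:
        if self.arm not in ("usual_care", "screening"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.arm == "usual_care" and self.screen_interval is not None:
            raise ValueError("usual_care does not screen; interval must be None")
        if self.arm == "screening" and self.screen_interval not in (1, 2):
            raise ValueError("screening interval must be 1 or 2 years")
        if self.biennial_mode not in ("compartment", "capped_yield"):
            raise ValueError(f"unknown biennial_mode {self.biennial_mode!r}")

    def is_screen_cycle(self, cycle_index: int) -> bool:
        if self.arm != "screening":
            return False
        return cycle_index % self.screen_interval == 0

    @staticmethod
    def usual_care(start_age: int = 55, horizon_years: int | None = None) -> "StrategySpec":
        return StrategySpec("usual_care", None, start_age, horizon_years)

    @staticmethod
    def screening(
        interval: int = 1,
        start_age: int = 55,
        horizon_years: int | None = None,
        biennial_mode: str = "compartment",
    ) -> "StrategySpec":
        return StrategySpec("screening", interval, start_age, horizon_years, biennial_mode)


def biennial_adapt(params: ParameterSet) -> dict[str, float]:
    """Split two-yearly diagnoses into screen-detected and interval shares.

    With a screen-detected : interval ratio ``r`` the screen-detected share
    is ``r / (r + 1)`` and the interval share ``1 / (r + 1)`` (r = 2.8 gives
    0.7368 / 0.2632).  Interval cancers carry the usual-care stage fractions
    and no overdiagnosis; screen-detected cancers carry the screening stage
    fractions.
    """
    r = params.detected_to_interval_ratio
    if not r > 0:
        raise ValueError("detected_to_interval_ratio must be > 0")
    if np.isinf(r):
        detected = 1.0
    else:
        detected = r / (r + 1.0)
    return {"screen_detected_share": detected, "interval_share": 1.0 - detected}


def biennial_stage_mix(params: ParameterSet, mode: str = "compartment") -> tuple[float, float, float]:
    """(overdiagnosis multiplier, localized fraction, disseminated fraction)
    for the biennial arm's diagnoses.

    ``compartment`` (default): diagnoses split into a screen-detected
    compartment (share ``r/(r+1)`` with r = 2.8, carrying the screening
    stage fractions) and an interval-cancer compartment (share ``1/(r+1)``,
    carrying the usual-care stage fractions).  Total detection equals the
    underlying incidence times ``biennial_overdiagnosis``; its default of
    1.0 (no overdiagnosis excess) follows the reported biennial outcome
    totals, which match usual care exactly.

    ``capped_yield``: the screen-detected compartment is additionally
    scaled by the overdiagnosis ratio and the biennial detection factor,
    capped so the biennial arm never detects more cancers than the annual
    arm.
    """
    a_s = params.value("stage_frac_localized_screen")
    b_s = params.value("stage_frac_disseminated_screen")
    a_u = params.value("stage_frac_localized_usual")
    b_u = params.value("stage_frac_disseminated_usual")
    shares = biennial_adapt(params)
    w_d, w_i = shares["screen_detected_share"], shares["interval_share"]
    if mode == "compartment":
        od = params.biennial_overdiagnosis
        return od, w_d * a_s + w_i * a_u, w_d * b_s + w_i * b_u
    if mode == "capped_yield":
        det_w = w_d * params.hr_overdiagnosis * params.biennial_detection_factor
        det_w = min(det_w, params.hr_overdiagnosis - w_i)  # cap at annual yield
        total = det_w + w_i
        f_loc = (det_w * a_s + w_i * a_u) / total
        f_dis = (det_w * b_s + w_i * b_u) / total
        return total, f_loc, f_dis
    raise ValueError(f"unknown biennial mode {mode!r}")


def _arm_stage_mix(params: ParameterSet, strategy: StrategySpec) -> tuple[float, float, float]:
    """(overdiagnosis multiplier, localized fraction, disseminated fraction)."""
    if strategy.arm == "usual_care":
        return (
            1.0,
            params.value("stage_frac_localized_usual"),
            params.value("stage_frac_disseminated_usual"),
        )
    if strategy.screen_interval == 1:
        return (
            params.hr_overdiagnosis,
            params.value("stage_frac_localized_screen"),
            params.value("stage_frac_disseminated_screen"),
        )
    return biennial_stage_mix(params, strategy.biennial_mode)


def transition_probs(
    age: int,
    sex: str,
    incidence_rate: float,
    params: ParameterSet,
    strategy: StrategySpec,
    life: LifeTable,
    cycle_index: int = 0,
) -> np.ndarray:
    """One-cycle transition matrix (rows = from-state, columns = to-state).

    ``incidence_rate`` is the lung-cancer rate per person-year (not per
    1000).  Converted to a one-cycle probability as ``1 - exp(-rate)`` and
    multiplied by the arm's overdiagnosis factor before the stage split.
    """
    if incidence_rate < 0:
        raise ValueError("incidence_rate must be >= 0")
    qx = life.qx(age, sex)
    od, f_loc, f_dis = _arm_stage_mix(params, strategy)
    p_lc = min((1.0 - np.exp(-incidence_rate)) * od, 1.0)
    fp = (
        params.fp_rate_per_screen
        if strategy.is_screen_cycle(cycle_index)
        else 0.0
    )
    m = np.zeros((N_STATES, N_STATES))
    h = HealthState
    m[h.HEALTHY, h.DEAD] = qx
    m[h.HEALTHY, h.LOCALIZED_LC] = (1 - qx) * p_lc * f_loc
    m[h.HEALTHY, h.DISSEMINATED_LC] = (1 - qx) * p_lc * f_dis
    m[h.HEALTHY, h.FALSE_POSITIVE] = (1 - qx) * (1 - p_lc) * fp
    m[h.HEALTHY, h.HEALTHY] = (1 - qx) * (1 - p_lc) * (1 - fp)
    p_dl = lc_death_prob(qx, params.hr_death_localized)
    m[h.LOCALIZED_LC, h.DEAD] = p_dl
    m[h.LOCALIZED_LC, h.LOCALIZED_LC] = 1 - p_dl
    p_dd = lc_death_prob(qx, params.hr_death_disseminated)
    m[h.DISSEMINATED_LC, h.DEAD] = p_dd
    m[h.DISSEMINATED_LC, h.DISSEMINATED_LC] = 1 - p_dd
    # the work-up year does not shield against cancer: a false positive
    # faces the same incidence as a healthy subject, then returns
    m[h.FALSE_POSITIVE, h.HEALTHY] = (1 - qx) * (1 - p_lc)
    m[h.FALSE_POSITIVE, h.LOCALIZED_LC] = (1 - qx) * p_lc * f_loc
    m[h.FALSE_POSITIVE, h.DISSEMINATED_LC] = (1 - qx) * p_lc * f_dis
    m[h.FALSE_POSITIVE, h.DEAD] = qx
    m[h.DEAD, h.DEAD] = 1.0
    bad = np.flatnonzero(np.abs(m.sum(axis=1) - 1.0) > _SUM_TOL)
    if bad.size or (m < -1e-15).any() or (m > 1 + 1e-15).any():
        raise ValueError(
            f"invalid transition row(s) {[HealthState(b).name for b in bad]} "
            f"at age {age}: {m}"
        )
    return m


@dataclasses.dataclass
class CohortTrace:
    """Per-cycle bookkeeping of one strategy arm.

    ``occupancy[t]`` is the state distribution after the transitions of
    cycle ``t`` (t = 0 is the first model year).  ``ages[t]`` is the age at
    the start of cycle ``t``.  Event counters are per-cycle flows per
    initial subject; ``screens[t]`` counts scans performed at the start of
    cycle ``t`` (healthy occupants at a screening round).
    """

    strategy: StrategySpec
    entry_age: int
    ages: np.ndarray
    occupancy: np.ndarray  # (T, 5)
    new_localized: np.ndarray
    new_disseminated: np.ndarray
    new_fp: np.ndarray
    screens: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > _DRIFT_TOL):
            raise ValueError(
                f"occupancy drift: max |sum - 1| = {np.max(np.abs(sums - 1)):.3g}"
            )
        if np.any(self.occupancy < -1e-12):
            raise ValueError("negative occupancy")
        dead = self.occupancy[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("DEAD occupancy must be non-decreasing")

    def total(self, field: str) -> float:
        return float(getattr(self, field).sum())

    def blend(self, other: "CohortTrace", w_self: float) -> "CohortTrace":
        """Occupancy-weighted mixture of two traces (linearity of the model)."""
        if self.n_cycles != other.n_cycles:
            raise ValueError("traces must share a horizon to blend")
        w = float(w_self)
        mix = lambda a, b: w * a + (1 - w) * b
        return CohortTrace(
            strategy=self.strategy,
            entry_age=self.entry_age,
            ages=self.ages,
            occupancy=mix(self.occupancy, other.occupancy),
            new_localized=mix(self.new_localized, other.new_localized),
            new_disseminated=mix(self.new_disseminated, other.new_disseminated),
            new_fp=mix(self.new_fp, other.new_fp),
            screens=mix(self.screens, other.screens),
        )


def run_trace(
    entry_age: int,
    sex: str,
    incidence: SubgroupSpec,
    params: ParameterSet,
    strategy: StrategySpec,
    life: LifeTable,
) -> CohortTrace:
    """Run the cohort trace for a single (entry age, sex) profile.

    The cohort starts fully HEALTHY.  A lifetime horizon runs until age 110;
    a fixed horizon runs ``strategy.horizon_years`` cycles.
    """
    lifetime = MAX_AGE - entry_age + 1  # includes the closing qx=1 cycle
    if strategy.horizon_years is None:
        n_cycles = lifetime
    else:
        n_cycles = min(strategy.horizon_years, lifetime)
    if entry_age >= MAX_AGE or n_cycles <= 0:
        raise ValueError(f"entry age {entry_age} leaves no cycles before {MAX_AGE}")

    ages = entry_age + np.arange(n_cycles)
    occupancy = np.zeros((n_cycles, N_STATES))
    new_loc = np.zeros(n_cycles)
    new_dis = np.zeros(n_cycles)
    new_fp = np.zeros(n_cycles)
    screens = np.zeros(n_cycles)

    # per-cycle inputs, precomputed (hot path: the PSA reruns this trace
    # thousands of times); the flow equations below mirror transition_probs
    # exactly, which a regression test asserts
    qx = life.qx_vector(entry_age, sex)[:n_cycles]
    od, f_loc, f_dis = _arm_stage_mix(params, strategy)
    p_lc = np.minimum(-np.expm1(-incidence.hazard_vector(ages)) * od, 1.0)
    p_dl = lc_death_prob(qx, params.hr_death_localized)
    p_dd = lc_death_prob(qx, params.hr_death_disseminated)
    screen_cycle = np.array([strategy.is_screen_cycle(t) for t in range(n_cycles)])
    fp_rate = np.where(screen_cycle, params.fp_rate_per_screen, 0.0)

    h = l = d = f = x = 0.0
    h = 1.0
    for t in range(n_cycles):
        if screen_cycle[t]:
            screens[t] = h
        at_risk = (h + f) * (1.0 - qx[t])  # FP work-up does not shield
        new_loc[t] = at_risk * p_lc[t] * f_loc
        new_dis[t] = at_risk * p_lc[t] * f_dis
        new_fp[t] = h * (1.0 - qx[t]) * (1.0 - p_lc[t]) * fp_rate[t]
        x = x + (h + f) * qx[t] + l * p_dl[t] + d * p_dd[t]
        l = l * (1.0 - p_dl[t]) + new_loc[t]
        d = d * (1.0 - p_dd[t]) + new_dis[t]
        h = at_risk * (1.0 - p_lc[t]) - new_fp[t]
        f = new_fp[t]
        occupancy[t] = (h, l, d, f, x)

    trace = CohortTrace(
        strategy=strategy,
        entry_age=entry_age,
        ages=ages,
        occupancy=occupancy,
        new_localized=new_loc,
        new_disseminated=new_dis,
        new_fp=new_fp,
        screens=screens,
    )
    trace.validate()
    return trace


def run_blended_trace(
    entry_age: int,
    incidence: SubgroupSpec,
    params: ParameterSet,
    strategy: StrategySpec,
    life: LifeTable,
    male_fraction: float = 0.948,
) -> CohortTrace:
    """Sex-blended trace: male and female traces mixed at the subject level."""
    male = run_trace(entry_age, "male", incidence, params, strategy, life)
    if male_fraction >= 1.0:
        return male
    female = run_trace(entry_age, "female", incidence, params, strategy, life)
    return male.blend(female, male_fraction)
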