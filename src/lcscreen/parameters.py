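"""Model parameters: deterministic values, parametric bounds and PSA distributions.

Every quantity the decision model consumes is held in a :class:`ParameterSet`:
stage-at-diagnosis fractions for each strategy arm, per-procedure costs,
health-state utilities, hazard ratios and the screening-programme constants.
Parameters that enter the probabilistic sensitivity analysis carry a
:class:`DistributionSpec` (family + deterministic value + low/high parametric
bounds); purely structural quantities are plain floats.

The low/high bounds are interpreted as a 95% interval, so the implied
standard error is ``(high - low) / 3.92``.  Gamma and beta distributions are
fitted by the method of moments to (deterministic, SE); normal draws use
(deterministic, SE) directly.  This is the standard convention in
cost-effectiveness modelling when only a point value and an interval are
reported.
"""

from __future__ import annotations

import dataclasses
import functools
import math
from importlib import resources
from typing import Iterator

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "DistributionSpec",
    "FittedDistribution",
    "ParameterSet",
    "fit_distribution",
    "draw_parameters",
    "draw_parameter_table",
    "load_parameters",
    "default_parameters",
]

FAMILIES = ("normal", "gamma", "beta", "fixed")

#: width of a central 95% normal interval, in standard-deviation units
Z95_SPAN = 3.92


@dataclasses.dataclass(frozen=True)
class DistributionSpec:
    """A parameter with a deterministic value and a parametric uncertainty spec.

    Parameters
    ----------
    family:
        One of ``normal``, ``gamma``, ``beta`` or ``fixed``.
    deterministic:
        The base-case (point-estimate) value used in deterministic runs.
    low, high:
        Parametric bounds, read as a 95% interval.  ``fixed`` parameters may
        omit them.
    """

    family: str
    deterministic: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if self.family == "fixed":
            return
        if self.low is None or self.high is None:
            raise ValueError(
                f"family {self.family!r} requires low/high bounds "
                f"(deterministic={self.deterministic})"
            )
        if not (self.low <= self.deterministic <= self.high):
            raise ValueError(
                "bounds must satisfy low <= deterministic <= high, got "
                f"low={self.low}, deterministic={self.deterministic}, "
                f"high={self.high}"
            )
        if self.family == "gamma" and self.deterministic <= 0:
            raise ValueError("gamma family requires deterministic > 0")
        if self.family == "beta" and not (0.0 <= self.deterministic <= 1.0):
            raise ValueError("beta family requires deterministic in [0, 1]")

    @property
    def se(self) -> float:
        """Standard error implied by the low/high 95% span."""
        if self.family == "fixed" or self.low is None or self.high is None:
            return 0.0
        return (self.high - self.low) / Z95_SPAN

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls(family="fixed", deterministic=float(value))


@dataclasses.dataclass(frozen=True)
class FittedDistribution:
    """A sampling recipe: distribution family plus its internal parameters.

    ``mean`` always equals the spec's deterministic value.  ``degenerate``
    recipes return the mean for every draw (used for ``fixed`` specs and for
    beta specs whose mean sits on the boundary of the unit interval, where
    finite beta moments do not exist).
    """

    family: str
    mean: float
    sd: float
    shape_a: float = math.nan  # gamma shape / beta alpha
    shape_b: float = math.nan  # gamma scale / beta beta

    @property
    def degenerate(self) -> bool:
        return self.family == "fixed" or self.sd == 0.0

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        if self.degenerate:
            return np.full(size, self.mean) if size is not None else self.mean
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape_a, self.shape_b, size=size)
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=size)
        raise AssertionError(f"unreachable family {self.family!r}")

    def frozen(self):
        """scipy frozen distribution (for quantiles / cross-checks)."""
        if self.degenerate:
            raise ValueError("degenerate recipe has no scipy counterpart")
        if self.family == "normal":
            return stats.norm(self.mean, self.sd)
        if self.family == "gamma":
            return stats.gamma(self.shape_a, scale=self.shape_b)
        if self.family == "beta":
            return stats.beta(self.shape_a, self.shape_b)
        raise AssertionError(f"unreachable family {self.family!r}")


def fit_distribution(spec: DistributionSpec, name: str = "") -> FittedDistribution:
    """Fit a sampling recipe to a :class:`DistributionSpec`.

    Method of moments throughout: the recipe's mean equals
    ``spec.deterministic`` and its standard deviation equals the SE implied by
    the (low, high) 95% span.

    Raises
    ------
    ValueError
        If the beta moment inversion yields a non-positive alpha or beta
        (infeasible moments), naming the parameter.
    """
    label = name or "parameter"
    m, se = spec.deterministic, spec.se
    if spec.family == "fixed" or se == 0.0:
        return FittedDistribution(family="fixed", mean=m, sd=0.0)
    if spec.family == "normal":
        return FittedDistribution(family="normal", mean=m, sd=se)
    if spec.family == "gamma":
        shape = (m / se) ** 2
        scale = se**2 / m
        return FittedDistribution(
            family="gamma", mean=m, sd=se, shape_a=shape, shape_b=scale
        )
    if spec.family == "beta":
        if m in (0.0, 1.0):
            # boundary mean: the moment-matched beta degenerates to a point
            # mass (utility of a transient state printed as exactly 1.000)
            return FittedDistribution(family="fixed", mean=m, sd=0.0)
        nu = m * (1.0 - m) / se**2 - 1.0
        alpha, beta = m * nu, (1.0 - m) * nu
        if alpha <= 0.0 or beta <= 0.0:
            raise ValueError(
                f"infeasible beta moments for {label!r}: mean={m}, se={se} "
                f"imply alpha={alpha:.4g}, beta={beta:.4g}"
            )
        return FittedDistribution(
            family="beta", mean=m, sd=se, shape_a=alpha, shape_b=beta
        )
    raise AssertionError(f"unreachable family {spec.family!r}")


@functools.lru_cache(maxsize=256)
def _fit_cached(spec: DistributionSpec, name: str) -> FittedDistribution:
    return fit_distribution(spec, name)


# ---------------------------------------------------------------------------
# parameter set
# ---------------------------------------------------------------------------

# names of the DistributionSpec-valued fields, in a stable draw order
_SPEC_FIELDS = (
    "stage_frac_localized_usual",
    "stage_frac_disseminated_usual",
    "stage_frac_localized_screen",
    "stage_frac_disseminated_screen",
    "cost_usual_annual",
    "cost_screen_round",
    "cost_localized_surgical_oneoff",
    "cost_localized_postsurgical_per2y",
    "cost_disseminated_per2y",
    "cost_false_positive",
    "utility_localized",
    "utility_disseminated",
    "utility_false_positive",
)

_COST_FIELDS = tuple(f for f in _SPEC_FIELDS if f.startswith("cost_"))
_UTILITY_FIELDS = tuple(f for f in _SPEC_FIELDS if f.startswith("utility_"))
_STAGE_PAIRS = (
    ("stage_frac_localized_usual", "stage_frac_disseminated_usual"),
    ("stage_frac_localized_screen", "stage_frac_disseminated_screen"),
)

_SCALAR_FIELDS = (
    "hr_overdiagnosis",
    "fp_rate_per_screen",
    "detected_to_interval_ratio",
    "biennial_detection_factor",
    "biennial_overdiagnosis",
    "hr_death_localized",
    "hr_death_disseminated",
    "utility_healthy",
    "discount_rate_annual",
    "postsurgical_cycle_fraction",
    "disseminated_cycle_fraction",
)


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """All model inputs for one analysis.

    Stage-at-diagnosis fractions multiply the stratum lung-cancer incidence
    (the SIR): under usual care 18.1% of cancers surface localized (stage
    I-II) and 81.9% disseminated (stage III-IV); under annual screening the
    split shifts to 70.2%/29.8% and total detection is inflated by the 1.13
    overdiagnosis hazard ratio.  Stage-specific death hazard ratios (2.68
    localized, 8.38 disseminated) act multiplicatively on the background
    survival curve.  Costs are in euros; the per-2-year treatment costs are
    accrued at half their value per annual cycle of state occupancy.
    """

    # stage-at-diagnosis fractions (multiply the stratum incidence)
    stage_frac_localized_usual: DistributionSpec
    stage_frac_disseminated_usual: DistributionSpec
    stage_frac_localized_screen: DistributionSpec
    stage_frac_disseminated_screen: DistributionSpec
    # costs (euros)
    cost_usual_annual: DistributionSpec
    cost_screen_round: DistributionSpec
    cost_localized_surgical_oneoff: DistributionSpec
    cost_localized_postsurgical_per2y: DistributionSpec
    cost_disseminated_per2y: DistributionSpec
    cost_false_positive: DistributionSpec
    # utilities
    utility_localized: DistributionSpec
    utility_disseminated: DistributionSpec
    utility_false_positive: DistributionSpec
    # structural scalars (held fixed in the base PSA)
    hr_overdiagnosis: float = 1.13
    fp_rate_per_screen: float = 0.012
    detected_to_interval_ratio: float = 2.8
    biennial_detection_factor: float = 1.5
    biennial_overdiagnosis: float = 1.0
    hr_death_localized: float = 2.68
    hr_death_disseminated: float = 8.38
    utility_healthy: float = 1.0
    discount_rate_annual: float = 0.03
    # fraction of each per-2-year treatment cost charged per annual cycle of
    # state occupancy; the localized default of 1.0 (the full amount each
    # year) reproduces the published per-arm cost totals, 0.5 is the strict
    # annualization
    postsurgical_cycle_fraction: float = 1.0
    disseminated_cycle_fraction: float = 0.5

    def __post_init__(self) -> None:
        for loc, dis in _STAGE_PAIRS:
            s = getattr(self, loc).deterministic + getattr(self, dis).deterministic
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"stage fractions {loc}/{dis} must sum to 1, got {s!r}"
                )
        for name in ("hr_overdiagnosis", "hr_death_localized", "hr_death_disseminated"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        for name in _COST_FIELDS:
            if getattr(self, name).deterministic < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in _UTILITY_FIELDS:
            u = getattr(self, name).deterministic
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {u}")
        if not 0.0 <= self.utility_healthy <= 1.0:
            raise ValueError("utility_healthy must lie in [0, 1]")

    # -- access ------------------------------------------------------------

    def value(self, name: str) -> float:
        """Deterministic value of any field, spec-valued or scalar."""
        v = getattr(self, name)
        return v.deterministic if isinstance(v, DistributionSpec) else float(v)

    def spec_fields(self) -> Iterator[tuple[str, DistributionSpec]]:
        for name in _SPEC_FIELDS:
            yield name, getattr(self, name)

    def replace(self, **overrides) -> "ParameterSet":
        """Return a copy with fields replaced.

        Spec-valued fields accept either a :class:`DistributionSpec` or a bare
        number (converted to a fixed spec).
        """
        fixed = {}
        for key, val in overrides.items():
            if key in _SPEC_FIELDS and not isinstance(val, DistributionSpec):
                val = DistributionSpec.fixed(float(val))
            fixed[key] = val
        return dataclasses.replace(self, **fixed)

    def all_fixed(self) -> "ParameterSet":
        """Copy with every distribution collapsed to its deterministic value."""
        return self.replace(**{n: s.deterministic for n, s in self.spec_fields()})


def draw_parameter_table(
    params: ParameterSet, n_draws: int, rng_seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """Sample ``n_draws`` joint parameter draws; columns are field names.

    Stage-fraction pairs are drawn independently (normal) and renormalized to
    sum to one within each arm; sampled costs are truncated at zero and
    utilities clipped to the unit interval.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    out: dict[str, np.ndarray] = {}
    for name, spec in params.spec_fields():
        draws = np.asarray(
            _fit_cached(spec, name).sample(rng, size=n_draws), dtype=float
        )
        if name in _COST_FIELDS:
            draws = np.maximum(draws, 0.0)
        elif name in _UTILITY_FIELDS:
            draws = np.clip(draws, 0.0, 1.0)
        out[name] = draws
    for loc, dis in _STAGE_PAIRS:
        total = out[loc] + out[dis]
        out[loc] = out[loc] / total
        out[dis] = out[dis] / total
    return out


def draw_parameters(params: ParameterSet, rng_seed: int | np.random.Generator) -> ParameterSet:
    """One joint PSA draw: every distribution replaced by a sampled value.

    Reproducible given the seed; structural scalars pass through unchanged.
    """
    table = draw_parameter_table(params, 1, rng_seed)
    return params.replace(**{name: float(col[0]) for name, col in table.items()})


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------


def _parse_config(doc: dict) -> ParameterSet:
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ValueError("config must contain a 'parameters' mapping")
    block = doc["parameters"]
    kwargs: dict[str, object] = {}
    for key, val in block.items():
        if key in _SPEC_FIELDS:
            if not isinstance(val, dict):
                raise ValueError(
                    f"parameter {key!r} must be a mapping with "
                    "family/deterministic/low/high"
                )
            unknown = set(val) - {"family", "deterministic", "low", "high"}
            if unknown:
                raise ValueError(f"unknown keys {sorted(unknown)} in parameter {key!r}")
            kwargs[key] = DistributionSpec(**val)
        elif key in _SCALAR_FIELDS:
            kwargs[key] = float(val)
        else:
            raise ValueError(f"unknown parameter key {key!r}")
    return ParameterSet(**kwargs)


def load_parameters(path: str | None = None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML config (bundled default if None)."""
    if path is None:
        text = (
            resources.files("lcscreen.data")
            .joinpath("default_config.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return _parse_config(yaml.safe_load(text))


def default_parameters() -> ParameterSet:
    """The bundled base-case parameter set."""
    return load_parameters(None)
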