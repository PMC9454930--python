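"""Background mortality (period life table) and stage-specific death probabilities.

The healthy-state annual death probability ``qx(age, sex)`` comes from a
period life table.  The package bundles a synthetic table built from a
Gompertz-Makeham hazard ``mu(x) = A + B * exp(C * x)`` calibrated so that
period life expectancy at 60 is ~23.0 years for men and ~27.5 years for
women (French 2019 period values).  Any table with the same three-column
schema (age, sex, qx) can be dropped in via :meth:`LifeTable.load`, e.g. an
official INED/INSEE table.

Death from diagnosed lung cancer is modelled by applying a stage-specific
hazard ratio to background survival:

    q_lc = 1 - (1 - qx) ** hr        (survival-exponent form)

The alternative rate-scaling form ``1 - exp(-hr * qx)`` (reading qx as an
approximate annual rate) is available via ``method=`` and differs by <1% at
the magnitudes involved.
"""

from __future__ import annotations

import dataclasses
import io
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GOMPERTZ_MAKEHAM",
    "gompertz_makeham_qx",
    "build_synthetic_table",
    "LifeTable",
    "lc_death_prob",
]

MIN_AGE = 50
MAX_AGE = 110
SEXES = ("male", "female")

#: frozen Gompertz-Makeham coefficients (A, B, C) of the bundled table;
#: B solved so that e(60) matches the calibration target for each sex.
GOMPERTZ_MAKEHAM: dict[str, tuple[float, float, float]] = {
    "male": (8.0e-4, 1.1515065705e-05, 0.105),
    "female": (3.0e-4, 6.8149304557e-06, 0.105),
}

_BUNDLED_NAME = "life_table_fr2019_synthetic.csv"


def gompertz_makeham_qx(age: float, sex: str) -> float:
    """Annual death probability from the bundled Gompertz-Makeham hazard.

    Integrates ``mu(x) = A + B exp(Cx)`` over one year of age:
    ``qx = 1 - exp(-(A + (B/C) exp(C age) (exp(C) - 1)))``.
    """
    a, b, c = GOMPERTZ_MAKEHAM[sex]
    cum_hazard = a + (b / c) * np.exp(c * age) * np.expm1(c)
    return float(1.0 - np.exp(-cum_hazard))


def build_synthetic_table() -> pd.DataFrame:
    """Construct the bundled life table (ages 50-110, both sexes).

    qx(110) is forced to 1 so the table is closed at the model's terminal age.
    """
    rows = []
    for sex in SEXES:
        for age in range(MIN_AGE, MAX_AGE + 1):
            qx = 1.0 if age == MAX_AGE else min(gompertz_makeham_qx(age, sex), 1.0)
            rows.append((age, sex, round(qx, 8)))
    return pd.DataFrame(rows, columns=["age", "sex", "qx"])


@dataclasses.dataclass(frozen=True)
class LifeTable:
    """Age x sex lookup of annual background death probability.

    Integer ages 50-110 for both sexes; no interpolation is performed.
    """

    _qx: dict[str, np.ndarray]  # sex -> array indexed by age - MIN_AGE

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        required = {"age", "sex", "qx"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        table: dict[str, np.ndarray] = {}
        for sex in SEXES:
            sub = frame[frame["sex"] == sex].sort_values("age")
            ages = sub["age"].to_numpy()
            expected = np.arange(MIN_AGE, MAX_AGE + 1)
            if not np.array_equal(ages, expected):
                raise ValueError(
                    f"life table must cover integer ages {MIN_AGE}-{MAX_AGE} "
                    f"for sex {sex!r}"
                )
            qx = sub["qx"].to_numpy(dtype=float)
            if np.any((qx < 0) | (qx > 1)):
                raise ValueError("qx values must lie in [0, 1]")
            if qx[-1] != 1.0:
                raise ValueError("table must close with qx = 1 at the top age")
            if np.any(np.diff(qx) < -1e-12):
                raise ValueError("qx must be non-decreasing in age")
            table[sex] = qx
        return cls(_qx=table)

    @classmethod
    def load(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def bundled(cls) -> "LifeTable":
        text = resources.files("lcscreen.data").joinpath(_BUNDLED_NAME).read_text()
        return cls.from_frame(pd.read_csv(io.StringIO(text)))

    def qx(self, age: int, sex: str) -> float:
        """Annual background death probability at integer ``age``."""
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
        if not MIN_AGE <= age <= MAX_AGE:
            raise ValueError(
                f"age {age} outside the supported range {MIN_AGE}-{MAX_AGE}"
            )
        return float(self._qx[sex][int(age) - MIN_AGE])

    def qx_vector(self, start_age: int, sex: str) -> np.ndarray:
        """qx for ages ``start_age .. MAX_AGE`` (used by the cohort trace)."""
        if not MIN_AGE <= start_age <= MAX_AGE:
            raise ValueError(
                f"age {start_age} outside the supported range {MIN_AGE}-{MAX_AGE}"
            )
        return self._qx[sex][int(start_age) - MIN_AGE :].copy()

    def life_expectancy(self, age: int, sex: str) -> float:
        """Period life expectancy at ``age`` (curtate + 1/2)."""
        q = self.qx_vector(age, sex)
        surv = np.cumprod(1.0 - q)
        return float(surv.sum() + 0.5)


def background_death_prob(table: LifeTable, age: int, sex: str) -> float:
    """Annual probability of death without lung cancer (healthy state)."""
    return table.qx(age, sex)


def lc_death_prob(qx, hr, method: str = "survival-exponent"):
    """Annual death probability in a lung-cancer state.

    Applies the stage-specific hazard ratio to background survival.  Accepts
    scalars or arrays; the result lies in ``[qx, 1]`` for ``hr >= 1``.
    """
    qx = np.asarray(qx, dtype=float)
    if np.any((qx < 0) | (qx > 1)):
        raise ValueError("qx must lie in [0, 1]")
    if np.any(np.asarray(hr) < 1.0):
        raise ValueError("hazard ratio must be >= 1")
    if method == "survival-exponent":
        out = 1.0 - (1.0 - qx) ** hr
    elif method == "rate-scaling":
        # read qx as an approximate annual rate and scale it
        out = 1.0 - np.exp(-hr * qx)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out if out.ndim else float(out)
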