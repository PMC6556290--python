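"""Background (all-cause) mortality.

The model needs an annual death probability q(a) for every simulated age.
The packaged default is a Gompertz-Makeham approximation

    q(a) = min(1, c + b * exp(g * a))

with coefficients chosen so life expectancy at birth is about 75 years,
the all-cause mortality level of the Chinese population around 2011. Any
table can be substituted from a two-column CSV (``age,qx``, ages 0-100).
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz-Makeham coefficients for the parametric fixture."""

    makeham_c: float = 5.0e-4   # age-independent annual death probability
    gompertz_b: float = 4.0e-5  # level of the senescent component
    gompertz_g: float = 0.095   # exponential slope per year of age

    def __post_init__(self) -> None:
        if self.makeham_c < 0 or self.gompertz_b < 0:
            raise ValidationError("life-table coefficients must be >= 0")


class LifeTable:
    """Annual all-cause death probabilities indexed by integer age 0-100."""

    def __init__(self, qx) -> None:
        qx = np.asarray(qx, dtype=float)
        if qx.shape != (101,):
            raise ValidationError("life table must cover ages 0-100")
        if np.any(qx < 0) or np.any(qx > 1) or not np.all(np.isfinite(qx)):
            raise ValidationError("qx values must be probabilities in [0, 1]")
        self.qx = qx
        self.qx.setflags(write=False)

    def __getitem__(self, age: int) -> float:
        return float(self.qx[age])

    def life_expectancy(self, from_age: int = 0) -> float:
        """Expected further years of life, trapezoid over the survival curve."""
        surv = np.cumprod(1.0 - self.qx[from_age:])
        return 0.5 + float(surv.sum())

    # -- IO -----------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": np.arange(101), "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        if not {"age", "qx"} <= set(df.columns):
            raise ValidationError("life-table CSV needs 'age' and 'qx' columns")
        qx = np.full(101, np.nan)
        qx[df["age"].to_numpy(dtype=int)] = df["qx"].to_numpy(dtype=float)
        if np.any(np.isnan(qx)):
            raise ValidationError("life-table CSV must define every age 0-100")
        return cls(qx)


def make_life_table(spec: LifeTableSpec = LifeTableSpec()) -> LifeTable:
    """Build a life table from Gompertz-Makeham coefficients."""
    ages = np.arange(101, dtype=float)
    qx = np.minimum(1.0, spec.makeham_c
                    + spec.gompertz_b * np.exp(spec.gompertz_g * ages))
    return LifeTable(qx)


def default_life_table() -> LifeTable:
    """The packaged parametric approximation of Chinese 2011 mortality."""
    text = resources.files("esccsim.data").joinpath(
        "life_table_cn2011_approx.csv").read_text()
    return LifeTable.from_csv(io.StringIO(text))
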