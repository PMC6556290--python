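"""Model parameters: transition intensities, detection and mortality.

The packaged point estimates (``ModelParameters.table1()``) are the
calibrated expected values published for this model. Percentage-valued
entries (stage progression, detection, disease-specific mortality) are
annual *rates* by default and are converted to annual probabilities with
1 - exp(-r) inside the engine; set ``input_scale="probability"`` to use them
as probabilities directly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .hazards import OnsetHazardParams, ProgressionHazardParams, rate_to_prob

#: Parameters searched during calibration, in vector order. Everything else
#: (SD -> TNM I progression, disease-specific mortality, the life table) is
#: fixed from the literature.
FREE_PARAMETERS = (
    "beta0", "beta1", "beta2", "beta3", "alpha0", "alpha1",
    "p_md_to_sd", "p_u1_u2", "p_u2_u3", "p_u3_u4",
    "det1", "det2", "det3", "det4",
)

_RATE_FIELDS = (
    "p_md_to_sd", "p_sd_to_u1", "p_u1_u2", "p_u2_u3", "p_u3_u4",
    "det1", "det2", "det3", "det4", "mort2", "mort3", "mort4",
)


@dataclass(frozen=True)
class ModelParameters:
    """All transition quantities of the 13-state model."""

    onset: OnsetHazardParams
    bchmd_to_md: ProgressionHazardParams
    p_md_to_sd: float          # MD -> SD
    p_sd_to_u1: float          # SD -> undetected TNM I (fixed, cohort study)
    p_u1_u2: float             # stage progression among undetected cancer
    p_u2_u3: float
    p_u3_u4: float
    det1: float                # clinical detection by TNM stage
    det2: float
    det3: float
    det4: float
    mort2: float               # disease-specific mortality, detected TNM II-IV
    mort3: float
    mort4: float
    input_scale: str = "rate"  # "rate" | "probability"

    def __post_init__(self) -> None:
        if self.input_scale not in ("rate", "probability"):
            raise ValidationError("input_scale must be 'rate' or 'probability'")
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0")
            if self.input_scale == "probability" and v > 1:
                raise ValidationError(f"{name} > 1 is not a probability")

    # -- annual-probability views -------------------------------------------

    def annual_prob(self, name: str) -> float:
        """Annual transition probability for one percentage-valued field."""
        v = getattr(self, name)
        return float(rate_to_prob(v)) if self.input_scale == "rate" else float(v)

    @property
    def stage_progression_probs(self) -> np.ndarray:
        """P(advance one TNM stage) for undetected stages I-IV (IV: 0)."""
        return np.array([self.annual_prob("p_u1_u2"),
                         self.annual_prob("p_u2_u3"),
                         self.annual_prob("p_u3_u4"), 0.0])

    @property
    def detection_probs(self) -> np.ndarray:
        return np.array([self.annual_prob(f"det{k}") for k in range(1, 5)])

    @property
    def excess_mortality_probs(self) -> np.ndarray:
        """Disease-specific annual death probability, detected TNM I-IV.

        Stage I is zero: survival after complete resection is taken as
        equivalent to the normal population, so only background mortality
        applies there.
        """
        return np.array([0.0, self.annual_prob("mort2"),
                         self.annual_prob("mort3"), self.annual_prob("mort4")])

    # -- calibration vector interface ---------------------------------------

    def to_vector(self, names: Iterable[str] = FREE_PARAMETERS) -> np.ndarray:
        return np.array([self._get_flat(n) for n in names], dtype=float)

    def with_vector(self, vector, names: Iterable[str] = FREE_PARAMETERS
                    ) -> "ModelParameters":
        """Copy with the named (free) parameters replaced by ``vector``."""
        flat = self.to_flat_dict()
        for name, value in zip(names, np.asarray(vector, dtype=float)):
            flat[name] = float(value)
        return ModelParameters.from_flat_dict(flat)

    def _get_flat(self, name: str) -> float:
        if name.startswith("beta"):
            return getattr(self.onset, name)
        if name.startswith("alpha"):
            return getattr(self.bchmd_to_md, name)
        return getattr(self, name)

    # -- (de)serialization ---------------------------------------------------

    def to_flat_dict(self) -> dict:
        d = {f"beta{k}": getattr(self.onset, f"beta{k}") for k in range(4)}
        d |= {"a1": self.onset.a1, "a2": self.onset.a2, "a3": self.onset.a3,
              "onset_form": self.onset.form,
              "alpha0": self.bchmd_to_md.alpha0,
              "alpha1": self.bchmd_to_md.alpha1}
        for f in dataclasses.fields(self):
            if f.name not in ("onset", "bchmd_to_md"):
                d[f.name] = getattr(self, f.name)
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        onset = OnsetHazardParams(
            beta0=d.pop("beta0"), beta1=d.pop("beta1"),
            beta2=d.pop("beta2"), beta3=d.pop("beta3"),
            a1=d.pop("a1", 15.0), a2=d.pop("a2", 40.0), a3=d.pop("a3", 100.0),
            form=d.pop("onset_form", "piecewise_offset"))
        prog = ProgressionHazardParams(alpha0=d.pop("alpha0"),
                                       alpha1=d.pop("alpha1"))
        return cls(onset=onset, bchmd_to_md=prog, **d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("sd", None)
        return cls.from_flat_dict(d)

    @classmethod
    def table1(cls, **overrides) -> "ModelParameters":
        """The packaged calibrated point estimates."""
        d = _load_table1()["parameters"] | overrides
        return cls.from_flat_dict(d)


def _load_table1() -> dict:
    with resources.files("esccsim.data").joinpath("table1.json").open() as fh:
        return json.load(fh)


def table1_standard_deviations() -> dict:
    """Published SDs of the calibrated parameters (for the SIR proposal)."""
    return dict(_load_table1()["sd"])
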