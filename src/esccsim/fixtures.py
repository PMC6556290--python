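"""Packaged data and synthetic generators.

Everything the model needs ships inside the package and can be regenerated
deterministically (``esccsim make-fixtures``): the calibrated parameter
point estimates with their SDs, the printed calibration targets, a
parametric life-table approximation, the two verification scenarios, and a
binomial synthetic-target generator used by parameter-recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .calibration import CalibrationTarget, model_outputs, save_targets
from .errors import ValidationError
from .life_table import LifeTable, LifeTableSpec, make_life_table
from .parameters import FREE_PARAMETERS, ModelParameters

# Calibrated expected values; percentage entries are annual rates on their
# printed scale. SDs of the non-hazard free parameters are not published and
# are set to 25% of the point estimate for proposal sampling.
TABLE1_PARAMETERS = {
    "beta0": -8.96, "beta1": 0.20481, "beta2": 0.00002, "beta3": 0.00836,
    "a1": 15.0, "a2": 40.0, "a3": 100.0, "onset_form": "piecewise_offset",
    "alpha0": -3.359, "alpha1": 0.03668,
    "p_md_to_sd": 0.1538, "p_sd_to_u1": 0.2094,
    "p_u1_u2": 0.1538, "p_u2_u3": 0.2094, "p_u3_u4": 0.4665,
    "det1": 0.5487, "det2": 0.3231, "det3": 0.0386, "det4": 0.3432,
    "mort2": 0.1515, "mort3": 0.3597, "mort4": 0.5647,
    "input_scale": "rate",
}

TABLE1_SD = {
    "beta0": 0.461, "beta1": 0.01815, "beta2": 0.0, "beta3": 0.00134,
    "alpha0": 0.171, "alpha1": 0.0095,
    "p_md_to_sd": 0.03845, "p_u1_u2": 0.03845, "p_u2_u3": 0.05235,
    "p_u3_u4": 0.116625, "det1": 0.137175, "det2": 0.080775,
    "det3": 0.00965, "det4": 0.0858,
}

# Published age-specific targets: ESCC incidence per 100,000 person-years
# and lesion prevalence in percent. The open-ended oldest rows are assigned
# the bands 85-99 (incidence) and 65-69 (prevalence, to stay inside the
# 40-69 prevalence-estimation range).
INCIDENCE_TARGETS = [
    (30, 34, 3.4), (35, 39, 12.4), (40, 44, 42.4), (45, 49, 93.1),
    (50, 54, 238.7), (55, 59, 475.8), (60, 64, 519.6), (65, 69, 636.8),
    (70, 74, 878.9), (75, 79, 925.1), (80, 84, 1145.1), (85, 99, 967.6),
]
PREVALENCE_TARGETS = {
    "bch_md": [(40, 44, 13.1), (45, 49, 16.7), (50, 54, 21.1),
               (55, 59, 22.6), (60, 64, 25.8), (65, 69, 24.3)],
    "md": [(40, 44, 1.24), (45, 49, 2.26), (50, 54, 3.62),
           (55, 59, 5.37), (60, 64, 5.5), (65, 69, 5.67)],
    "sd": [(40, 44, 0.34), (45, 49, 0.77), (50, 54, 1.71),
           (55, 59, 2.58), (60, 64, 2.64), (65, 69, 3.84)],
}

# Stage-at-diagnosis shares (percent): SYNTHETIC placeholders. The cohort
# these were calibrated to is shown only graphically in the source, so no
# printed values exist; these are plausible, editable stand-ins.
STAGE_TARGETS_SYNTHETIC = [("stage1", 12.0), ("stage2", 32.0),
                           ("stage3", 38.0), ("stage4", 18.0)]

N_EFF_PREVALENCE = 1_000.0
N_EFF_INCIDENCE = 100_000.0
N_EFF_STAGE = 1_000.0

SCENARIOS = {
    "hua_county": {
        "name": "hua_county",
        "onset_multiplier": 0.469,
        "eligible_age_lo": 45, "eligible_age_hi": 69,
        "uptake": 1.0, "sensitivity": 0.96, "specificity": 0.63,
        "followup": 10,
    },
    "cixian": {
        "name": "cixian",
        "onset_multiplier": 1.30,
        "eligible_age_lo": 40, "eligible_age_hi": 69,
        "uptake": 0.486, "sensitivity": 0.96, "specificity": 0.63,
        "followup": 10,
    },
}


def table2_target_list() -> list[CalibrationTarget]:
    """The printed targets as CalibrationTarget objects (30 of them)."""
    out = [CalibrationTarget("incidence", "escc", lo, hi, v, N_EFF_INCIDENCE)
           for lo, hi, v in INCIDENCE_TARGETS]
    for label, rows in PREVALENCE_TARGETS.items():
        out += [CalibrationTarget("prevalence", label, lo, hi, v,
                                  N_EFF_PREVALENCE) for lo, hi, v in rows]
    return out


def stage_target_list() -> list[CalibrationTarget]:
    return [CalibrationTarget("stage_proportion", label, 15, 99, v,
                              N_EFF_STAGE)
            for label, v in STAGE_TARGETS_SYNTHETIC]


# -- synthetic targets for recovery experiments ------------------------------

def default_recovery_definitions() -> list[tuple[str, str, int, int]]:
    """Compact target set for scaled-down parameter-recovery runs."""
    defs = [("prevalence", label, lo, hi)
            for label in ("bch_md", "md", "sd")
            for lo, hi in ((45, 49), (60, 64))]
    defs += [("incidence", "escc", lo, hi)
             for lo, hi in ((45, 49), (60, 64), (70, 74))]
    defs += [("stage_proportion", f"stage{k}", 15, 99) for k in range(1, 5)]
    return defs


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Recipe for binomial synthetic targets around a known model."""

    params: ModelParameters
    n_eff: float = 10_000.0
    seed: int = 0
    definitions: list[tuple[str, str, int, int]] = field(
        default_factory=default_recovery_definitions)

    def __post_init__(self) -> None:
        if self.n_eff <= 0:
            raise ValidationError("n_eff must be positive")


def make_synthetic_targets(spec: SyntheticTargetSpec,
                           life_table: LifeTable) -> list[CalibrationTarget]:
    """Binomial draws k/n around the generating model's target outputs."""
    probes = [CalibrationTarget(kind, label, lo, hi, 0.0, spec.n_eff)
              for kind, label, lo, hi in spec.definitions]
    truth = model_outputs(spec.params, life_table, probes)
    if np.any(truth < 0) or np.any(truth > 1):
        raise ValidationError("generating model produced a proportion "
                              "outside [0, 1]")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.n_eff))
    ks = rng.binomial(n, truth)
    out = []
    for probe, k in zip(probes, ks):
        scale = 1e5 if probe.kind == "incidence" else 100.0
        out.append(CalibrationTarget(probe.kind, probe.label, probe.age_lo,
                                     probe.age_hi, k / n * scale, spec.n_eff))
    return out


# -- fixture-file regeneration ----------------------------------------------

def write_fixture_files(out_dir) -> list[Path]:
    """Write every packaged data file into ``out_dir``, deterministically."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "table1.json"
    with open(path, "w") as fh:
        json.dump({"parameters": TABLE1_PARAMETERS, "sd": TABLE1_SD},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)

    path = out / "table2_targets.csv"
    save_targets(table2_target_list(), path)
    written.append(path)

    path = out / "stage_targets_synthetic.csv"
    save_targets(stage_target_list(), path)
    written.append(path)

    path = out / "life_table_cn2011_approx.csv"
    make_life_table(LifeTableSpec()).to_csv(path)
    written.append(path)

    for name, scenario in SCENARIOS.items():
        path = out / f"{name}.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(scenario, fh, sort_keys=True)
        written.append(path)
    return written
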