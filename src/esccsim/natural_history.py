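"""Deterministic cohort state-transition engine.

A closed cohort enters the model at age 15 entirely in the normal state and
is followed in annual cycles to age 100 or death. Each cycle every
compartment distributes its occupancy over destination compartments
according to competing annual event probabilities:

* normal mucosa: lesion onset (age-dependent hazard) vs background death;
* BCH/mD duration tunnels: progression to MD (duration-dependent hazard)
  vs background death, otherwise advancing one tunnel;
* MD and SD: fixed annual progression vs background death;
* undetected TNM stages: stage progression vs clinical detection vs
  background death (undetected cancer carries no excess mortality);
* detected TNM I: background mortality only (post-resection survival is
  taken as equivalent to the normal population);
* detected TNM II-IV: disease-specific mortality composed multiplicatively
  with background mortality, 1 - (1-q_bg)(1-q_dis).

Competing events within a cycle are mutually exclusive; in the rare case
their probabilities sum above 1 they are renormalized to the simplex.
Clinical detection (first entry into a detected state) is the incidence
event, matching cancer-registry incidence.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (ConservationError, DomainError, UndefinedResultError,
                     ValidationError)
from .hazards import bchmd_progression_hazard, onset_hazard, rate_to_prob
from .life_table import LifeTable
from .parameters import ModelParameters
from .states import ALIVE, DETECTED, UNDETECTED, CompartmentLayout, HealthState

CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class CohortTrajectory:
    """Per-cycle occupancy and event counts of one cohort run.

    ``occupancy[t]`` is the compartment distribution at exact age
    ``start_age + t`` (row 0 is the initial state); ``new_detections[t]``
    and ``deaths[t]`` are the event fractions during cycle t.
    """

    layout: CompartmentLayout
    start_age: int              # age at occupancy row 0 (>= layout.start_age)
    occupancy: np.ndarray       # (n_cycles + 1, n_compartments)
    new_detections: np.ndarray  # (n_cycles, 4), by TNM stage
    deaths: np.ndarray          # (n_cycles,)

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0])

    def age_row(self, age: int) -> int:
        row = int(age) - self.start_age
        if not 0 <= row < self.occupancy.shape[0]:
            raise DomainError(f"age {age} outside simulated range")
        return row

    def alive(self) -> np.ndarray:
        """Fraction alive at each exact age."""
        return self.occupancy[:, :self.layout.death].sum(axis=1)

    def state_occupancy(self) -> pd.DataFrame:
        """Occupancy aggregated over duration tunnels, one column per state."""
        cols = {s.value: self.occupancy[:, self.layout.indices(s)].sum(axis=1)
                for s in HealthState}
        return pd.DataFrame(cols, index=pd.Index(self.ages, name="age"))

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: cycle, age, state, duration_index, occupancy."""
        rows = []
        for idx in range(self.layout.n_compartments):
            state, dur = self.layout.state_of(idx)
            rows.append(pd.DataFrame({
                "cycle": np.arange(self.occupancy.shape[0]),
                "age": self.ages,
                "state": state.value,
                "duration_index": dur,
                "occupancy": self.occupancy[:, idx]}))
        return pd.concat(rows, ignore_index=True)


def _compete(probs: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalize competing event probabilities; return (events, stay)."""
    total = probs.sum()
    if total > 1.0:
        probs = probs / total
        total = 1.0
    return probs, 1.0 - total


class _Precomputed:
    """Per-run constants: annual event probabilities by age and duration."""

    def __init__(self, params: ModelParameters, life_table: LifeTable,
                 layout: CompartmentLayout, onset_multiplier: float) -> None:
        if onset_multiplier < 0:
            raise DomainError("onset_multiplier must be >= 0")
        ages = np.arange(layout.start_age, layout.end_age, dtype=float)
        self.q_bg = life_table.qx[layout.start_age:layout.end_age].copy()
        lam1 = onset_multiplier * np.asarray(onset_hazard(ages, params.onset))
        self.p_onset = rate_to_prob(lam1)
        durations = np.arange(layout.n_tunnels, dtype=float)
        lam2 = bchmd_progression_hazard(durations, params.bchmd_to_md)
        self.p_tunnel = np.asarray(rate_to_prob(lam2))
        self.p_md_sd = params.annual_prob("p_md_to_sd")
        self.p_sd_u1 = params.annual_prob("p_sd_to_u1")
        self.p_stage = params.stage_progression_probs
        self.p_det = params.detection_probs
        self.p_excess = params.excess_mortality_probs


def _step(occ: np.ndarray, t: int, pre: _Precomputed,
          layout: CompartmentLayout) -> tuple[np.ndarray, np.ndarray, float]:
    """One annual cycle; returns (next occupancy, detections by stage, deaths)."""
    L = layout
    q = pre.q_bg[t]
    new = np.zeros_like(occ)
    det_new = np.zeros(4)
    deaths = 0.0

    # normal mucosa: onset vs background death
    (p_on, p_d), stay = _compete(np.array([pre.p_onset[t], q]))
    new[L.tunnel0] += occ[L.normal] * p_on
    deaths += occ[L.normal] * p_d
    new[L.normal] += occ[L.normal] * stay

    # BCH/mD tunnels: progression vs death, survivors advance one tunnel
    tun = occ[L.tunnel0:L.tunnel0 + L.n_tunnels]
    total = pre.p_tunnel + q
    scale = np.where(total > 1.0, 1.0 / total, 1.0)
    new[L.md] += float(tun @ (pre.p_tunnel * scale))
    deaths += float(tun @ (q * scale))
    stay_t = tun * np.maximum(0.0, 1.0 - total * scale)
    new[L.tunnel0 + 1:L.tunnel0 + L.n_tunnels] += stay_t[:-1]
    new[L.tunnel0 + L.n_tunnels - 1] += stay_t[-1]  # last tunnel saturates

    # MD and SD: fixed annual progression vs death
    for src, p_prog, dest in ((L.md, pre.p_md_sd, L.sd),
                              (L.sd, pre.p_sd_u1, L.u1)):
        (pp, pd_), stay = _compete(np.array([p_prog, q]))
        new[dest] += occ[src] * pp
        deaths += occ[src] * pd_
        new[src] += occ[src] * stay

    # undetected TNM stages: progression vs detection vs background death
    for s in range(4):
        src = L.u1 + s
        (pp, pdet, pd_), stay = _compete(
            np.array([pre.p_stage[s], pre.p_det[s], q]))
        if s < 3:
            new[src + 1] += occ[src] * pp
        new[L.d1 + s] += occ[src] * pdet
        det_new[s] += occ[src] * pdet
        deaths += occ[src] * pd_
        new[src] += occ[src] * stay

    # detected TNM stages: excess mortality composed with background
    for s in range(4):
        src = L.d1 + s
        p_die = 1.0 - (1.0 - q) * (1.0 - pre.p_excess[s])
        deaths += occ[src] * p_die
        new[src] += occ[src] * (1.0 - p_die)

    new[L.death] += occ[L.death] + deaths
    return new, det_new, deaths


def run_cohort(params: ModelParameters, life_table: LifeTable,
               start_age: int = 15, end_age: int = 100,
               onset_multiplier: float = 1.0,
               init_occupancy: np.ndarray | None = None,
               layout: CompartmentLayout | None = None) -> CohortTrajectory:
    """Propagate a cohort from ``start_age`` to ``end_age``.

    By default the cohort starts fully in the normal state; screening
    scenarios pass modified initial occupancies via ``init_occupancy``
    (which must match ``layout``). ``onset_multiplier`` scales the onset
    hazard only (regional risk adjustment).
    """
    if layout is None:
        layout = CompartmentLayout(start_age, end_age)
    elif (start_age < layout.start_age or end_age > layout.end_age):
        raise DomainError("ages outside the layout's range")
    pre = _Precomputed(params, life_table, layout, onset_multiplier)
    n = end_age - start_age
    occ = np.zeros((n + 1, layout.n_compartments))
    if init_occupancy is None:
        occ[0, layout.normal] = 1.0
    else:
        init_occupancy = np.asarray(init_occupancy, dtype=float)
        if init_occupancy.shape != (layout.n_compartments,):
            raise ValidationError("init_occupancy does not match layout")
        occ[0] = init_occupancy
    mass = occ[0].sum()
    dets = np.zeros((n, 4))
    deaths = np.zeros(n)
    offset = start_age - layout.start_age
    for t in range(n):
        occ[t + 1], dets[t], deaths[t] = _step(occ[t], offset + t, pre, layout)
        if abs(occ[t + 1].sum() - mass) > CONSERVATION_TOL:
            raise ConservationError(
                f"occupancy mass drifted at cycle {t}: "
                f"{occ[t + 1].sum():.12f} != {mass:.12f}")
    return CohortTrajectory(layout=layout, start_age=start_age, occupancy=occ,
                            new_detections=dets, deaths=deaths)


def build_transition_row(state: HealthState, age: int, duration_index: int,
                         params: ModelParameters, life_table: LifeTable,
                         onset_multiplier: float = 1.0,
                         layout: CompartmentLayout | None = None
                         ) -> dict[tuple[HealthState, int], float]:
    """One row of the annual transition matrix, as a destination map.

    Keys are (state, duration) compartments; values sum to 1. Provided for
    inspection and testing; the engine computes the same flows vectorized.
    """
    if layout is None:
        layout = CompartmentLayout()
    if not layout.start_age <= age < layout.end_age:
        raise DomainError(f"age {age} outside [{layout.start_age}, "
                          f"{layout.end_age})")
    q = life_table[age]
    row: dict[tuple[HealthState, int], float] = {}

    def put(state_to: HealthState, dur: int, p: float) -> None:
        if p < 0 or p > 1:
            raise ValidationError(f"invalid probability {p} toward "
                                  f"{state_to.value} from {state.value}")
        if p > 0:
            row[(state_to, dur)] = row.get((state_to, dur), 0.0) + p

    if state is HealthState.DEATH:
        put(HealthState.DEATH, 0, 1.0)
        return row
    if state is HealthState.NORMAL:
        lam = onset_multiplier * onset_hazard(float(age), params.onset)
        (p_on, p_d), stay = _compete(np.array([rate_to_prob(lam), q]))
        put(HealthState.BCH_MD, 0, p_on)
        put(HealthState.DEATH, 0, p_d)
        put(HealthState.NORMAL, 0, stay)
    elif state is HealthState.BCH_MD:
        lam = bchmd_progression_hazard(float(duration_index), params.bchmd_to_md)
        (p_p, p_d), stay = _compete(np.array([rate_to_prob(lam), q]))
        put(HealthState.MD, 0, p_p)
        put(HealthState.DEATH, 0, p_d)
        nxt = min(duration_index + 1, layout.n_tunnels - 1)
        put(HealthState.BCH_MD, nxt, stay)
    elif state in (HealthState.MD, HealthState.SD):
        p_prog = params.annual_prob(
            "p_md_to_sd" if state is HealthState.MD else "p_sd_to_u1")
        dest = HealthState.SD if state is HealthState.MD else HealthState.U1
        (p_p, p_d), stay = _compete(np.array([p_prog, q]))
        put(dest, 0, p_p)
        put(HealthState.DEATH, 0, p_d)
        put(state, 0, stay)
    elif state in UNDETECTED:
        s = UNDETECTED.index(state)
        (p_p, p_det, p_d), stay = _compete(np.array(
            [params.stage_progression_probs[s], params.detection_probs[s], q]))
        if s < 3:
            put(UNDETECTED[s + 1], 0, p_p)
        put(DETECTED[s], 0, p_det)
        put(HealthState.DEATH, 0, p_d)
        put(state, 0, stay)
    else:  # detected
        s = DETECTED.index(state)
        p_die = 1.0 - (1.0 - q) * (1.0 - params.excess_mortality_probs[s])
        put(HealthState.DEATH, 0, p_die)
        put(state, 0, 1.0 - p_die)
    return row


# -- epidemiological outputs -------------------------------------------------

def prevalence(traj: CohortTrajectory, states: Iterable[HealthState],
               age_lo: int, age_hi: int) -> float:
    """Survivor-weighted prevalence of ``states`` over ages [age_lo, age_hi].

    Occupancy of the states summed over every exact age in the range,
    divided by the alive occupancy summed likewise.
    """
    states = list(states)
    if not states:
        raise ValidationError("states must be non-empty")
    rows = slice(traj.age_row(age_lo), traj.age_row(age_hi) + 1)
    idx = [i for s in states for i in traj.layout.indices(s)]
    alive = traj.occupancy[rows, :traj.layout.death].sum()
    if alive <= 0:
        raise UndefinedResultError("no survivors in the age range")
    return float(traj.occupancy[rows][:, idx].sum() / alive)


def incidence(traj: CohortTrajectory, age_lo: int, age_hi: int) -> float:
    """Clinical detections per 100,000 person-years over [age_lo, age_hi]."""
    lo, hi = traj.age_row(age_lo), traj.age_row(age_hi)
    if hi >= traj.new_detections.shape[0]:
        raise DomainError("age range extends past the last simulated cycle")
    person_years = traj.occupancy[lo:hi + 1, :traj.layout.death].sum()
    if person_years <= 0:
        raise UndefinedResultError("no person-years in the age range")
    events = traj.new_detections[lo:hi + 1].sum()
    return float(events / person_years * 1e5)


def stage_distribution(traj: CohortTrajectory, age_lo: int, age_hi: int
                       ) -> np.ndarray:
    """Share of new detections by TNM stage, accumulated over the age range."""
    lo, hi = traj.age_row(age_lo), traj.age_row(age_hi)
    if hi >= traj.new_detections.shape[0]:
        raise DomainError("age range extends past the last simulated cycle")
    by_stage = traj.new_detections[lo:hi + 1].sum(axis=0)
    total = by_stage.sum()
    if total <= 0:
        raise UndefinedResultError("no detections in the age range")
    return by_stage / total
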