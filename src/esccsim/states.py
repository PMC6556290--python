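"""Health states and the compartment layout of the cohort model.

The disease process is an ordered, no-regression sequence

    NORMAL -> BCH/mD -> MD -> SD -> undetected TNM I..IV -> detected TNM I..IV

with DEATH absorbing. BCH/mD (basal cell hyperplasia merged with mild
dysplasia) is the only state whose exit hazard depends on time-in-state, so
it is expanded into annual duration "tunnel" compartments; every other state
is memoryless and occupies a single compartment.
"""
from __future__ import annotations

import enum


class HealthState(enum.Enum):
    NORMAL = "normal"
    BCH_MD = "bch_md"  # basal cell hyperplasia / mild dysplasia
    MD = "md"          # moderate dysplasia
    SD = "sd"          # severe dysplasia
    U1 = "u1"          # undetected ESCC, TNM stage I
    U2 = "u2"
    U3 = "u3"
    U4 = "u4"
    D1 = "d1"          # clinically detected ESCC, TNM stage I
    D2 = "d2"
    D3 = "d3"
    D4 = "d4"
    DEATH = "death"


UNDETECTED = (HealthState.U1, HealthState.U2, HealthState.U3, HealthState.U4)
DETECTED = (HealthState.D1, HealthState.D2, HealthState.D3, HealthState.D4)
PRECANCER = (HealthState.BCH_MD, HealthState.MD, HealthState.SD)
ALIVE = tuple(s for s in HealthState if s is not HealthState.DEATH)


class CompartmentLayout:
    """Index map from (state, duration) compartments to a flat vector.

    Order: NORMAL, BCH/mD tunnels (duration 0 .. n_tunnels-1), MD, SD,
    U1-U4, D1-D4, DEATH. The number of tunnels equals the number of annual
    cycles, so no duration is ever truncated.
    """

    def __init__(self, start_age: int = 15, end_age: int = 100) -> None:
        if not start_age < end_age:
            raise ValueError("start_age must be below end_age")
        self.start_age = int(start_age)
        self.end_age = int(end_age)
        self.n_cycles = self.end_age - self.start_age
        self.n_tunnels = self.n_cycles
        self.normal = 0
        self.tunnel0 = 1
        self.md = self.tunnel0 + self.n_tunnels
        self.sd = self.md + 1
        self.u1 = self.sd + 1
        self.d1 = self.u1 + 4
        self.death = self.d1 + 4
        self.n_compartments = self.death + 1

    def index(self, state: HealthState, duration: int = 0) -> int:
        """Flat index of a (state, duration) compartment."""
        if state is HealthState.BCH_MD:
            if not 0 <= duration < self.n_tunnels:
                raise IndexError(f"duration {duration} outside tunnel range")
            return self.tunnel0 + duration
        simple = {
            HealthState.NORMAL: self.normal,
            HealthState.MD: self.md,
            HealthState.SD: self.sd,
            HealthState.DEATH: self.death,
        }
        if state in simple:
            return simple[state]
        if state in UNDETECTED:
            return self.u1 + UNDETECTED.index(state)
        return self.d1 + DETECTED.index(state)

    def indices(self, state: HealthState) -> list[int]:
        """All flat indices belonging to one health state."""
        if state is HealthState.BCH_MD:
            return list(range(self.tunnel0, self.tunnel0 + self.n_tunnels))
        return [self.index(state)]

    def state_of(self, index: int) -> tuple[HealthState, int]:
        """Inverse of :meth:`index`: (state, duration) of a flat index."""
        if index == self.normal:
            return HealthState.NORMAL, 0
        if self.tunnel0 <= index < self.tunnel0 + self.n_tunnels:
            return HealthState.BCH_MD, index - self.tunnel0
        for state in (HealthState.MD, HealthState.SD, *UNDETECTED, *DETECTED,
                      HealthState.DEATH):
            if index == self.index(state):
                return state, 0
        raise IndexError(index)
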