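"""Broadcast-media fear spread: siting, position dynamics, influence.

A media outlet ("broadcaster") is sited in every community that employs
at least one publishing/broadcasting worker; all such workers in the
community are its employees.  Each broadcaster reaches every agent in
its census tract and takes one of three positions:

* ``NEUTRAL`` - before activation, and while case counts remain high;
  influences nobody.
* ``FEAR`` - entered when the fearful fraction of its employees first
  reaches ``p_bc_start``; the tract-wide per-capita new-infection rate
  at that moment is recorded once as the baseline ``E_dot_0``.
* ``COUNTER`` - entered when the current rate ``E_dot_t`` falls below
  ``p_bc_counter * E_dot_0``.

After activation the position is a pure threshold function of
``E_dot_t``: below ``p_bc_counter * E_dot_0`` the broadcaster counters
fear, between that and ``p_bc_neutral * E_dot_0`` it is neutral, and
above it spreads fear.  A broadcaster never de-activates and its
baseline is never re-recorded.

Each non-neutral broadcaster influences every mismatched agent in its
tract independently with probability ``p_bc`` per day (a FEAR
broadcast targets neutral agents, a COUNTER broadcast fearful ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List

import numpy as np

from fearcast.synthetic_population import OCC_MEDIA, Population

__all__ = [
    "Position",
    "BroadcastParams",
    "Broadcaster",
    "site_broadcasters",
    "update_position",
    "influence",
    "tract_flip_probabilities",
]


class Position(str, Enum):
    FEAR = "fear"
    NEUTRAL = "neutral"
    COUNTER = "counter"


@dataclass(frozen=True)
class BroadcastParams:
    """Thresholds of the broadcaster state machine.

    ``p_bc_start`` is the fearful-employee fraction that activates a
    broadcaster; ``p_bc_counter < p_bc_neutral`` are the multiples of
    the recorded baseline infection rate below which it counters fear
    or goes quiet; ``p_bc`` is the per-day influence probability on
    each tract resident.
    """

    p_bc_start: float = 0.25
    p_bc_counter: float = 0.25
    p_bc_neutral: float = 0.75
    p_bc: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bc_start <= 1.0:
            raise ValueError("p_bc_start must lie in [0, 1]")
        if not 0.0 <= self.p_bc <= 1.0:
            raise ValueError("p_bc must lie in [0, 1]")
        if self.p_bc_counter <= 0 or self.p_bc_neutral <= 0:
            raise ValueError("position thresholds must be positive")
        if not self.p_bc_counter < self.p_bc_neutral:
            raise ValueError("p_bc_counter must be smaller than p_bc_neutral")


@dataclass
class Broadcaster:
    id: int
    community_id: int
    tract_id: int
    employee_ids: np.ndarray
    position: Position = Position.NEUTRAL
    activated: bool = False
    E_dot_0: float | None = None


def site_broadcasters(pop: Population) -> List[Broadcaster]:
    """One broadcaster per community employing at least one media worker."""
    media = np.flatnonzero(pop.occupation == OCC_MEDIA)
    bcs: List[Broadcaster] = []
    if len(media) == 0:
        return bcs
    venues = pop.day_venue[media]
    for i, c in enumerate(np.unique(venues)):
        bcs.append(
            Broadcaster(
                id=i,
                community_id=int(c),
                tract_id=int(pop.community_tract[c]),
                employee_ids=media[venues == c],
            )
        )
    return bcs


def update_position(
    bc: Broadcaster,
    fearful_employee_frac: float,
    E_dot_t: float,
    params: BroadcastParams,
) -> Broadcaster:
    """Advance one broadcaster's position given today's observations.

    Mutates and returns ``bc``.  Before activation the broadcaster
    stays neutral until its employees are sufficiently fearful; the
    activation day's infection rate becomes the permanent baseline.
    """
    if E_dot_t < 0:
        raise ValueError("E_dot_t must be non-negative")
    if not bc.activated:
        if fearful_employee_frac >= params.p_bc_start:
            bc.activated = True
            bc.E_dot_0 = float(E_dot_t)
            bc.position = Position.FEAR
        return bc
    base = bc.E_dot_0
    if E_dot_t < params.p_bc_counter * base:
        bc.position = Position.COUNTER
    elif E_dot_t < params.p_bc_neutral * base:
        bc.position = Position.NEUTRAL
    else:
        bc.position = Position.FEAR
    return bc


def influence(
    bc: Broadcaster,
    audience_fearful: np.ndarray,
    p_bc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one broadcaster's influence to its audience.

    ``audience_fearful`` is the boolean fear state of every agent in
    the broadcaster's tract; returns the updated array (a copy).  A
    FEAR broadcast flips each neutral agent with probability ``p_bc``,
    a COUNTER broadcast flips each fearful agent; NEUTRAL is inert.
    """
    out = audience_fearful.copy()
    if bc.position is Position.NEUTRAL:
        return out
    if bc.position is Position.FEAR:
        targets = ~out
    else:
        targets = out
    flips = targets & (rng.random(len(out)) < p_bc)
    out[flips] = ~out[flips]
    return out


def tract_flip_probabilities(
    bcs: List[Broadcaster], n_tracts: int, p_bc: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tract daily flip probabilities from all broadcasters at once.

    With ``k`` independent FEAR broadcasters in a tract, a neutral
    resident flips with probability ``1 - (1 - p_bc)^k`` (and likewise
    for COUNTER broadcasters and fearful residents).  Equivalent in law
    to applying :func:`influence` broadcaster-by-broadcaster in any
    order, which is how the engine exploits it.
    """
    n_fear = np.zeros(n_tracts, dtype=np.int64)
    n_counter = np.zeros(n_tracts, dtype=np.int64)
    for bc in bcs:
        if bc.position is Position.FEAR:
            n_fear[bc.tract_id] += 1
        elif bc.position is Position.COUNTER:
            n_counter[bc.tract_id] += 1
    p_to_fear = 1.0 - (1.0 - p_bc) ** n_fear
    p_to_calm = 1.0 - (1.0 - p_bc) ** n_counter
    return p_to_fear, p_to_calm
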