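"""Scaled-down synthetic population for the coupled-contagion simulator.

Generates a desk-scale population with the structural features the
agent-based engine relies on: agents live in households, households are
grouped into communities, communities into census tracts.  Workers
commute to a day venue (their own or another community), students
attend school in their home community, and a configurable fraction of
workers hold publishing/broadcasting occupations, which downstream
modules use to site media outlets.  Mobility is abstracted to two
scalars: the fraction of workers whose day venue is outside their home
community, and a per-day probability of starting a long-distance trip.

The generator is fully deterministic given ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "OCC_NONE",
    "OCC_MEDIA",
    "OCC_OTHER",
    "PopulationSpec",
    "Population",
    "generate",
    "seed_infections",
]

# occupation codes
OCC_NONE = 0   # not employed (includes students and others)
OCC_MEDIA = 1  # publishing / broadcasting worker
OCC_OTHER = 2  # any other employment

# role codes (day-venue behaviour)
ROLE_HOME = 0
ROLE_WORKER = 1
ROLE_STUDENT = 2


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the synthetic population.

    Defaults give the desk-scale reference population: 1e5 agents in
    roughly 200 communities across 20 tracts, mean household size 2.5,
    half the population employed, a fifth in school, and 0.5% of
    workers in publishing/broadcasting.
    """

    n_agents: int = 100_000
    mean_household_size: float = 2.5
    households_per_community: int = 200
    communities_per_tract: int = 10
    employment_fraction: float = 0.50
    school_fraction: float = 0.20
    media_occupation_frac: float = 0.005
    commute_out_frac: float = 0.30
    travel_prob_per_day: float = 0.0005
    travel_duration_days: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 100:
            raise ValueError("n_agents must be at least 100")
        if self.mean_household_size < 1.0:
            raise ValueError("mean_household_size must be >= 1")
        if self.households_per_community < 1 or self.communities_per_tract < 1:
            raise ValueError("community structure parameters must be positive")
        if self.employment_fraction + self.school_fraction > 1.0 + 1e-9:
            raise ValueError("employment_fraction + school_fraction must not exceed 1")
        for name in (
            "employment_fraction",
            "school_fraction",
            "media_occupation_frac",
            "commute_out_frac",
            "travel_prob_per_day",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.travel_duration_days < 1:
            raise ValueError("travel_duration_days must be >= 1")


@dataclass
class Population:
    """Generated population, stored as flat per-agent arrays.

    ``day_venue`` is the community where the agent spends the day phase
    (equal to ``home_community`` for students and non-workers who stay
    local); ``tract`` indexes the census tract of the home community.
    """

    spec: PopulationSpec
    household_id: np.ndarray
    home_community: np.ndarray
    day_venue: np.ndarray
    tract: np.ndarray
    role: np.ndarray
    occupation: np.ndarray
    n_communities: int
    n_tracts: int
    community_tract: np.ndarray  # tract of each community

    @property
    def n_agents(self) -> int:
        return len(self.household_id)

    def agents_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent_id": np.arange(self.n_agents),
                "household_id": self.household_id,
                "home_community": self.home_community,
                "day_venue": self.day_venue,
                "tract": self.tract,
                "role": self.role,
                "occupation": self.occupation,
            }
        )

    def communities_frame(self) -> pd.DataFrame:
        residents = np.bincount(self.home_community, minlength=self.n_communities)
        venue = np.bincount(self.day_venue, minlength=self.n_communities)
        return pd.DataFrame(
            {
                "community_id": np.arange(self.n_communities),
                "tract": self.community_tract,
                "n_residents": residents,
                "n_day_venue": venue,
            }
        )

    def metadata(self) -> Dict:
        return {
            "spec": asdict(self.spec),
            "n_agents": int(self.n_agents),
            "n_communities": int(self.n_communities),
            "n_tracts": int(self.n_tracts),
            "n_media_workers": int((self.occupation == OCC_MEDIA).sum()),
        }


def _truncated_poisson_lambda(target_mean: float) -> float:
    """Rate of a zero-truncated Poisson with the requested mean."""
    if target_mean <= 1.0 + 1e-9:
        return 1e-9
    return brentq(
        lambda lam: lam / (1.0 - np.exp(-lam)) - target_mean, 1e-9, 4 * target_mean
    )


def generate(spec: PopulationSpec) -> Population:
    """Generate a population deterministically from its spec.

    Household sizes follow a zero-truncated Poisson whose mean equals
    ``mean_household_size``; households fill communities in blocks of
    ``households_per_community``, communities fill tracts likewise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_agents
    lam = _truncated_poisson_lambda(spec.mean_household_size)

    # draw enough households to cover n agents
    est = int(n / max(spec.mean_household_size, 1.0) * 1.2) + 50
    sizes: List[np.ndarray] = []
    total = 0
    while total < n:
        draw = rng.poisson(lam, est)
        draw = draw[draw > 0]
        sizes.append(draw)
        total += int(draw.sum())
    hh_sizes = np.concatenate(sizes)
    cum = np.cumsum(hh_sizes)
    n_hh = int(np.searchsorted(cum, n)) + 1
    hh_sizes = hh_sizes[:n_hh]
    hh_sizes[-1] -= int(cum[n_hh - 1] - n)  # trim the last household to fit
    if hh_sizes[-1] == 0:
        hh_sizes = hh_sizes[:-1]
        n_hh -= 1

    household_id = np.repeat(np.arange(n_hh), hh_sizes)
    n_communities = int(np.ceil(n_hh / spec.households_per_community))
    hh_community = np.arange(n_hh) // spec.households_per_community
    home_community = hh_community[household_id]
    n_tracts = int(np.ceil(n_communities / spec.communities_per_tract))
    community_tract = np.arange(n_communities) // spec.communities_per_tract
    tract = community_tract[home_community]

    # roles: worker / student / home
    u = rng.random(n)
    role = np.full(n, ROLE_HOME, dtype=np.int8)
    role[u < spec.employment_fraction] = ROLE_WORKER
    role[
        (u >= spec.employment_fraction)
        & (u < spec.employment_fraction + spec.school_fraction)
    ] = ROLE_STUDENT

    # day venues: students study at home community; workers commute out
    # with probability commute_out_frac to a uniformly random other
    # community
    day_venue = home_community.copy()
    workers = np.flatnonzero(role == ROLE_WORKER)
    out = workers[rng.random(len(workers)) < spec.commute_out_frac]
    if n_communities > 1 and len(out):
        shift = rng.integers(1, n_communities, len(out))
        day_venue[out] = (home_community[out] + shift) % n_communities

    occupation = np.full(n, OCC_NONE, dtype=np.int8)
    occupation[workers] = OCC_OTHER
    media = workers[rng.random(len(workers)) < spec.media_occupation_frac]
    occupation[media] = OCC_MEDIA

    return Population(
        spec=spec,
        household_id=household_id,
        home_community=home_community,
        day_venue=day_venue,
        tract=tract,
        role=role,
        occupation=occupation,
        n_communities=n_communities,
        n_tracts=n_tracts,
        community_tract=community_tract,
    )


def seed_infections(
    pop: Population,
    frac_per_day: float,
    n_days: int,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Draw the index-case schedule: one array of agent ids per day.

    On each of the first ``n_days`` days, ``round(frac_per_day *
    n_agents)`` distinct agents are selected uniformly at random
    (without replacement across days), which makes the expected seeded
    count per community proportional to community size.
    """
    if not 0.0 <= frac_per_day < 1.0:
        raise ValueError("frac_per_day must lie in [0, 1)")
    if n_days < 0:
        raise ValueError("n_days must be non-negative")
    per_day = int(round(frac_per_day * pop.n_agents))
    total = per_day * n_days
    if total > pop.n_agents:
        raise ValueError(
            f"seeding schedule needs {total} agents but population has {pop.n_agents}"
        )
    if total == 0:
        return [np.empty(0, dtype=np.int64) for _ in range(n_days)]
    chosen = rng.choice(pop.n_agents, size=total, replace=False)
    return [chosen[d * per_day : (d + 1) * per_day] for d in range(n_days)]
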