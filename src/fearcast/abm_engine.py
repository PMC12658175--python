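"""Agent-based coupled fear-disease dynamics, advanced one day at a time.

Disease states follow S -> E -> P -> {Is | Ia} -> {Rs | Ra}; every agent
additionally carries a binary fear state.  Each day has a day phase
(workplace/school venues plus ambient community contact for those not
at a venue) and a night phase (household plus ambient community
contact).  Contacts drive three processes on the same structure:

* disease transmission from P/Is/Ia to S, scaled by relative
  infectivity and - when the protective-behaviour toggle is on - by
  ``sigma_f`` for fearful susceptibles;
* local fear contagion: symptomatic and fearful agents convert neutral
  contacts with probability ``p_contact_fear`` per contact;
* local calming: knowingly-recovered neutral agents (``<Rs, N>``)
  convert fearful contacts with probability ``p_contact_calm``.

Contact law.  Within a household the engine uses complete mixing: a
target meets every housemate once per night.  In every other layer each
present agent draws ``degree`` partners uniformly (with replacement)
from the group present there; because the draws are independent, the
per-target outcome is Bernoulli with ``1 - (1 - w * h)^degree`` where
``h`` is the group's per-member source weight.  The engine evaluates
that closed form directly - one random number per agent and process -
which is equivalent in law to enumerating the sampled contacts.

Behaviour.  Hospitalised symptomatic agents withdraw for their whole
symptomatic period regardless of fear; symptomatic-and-fearful agents
withdraw while that holds (toggle ``withdraw_sick``); other fearful
agents withdraw with probability ``p_fear`` per day for ``t_with`` days
(toggle ``withdraw_fear``).  A withdrawn agent contacts only its
household and aborts any long-distance travel.  All updates within a
day are evaluated against the morning snapshot of states, so results do
not depend on agent iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from fearcast.broadcast_media import (
    BroadcastParams,
    Broadcaster,
    Position,
    site_broadcasters,
    tract_flip_probabilities,
    update_position,
)
from fearcast.synthetic_population import (
    ROLE_HOME,
    ROLE_STUDENT,
    ROLE_WORKER,
    Population,
)
from fearcast.wave_metrics import DailySeries

__all__ = [
    "S", "E", "P", "IS", "IA", "RS", "RA",
    "DiseaseParams",
    "FearParams",
    "SimState",
    "init_state",
    "step_day",
    "run_simulation",
    "transmission_probability",
    "sample_dwell",
]

# disease-state codes
S, E, P, IS, IA, RS, RA = 0, 1, 2, 3, 4, 5, 6
STATE_NAMES = ("S", "E", "P", "Is", "Ia", "Rs", "Ra")

_ALLOWED_TRANSITIONS = {(S, E), (E, P), (P, IS), (P, IA), (IS, RS), (IA, RA)}


@dataclass(frozen=True)
class DiseaseParams:
    """Transmission and progression parameters of the agent model.

    Contact weights are per-contact transmission probabilities for a
    fully infectious (``Is``) source; dwell means are in days and the
    realised dwell times are geometric (memoryless daily progression,
    minimum one day).
    """

    w_household: float = 0.10
    w_workplace: float = 0.03
    w_community: float = 0.008
    degree_workplace: int = 8
    degree_community: int = 8
    rel_inf_presym: float = 0.65
    rel_inf_sym: float = 1.0
    rel_inf_asym: float = 0.65
    dwell_E: float = 3.0
    dwell_P: float = 2.0
    dwell_I: float = 6.0
    p_sym: float = 0.60
    p_hosp: float = 0.05

    def __post_init__(self) -> None:
        for name in ("w_household", "w_workplace", "w_community"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("p_sym", "p_hosp"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("dwell_E", "dwell_P", "dwell_I"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 day")
        if self.degree_workplace < 0 or self.degree_community < 0:
            raise ValueError("contact degrees must be non-negative")


@dataclass(frozen=True)
class FearParams:
    """Fear contagion and behavioural-response parameters.

    Toggles mirror the scenario design: hospital withdrawal, sick
    (symptomatic-and-fearful) withdrawal, pure-fear withdrawal, and the
    protective susceptibility reduction for fearful susceptibles.
    """

    p_contact_fear: float = 0.04
    p_contact_calm: float = 0.45
    sigma_f: float = 0.15
    p_fear: float = 0.10
    t_with: int = 28
    withdraw_hosp: bool = True
    withdraw_sick: bool = True
    withdraw_fear: bool = False
    reduced_sus: bool = False
    fear_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("p_contact_fear", "p_contact_calm", "sigma_f", "p_fear"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.t_with < 1:
            raise ValueError("t_with must be at least 1 day")


@dataclass
class SimState:
    """Mutable per-run simulation state (flat arrays over agents)."""

    pop: Population
    disease_params: DiseaseParams
    fear_params: FearParams
    bc_params: Optional[BroadcastParams]
    rng: np.random.Generator
    day: int
    disease: np.ndarray          # int8 state codes
    fearful: np.ndarray          # bool
    timer: np.ndarray            # int32, days left in E/P/I states
    hospitalized: np.ndarray     # bool, set at Is onset
    withdrawn_until: np.ndarray  # int32, exclusive day bound; 0 = never
    travel_until: np.ndarray     # int32, exclusive day bound; 0 = not traveling
    travel_dest: np.ndarray      # int32 community id, -1 when home
    broadcasters: List[Broadcaster] = field(default_factory=list)
    log_events: bool = False
    events: List[Tuple[int, int, str, str, str]] = field(default_factory=list)
    presence_log: List[Tuple[int, int, str]] = field(default_factory=list)
    last_withdrawn: Optional[np.ndarray] = None

    def n_agents(self) -> int:
        return len(self.disease)

    def withdrawn_today(self) -> np.ndarray:
        """Agents restricted to household contact today."""
        fp = self.fear_params
        w = self.day < self.withdrawn_until
        if fp.withdraw_hosp:
            w = w | (self.hospitalized & (self.disease == IS))
        if fp.withdraw_sick:
            w = w | ((self.disease == IS) & self.fearful)
        return w

    def _log(self, agents: np.ndarray, frm: str, to: str, cause: str) -> None:
        if self.log_events:
            for a in agents:
                self.events.append((self.day, int(a), frm, to, cause))


def sample_dwell(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Geometric dwell times (days, >= 1) with the given mean."""
    return rng.geometric(1.0 / mean, size).astype(np.int32)


def transmission_probability(
    source_state: int,
    target_fearful: bool,
    layer_weight: float,
    dp: DiseaseParams,
    fp: FearParams,
) -> float:
    """Per-contact infection probability for one infectious-susceptible pair."""
    rel = {P: dp.rel_inf_presym, IS: dp.rel_inf_sym, IA: dp.rel_inf_asym}
    if source_state not in rel:
        raise ValueError("source must be an infectious state (P, Is, Ia)")
    p = layer_weight * rel[source_state]
    if target_fearful and fp.reduced_sus:
        p *= fp.sigma_f
    return p


def init_state(
    pop: Population,
    disease_params: DiseaseParams,
    fear_params: FearParams,
    bc_params: Optional[BroadcastParams],
    rng: np.random.Generator,
    log_events: bool = False,
) -> SimState:
    n = pop.n_agents
    broadcasters = site_broadcasters(pop) if bc_params is not None else []
    if bc_params is not None and not broadcasters:
        raise ValueError(
            "broadcasters enabled but the population has no media workers"
        )
    return SimState(
        pop=pop,
        disease_params=disease_params,
        fear_params=fear_params,
        bc_params=bc_params,
        rng=rng,
        day=0,
        disease=np.zeros(n, dtype=np.int8),
        fearful=np.zeros(n, dtype=bool),
        timer=np.zeros(n, dtype=np.int32),
        hospitalized=np.zeros(n, dtype=bool),
        withdrawn_until=np.zeros(n, dtype=np.int32),
        travel_until=np.zeros(n, dtype=np.int32),
        travel_dest=np.full(n, -1, dtype=np.int32),
        broadcasters=broadcasters,
        log_events=log_events,
    )


def _rel_inf_vector(dp: DiseaseParams) -> np.ndarray:
    rel = np.zeros(7)
    rel[P], rel[IS], rel[IA] = dp.rel_inf_presym, dp.rel_inf_sym, dp.rel_inf_asym
    return rel


def _accumulate_group_layer(
    grp: np.ndarray,
    present: np.ndarray,
    weight: float,
    degree: int,
    state: SimState,
    rel: np.ndarray,
    sus_mask: np.ndarray,
    spreader: np.ndarray,
    calmer: np.ndarray,
    log_inf: np.ndarray,
    log_fear: np.ndarray,
    log_calm: np.ndarray,
    n_groups: int,
    layer_name: str,
) -> None:
    """Add one sampled-partner layer's log survival to the accumulators.

    ``grp`` maps agents to group ids (only where ``present``).  For a
    present target, each of ``degree`` partner draws lands on an
    infectious / fear-spreading / calming member with the group's
    source fraction, excluding the target itself from its own sources.
    """
    if degree == 0 or weight == 0.0:
        return
    idx = np.flatnonzero(present)
    if len(idx) == 0:
        return
    g = grp[idx]
    size = np.bincount(g, minlength=n_groups).astype(float)
    inf_w = np.bincount(g, weights=rel[state.disease[idx]], minlength=n_groups)
    n_spread = np.bincount(g, weights=spreader[idx].astype(float), minlength=n_groups)
    n_calm = np.bincount(g, weights=calmer[idx].astype(float), minlength=n_groups)
    if state.log_events:
        for a in idx:
            state.presence_log.append((state.day, int(a), layer_name))

    sz = size[g]
    # disease: targets are present susceptibles
    t = idx[sus_mask[idx]]
    if len(t):
        h = inf_w[grp[t]] / sz[sus_mask[idx]]
        fearful_t = state.fearful[t] & state.fear_params.reduced_sus
        sig = np.where(fearful_t, state.fear_params.sigma_f, 1.0)
        log_inf[t] += degree * np.log1p(-np.clip(weight * sig * h, 0.0, 1.0 - 1e-12))
    fp = state.fear_params
    if fp.fear_enabled:
        # fear: neutral targets; exclude self from the spreader count
        t = idx[~state.fearful[idx]]
        if len(t) and fp.p_contact_fear > 0:
            own = spreader[t].astype(float)
            frac = (n_spread[grp[t]] - own) / sz[~state.fearful[idx]]
            log_fear[t] += degree * np.log1p(
                -np.clip(fp.p_contact_fear * frac, 0.0, 1.0 - 1e-12)
            )
        # calming: fearful targets (calmers are neutral, never the target)
        t = idx[state.fearful[idx]]
        if len(t) and fp.p_contact_calm > 0:
            frac = n_calm[grp[t]] / sz[state.fearful[idx]]
            log_calm[t] += degree * np.log1p(
                -np.clip(fp.p_contact_calm * frac, 0.0, 1.0 - 1e-12)
            )


def _accumulate_household_layer(
    state: SimState,
    at_home: np.ndarray,
    rel: np.ndarray,
    spreader: np.ndarray,
    calmer: np.ndarray,
    log_inf: np.ndarray,
    log_fear: np.ndarray,
    log_calm: np.ndarray,
) -> None:
    """Complete-mixing household contacts (night phase)."""
    dp = state.disease_params
    fp = state.fear_params
    hh = state.pop.household_id
    n_hh = int(hh.max()) + 1
    idx = np.flatnonzero(at_home)
    g = hh[idx]
    w = dp.w_household
    # per-household sums of log(1 - w * rel) for neutral / fearful targets
    li = np.log1p(-np.clip(w * rel[state.disease[idx]], 0.0, 1.0 - 1e-12))
    sum_n = np.bincount(g, weights=li, minlength=n_hh)
    if fp.reduced_sus and fp.sigma_f != 1.0:
        lif = np.log1p(-np.clip(w * fp.sigma_f * rel[state.disease[idx]], 0.0, 1.0 - 1e-12))
        sum_f = np.bincount(g, weights=lif, minlength=n_hh)
    else:
        sum_f = sum_n
    sus = idx[state.disease[idx] == S]
    if len(sus):
        fearful_t = state.fearful[sus]
        log_inf[sus] += np.where(fearful_t, sum_f[hh[sus]], sum_n[hh[sus]])
        # susceptible targets contribute 0 to the sums themselves
    if fp.fear_enabled:
        n_spread = np.bincount(g, weights=spreader[idx].astype(float), minlength=n_hh)
        n_calm = np.bincount(g, weights=calmer[idx].astype(float), minlength=n_hh)
        tn = idx[~state.fearful[idx]]
        if len(tn) and fp.p_contact_fear > 0:
            cnt = n_spread[hh[tn]] - spreader[tn]
            log_fear[tn] += cnt * np.log1p(-min(fp.p_contact_fear, 1 - 1e-12))
        tf = idx[state.fearful[idx]]
        if len(tf) and fp.p_contact_calm > 0:
            cnt = n_calm[hh[tf]]
            log_calm[tf] += cnt * np.log1p(-min(fp.p_contact_calm, 1 - 1e-12))


def step_day(
    state: SimState, seeds_today: Optional[np.ndarray] = None
) -> Dict[str, float]:
    """Advance the simulation by one day; returns the day's tallies.

    Order within the day: (1) day-phase contacts, (2) night-phase
    contacts - both against the morning snapshot - then (3) broadcaster
    influence and position updates, (4) disease progression and new
    infections, (5) behaviour updates (withdrawal sampling and expiry,
    travel).  Seeds enter the exposed state and count as that day's new
    cases.
    """
    rng = state.rng
    pop = state.pop
    dp = state.disease_params
    fp = state.fear_params
    n = state.n_agents()
    rel = _rel_inf_vector(dp)

    withdrawn = state.withdrawn_today()
    state.last_withdrawn = withdrawn.copy()  # exposed for contact audits
    traveling = state.day < state.travel_until
    # withdrawal aborts travel immediately
    aborted = traveling & withdrawn
    state.travel_until[aborted] = 0
    state.travel_dest[aborted] = -1
    traveling = traveling & ~withdrawn

    spreader = (state.disease == IS) | state.fearful
    calmer = (state.disease == RS) & ~state.fearful
    sus_mask = state.disease == S

    log_inf = np.zeros(n)
    log_fear = np.zeros(n)
    log_calm = np.zeros(n)

    # --- day phase -----------------------------------------------------
    at_work = (
        ((pop.role == ROLE_WORKER) | (pop.role == ROLE_STUDENT))
        & ~withdrawn
        & ~traveling
    )
    _accumulate_group_layer(
        pop.day_venue, at_work, dp.w_workplace, dp.degree_workplace,
        state, rel, sus_mask, spreader, calmer,
        log_inf, log_fear, log_calm, pop.n_communities, "workplace",
    )
    day_comm = np.where(traveling, state.travel_dest, pop.home_community)
    ambient_day = ~withdrawn & (traveling | ~at_work)
    _accumulate_group_layer(
        day_comm, ambient_day, dp.w_community, dp.degree_community,
        state, rel, sus_mask, spreader, calmer,
        log_inf, log_fear, log_calm, pop.n_communities, "community_day",
    )

    # --- night phase ---------------------------------------------------
    at_home = ~traveling
    _accumulate_household_layer(
        state, at_home, rel, spreader, calmer, log_inf, log_fear, log_calm
    )
    night_comm = np.where(traveling, state.travel_dest, pop.home_community)
    ambient_night = ~withdrawn
    _accumulate_group_layer(
        night_comm, ambient_night, dp.w_community, dp.degree_community,
        state, rel, sus_mask, spreader, calmer,
        log_inf, log_fear, log_calm, pop.n_communities, "community_night",
    )

    # --- resolve contact outcomes (synchronous) ------------------------
    p_inf = -np.expm1(log_inf)
    new_inf = sus_mask & (rng.random(n) < p_inf)
    new_fear = ~state.fearful & (rng.random(n) < -np.expm1(log_fear))
    new_calm = state.fearful & (rng.random(n) < -np.expm1(log_calm))
    state._log(np.flatnonzero(new_fear), "N", "F", "contact")
    state._log(np.flatnonzero(new_calm), "F", "N", "contact")
    state.fearful[new_fear] = True
    state.fearful[new_calm] = False

    # --- broadcaster influence and update ------------------------------
    bc_fear_count = 0
    bc_counter_count = 0
    if state.bc_params is not None and state.broadcasters:
        bp = state.bc_params
        p_to_fear, p_to_calm = tract_flip_probabilities(
            state.broadcasters, pop.n_tracts, bp.p_bc
        )
        pt_f = p_to_fear[pop.tract]
        pt_c = p_to_calm[pop.tract]
        flips_f = ~state.fearful & (rng.random(n) < pt_f)
        flips_c = state.fearful & (rng.random(n) < pt_c)
        state._log(np.flatnonzero(flips_f), "N", "F", "broadcast")
        state._log(np.flatnonzero(flips_c), "F", "N", "broadcast")
        state.fearful[flips_f] = True
        state.fearful[flips_c] = False

    # --- disease progression (existing infections first) ---------------
    infected = (state.disease == E) | (state.disease == P) | \
               (state.disease == IS) | (state.disease == IA)
    state.timer[infected] -= 1
    due = infected & (state.timer <= 0)
    stage = state.disease.copy()  # stage snapshot: one transition per day

    e_done = np.flatnonzero(due & (stage == E))
    if len(e_done):
        state.disease[e_done] = P
        state.timer[e_done] = sample_dwell(dp.dwell_P, len(e_done), rng)
        state._log(e_done, "E", "P", "progression")
    p_done = np.flatnonzero(due & (stage == P))
    if len(p_done):
        sym = rng.random(len(p_done)) < dp.p_sym
        to_is = p_done[sym]
        to_ia = p_done[~sym]
        state.disease[to_is] = IS
        state.disease[to_ia] = IA
        state.timer[p_done] = sample_dwell(dp.dwell_I, len(p_done), rng)
        if fp.withdraw_hosp and len(to_is):
            state.hospitalized[to_is] = rng.random(len(to_is)) < dp.p_hosp
        state._log(to_is, "P", "Is", "progression")
        state._log(to_ia, "P", "Ia", "progression")
    i_done = np.flatnonzero(due & (stage == IS))
    if len(i_done):
        state.disease[i_done] = RS
        state.hospitalized[i_done] = False
        state._log(i_done, "Is", "Rs", "progression")
    a_done = np.flatnonzero(due & (stage == IA))
    if len(a_done):
        state.disease[a_done] = RA
        state._log(a_done, "Ia", "Ra", "progression")

    # --- new infections (transmission + seeds) -------------------------
    new_idx = np.flatnonzero(new_inf)
    state._log(new_idx, "S", "E", "transmission")
    if seeds_today is not None and len(seeds_today):
        seed_idx = seeds_today[state.disease[seeds_today] == S]
        state._log(seed_idx, "S", "E", "seed")
        new_idx = np.concatenate([new_idx, seed_idx])
    if len(new_idx):
        state.disease[new_idx] = E
        state.timer[new_idx] = sample_dwell(dp.dwell_E, len(new_idx), rng)

    # tract-level infection rate for broadcasters, then position update
    if state.bc_params is not None and state.broadcasters:
        tract_pop = np.bincount(pop.tract, minlength=pop.n_tracts).astype(float)
        tract_new = np.bincount(
            pop.tract[new_idx], minlength=pop.n_tracts
        ) if len(new_idx) else np.zeros(pop.n_tracts)
        e_dot = tract_new / tract_pop
        for bc in state.broadcasters:
            frac = float(state.fearful[bc.employee_ids].mean())
            update_position(bc, frac, float(e_dot[bc.tract_id]), state.bc_params)
        bc_fear_count = sum(
            1 for b in state.broadcasters if b.position is Position.FEAR
        )
        bc_counter_count = sum(
            1 for b in state.broadcasters if b.position is Position.COUNTER
        )

    # --- behaviour updates for the coming days --------------------------
    if fp.withdraw_fear and fp.p_fear > 0:
        eligible = (
            state.fearful
            & (state.disease != IS)
            & ~(state.day + 1 < state.withdrawn_until)
        )
        draw = eligible & (rng.random(n) < fp.p_fear)
        state.withdrawn_until[draw] = state.day + 1 + fp.t_with

    # travel: end expired trips, start new ones for mobile agents
    spec = pop.spec
    ended = (state.travel_until != 0) & (state.day + 1 >= state.travel_until)
    state.travel_until[ended] = 0
    state.travel_dest[ended] = -1
    if spec.travel_prob_per_day > 0 and pop.n_communities > 1:
        can_travel = (
            (state.travel_until == 0)
            & ~withdrawn
            & ~state.withdrawn_today()
        )
        start = can_travel & (rng.random(n) < spec.travel_prob_per_day)
        s_idx = np.flatnonzero(start)
        if len(s_idx):
            state.travel_until[s_idx] = state.day + 1 + spec.travel_duration_days
            shift = rng.integers(1, pop.n_communities, len(s_idx))
            state.travel_dest[s_idx] = (
                pop.home_community[s_idx] + shift
            ) % pop.n_communities

    state.day += 1
    return {
        "new_cases": float(len(new_idx)),
        "fearful": float(state.fearful.sum()),
        "bc_fear_count": bc_fear_count,
        "bc_counter_count": bc_counter_count,
    }


def run_simulation(
    pop: Population,
    disease_params: DiseaseParams,
    fear_params: FearParams,
    bc_params: Optional[BroadcastParams],
    horizon_days: int,
    seed_schedule: Sequence[np.ndarray],
    rng: np.random.Generator,
    log_events: bool = False,
) -> Tuple[DailySeries, SimState]:
    """Run a full scenario and collect its daily series.

    ``seed_schedule`` holds the index-case agent ids for the first
    days; ``new_cases_frac`` counts seeds and transmissions alike.
    """
    state = init_state(pop, disease_params, fear_params, bc_params, rng, log_events)
    n = pop.n_agents
    rows = {k: [] for k in ("new_cases_frac", "fearful_frac", "bc_fear_count", "bc_counter_count")}
    for day in range(horizon_days):
        seeds = seed_schedule[day] if day < len(seed_schedule) else None
        out = step_day(state, seeds)
        rows["new_cases_frac"].append(out["new_cases"] / n)
        rows["fearful_frac"].append(out["fearful"] / n)
        rows["bc_fear_count"].append(int(out["bc_fear_count"]))
        rows["bc_counter_count"].append(int(out["bc_counter_count"]))
    series = DailySeries(
        day=np.arange(horizon_days),
        new_cases_frac=np.array(rows["new_cases_frac"]),
        fearful_frac=np.array(rows["fearful_frac"]),
        bc_fear_count=np.array(rows["bc_fear_count"]),
        bc_counter_count=np.array(rows["bc_counter_count"]),
    )
    return series, state
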