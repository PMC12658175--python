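"""Agent-engine unit, frequency and audit tests."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from fearcast.abm_engine import (
    E, IA, IS, P, RA, RS, S,
    DiseaseParams,
    FearParams,
    init_state,
    run_simulation,
    sample_dwell,
    step_day,
    transmission_probability,
)
from fearcast.synthetic_population import (
    Population,
    PopulationSpec,
    generate,
    seed_infections,
)

from _oracles import naive_contact_epidemic

NO_FEAR = FearParams(fear_enabled=False, withdraw_hosp=False, withdraw_sick=False)


def build_pop(hh_sizes, n_communities=1):
    """Hand-built population: explicit household sizes, everyone home-bound."""
    n = int(sum(hh_sizes))
    household_id = np.repeat(np.arange(len(hh_sizes)), hh_sizes)
    comm = np.arange(len(hh_sizes)) % n_communities
    home = comm[household_id]
    spec = PopulationSpec(n_agents=max(100, n), travel_prob_per_day=0.0)
    return Population(
        spec=spec,
        household_id=household_id,
        home_community=home,
        day_venue=home.copy(),
        tract=np.zeros(n, dtype=int),
        role=np.zeros(n, dtype=np.int8),
        occupation=np.zeros(n, dtype=np.int8),
        n_communities=n_communities,
        n_tracts=1,
        community_tract=np.zeros(n_communities, dtype=int),
    )


class TestStepBasics:
    def test_quiescent_population_only_advances_clock(self, rng):
        pop = build_pop([4] * 50)
        st = init_state(pop, DiseaseParams(), FearParams(), None, rng)
        before_d = st.disease.copy()
        before_f = st.fearful.copy()
        step_day(st)
        assert st.day == 1
        assert np.array_equal(st.disease, before_d)
        assert np.array_equal(st.fearful, before_f)

    def test_certain_household_transmission_exposes_all_housemates(self, rng):
        pop = build_pop([10])
        dp = DiseaseParams(w_household=1.0, w_community=0.0, w_workplace=0.0)
        st = init_state(pop, dp, NO_FEAR, None, rng)
        st.disease[0] = IS
        st.timer[0] = 100
        step_day(st)
        assert (st.disease[1:] == E).all()

    def test_agent_count_conserved(self, small_pop, rng):
        sched = seed_infections(small_pop, 0.00265, 5, rng)
        series, st = run_simulation(
            small_pop, DiseaseParams(), FearParams(withdraw_fear=True), None,
            60, sched, rng,
        )
        assert st.n_agents() == small_pop.n_agents
        counts = np.bincount(st.disease, minlength=7)
        assert counts.sum() == small_pop.n_agents


class TestTransmission:
    def test_full_protection_blocks_fearful_targets(self, rng):
        pop = build_pop([2] * 500)
        dp = DiseaseParams(w_household=0.8, w_community=0.0, w_workplace=0.0)
        fp = FearParams(reduced_sus=True, sigma_f=0.0, p_contact_fear=0.0,
                        p_contact_calm=0.0, withdraw_hosp=False, withdraw_sick=False)
        st = init_state(pop, dp, fp, None, rng)
        sources = np.arange(0, 1000, 2)
        st.disease[sources] = IS
        st.timer[sources] = 100
        st.fearful[:] = True
        step_day(st)
        assert (st.disease[1::2] == S).all()

    def test_no_protection_equals_neutral_probability(self):
        dp, fp = DiseaseParams(), FearParams(reduced_sus=True, sigma_f=1.0)
        p_f = transmission_probability(IS, True, 0.3, dp, fp)
        p_n = transmission_probability(IS, False, 0.3, dp, fp)
        assert p_f == p_n == pytest.approx(0.3)

    def test_relative_infectivity_scales_probability(self):
        dp, fp = DiseaseParams(), FearParams()
        assert transmission_probability(P, False, 0.2, dp, fp) == pytest.approx(
            0.2 * dp.rel_inf_presym
        )
        with pytest.raises(ValueError):
            transmission_probability(RS, False, 0.2, dp, fp)

    def test_empirical_infection_frequency_matches_formula(self, rng):
        # 25k independent source-target pairs, one night of household
        # contact: empirical frequency within 3 sigma of w * rel_inf
        n_pairs = 25_000
        pop = build_pop([2] * n_pairs)
        w = 0.23
        dp = DiseaseParams(w_household=w, w_community=0.0, w_workplace=0.0,
                           rel_inf_asym=0.4)
        st = init_state(pop, dp, NO_FEAR, None, rng)
        sources = np.arange(0, 2 * n_pairs, 2)
        st.disease[sources] = IA
        st.timer[sources] = 100
        step_day(st)
        p_expect = w * 0.4
        freq = (st.disease[1::2] == E).mean()
        se = np.sqrt(p_expect * (1 - p_expect) / n_pairs)
        assert abs(freq - p_expect) < 3 * se

    def test_attack_rate_matches_naive_contact_loop_oracle(self):
        # dual-implementation check on a frozen tiny configuration
        hh_sizes = [3] * 140
        pop = build_pop(hh_sizes)
        dp = DiseaseParams(
            w_household=0.15, w_community=0.01, w_workplace=0.0,
            degree_community=4, rel_inf_presym=0.0, rel_inf_asym=1.0,
            dwell_E=1.0, dwell_P=1.0, dwell_I=5.0, p_sym=1.0, p_hosp=0.0,
        )
        engine_attacks, oracle_attacks = [], []
        for rep in range(10):
            rng_e = np.random.default_rng(900 + rep)
            st = init_state(pop, dp, NO_FEAR, None, rng_e)
            seeds = np.arange(5)
            st.disease[seeds] = E
            st.timer[seeds] = 1
            for _ in range(40):
                step_day(st)
            engine_attacks.append((st.disease != S).mean())
            rng_o = np.random.default_rng(5000 + rep)
            oracle_attacks.append(
                naive_contact_epidemic(
                    pop.household_id, pop.home_community, 0.15, 0.01, 4,
                    5.0, seeds, 40, rng_o,
                )
            )
        m_e, m_o = np.mean(engine_attacks), np.mean(oracle_attacks)
        se = np.sqrt(np.var(engine_attacks) / 10 + np.var(oracle_attacks) / 10)
        assert abs(m_e - m_o) < 3 * se + 0.02


class TestProgression:
    def test_always_symptomatic_never_reaches_asymptomatic_branch(self, rng):
        pop = build_pop([5] * 100)
        dp = DiseaseParams(p_sym=1.0, w_household=0.5)
        st = init_state(pop, dp, NO_FEAR, None, rng)
        st.disease[:10] = E
        st.timer[:10] = 1
        for _ in range(60):
            step_day(st)
        counts = np.bincount(st.disease, minlength=7)
        assert counts[IA] == 0 and counts[RA] == 0

    def test_never_symptomatic_silences_local_fear(self, rng):
        pop = build_pop([5] * 100)
        dp = DiseaseParams(p_sym=0.0, w_household=0.5)
        fp = FearParams(p_contact_fear=0.5, p_contact_calm=0.1)
        st = init_state(pop, dp, fp, None, rng)
        st.disease[:10] = E
        st.timer[:10] = 1
        for _ in range(60):
            step_day(st)
        counts = np.bincount(st.disease, minlength=7)
        assert counts[IS] == 0 and counts[RS] == 0
        assert not st.fearful.any()  # fear is seeded only by symptomatic cases

    def test_dwell_distribution_is_geometric(self, rng):
        mean = 3.0
        draws = sample_dwell(mean, 20_000, rng)
        kmax = 12
        obs = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)[1:]
        p = 1.0 / mean
        pmf = p * (1 - p) ** (np.arange(1, kmax + 1) - 1)
        pmf[-1] = (1 - p) ** (kmax - 1)  # tail lump
        chi2 = ((obs - 20_000 * pmf) ** 2 / (20_000 * pmf)).sum()
        assert stats.chi2.sf(chi2, kmax - 1) > 1e-4

    def test_realized_exposed_dwells_match_configuration(self, tiny_pop, rng):
        sched = seed_infections(tiny_pop, 0.01, 3, rng)
        _, st = run_simulation(
            tiny_pop, DiseaseParams(), FearParams(), None, 80, sched, rng,
            log_events=True,
        )
        start = {}
        dwells = []
        for day, agent, frm, to, _cause in st.events:
            if to == "E":
                start[agent] = day
            elif frm == "E" and agent in start:
                dwells.append(day - start[agent])
        dwells = np.array(dwells)
        assert len(dwells) > 300
        assert dwells.min() >= 1
        assert dwells.mean() == pytest.approx(3.0, rel=0.15)


class TestBehaviour:
    def test_universal_fear_withdrawal_cancels_all_day_venues(self, rng):
        pop = generate(PopulationSpec(n_agents=2000, rng_seed=9, travel_prob_per_day=0.0))
        fp = FearParams(withdraw_fear=True, p_fear=1.0, p_contact_calm=0.0,
                        withdraw_sick=False, withdraw_hosp=False)
        st = init_state(pop, DiseaseParams(), fp, None, rng, log_events=True)
        st.fearful[:] = True
        step_day(st)   # day 0: withdrawal sampled for day 1
        st.presence_log.clear()
        step_day(st)   # day 1: everyone withdrawn
        assert st.last_withdrawn.all()
        assert st.presence_log == []

    def test_zero_p_fear_never_withdraws_for_fear_alone(self, rng):
        pop = build_pop([4] * 100)
        fp = FearParams(withdraw_fear=True, p_fear=0.0)
        st = init_state(pop, DiseaseParams(), fp, None, rng)
        st.fearful[:] = True
        for _ in range(10):
            step_day(st)
        assert (st.withdrawn_until == 0).all()

    def test_withdrawal_frequency_matches_p_fear(self, rng):
        pop = build_pop([1] * 20_000)
        fp = FearParams(withdraw_fear=True, p_fear=0.3, p_contact_calm=0.0)
        st = init_state(pop, DiseaseParams(), fp, None, rng)
        st.fearful[:] = True
        step_day(st)
        freq = (st.withdrawn_until > 0).mean()
        se = np.sqrt(0.3 * 0.7 / 20_000)
        assert abs(freq - 0.3) < 3 * se

    def test_withdrawn_agents_contact_household_only(self, small_pop):
        rng = np.random.default_rng(77)
        sched = seed_infections(small_pop, 0.005, 3, rng)
        fp = FearParams(withdraw_fear=True, p_fear=0.5)
        st = init_state(small_pop, DiseaseParams(), fp, None, rng, log_events=True)
        violations = 0
        for day in range(40):
            st.presence_log.clear()
            step_day(st, sched[day] if day < len(sched) else None)
            withdrawn = st.last_withdrawn
            for _d, agent, layer in st.presence_log:
                if withdrawn[agent]:
                    violations += 1
        assert violations == 0

    def test_transition_audit_only_legal_edges(self, tiny_pop):
        rng = np.random.default_rng(5)
        sched = seed_infections(tiny_pop, 0.01, 3, rng)
        fp = FearParams(withdraw_fear=True, p_fear=0.2)
        _, st = run_simulation(
            tiny_pop, DiseaseParams(), fp, None, 120, sched, rng, log_events=True
        )
        allowed = {("S", "E"), ("E", "P"), ("P", "Is"), ("P", "Ia"),
                   ("Is", "Rs"), ("Ia", "Ra"), ("N", "F"), ("F", "N")}
        seen_infection = set()
        for day, agent, frm, to, cause in st.events:
            assert (frm, to) in allowed, (frm, to, cause)
            if (frm, to) == ("S", "E"):
                assert agent not in seen_infection  # no reinfection
                seen_infection.add(agent)

    def test_behaviour_off_makes_fear_epidemiologically_inert(self, small_pop):
        # sigma_f = 1, p_fear = 0, sick withdrawal off, no broadcasters:
        # attack-rate distribution matches a fear-disabled run
        def attacks(fp, base_seed):
            out = []
            for s in range(20):
                rng = np.random.default_rng(base_seed + s)
                sched = seed_infections(small_pop, 0.00265, 5, rng)
                series, _ = run_simulation(
                    small_pop, DiseaseParams(), fp, None, 120, sched, rng
                )
                out.append(series.new_cases_frac.sum())
            return np.array(out)

        inert = FearParams(reduced_sus=True, sigma_f=1.0, p_fear=0.0,
                           withdraw_fear=True, withdraw_sick=False)
        disabled = FearParams(fear_enabled=False, withdraw_sick=False)
        a, b = attacks(inert, 100), attacks(disabled, 200)
        se = np.sqrt(a.var() / len(a) + b.var() / len(b))
        assert abs(a.mean() - b.mean()) < 3 * se + 0.01
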