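"""Unit and property tests for the coupled fear-disease ODE family."""

import numpy as np
import pytest
from dataclasses import replace

from fearcast.compartmental import (
    DISEASE_STATES,
    ModelVariant,
    OdeParams,
    build_model,
    default_init,
    reduced_rhs_from_full,
    solve,
)

ALL_VARIANTS = list(ModelVariant)


def random_simplex(rng, dim, n):
    y = rng.random((n, dim))
    return y / y.sum(axis=1, keepdims=True)


class TestConstruction:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown model variant"):
            build_model("SIRS_NF", OdeParams())

    @pytest.mark.parametrize(
        "bad", [dict(beta_disease=-0.1), dict(sigma_f=1.5), dict(rho_f=-0.01),
                dict(gamma_fear=-1.0), dict(p_sym=2.0)]
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            OdeParams(**bad)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_compartment_layout(self, variant):
        m = build_model(variant, OdeParams())
        assert m.n_compartments == 2 * len(DISEASE_STATES[variant.value])
        assert m.labels[0] == "S_N"


class TestRhs:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_disease_free_fear_free_equilibrium(self, variant):
        m = build_model(variant, OdeParams())
        y = np.zeros(m.n_compartments)
        y[m.index("S", "N")] = 1.0
        assert np.allclose(m.rhs(0.0, y), 0.0)

    @pytest.mark.parametrize("variant", [ModelVariant.SIsIaRsRa_NF, ModelVariant.SEPIsIaRsRa_NF])
    def test_all_mass_in_Ra_N_is_absorbing(self, variant):
        # Ra alone drives no flow: no disease, no fear spreaders, and
        # fear recovery needs <Rs,N> which is empty
        m = build_model(variant, OdeParams())
        y = np.zeros(m.n_compartments)
        y[m.index("Ra", "N")] = 1.0
        assert np.allclose(m.rhs(0.0, y), 0.0)

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_mass_conservation_of_rhs(self, variant, rng):
        m = build_model(variant, OdeParams())
        for y in random_simplex(rng, m.n_compartments, 1000):
            assert abs(m.rhs(0.0, y).sum()) < 1e-12

    def test_dimension_mismatch_rejected(self):
        m = build_model(ModelVariant.SIR_NF, OdeParams())
        with pytest.raises(ValueError, match="shape"):
            m.rhs(0.0, np.zeros(14))

    def test_rho_zero_blocks_refearing_of_knowing_recovered(self):
        # with rho_f = 0 the <Rs,N> compartment has no outflow to fear
        p = replace(OdeParams(), rho_f=0.0)
        m = build_model(ModelVariant.SIR_NF, p)
        y = np.zeros(6)
        y[m.index("Rs", "N")] = 0.5
        y[m.index("S", "F")] = 0.5  # fearful mass generating fear force
        dy = m.rhs(0.0, y)
        assert dy[m.index("Rs", "F")] <= 0.0
        # ...and with rho_f = 1 the same state feeds Rs_F
        m1 = build_model(ModelVariant.SIR_NF, replace(p, rho_f=1.0))
        assert m1.rhs(0.0, y)[m1.index("Rs", "F")] > 0.0


class TestNesting:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_reduced_variants_are_contractions_of_full_system(self, variant, rng):
        p = OdeParams()
        m = build_model(variant, p)
        contracted = reduced_rhs_from_full(variant, p)
        for y in random_simplex(rng, m.n_compartments, 1000):
            assert np.abs(m.rhs(0.0, y) - contracted(0.0, y)).max() < 1e-12

    def test_fast_progression_limit_approaches_reduced_model(self):
        # pushing E and P dwell rates up makes the seven-state system
        # collapse onto the five-state one; the gap must shrink
        base = OdeParams()
        m_red = build_model(ModelVariant.SIsIaRsRa_NF, base)
        tr_red = solve(m_red, default_init(m_red), horizon_days=120)
        gaps = []
        for rate in (1e2, 1e3, 1e4):
            pf = replace(base, rate_EP=rate, rate_P_I=rate)
            m = build_model(ModelVariant.SEPIsIaRsRa_NF, pf)
            y0 = np.zeros(14)
            y0[m.index("Is", "N")] = base.p_sym * 2e-5
            y0[m.index("Ia", "N")] = (1 - base.p_sym) * 2e-5
            y0[m.index("S", "N")] = 1 - 2e-5
            tr = solve(m, y0, horizon_days=120)
            shared = np.zeros_like(tr_red.fractions)
            for j, lab in enumerate(tr_red.labels):
                shared[:, j] = tr.compartment(lab)
            gaps.append(np.abs(shared - tr_red.fractions).max())
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 5e-3


class TestSolve:
    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_conservation_along_trajectory(self, variant):
        m = build_model(variant, OdeParams())
        tr = solve(m, default_init(m), horizon_days=360)
        totals = tr.fractions.sum(axis=1)
        assert np.abs(totals - 1.0).max() < 1e-6
        assert tr.fractions.min() >= 0.0

    def test_no_transmission_keeps_susceptibles_constant(self):
        p = replace(OdeParams(), beta_disease=0.0)
        m = build_model(ModelVariant.SEPIsIaRsRa_NF, p)
        tr = solve(m, default_init(m), horizon_days=90)
        s = tr.susceptible_total()
        assert np.abs(s - s[0]).max() < 1e-9

    def test_decoupling_limit_matches_fear_free_dynamics(self):
        # no fear transmission and all-neutral start: the fear overlay
        # stays empty and sigma_f has no effect on the disease
        p = replace(OdeParams(), beta_fear=0.0, gamma_fear=0.0, fear_self_weight=0.0)
        m = build_model(ModelVariant.SEPIsIaRsRa_NF, p)
        tr = solve(m, default_init(m), horizon_days=200)
        assert tr.fearful_total().max() < 1e-12
        other = build_model(
            ModelVariant.SEPIsIaRsRa_NF, replace(p, sigma_f=0.9)
        )
        tr2 = solve(other, default_init(other), horizon_days=200)
        assert np.abs(tr.susceptible_total() - tr2.susceptible_total()).max() < 1e-7

    def test_attack_rate_monotone_in_sigma_f(self):
        attacks = []
        for sig in (0.0, 0.25, 0.5, 0.75, 1.0):
            p = replace(OdeParams(), sigma_f=sig)
            m = build_model(ModelVariant.SIR_NF, p)
            attacks.append(solve(m, default_init(m), horizon_days=360).attack_rate())
        assert all(a2 >= a1 - 1e-9 for a1, a2 in zip(attacks, attacks[1:]))

    def test_bad_initial_conditions_rejected(self):
        m = build_model(ModelVariant.SIR_NF, OdeParams())
        with pytest.raises(ValueError, match="sum to 1"):
            solve(m, np.full(6, 0.5), horizon_days=10)
        with pytest.raises(ValueError, match="horizon"):
            solve(m, default_init(m), horizon_days=0)

    def test_incidence_matches_susceptible_depletion(self):
        # with no demography, cumulative incidence equals S(0) - S(t)
        m = build_model(ModelVariant.SIR_NF, OdeParams())
        tr = solve(m, default_init(m), horizon_days=200)
        cum = np.concatenate(
            [[0.0], np.cumsum((tr.incidence[1:] + tr.incidence[:-1]) / 2) * 0.25]
        )
        depletion = tr.susceptible_total()[0] - tr.susceptible_total()
        assert np.abs(cum - depletion).max() < 1e-4
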