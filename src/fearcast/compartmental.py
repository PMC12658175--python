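"""Coupled fear-disease compartmental ODE models.

Three nested variants couple a disease process with a two-state fear
overlay (Neutral / Fearful):

* ``SIR_NF`` - classic susceptible / infectious / recovered disease
  dynamics crossed with fear.  The single infectious state is treated as
  symptomatic (it spreads fear) and the recovered state as knowingly
  recovered (it counters fear).
* ``SIsIaRsRa_NF`` - splits infectious and recovered into symptomatic
  (``Is``/``Rs``) and asymptomatic (``Ia``/``Ra``) branches.  Only
  symptomatic infections are visible to the fear process: ``Is`` spreads
  fear, ``Rs`` counters it, and knowingly-recovered individuals become
  fearful at a reduced relative rate ``rho_f``.
* ``SEPIsIaRsRa_NF`` - additionally inserts an exposed (``E``,
  incubating, non-infectious) and a presymptomatic (``P``, infectious)
  state before symptom onset.

Every compartment is a ``(disease state, fear state)`` pair.  Fear flows
never change the disease state and disease flows never change the fear
state.  The coupling is bilinear (mass action):

* force of infection ``lambda = beta_disease * (rel_P * P + Is +
  rel_a * Ia)`` summed over both fear states; fearful susceptibles are
  infected at ``sigma_f * lambda`` (protective behaviour),
* fear force ``phi = beta_fear * (Is_total + fear_self_weight *
  (F_total - Is_F))`` - fear is spread by symptomatic individuals
  (fully visible, weight 1 regardless of their own fear state) and by
  otherwise-fearful individuals at a reduced weight,
* calming force ``psi = gamma_fear * Rs_N`` - fear is countered only by
  individuals who know they have recovered and are themselves calm.

The neutral-to-fearful flow out of ``<Rs, N>`` is scaled by ``rho_f``;
``rho_f = 0`` reproduces the classic coupled-contagion baseline in which
the knowingly recovered never become fearful again.

The simpler variants are exact contractions of the full seven-state
system: delete the absent compartments and route flows through them to
the next present state (see :func:`reduced_rhs_from_full`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelVariant",
    "OdeParams",
    "CompartmentalModel",
    "Trajectory",
    "build_model",
    "solve",
    "default_init",
    "reduced_rhs_from_full",
    "DISEASE_STATES",
    "FEAR_STATES",
]

DISEASE_STATES: Dict[str, Tuple[str, ...]] = {
    "SIR_NF": ("S", "Is", "Rs"),
    "SIsIaRsRa_NF": ("S", "Is", "Ia", "Rs", "Ra"),
    "SEPIsIaRsRa_NF": ("S", "E", "P", "Is", "Ia", "Rs", "Ra"),
}
FEAR_STATES: Tuple[str, str] = ("N", "F")


class ModelVariant(str, Enum):
    SIR_NF = "SIR_NF"
    SIsIaRsRa_NF = "SIsIaRsRa_NF"
    SEPIsIaRsRa_NF = "SEPIsIaRsRa_NF"


@dataclass(frozen=True)
class OdeParams:
    """Rate constants for the coupled fear-disease ODE family.

    All rates are per day.  Defaults are the package's reference
    parameterisation, calibrated once so that the three variants exhibit
    the canonical regimes of the model family (fear-suppressed single
    wave vs. fear-relapse second wave); see ``docs/methods.md``.

    Attributes
    ----------
    beta_disease:
        Disease transmission rate (per day, mass action).
    rel_inf_asym, rel_inf_presym:
        Infectivity of ``Ia`` / ``P`` relative to ``Is``.
    sigma_f:
        Susceptibility multiplier for fearful susceptibles, in [0, 1].
        1 means fear gives no protection, 0 full protection.
    beta_fear:
        Fear transmission rate (per day, mass action).
    gamma_fear:
        Fear recovery rate per unit of calm knowingly-recovered mass.
    rho_f:
        Relative rate at which ``<Rs, N>`` individuals become fearful,
        in [0, 1].  0 recovers the baseline in which the knowingly
        recovered stay calm.
    rate_EP:
        E -> P progression rate (1 / mean incubation remainder).
    rate_P_I:
        P -> {Is, Ia} progression rate (1 / mean presymptomatic period).
    p_sym:
        Probability an infection is symptomatic.
    gamma_rec:
        Recovery rate from ``Is`` / ``Ia``.
    fear_self_weight:
        Weight of fearful (non-symptomatic) individuals in the fear
        force, relative to symptomatic individuals.  Symptoms are fully
        visible to contacts; fear alone transmits more weakly.
    """

    beta_disease: float = 0.330
    rel_inf_asym: float = 0.65
    rel_inf_presym: float = 0.65
    sigma_f: float = 0.25
    beta_fear: float = 3.27
    gamma_fear: float = 0.361
    rho_f: float = 1.0
    rate_EP: float = 0.50
    rate_P_I: float = 0.80
    p_sym: float = 0.95
    gamma_rec: float = 0.122
    fear_self_weight: float = 0.0119

    def __post_init__(self) -> None:
        rates = {
            "beta_disease": self.beta_disease,
            "rel_inf_asym": self.rel_inf_asym,
            "rel_inf_presym": self.rel_inf_presym,
            "beta_fear": self.beta_fear,
            "gamma_fear": self.gamma_fear,
            "rate_EP": self.rate_EP,
            "rate_P_I": self.rate_P_I,
            "gamma_rec": self.gamma_rec,
            "fear_self_weight": self.fear_self_weight,
        }
        for name, value in rates.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be a finite non-negative rate, got {value}")
        for name, value in {
            "sigma_f": self.sigma_f,
            "rho_f": self.rho_f,
            "p_sym": self.p_sym,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _labels(disease_states: Sequence[str]) -> List[str]:
    return [f"{d}_{f}" for d in disease_states for f in FEAR_STATES]


@dataclass(frozen=True)
class CompartmentalModel:
    """A concrete variant of the coupled fear-disease ODE family."""

    variant: ModelVariant
    params: OdeParams
    disease_states: Tuple[str, ...]
    labels: Tuple[str, ...]
    _rhs: Callable[[float, np.ndarray], np.ndarray] = field(repr=False)
    _incidence: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def n_compartments(self) -> int:
        return len(self.labels)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        """Time derivative of the compartment-fraction vector.

        Derivatives sum to zero exactly (closed population).
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_compartments,):
            raise ValueError(
                f"state has shape {y.shape}, expected ({self.n_compartments},) "
                f"for variant {self.variant.value}"
            )
        return self._rhs(t, y)

    def incidence_rate(self, y: np.ndarray) -> float:
        """Instantaneous new-infection inflow (fraction of population per day)."""
        return float(self._incidence(np.asarray(y, dtype=float)))

    def index(self, disease: str, fear: str) -> int:
        return self.labels.index(f"{disease}_{fear}")


# ---------------------------------------------------------------------------
# Right-hand sides.  One builder per variant so that a correction to the
# flow structure of one variant touches exactly one function.
# ---------------------------------------------------------------------------


def _fear_forces(
    p: OdeParams, is_total: float, f_other: float, rs_n: float
) -> Tuple[float, float]:
    """Fear transmission and calming forces.

    ``is_total`` is the symptomatic mass (both fear states, fully
    visible); ``f_other`` the fearful mass outside ``Is``, which
    transmits fear at the reduced ``fear_self_weight``; ``rs_n`` the
    calm knowingly-recovered mass that counters fear.
    """
    phi = p.beta_fear * (is_total + p.fear_self_weight * f_other)
    psi = p.gamma_fear * rs_n
    return phi, psi


def _build_sir(p: OdeParams):
    # layout: S_N S_F Is_N Is_F Rs_N Rs_F
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        s_n, s_f, i_n, i_f, r_n, r_f = y
        lam = p.beta_disease * (i_n + i_f)
        phi, psi = _fear_forces(p, i_n + i_f, s_f + r_f, r_n)
        inf_n = lam * s_n
        inf_f = p.sigma_f * lam * s_f
        rec_n = p.gamma_rec * i_n
        rec_f = p.gamma_rec * i_f
        # fear transitions per disease state (N->F, F->N)
        fs = phi * s_n - psi * s_f
        fi = phi * i_n - psi * i_f
        fr = p.rho_f * phi * r_n - psi * r_f
        return np.array(
            [
                -inf_n - fs,
                -inf_f + fs,
                inf_n - rec_n - fi,
                inf_f - rec_f + fi,
                rec_n - fr,
                rec_f + fr,
            ]
        )

    def incidence(y: np.ndarray) -> float:
        s_n, s_f, i_n, i_f, *_ = y
        lam = p.beta_disease * (i_n + i_f)
        return lam * (s_n + p.sigma_f * s_f)

    return rhs, incidence


def _build_siiarr(p: OdeParams):
    # layout: S_N S_F Is_N Is_F Ia_N Ia_F Rs_N Rs_F Ra_N Ra_F
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        s_n, s_f, is_n, is_f, ia_n, ia_f, rs_n, rs_f, ra_n, ra_f = y
        lam = p.beta_disease * ((is_n + is_f) + p.rel_inf_asym * (ia_n + ia_f))
        f_other = s_f + ia_f + rs_f + ra_f
        phi, psi = _fear_forces(p, is_n + is_f, f_other, rs_n)
        inf_n = lam * s_n
        inf_f = p.sigma_f * lam * s_f
        fs = phi * s_n - psi * s_f
        fis = phi * is_n - psi * is_f
        fia = phi * ia_n - psi * ia_f
        frs = p.rho_f * phi * rs_n - psi * rs_f
        fra = phi * ra_n - psi * ra_f
        g = p.gamma_rec
        return np.array(
            [
                -inf_n - fs,
                -inf_f + fs,
                p.p_sym * inf_n - g * is_n - fis,
                p.p_sym * inf_f - g * is_f + fis,
                (1 - p.p_sym) * inf_n - g * ia_n - fia,
                (1 - p.p_sym) * inf_f - g * ia_f + fia,
                g * is_n - frs,
                g * is_f + frs,
                g * ia_n - fra,
                g * ia_f + fra,
            ]
        )

    def incidence(y: np.ndarray) -> float:
        s_n, s_f, is_n, is_f, ia_n, ia_f, *_ = y
        lam = p.beta_disease * ((is_n + is_f) + p.rel_inf_asym * (ia_n + ia_f))
        return lam * (s_n + p.sigma_f * s_f)

    return rhs, incidence


def _build_sepiiarr(p: OdeParams):
    # layout: S_N S_F E_N E_F P_N P_F Is_N Is_F Ia_N Ia_F Rs_N Rs_F Ra_N Ra_F
    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        (s_n, s_f, e_n, e_f, pp_n, pp_f, is_n, is_f, ia_n, ia_f,
         rs_n, rs_f, ra_n, ra_f) = y
        lam = p.beta_disease * (
            p.rel_inf_presym * (pp_n + pp_f)
            + (is_n + is_f)
            + p.rel_inf_asym * (ia_n + ia_f)
        )
        f_other = s_f + e_f + pp_f + ia_f + rs_f + ra_f
        phi, psi = _fear_forces(p, is_n + is_f, f_other, rs_n)
        inf_n = lam * s_n
        inf_f = p.sigma_f * lam * s_f
        fs = phi * s_n - psi * s_f
        fe = phi * e_n - psi * e_f
        fp = phi * pp_n - psi * pp_f
        fis = phi * is_n - psi * is_f
        fia = phi * ia_n - psi * ia_f
        frs = p.rho_f * phi * rs_n - psi * rs_f
        fra = phi * ra_n - psi * ra_f
        g = p.gamma_rec
        k = p.rate_EP
        d = p.rate_P_I
        return np.array(
            [
                -inf_n - fs,
                -inf_f + fs,
                inf_n - k * e_n - fe,
                inf_f - k * e_f + fe,
                k * e_n - d * pp_n - fp,
                k * e_f - d * pp_f + fp,
                p.p_sym * d * pp_n - g * is_n - fis,
                p.p_sym * d * pp_f - g * is_f + fis,
                (1 - p.p_sym) * d * pp_n - g * ia_n - fia,
                (1 - p.p_sym) * d * pp_f - g * ia_f + fia,
                g * is_n - frs,
                g * is_f + frs,
                g * ia_n - fra,
                g * ia_f + fra,
            ]
        )

    def incidence(y: np.ndarray) -> float:
        s_n, s_f = y[0], y[1]
        pp = y[4] + y[5]
        is_ = y[6] + y[7]
        ia = y[8] + y[9]
        lam = p.beta_disease * (p.rel_inf_presym * pp + is_ + p.rel_inf_asym * ia)
        return lam * (s_n + p.sigma_f * s_f)

    return rhs, incidence


_BUILDERS = {
    ModelVariant.SIR_NF: _build_sir,
    ModelVariant.SIsIaRsRa_NF: _build_siiarr,
    ModelVariant.SEPIsIaRsRa_NF: _build_sepiiarr,
}


def build_model(variant: ModelVariant | str, params: OdeParams) -> CompartmentalModel:
    """Construct a concrete coupled fear-disease model.

    Parameters are validated at construction; an unknown variant or a
    negative rate is rejected immediately.
    """
    try:
        variant = ModelVariant(variant)
    except ValueError as exc:
        raise ValueError(f"unknown model variant: {variant!r}") from exc
    if not isinstance(params, OdeParams):
        raise TypeError("params must be an OdeParams instance")
    disease_states = DISEASE_STATES[variant.value]
    rhs, incidence = _BUILDERS[variant](params)
    return CompartmentalModel(
        variant=variant,
        params=params,
        disease_states=disease_states,
        labels=tuple(_labels(disease_states)),
        _rhs=rhs,
        _incidence=incidence,
    )


# ---------------------------------------------------------------------------
# Variant nesting: the simpler systems are contractions of the full one.
# ---------------------------------------------------------------------------

# Representative of each full disease state among a reduced variant's
# states, with branch weights where a transit state feeds a symptomatic /
# asymptomatic split downstream.
def _projection_matrix(variant: ModelVariant, p: OdeParams) -> np.ndarray:
    full = DISEASE_STATES[ModelVariant.SEPIsIaRsRa_NF.value]
    reduced = DISEASE_STATES[variant.value]
    if variant is ModelVariant.SEPIsIaRsRa_NF:
        rep = {d: {d: 1.0} for d in full}
    elif variant is ModelVariant.SIsIaRsRa_NF:
        rep = {
            "S": {"S": 1.0},
            "E": {"Is": p.p_sym, "Ia": 1 - p.p_sym},
            "P": {"Is": p.p_sym, "Ia": 1 - p.p_sym},
            "Is": {"Is": 1.0},
            "Ia": {"Ia": 1.0},
            "Rs": {"Rs": 1.0},
            "Ra": {"Ra": 1.0},
        }
    elif variant is ModelVariant.SIR_NF:
        # asymptomatic branch merges into the symptomatic chain
        rep = {
            "S": {"S": 1.0},
            "E": {"Is": 1.0},
            "P": {"Is": 1.0},
            "Is": {"Is": 1.0},
            "Ia": {"Is": 1.0},
            "Rs": {"Rs": 1.0},
            "Ra": {"Rs": 1.0},
        }
    else:  # pragma: no cover
        raise ValueError(variant)
    m = np.zeros((2 * len(reduced), 2 * len(full)))
    for j, d in enumerate(full):
        for target, w in rep[d].items():
            i = reduced.index(target)
            for f in range(2):
                m[2 * i + f, 2 * j + f] = w
    return m


def reduced_rhs_from_full(
    variant: ModelVariant | str, params: OdeParams
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Derive a reduced variant's right-hand side from the full system.

    The reduced state is embedded into the full state with the absent
    compartments at zero, the full right-hand side is evaluated, and the
    rows of absent compartments are folded into their downstream present
    representatives (transit through an absent state is instantaneous).
    This is the ``set the absent compartments to zero'' construction and
    must agree with the explicitly written reduced system; the agreement
    is asserted in the test suite on random states.
    """
    variant = ModelVariant(variant)
    full_model = build_model(ModelVariant.SEPIsIaRsRa_NF, params)
    m = _projection_matrix(variant, params)
    # embedding = transpose of the 0/1 part of the projection restricted
    # to present states
    full = DISEASE_STATES[ModelVariant.SEPIsIaRsRa_NF.value]
    reduced = DISEASE_STATES[variant.value]
    embed = np.zeros((2 * len(full), 2 * len(reduced)))
    for i, d in enumerate(reduced):
        j = full.index(d)
        embed[2 * j, 2 * i] = 1.0
        embed[2 * j + 1, 2 * i + 1] = 1.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return m @ full_model.rhs(t, embed @ np.asarray(y, dtype=float))

    return rhs


# ---------------------------------------------------------------------------
# Solving
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trajectory:
    """Solution of a coupled fear-disease model on a uniform daily grid."""

    time_grid: np.ndarray
    fractions: np.ndarray  # (n_time, n_compartments)
    incidence: np.ndarray  # new-infection inflow per day, on the grid
    labels: Tuple[str, ...]
    variant: ModelVariant

    def compartment(self, label: str) -> np.ndarray:
        return self.fractions[:, self.labels.index(label)]

    def disease_total(self, disease: str) -> np.ndarray:
        return self.compartment(f"{disease}_N") + self.compartment(f"{disease}_F")

    def fearful_total(self) -> np.ndarray:
        cols = [i for i, lab in enumerate(self.labels) if lab.endswith("_F")]
        return self.fractions[:, cols].sum(axis=1)

    def susceptible_total(self) -> np.ndarray:
        return self.disease_total("S")

    def attack_rate(self) -> float:
        """Cumulative infected fraction at the end of the horizon."""
        s = self.susceptible_total()
        return float(s[0] - s[-1])

    def daily_incidence(self) -> np.ndarray:
        """Incidence aggregated onto integer days (fraction per day)."""
        days = np.arange(0, int(np.floor(self.time_grid[-1])) + 1)
        return np.interp(days, self.time_grid, self.incidence)

    def to_frame(self):
        """Tidy long-format table: time, compartment, fraction."""
        import pandas as pd

        n_t = len(self.time_grid)
        return pd.DataFrame(
            {
                "time": np.repeat(self.time_grid, len(self.labels)),
                "compartment": np.tile(np.asarray(self.labels), n_t),
                "fraction": self.fractions.ravel(),
            }
        )


def default_init(
    model: CompartmentalModel, seed_frac: float = 2e-5
) -> np.ndarray:
    """All-neutral initial condition with a small infectious seed.

    The seed enters the first infected state of the variant (``E`` where
    it exists, otherwise the infectious state(s) split by ``p_sym``),
    with the remainder in ``<S, N>``.
    """
    if not 0 <= seed_frac < 1:
        raise ValueError("seed_frac must lie in [0, 1)")
    y0 = np.zeros(model.n_compartments)
    p = model.params
    if model.variant is ModelVariant.SEPIsIaRsRa_NF:
        y0[model.index("E", "N")] = seed_frac
    elif model.variant is ModelVariant.SIsIaRsRa_NF:
        y0[model.index("Is", "N")] = p.p_sym * seed_frac
        y0[model.index("Ia", "N")] = (1 - p.p_sym) * seed_frac
    else:
        y0[model.index("Is", "N")] = seed_frac
    y0[model.index("S", "N")] = 1.0 - seed_frac
    return y0


def solve(
    model: CompartmentalModel,
    init: np.ndarray | None = None,
    horizon_days: float = 360,
    step_days: float = 0.25,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model and return its trajectory on a uniform grid.

    Uses an adaptive LSODA integrator (stiff-capable: the nested-variant
    comparison drives progression rates far above the transmission
    scale).  Tight tolerances matter here because second-wave timing is
    sensitive to accumulated integration error over a year-long horizon.

    Raises
    ------
    RuntimeError
        If the integrator fails or the solution leaves the simplex by
        more than the documented clamp (1e-9).
    """
    if init is None:
        init = default_init(model)
    init = np.asarray(init, dtype=float)
    if init.shape != (model.n_compartments,):
        raise ValueError("initial condition has wrong dimension for variant")
    if abs(init.sum() - 1.0) > 1e-8:
        raise ValueError(f"initial condition must sum to 1, got {init.sum()!r}")
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    t_eval = np.arange(0.0, horizon_days + 0.5 * step_days, step_days)
    sol = solve_ivp(
        model.rhs,
        (0.0, float(t_eval[-1])),
        init,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        raise RuntimeError("ODE solution contains non-finite values")
    if y.min() < -1e-9:
        raise RuntimeError(
            f"solution left the simplex: min fraction {y.min():.3e} < -1e-9"
        )
    y = np.clip(y, 0.0, None)
    inc = np.array([model.incidence_rate(row) for row in y])
    return Trajectory(
        time_grid=sol.t,
        fractions=y,
        incidence=inc,
        labels=model.labels,
        variant=model.variant,
    )
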