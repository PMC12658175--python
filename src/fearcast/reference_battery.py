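"""Reference experiment battery: the runs behind the headline results.

Collects in one place the computations that reproduce the model
family's published behaviour: the six compartmental landmark solves,
the six named agent-based scenarios over matched seeds, and the
two-mode sensitivity sweep.  Both the test suite and the
results-reproduction script drive these functions, so the numbers they
report always come from fresh simulation runs.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from fearcast.abm_engine import DiseaseParams, FearParams
from fearcast.compartmental import (
    ModelVariant,
    OdeParams,
    build_model,
    default_init,
    solve,
)
from fearcast.scenario_runner import (
    ScenarioConfig,
    SweepSpec,
    run_scenario,
    run_sweep,
)
from fearcast.synthetic_population import PopulationSpec, generate
from fearcast.wave_metrics import count_waves, rolling_max_7

# problem sizes for the desk-scale battery: scenario comparisons use
# 20k agents, the 5x5 sweeps 10k, both over a 200-day horizon
SCENARIO_N_AGENTS = 20_000
SWEEP_N_AGENTS = 10_000
HORIZON = 200

ODE_LANDMARK_RUNS: Dict[str, Tuple[ModelVariant, dict]] = {
    "sir_rho1": (ModelVariant.SIR_NF, dict(rho_f=1.0)),
    "sir_rho0": (ModelVariant.SIR_NF, dict(rho_f=0.0)),
    "siiarr_s25": (ModelVariant.SIsIaRsRa_NF, dict(sigma_f=0.25)),
    "siiarr_s35": (ModelVariant.SIsIaRsRa_NF, dict(sigma_f=0.35)),
    "sep_s25": (ModelVariant.SEPIsIaRsRa_NF, dict(sigma_f=0.25)),
    "sep_s35": (ModelVariant.SEPIsIaRsRa_NF, dict(sigma_f=0.35)),
}


def ode_landmarks(horizon_days: float = 360) -> Dict[str, dict]:
    """Solve the six reference runs and extract their landmarks."""
    out = {}
    for name, (variant, overrides) in ODE_LANDMARK_RUNS.items():
        params = replace(OdeParams(), **overrides)
        model = build_model(variant, params)
        tr = solve(model, default_init(model), horizon_days=horizon_days)
        waves = count_waves(rolling_max_7(tr.daily_incidence()))
        out[name] = {
            "susceptible_end": float(tr.susceptible_total()[-1]),
            "fearful_end": float(tr.fearful_total()[-1]),
            "n_waves": waves.n_waves,
            "peak_days": waves.peak_days,
            "attack_rate": tr.attack_rate(),
        }
    return out


def scenario_battery(
    seed: int, n_seeds: int = 20, n_agents: int = SCENARIO_N_AGENTS
) -> pd.DataFrame:
    """All six named scenarios over matched replicate seeds."""
    from fearcast.scenario_runner import SCENARIO_NAMES

    spec = PopulationSpec(
        n_agents=n_agents, households_per_community=100, rng_seed=seed % 2**31
    )
    pop = generate(spec)
    rows = []
    for name in SCENARIO_NAMES:
        for r in range(n_seeds):
            cfg = ScenarioConfig(
                scenario_name=name,
                population_spec=spec,
                horizon_days=HORIZON,
                rng_seed=(seed + 7919 * r + 1) % 2**31,
            )
            res = run_scenario(cfg, pop=pop)
            rows.append(
                {
                    "scenario": name,
                    "replicate": r,
                    "attack_rate": res.attack_rate,
                    "peak_height": float(
                        rolling_max_7(res.series.new_cases_frac).max()
                    ),
                    "n_waves": res.waves.n_waves,
                    "peak_fear": res.peak_fear,
                    "final_fear": res.final_fear,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_sweeps(
    seed: int, replicates: int = 20, n_agents: int = SWEEP_N_AGENTS
) -> pd.DataFrame:
    """The default 5x5 p_fear x sigma_f sweep, local and with media."""
    spec = PopulationSpec(
        n_agents=n_agents, households_per_community=100, rng_seed=seed % 2**31
    )
    base = ScenarioConfig(
        population_spec=spec, horizon_days=HORIZON, rng_seed=seed % 2**31
    )
    sweep = SweepSpec(replicates=replicates)
    return run_sweep(sweep, base, pop=generate(spec))


def corner_summary(grid: pd.DataFrame) -> Dict[str, float]:
    """Attack rates at the four (p_fear, sigma_f) grid corners per mode."""
    out = {}
    for mode, g in grid.groupby("mode"):
        for pf in (0.0, 1.0):
            for sg in (0.0, 1.0):
                cell = g[(g.p_fear == pf) & (g.sigma_f == sg)]
                out[f"{mode}_pf{pf:g}_sg{sg:g}"] = float(
                    cell["mean_attack_rate"].iloc[0]
                )
    return out
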