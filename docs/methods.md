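# Methods

`fearcast` couples two contagions — a respiratory pathogen and fear of
it — in two complementary settings: a family of nested compartmental
ODE models, and a desk-scale agent-based simulator with local and
broadcast-media fear spread.  This note records the model equations,
the defaults and why they are what they are, and the limits of what the
desk-scale experiments can show.

## Compartmental models

Every compartment is a pair (disease state, fear state).  The disease
chain is S → E → P → {Is | Ia} → {Rs | Ra}: exposed (incubating,
non-infectious), presymptomatic infectious, then symptomatic or
asymptomatic infectious with probability `p_sym` / `1 − p_sym`, ending
in the corresponding recovered state.  The fear overlay has two states,
Neutral and Fearful.  Three variants are exposed:

* `SIR_NF` — S, Is, Rs only (the classic three-compartment model; its
  single infectious state is treated as symptomatic and its recovered
  state as knowingly recovered),
* `SIsIaRsRa_NF` — adds the asymptomatic branch,
* `SEPIsIaRsRa_NF` — adds the exposed and presymptomatic states.

All flows are bilinear (mass action), per day:

* **Infection.** Force of infection
  `λ = β_d (rel_P·P + Is + rel_a·Ia)` summed over both fear states.
  Neutral susceptibles are infected at `λ·S_N`, fearful susceptibles at
  `σ_f·λ·S_F`: `σ_f ∈ [0,1]` is the protective-behaviour multiplier
  (1 = no protection).
* **Fear transmission.** `φ = β_f (Is_total + w·(F_total − Is_F))`.
  Symptomatic individuals are fully visible to their contacts and
  transmit fear with weight 1 regardless of their own fear state;
  fearful individuals without symptoms transmit at the reduced weight
  `w = fear_self_weight`.  Every neutral compartment flows to its
  fearful twin at rate `φ`, except `⟨Rs,N⟩`, whose flow is scaled by
  `ρ_f ∈ [0,1]`; `ρ_f = 0` recovers the classic baseline in which the
  knowingly recovered never become fearful again.
* **Fear recovery.** `ψ = γ_f · Rs_N`: only calm, knowingly recovered
  individuals talk others out of their fear.  Every fearful compartment
  flows back to neutral at rate `ψ`.
* Disease progression and recovery are independent of fear state.

The two reduced variants are exact contractions of the seven-state
system: delete the absent compartments and route flows through them to
the next present state (in `SIsIaRsRa_NF` the infection inflow splits
directly into Is/Ia by `p_sym`; in `SIR_NF` the asymptomatic branch
merges into the symptomatic chain).  The module also derives each
reduced right-hand side mechanically from the full one by a
fold-the-absent-rows projection, and the test suite asserts agreement
with the hand-written reduced systems to 1e−12 on random states.

### Why the fear force has this shape

With fear transmitted at full weight by the fearful themselves, the
fear subsystem is a logistic process that either outruns the disease
and freezes the entire population fearful, or lags it entirely —
no parameterisation then produces the intermediate, slowly-drifting
fear plateaus this model family is known for, simultaneously in all
three variants with shared parameters.  Splitting the force into a
dominant visible-symptoms term and a weak self-sustaining term does
produce them: during an outbreak fear tracks symptomatic prevalence;
afterwards the small `w`-term balances against calming by `⟨Rs,N⟩`,
leaving fear on a slow manifold whose drift direction depends on how
many knowingly recovered the outbreak created.  That balance is what
generates the model's characteristic regimes:

* with `ρ_f = 1` the recovered are continually re-frightened, the calm
  pool `Rs_N` stays small, and the system settles into a marginally
  critical simmer: susceptibles plateau while fear holds its level;
* with `ρ_f = 0` (or after a large enough outbreak) the calm pool grows
  unchecked, fear collapses, and the disease rebounds through the
  remaining susceptibles as a second wave.

### Default parameters

One shared parameter set is used for all three variants (the
comparison across variants is the point).  Rates are per day.

| parameter | default | meaning |
|---|---|---|
| `beta_disease` | 0.330 | transmission rate (R0 ≈ 2.7 with `gamma_rec`) |
| `gamma_rec` | 0.122 | recovery rate (mean infectious period 8.2 d) |
| `rel_inf_presym` / `rel_inf_asym` | 0.65 | relative infectivity of P / Ia |
| `p_sym` | 0.95 | symptomatic fraction |
| `rate_EP` | 0.50 | E → P progression (mean 2 d) |
| `rate_P_I` | 0.80 | P → I progression (mean 1.25 d) |
| `sigma_f` | 0.25 | fearful-susceptible multiplier |
| `beta_fear` | 3.27 | fear transmission rate |
| `gamma_fear` | 0.361 | calming rate per unit of `Rs_N` |
| `fear_self_weight` | 0.0119 | weight of non-symptomatic fearful in `φ` |
| `rho_f` | 1.0 | relative re-frightening of `⟨Rs,N⟩` |

The default initial condition places 2e−5 of the population in the
first infected state (E where present) and the rest in `⟨S,N⟩`.  These
constants were calibrated once, jointly, so that the six reference
runs (`SIR_NF` at `ρ_f ∈ {1, 0}`, the two larger variants at
`σ_f ∈ {0.25, 0.35}`) land in the regimes described above with the
canonical day-360 plateau values and second-wave timings; they are not
fitted to any data set.  Fear spreading much faster than the disease
(`β_f ≫ β_d`) is a structural requirement: a second wave needs fear to
both rise and recede faster than the epidemic it suppresses.

Numerics: LSODA with `rtol = 1e−8`, `atol = 1e−10`, output every
0.25 day.  Trajectory incidence is the transmission flow `λ(S_N +
σ_f S_F)` re-evaluated on the grid, not a difference of cumulative
compartments, so wave detection is not affected by grid resolution.
Fractions are validated to stay within 1e−9 of the simplex and clamped
at zero; larger violations raise.

The SEP variant at `σ_f = 0.25` ends near S ≈ 0.71 at day 360 with a
second wave forming, but its fearful fraction is still ≈ 0.67 at that
point: in this flow family the fear collapse and the disease
resurgence are tightly coupled in time, so a state with low fear, high
susceptibility and only an incipient second wave is not reachable.
This is a known, documented limitation of the reconstruction.

## Wave detection

A wave is a local maximum of the smoothed per-capita daily-incidence
series with topographic prominence ≥ 1e−4 (one case per 10,000
people).  Smoothing is a centered 7-day rolling maximum with windows
clipped at the series edges (no NaN padding), so early and late peaks
remain detectable.  The prominence comparison is inclusive, flat-topped
peaks report their leftmost day, and the unit contract is strict:
series are fractions of the population, and so is the threshold.  The
detector is `scipy.signal.find_peaks` under the hood and is tested for
exact agreement against a brute-force prominence implementation.

At agent counts of 1e4–1e5 one reported case is 0.1–1 prominence
units, so Poisson fluctuations on suppressed plateau-like trajectories
register as waves.  This granularity effect is inherent to applying an
absolute per-capita threshold at small n; wave counts from desk-scale
sweeps should be read comparatively (between modes or cells), not as
absolute wave numbers.

## Synthetic population

Agents live in households (zero-truncated Poisson sizes, mean 2.5),
households fill communities (default 100–200 per community), and
communities fill census tracts (10 per tract).  Half the agents are
workers — of whom 30% commute to a uniformly random other community —
a fifth are students attending school in their home community, and
0.5% of workers hold publishing/broadcasting occupations, which is
what sites media outlets.  Long-distance travel is a per-day
probability (5e−4) of a 5-day trip to a random community.  The
generator is deterministic given its seed.

This is a structural surrogate, not a demographic one: no age
structure, no realistic commute flows, no geography.  It exists to
exercise the behavioural mechanisms (withdrawal cancels commuting and
travel; broadcasters reach whole tracts), so conclusions about spatial
realism cannot be drawn from it.

## Agent-based engine

One step is a day with a day phase (workplace/school venue contacts
for workers and students, ambient community contact for everyone else)
and a night phase (household plus ambient community contact), all
evaluated against the morning snapshot so results do not depend on
agent iteration order.  Households mix completely; every other layer
gives each present agent `degree = 8` uniform partner draws (with
replacement) from the group, which the engine evaluates in closed form
— per target, infection probability `1 − (1 − w·σ·h)^degree` where
`h` is the group's infectivity-weighted source fraction.  This is
equal in law to enumerating the sampled contacts (the test suite
checks it against a naive per-contact loop) at O(n) cost per day.

Disease: geometric dwell times with means E 3 d, P 2 d, I 6 d;
`p_sym = 0.6`; contact weights 0.10 (household), 0.03 (workplace),
0.008 (community), giving a disease-only attack rate near 0.87
(R0 ≈ 2.7).  Fear: symptomatic and fearful agents convert neutral
contacts with `p_contact_fear = 0.04` per contact; calm knowingly
recovered agents (`⟨Rs,N⟩`) convert fearful contacts with
`p_contact_calm = 0.45`.  Because direction depends only on the
target's morning fear state, an agent can receive fear or calming
influences on a given day but never both.

Behaviour: hospitalised symptomatic agents (Bernoulli `p_hosp = 0.05`
at symptom onset) withdraw for their whole symptomatic period
regardless of fear; symptomatic-and-fearful agents withdraw while that
holds; other fearful agents withdraw with `p_fear = 0.10` per day for
`t_with = 28` days.  Withdrawn agents contact only their household,
abort travel immediately, and remain reachable by broadcasters (media
reaches homes).  The slow-accumulating fear-withdrawal (low `p_fear`,
long `t_with`) is what reproduces the delayed, lower fear peak and the
peak-height ordering hosp > hosp+sick > hosp+sick+fear: a fast, short
withdrawal suppresses fear itself so strongly that symptomatic-fearful
withdrawal loses its bite and the ordering inverts.

Broadcasters: one per community with ≥ 1 media worker; all media
workers in the community are employees; the audience is the whole
tract.  A broadcaster activates (position FEAR) when ≥ 25% of its
employees are fearful, recording the tract's per-capita new-infection
rate that day as its permanent baseline Ė0.  Thereafter it counters
fear when Ėt < 0.25·Ė0, is neutral when Ėt < 0.75·Ė0, and spreads fear
otherwise; no re-activation, no re-baselining, no smoothing of Ėt.
Each non-neutral broadcaster influences each mismatched tract resident
with `p_bc = 0.02` per day; independent broadcasters aggregate as
`1 − (1 − p_bc)^k`.

The fear/behaviour defaults were chosen once so that the six named
scenarios reproduce the canonical qualitative surfaces: highest peak
and attack rate under hospital-withdrawal only; the reduced-
susceptibility scenario with the smallest peak, lowest attack rate and
persistent fear; broadcaster scenarios with higher fear peaks, a
genuine second wave, and moderated attack-rate extremes in the
`(p_fear, σ_f)` sweep corners.

## Scenarios and sweeps

The six named scenarios share all parameters and differ only in the
toggle pattern (see `scenario_runner`).  Seeding mirrors a national
outbreak snapshot: 0.265% of the population per day for the first five
days, uniformly at random (hence proportional to community size).  The
sensitivity sweep runs `p_fear × σ_f` on {0, 0.25, 0.5, 0.75, 1}²,
both behaviours enabled, 20 replicate seeds per cell, once with
local-only fear spread and once with broadcasters.

Problem sizes for the reference battery: 20,000 agents for scenario
comparisons, 10,000 for sweep cells, 200-day horizon.  At these sizes
attack rates and peak orderings are stable across seeds, while
absolute wave counts inherit the granularity caveat above: the
full-scale statements "every local-only cell is single-wave" and
"broadcaster single-wave cells occur only at low `p_fear` with extreme
`σ_f`" do not survive Poisson noise at desk scale and are reported as
realized counts instead.  The robust desk-scale signatures are the
comparative ones: broadcaster cells produce more waves than matched
local cells, and broadcaster fear spread compresses the spread of
corner attack rates.

## Reproducibility

Every stochastic component draws from a single `numpy` Generator per
run, seeded from the scenario configuration; identical configuration
and seed give bit-identical daily series.  The population generator
has its own seed so one population can be shared across matched-seed
scenario comparisons.
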