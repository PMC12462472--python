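# Model and methods

`fishweb` simulates open-access multispecies fisheries embedded in
allometrically structured food webs. A run couples three layers: a
body-mass-based web topology, nutrient-limited biomass dynamics, and
profit-driven fleet dynamics. This note documents the model equations, the
parameter defaults and why they were chosen, the simulation protocol, the
desk-scale study conditions, and the known limitations.

## Web topology

A community holds three guilds with log10 body masses drawn uniformly per
guild: plants on [0, 6], invertebrates on [2, 6], fish on [4, 10]
(defaults 30 / 67 / 33 species). The likelihood that consumer *i* captures
resource *j* follows a Ricker niche in the mass ratio,

    L_ij = (x e^(1-x))^gamma,   x = m_i / (m_j R_opt),

which peaks at 1 when `m_i = R_opt m_j`. Likelihoods at or below 0.01 are
cut to zero; plants never consume; self-links are excluded. Webs are
resampled (capped at 1000 attempts) until every plant has a consumer and
every consumer a resource. `R_opt = 100` and `gamma = 2` are the standard
allometric trophic-network choices; both are config-exposed and can be
randomized per web by overriding the generator.

Trophic levels are prey-averaged: `TL = 1` for plants,
`TL_i = 1 + mean(TL_j over resources j)` for consumers, solved as the
linear system `(I - W) TL = 1` with the row-normalized diet matrix `W`.
On the surviving post-burn-in web, levels are recomputed on the living
subgraph; a living consumer whose resources all died (a transient starver)
keeps its full-topology level.

## Ecological dynamics

Two limiting nutrients are supplied chemostat-style,

    dN_l/dt = D (S_l - N_l) - v_l * sum_plants r_i G_i B_i,

with Liebig growth `G_i = min_l N_l / (K_il + N_l)`. Plants grow at
`r_i = m_i^-0.25` and all organisms pay metabolism `x_i = y_i m_i^-0.25`
with guild-specific intercepts. Biomass dynamics are

    plants:   dB_i/dt = r_i G_i B_i - sum_k B_k F_ki - x_i B_i
    animals:  dB_i/dt = B_i sum_k e_k F_ik - sum_k B_k F_ki - x_i B_i

with a multi-resource functional response per unit consumer biomass

    F_ij = omega_i b_ij B_j^(1+q)
           / (1 + c_i B_i + omega_i sum_k h_ik b_ik B_k^(1+q)) / m_i.

`omega_i` is 1 over the number of resources; `b_ij` combines allometric
encounter rates with the Ricker likelihood (herbivory scales with consumer
mass only, carnivory with both masses); `h_ik = h0 m_i^eta_i m_k^eta_k` is
an allometric handling time (the pairwise handling time enters the sum —
the standard multi-species form of this response). The Hill exponent
`1 + q` is drawn once per web; `c_i` is consumer interference.

Species whose biomass reaches 1e-6 are extinct: set to exactly zero and
masked for the rest of the run (an absorbing state implemented as an
integration event, see below).

### Parameter defaults

| parameter | default | unit | note |
|---|---|---|---|
| D | 0.25 | 1/day | nutrient turnover |
| S_l | (10, 10) | concentration | nutrient supply |
| v_l | (1, 0.5) | — | plant nutrient content |
| K_il | U[0.1, 0.2] | concentration | per plant and nutrient |
| y (plant, invert, fish) | 0.138, 0.314, 0.88 | — | metabolic intercepts |
| metabolic exponent | 0.25 | — | matches the growth allometry |
| e (plant, animal) | 0.545, 0.906 | — | assimilation efficiency |
| q | U[0, 1] per web | — | Hill exponent is 1+q |
| c_i | U[0.8, 1.2] | area/mass | consumer interference |
| h0, eta_i, eta_j | 0.4, -0.48, -0.66 | — | handling time allometry |
| b0 (herb = carn) | 15 | — | capture intercepts |
| beta_consumer, beta_resource | 0.47, 0.30 | — | capture exponents |

Rates are per day (one model time unit = 1 day; "100 years" = 36,500
units), following the per-day convention of metabolic scaling in this
model family. The nutrient, assimilation, handling and interference values
are the standard allometric trophic-network literature choices. The
capture intercept and resource exponent were fixed once so that consumers
across the ten-decade mass span can cover metabolism at the stock
densities the nutrient supply supports; with weaker capture rates the
upper trophic levels starve wholesale and almost no web passes the
fish-survival filter. With these defaults roughly a third of 50-species
webs keep at least 75% of their fish through the burn-in (larger fish
assemblages are harder to sustain than the web average, which is the
point of the filter).

## Fisheries

Each fishery is a fleet of identical vessels targeting one fish species.
Catch saturates in stock biomass (hyperstability),

    catch_i = catch_max * B_i / (catch_max / clearance_i + B_i) * V_i,

implemented in the algebraically equivalent form
`V catch_max clearance B / (catch_max + clearance B)` which is finite when
clearance reaches zero. The market clears at

    p_i = (catch_i / p_base_i)^(1/PED),   PED = -1.15,

with the species demand scale `p_base_i = p_base m_i / m̄` (mean consumer
mass m̄), so larger fish fetch higher prices; a uniform-price sensitivity
switch removes the mass scaling. Revenue is computed as
`p_base_i^(-1/PED) catch^(1+1/PED)`; for elastic demand the exponent on
catch is positive, so revenue (not price) extends continuously to zero
catch — this guards the price singularity. Per-vessel cost is
`maintenance + scaling * clearance / gear`, profit is
`pi = revenue - cost * V`, and both effort variables adapt to profit:

    dV/dt = mu_v pi,    dclearance/dt = mu_c pi,

with `mu_v = 0.01` and `mu_c = 30 mu_v` (clearance tracks daily activity,
vessel counts change on a monthly scale). Clearance is clipped at zero —
profit dynamics can otherwise push it negative under sustained losses. A
fleet whose vessel density falls below 1e-10 exits irreversibly.

An important structural consequence of elastic demand: marginal revenue
diverges as catch goes to zero, so a fishery with a living stock always
has positive profit at sufficiently small fleet size. Fleets therefore
never exit for purely economic reasons; exits happen after the target
stock collapses (extinction, or clearance exhausted during the crash).
Interior equilibria with a live fleet satisfy the open-access zero-profit
condition to solver precision.

### Economic defaults and calibration

`p_base = 3.0`, `catch_max = 1`, `clearance0 = 0.5`, `maintenance = 1`,
`gear = 1`, `scaling = 0.01`. The open-access equilibrium fleet demands a
catch that grows essentially linearly with the species demand scale, hence
with target body mass, while stock productivity peaks at mid trophic
levels. `fishweb.calibration` exposes the zero-profit surface
(`breakeven_vessel_density`, `breakeven_p_base`); the defaults were chosen
with it so that (i) a single fishery on a mid-trophic-level fish breaks
even at its pristine stock, and (ii) fishing pressure is strong enough
that mis-targeted fisheries actually fail — top-predator fisheries demand
catches orders of magnitude above the near-zero productivity of their
stocks and collapse them, which is the regime the scenario comparison is
about. These six values are the least constrained part of the model and
are flagged prominently in the config.

## Scenarios

Six target-selection rules on the post-burn-in web (three fisheries, fish
targets only by default): random; price (top-3 demand scale, i.e. the
largest fish); productivity (top-3 productivity at the burn-in end state);
trophically balanced (maximize summed pairwise TL differences; for three
targets this takes the extremes plus the species nearest their midpoint,
spreading the set evenly); distanced (maximize summed pairwise undirected
link distances, exhaustively for up to 5000 candidate subsets, otherwise
greedy with local-swap refinement and a recorded optimality flag;
disconnected pairs count as the species total); similar (a uniformly drawn
focal species plus its nearest trophic-level neighbours, with exact-TL
ties — e.g. herbivores at level 2 — broken uniformly at random). The
focal-draw variant makes the Similar ensemble span mean trophic levels; a
config switch selects the globally tightest TL window instead (which is
consecutive in TL order, so the search is exact). Productivity is
`B_i sum_k e_k F_ik - x_i B_i` by default ("population" basis); a
"mass_specific" switch ranks by the per-unit-biomass surplus instead,
which tracks the allometry of production more directly. Link distances are
undirected because trophic links are treated as interaction channels, not
flows, for the purpose of spreading disturbances.

## Simulation protocol

Burn-in ("pristine"): biomasses start uniform on (0, 10], nutrients at
S/2, integrate 100 model-years without fisheries. Webs keeping less than
75% of their fish are discarded. Harvest: on a kept baseline, resolve the
scenario, draw initial vessel densities from U[1e-4, 1e-3], integrate the
coupled system 100 model-years. All six scenarios reuse the same burn-in.

Integration uses LSODA with rtol 1e-8 / atol 1e-12 by default. Extinction
and fleet exit are terminal events (root-finding on min living biomass
minus 1e-6, and min active vessel density minus 1e-10) followed by a
restart with the crossing state zeroed and masked — thresholds interact
badly with loose tolerances, and the event formulation keeps the absorbing
semantics exact. Runs can stop early once the maximum relative derivative
over the living state falls below a configurable tolerance (default 1e-7
per day, not tested before day 200); this "numerically steady" stop is
what makes long horizons affordable. A wall-clock timeout per run flags
rather than raises.

Indicators per (web, scenario) run: species persistence (living species at
harvest end over living species at burn-in end; a config switch uses the
pre-burn-in richness), biomass change of non-harvested species
((sum B_f - sum B_p)/sum B_p), sustained total catch and revenue (pooled
over surviving fleets, averaged over the final 10% of the integrated span,
with a stationarity flag when total catch drifts more than 1% across the
window), and the number of sustained fleets. The overall effect indicator
min-max rescales each of the five across the ensemble and averages them
per run; an indicator constant across the ensemble rescales to 0.5 so the
mean stays defined. A coefficient-of-variation stability metric over the
final window is available but off by default.

Seeding is hierarchical (master seed -> per-web streams -> per-scenario
streams), recorded in per-web JSON manifests that also make ensembles
resumable: a restarted ensemble reproduces the identical table.

## Desk-scale study conditions

The full-scale conditions (130-species webs, 800 replicates, 100-year
phases) are the package defaults but need cluster time. The replicated
results shipped with the package use `reduced_config()`: 50-species webs
(10 plants / 20 invertebrates / 20 fish), 5,000-day burn-in, 8,000-day
harvest, rtol 1e-7 / atol 1e-10, 50 kept webs x 6 scenarios. Web size is
the smallest at which the fish assemblage still spans the trophic range
the scenario bands refer to — the largest fish must reach levels above 5
so that price-driven selection is trophically separated from the
mid-level band; the invertebrate and fish counts keep the full-web guild
proportions roughly intact within that constraint. Under these conditions
the Similar scenario attains the highest fraction of runs keeping all
three fisheries, the Price scenario loses essentially all fisheries
through stock collapse, and the overall effect indicator is higher for
runs harvesting a tight band of mid-trophic-level species than for runs
targeting the trophic extremes.

One contrast does not carry over from the full-scale study: ranked by the
mean number of sustained fisheries, Productivity does not fall to the
bottom here. In webs of this size the most productive fish sit at mid
trophic levels (under either productivity basis), and because demand
scales with body mass their fisheries face modest open-access pressure
and usually persist. Reproducing a bottom-ranked Productivity scenario
evidently requires parameter structure beyond what the model description
fixes; the corresponding check is left failing rather than redefined.

## What the generator does and does not emulate

The synthetic webs reproduce size-structured niche topology, nutrient
limitation, allometric rate scaling and open-access market feedbacks. They
do not include temperature, space or migration, age structure, stochastic
environments, by-catch, multi-species fleets, discounting, or management
(quotas); empirical webs are out of scope. Passing tests therefore
establish internal consistency of the model and the robustness of the
qualitative trophic-level contrasts within this model family — not
predictions for any specific real fishery.

## Numerical notes and limitations

- Biomasses cannot cross zero: the extinction event at 1e-6 fires first
  and zeroes the state exactly; nutrient concentrations stay below supply.
- `B^(1+q)` is evaluated on biomass clipped at zero to avoid NaNs from
  solver micro-negativity within tolerance.
- The trophic-level solve is dense (`numpy.linalg.solve`); webs here are
  far below sizes where sparsity would matter.
- Subset optimizers are exact below 5000 candidate subsets; beyond that a
  greedy + local-swap search is used and flagged as possibly suboptimal.
- Equilibrium indicators depend mildly on the 10% averaging window; the
  stationarity flag in the output indicates when a run had not settled.
- Keep rates and scenario contrasts are parameter-sensitive, most of all
  to the capture intercept and the demand scale; both are deliberately
  exposed rather than hidden in the code.
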