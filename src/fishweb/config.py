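"""Configuration tree for the food-web / fishery simulator.

Every numeric constant of the model lives here so that a YAML file can
override any of them.  Defaults reproduce the study conditions: 130-species
webs (30 plants / 67 invertebrates / 33 fish), 100 model-years (36,500 days)
of pristine and of harvested dynamics, three single-species open-access
fisheries.  One model time unit is one day.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "WebConfig",
    "EcoConfig",
    "EconConfig",
    "ScenarioConfig",
    "RunConfig",
    "SimulationConfig",
    "load_config",
    "save_config",
]

DAYS_PER_YEAR = 365.0


@dataclass
class WebConfig:
    """Food-web generation: guild sizes, mass ranges and the Ricker niche."""

    n_plants: int = 30
    n_invertebrates: int = 67
    n_fish: int = 33
    #: log10 body-mass ranges per guild (uniform sampling)
    plant_mass_range: tuple[float, float] = (0.0, 6.0)
    invertebrate_mass_range: tuple[float, float] = (2.0, 6.0)
    fish_mass_range: tuple[float, float] = (4.0, 10.0)
    #: optimal consumer/resource body-mass ratio of the Ricker niche
    r_opt: float = 100.0
    #: niche-width exponent of the Ricker curve
    gamma: float = 2.0
    #: capture likelihoods at or below this value are cut to zero
    link_threshold: float = 0.01
    #: viability resampling cap before generation errors out
    max_attempts: int = 1000

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_plants, self.n_invertebrates, self.n_fish)


@dataclass
class EcoConfig:
    """Ecological dynamics: nutrients, allometric rates, functional response.

    Rates are per day; body masses are in arbitrary mass units on the
    sampled log10 scales.  Values not fixed by the model description follow
    the allometric trophic-network literature this model family builds on
    and are exposed for sensitivity analysis.
    """

    # --- nutrient model (two limiting nutrients) ---
    nutrient_turnover: float = 0.25          # D
    nutrient_supply: tuple[float, float] = (10.0, 10.0)   # S_l
    nutrient_content: tuple[float, float] = (1.0, 0.5)    # v_l
    half_saturation_range: tuple[float, float] = (0.1, 0.2)  # K_il ~ U
    # --- allometry ---
    growth_exponent: float = -0.25           # r_i = m_i**growth_exponent
    metabolic_exponent: float = 0.25         # x_i = y_i * m_i**-a
    metabolic_intercepts: tuple[float, float, float] = (0.138, 0.314, 0.88)
    # --- assimilation ---
    e_plant: float = 0.545
    e_animal: float = 0.906
    # --- functional response ---
    hill_q_range: tuple[float, float] = (0.0, 1.0)   # one q per web
    interference_range: tuple[float, float] = (0.8, 1.2)  # c_i ~ U
    h0: float = 0.4
    eta_consumer: float = -0.48
    eta_resource: float = -0.66
    b0_herbivore: float = 15.0
    b0_carnivore: float = 15.0
    beta_consumer: float = 0.47
    beta_resource: float = 0.30
    # --- thresholds / solver ---
    extinction_threshold: float = 1e-6
    rtol: float = 1e-8
    atol: float = 1e-12


@dataclass
class EconConfig:
    """Open-access fleet economics.

    `p_base`, `catch_max`, `clearance0`, `maintenance`, `gear` and `scaling`
    are calibrated (see :mod:`fishweb.calibration`) so that a single fishery
    on a mid-trophic-level fish can break even; the qualitative scenario
    contrasts depend on break-even feasibility, not on the exact values.
    """

    ped: float = -1.15                      # price elasticity of demand
    p_base: float = 3.0                     # demand-scale parameter
    uniform_price: bool = False             # sensitivity switch (Eq.-14 off)
    catch_max: float = 1.0                  # mass/day per vessel
    clearance0: float = 0.5                 # area/day per vessel at start
    maintenance: float = 1.0                # currency/day per vessel
    gear: float = 1.0
    scaling: float = 0.01                   # currency·day/area
    mu_vessel: float = 0.01                 # vessel-density adaptation speed
    mu_clearance_factor: float = 30.0       # mu_c = factor * mu_v
    v0_range: tuple[float, float] = (1e-4, 1e-3)
    exit_threshold: float = 1e-10

    @property
    def mu_clearance(self) -> float:
        return self.mu_vessel * self.mu_clearance_factor


@dataclass
class ScenarioConfig:
    """Target-species selection."""

    n_fisheries: int = 3
    #: admit invertebrates as targets (sensitivity switch); default fish-only
    allow_invertebrates: bool = False
    #: "post_pristine" recomputes trophic levels on the surviving web,
    #: "initial" uses the full generated topology
    tl_basis: str = "post_pristine"
    #: Similar scenario: draw a random focal species ("focal") or take the
    #: globally tightest trophic-level window ("global")
    similar_mode: str = "focal"
    #: restrict the Similar focal draw to a trophic band
    similar_band: str = "free"  # low | intermediate | high | free
    #: productivity ranking basis: "mass_specific" (per-unit-biomass
    #: surplus, tracks allometry) or "population" (stock-weighted)
    productivity_basis: str = "population"
    #: exhaustive subset search only below this many candidate subsets
    exhaustive_limit: int = 5000


@dataclass
class RunConfig:
    """Integration protocol for pristine and harvest phases."""

    pristine_days: float = 100 * DAYS_PER_YEAR
    harvest_days: float = 100 * DAYS_PER_YEAR
    #: minimum fraction of fish surviving the pristine run to keep a web
    fish_survival_threshold: float = 0.75
    #: number of saved trajectory samples per phase
    n_save: int = 201
    #: initial biomasses ~ U(0, biomass_init_max]
    biomass_init_max: float = 10.0
    #: nutrients start at this fraction of their supply concentration
    nutrient_init_fraction: float = 0.5
    #: stop a phase early once max |dy/dt|/y over living state falls below
    #: this tolerance (None disables early stopping)
    steady_tolerance: float | None = 1e-7
    #: do not test the steady-state stop before this time (transient guard)
    steady_min_days: float = 200.0
    #: wall-clock cap per (web, scenario) run, seconds; None disables
    timeout_seconds: float | None = 1200.0
    #: fraction of the integrated span used as the equilibrium window
    equilibrium_window: float = 0.1


@dataclass
class SimulationConfig:
    web: WebConfig = field(default_factory=WebConfig)
    eco: EcoConfig = field(default_factory=EcoConfig)
    econ: EconConfig = field(default_factory=EconConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    run: RunConfig = field(default_factory=RunConfig)
    n_webs: int = 800
    master_seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        def build(klass, data):
            if data is None:
                return klass()
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for key, value in data.items():
                if key not in fields:
                    raise KeyError(f"unknown config key {key!r} for {klass.__name__}")
                ftype = fields[key].type
                if isinstance(value, list) and "tuple" in str(ftype):
                    value = tuple(value)
                kwargs[key] = value
            return klass(**kwargs)

        d = dict(d)
        return cls(
            web=build(WebConfig, d.pop("web", None)),
            eco=build(EcoConfig, d.pop("eco", None)),
            econ=build(EconConfig, d.pop("econ", None)),
            scenario=build(ScenarioConfig, d.pop("scenario", None)),
            run=build(RunConfig, d.pop("run", None)),
            **d,
        )


def reduced_config(
    n_webs: int = 50, master_seed: int = 0
) -> SimulationConfig:
    """Desk-scale study conditions: 50-species webs (10 plants /
    20 invertebrates / 20 fish), shorter pristine (5,000 d) and harvest
    (8,000 d) phases and slightly relaxed solver tolerances.  The web is
    the smallest whose fish assemblage still spans trophic levels beyond 5,
    so that the trophic-band structure of the scenario comparison survives
    the scale-down.  These are the conditions under which the qualitative
    scenario contrasts are evaluated in the test suite and the acceptance
    script; the full-scale conditions remain the plain defaults.
    """
    config = SimulationConfig(n_webs=n_webs, master_seed=master_seed)
    config.web.n_plants = 10
    config.web.n_invertebrates = 20
    config.web.n_fish = 20
    config.run.pristine_days = 5000.0
    config.run.harvest_days = 8000.0
    config.eco.rtol = 1e-7
    config.eco.atol = 1e-10
    return config


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
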