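"""Break-even calibration of the fleet economics defaults.

The cost and demand parameters (`p_base`, `catch_max`, `clearance0`,
`maintenance`, `gear`, `scaling`) are not pinned down by the model
structure; what matters for the scenario contrasts is that a single fishery
on a mid-trophic-level fish can break even at plausible stock densities,
while fisheries on very small (cheap) fish run losses and fisheries on very
large (scarce) fish overshoot their stock.  This module computes the
zero-profit surface so that defaults can be chosen — and audited — against
that requirement.
"""

from __future__ import annotations

from .config import EconConfig
from .economics import catch_rate, cost_per_vessel, revenue_from_catch

__all__ = ["breakeven_vessel_density", "breakeven_p_base", "profit_at"]


def profit_at(
    B: float,
    V: float,
    mass_ratio: float,
    config: EconConfig,
    clearance: float | None = None,
) -> float:
    """Fleet profit (currency/day) at stock biomass ``B`` and vessel
    density ``V`` for a target whose mass is ``mass_ratio`` times the mean
    consumer mass."""
    clearance = config.clearance0 if clearance is None else clearance
    catch = catch_rate(B, config.catch_max, clearance, V)
    p_base_i = config.p_base * mass_ratio if not config.uniform_price else config.p_base
    rev = revenue_from_catch(catch, p_base_i, config.ped)
    cost = cost_per_vessel(config.maintenance, config.scaling, clearance, config.gear)
    return float(rev - cost * V)


def breakeven_vessel_density(
    B: float, mass_ratio: float, config: EconConfig,
    clearance: float | None = None,
) -> float:
    """Vessel density V* with zero profit at stock ``B`` (open-access
    equilibrium fleet size).  Revenue ~ V^(1+1/PED) is concave in V, so the
    zero-profit point is unique; solved in closed form."""
    clearance = config.clearance0 if clearance is None else clearance
    per_vessel_catch = catch_rate(B, config.catch_max, clearance, 1.0)
    if per_vessel_catch <= 0:
        return 0.0
    p_base_i = config.p_base * mass_ratio if not config.uniform_price else config.p_base
    cost = cost_per_vessel(config.maintenance, config.scaling, clearance, config.gear)
    expo = 1.0 + 1.0 / config.ped          # in (0, 1) for |PED| > 1
    # revenue = pb^(-1/ped) * (q*V)^expo  = cost * V  at the equilibrium
    coeff = p_base_i ** (-1.0 / config.ped) * per_vessel_catch**expo / cost
    return float(coeff ** (1.0 / (1.0 - expo)))


def breakeven_p_base(
    B: float,
    V: float,
    mass_ratio: float,
    config: EconConfig,
    clearance: float | None = None,
) -> float:
    """The demand scale p_base making profit exactly zero at (B, V)."""
    clearance = config.clearance0 if clearance is None else clearance
    catch = catch_rate(B, config.catch_max, clearance, V)
    if catch <= 0:
        raise ValueError("no catch at the requested state")
    cost = cost_per_vessel(config.maintenance, config.scaling, clearance, config.gear)
    # cost*V = (pb * ratio)^(-1/ped) * catch^(1+1/ped)
    target = cost * V
    pb_i = (target / catch ** (1.0 + 1.0 / config.ped)) ** (-config.ped)
    return float(pb_i / mass_ratio)
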