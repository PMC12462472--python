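"""Open-access fishery fleets: catch, price, cost, profit, adaptation.

Each fleet targets one species.  Catch saturates in stock biomass
(hyperstability):

    catch_i = catch_max_i * B / (catch_max_i / clearance_i + B) * V_i

The market clears at a demand-elastic price p_i = (catch_i / p_base_i)^(1/PED)
with PED = -1.15, where the species demand scale p_base_i = p_base * m_i / m̄
values larger fish higher.  Vessels and clearance adapt to profit,
dV/dt = mu_v * pi and dclearance/dt = mu_c * pi, so interior equilibria are
zero-profit.  A fleet whose vessel density falls below 1e-10 exits for good.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import EconConfig

__all__ = [
    "FleetSet",
    "catch_rate",
    "market_price",
    "revenue_from_catch",
    "species_price_scale",
    "cost_per_vessel",
    "fleet_profit",
    "fleet_derivatives",
    "init_fleets",
]


@dataclass
class FleetSet:
    """Parameter and state arrays for a set of single-species fleets."""

    target: np.ndarray          # species ids, shape (nf,)
    catch_max: np.ndarray
    maintenance: np.ndarray
    gear: np.ndarray
    scaling: np.ndarray
    p_base_i: np.ndarray
    ped: float
    mu_vessel: float
    mu_clearance: float
    V0: np.ndarray
    clearance0: np.ndarray
    exit_threshold: float
    active: np.ndarray = field(default=None)
    V_final: np.ndarray | None = None
    clearance_final: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.active is None:
            self.active = np.ones(self.n, dtype=bool)

    @property
    def n(self) -> int:
        return int(np.asarray(self.target).size)

    def copy(self) -> "FleetSet":
        import copy as _copy

        return _copy.deepcopy(self)


def catch_rate(B, catch_max, clearance, V):
    """Saturating harvest rate (mass/day).

    Written as V * catch_max * clearance * B / (catch_max + clearance * B),
    algebraically identical to the half-saturation form
    catch_max * B / (catch_max/clearance + B) * V but finite at zero
    clearance.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("stock biomass must be non-negative")
    clearance = np.clip(np.asarray(clearance, dtype=float), 0.0, None)
    denom = catch_max + clearance * B
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, V * catch_max * clearance * B / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def market_price(catch, p_base_i, ped: float):
    """Demand-clearing price p = (catch / p_base_i)^(1/PED); undefined at
    zero catch (use :func:`revenue_from_catch` which takes the limit)."""
    catch = np.asarray(catch, dtype=float)
    if np.any(catch <= 0):
        raise ValueError("price is undefined at zero catch")
    return (catch / p_base_i) ** (1.0 / ped)


def revenue_from_catch(catch, p_base_i, ped: float):
    """Revenue p * catch = p_base_i^(-1/PED) * catch^(1 + 1/PED).

    For elastic demand (|PED| > 1) the exponent on catch is positive, so
    revenue tends to 0 as catch tends to 0; that limit defines the value at
    zero catch without evaluating the (singular) price.
    """
    catch = np.asarray(catch, dtype=float)
    expo = 1.0 + 1.0 / ped
    with np.errstate(invalid="ignore"):
        rev = np.where(
            catch > 0,
            np.asarray(p_base_i, dtype=float) ** (-1.0 / ped)
            * np.where(catch > 0, catch, 1.0) ** expo,
            0.0,
        )
    return rev if rev.ndim else float(rev)


def species_price_scale(m_i, mean_consumer_mass: float, p_base: float,
                        uniform_price: bool = False):
    """Demand scale p_base_i = p_base * (m_i / m̄); larger fish fetch higher
    prices.  The uniform-price sensitivity switch removes the mass scaling."""
    m_i = np.asarray(m_i, dtype=float)
    if np.any(m_i <= 0) or mean_consumer_mass <= 0:
        raise ValueError("masses must be positive")
    if uniform_price:
        out = np.broadcast_to(float(p_base), m_i.shape).copy()
        return out if out.ndim else float(out)
    out = p_base * m_i / mean_consumer_mass
    return out if out.ndim else float(out)


def cost_per_vessel(maintenance, scaling, clearance, gear):
    """cost_i = maintenance + scaling * clearance / gear (currency/day)."""
    clearance = np.clip(np.asarray(clearance, dtype=float), 0.0, None)
    return maintenance + scaling * clearance / gear


def fleet_profit(catch, fleets: FleetSet, clearance, V):
    """pi_i = revenue_i - cost_i * V_i for each fleet."""
    rev = revenue_from_catch(catch, fleets.p_base_i, fleets.ped)
    cost = cost_per_vessel(fleets.maintenance, fleets.scaling, clearance, fleets.gear)
    return rev - cost * np.asarray(V, dtype=float)


def fleet_derivatives(profit, fleets: FleetSet):
    """(dV/dt, dclearance/dt) = (mu_v * pi, mu_c * pi) for active fleets."""
    pi = np.where(fleets.active, np.asarray(profit, dtype=float), 0.0)
    return fleets.mu_vessel * pi, fleets.mu_clearance * pi


def init_fleets(
    targets,
    mass: np.ndarray,
    is_plant: np.ndarray,
    is_consumer: np.ndarray,
    config: EconConfig,
    rng: np.random.Generator,
) -> FleetSet:
    """One fleet per distinct non-plant target, with vessel densities drawn
    uniformly from the configured starting range."""
    targets = np.asarray(targets, dtype=int)
    if targets.size != np.unique(targets).size:
        raise ValueError("duplicate fishery targets")
    if np.any(is_plant[targets]):
        raise ValueError("plants are not harvested")
    nf = targets.size
    mean_consumer_mass = float(mass[is_consumer].mean())
    p_base_i = species_price_scale(
        mass[targets], mean_consumer_mass, config.p_base, config.uniform_price
    )
    return FleetSet(
        target=targets,
        catch_max=np.full(nf, config.catch_max),
        maintenance=np.full(nf, config.maintenance),
        gear=np.full(nf, config.gear),
        scaling=np.full(nf, config.scaling),
        p_base_i=np.atleast_1d(np.asarray(p_base_i, dtype=float)),
        ped=config.ped,
        mu_vessel=config.mu_vessel,
        mu_clearance=config.mu_clearance,
        V0=rng.uniform(*config.v0_range, size=nf),
        clearance0=np.full(nf, config.clearance0),
        exit_threshold=config.exit_threshold,
    )
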