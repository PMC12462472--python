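"""Ricker-niche food-web generation.

Species pools are three guilds (plants, invertebrates, fish) with log10
body masses drawn uniformly from guild-specific ranges.  Feeding links are
assigned by the Ricker capture-likelihood curve

    L_ij = ( (m_i / (m_j * R_opt)) * exp(1 - m_i / (m_j * R_opt)) ) ** gamma

for consumer i on resource j, thresholded at 0.01 so that implausible
body-mass ratios yield no interaction.  Generated webs are resampled until
every plant has a consumer and every consumer has a resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import WebConfig

__all__ = [
    "PLANT",
    "INVERTEBRATE",
    "FISH",
    "GUILD_NAMES",
    "SpeciesPool",
    "FoodWeb",
    "sample_body_masses",
    "ricker_likelihood",
    "build_topology",
    "trophic_levels",
    "effective_trophic_levels",
    "check_viability",
    "generate_food_web",
    "web_to_tables",
    "web_from_tables",
    "save_web",
    "load_web",
]

PLANT, INVERTEBRATE, FISH = 0, 1, 2
GUILD_NAMES = ("plant", "invertebrate", "fish")


@dataclass
class SpeciesPool:
    """Guild membership and body masses of a species community."""

    guild: np.ndarray       # int codes, shape (n,)
    log10_mass: np.ndarray  # shape (n,)

    def __post_init__(self) -> None:
        self.guild = np.asarray(self.guild, dtype=np.int64)
        self.log10_mass = np.asarray(self.log10_mass, dtype=float)
        if self.guild.shape != self.log10_mass.shape:
            raise ValueError("guild and mass arrays must align")

    @property
    def n_species(self) -> int:
        return self.guild.size

    @property
    def mass(self) -> np.ndarray:
        return 10.0 ** self.log10_mass

    @property
    def is_plant(self) -> np.ndarray:
        return self.guild == PLANT

    @property
    def is_consumer(self) -> np.ndarray:
        return self.guild != PLANT

    @property
    def is_fish(self) -> np.ndarray:
        return self.guild == FISH

    @property
    def counts(self) -> tuple[int, int, int]:
        return tuple(int(np.sum(self.guild == g)) for g in (PLANT, INVERTEBRATE, FISH))


@dataclass
class FoodWeb:
    """A species pool plus its thresholded feeding topology.

    ``likelihood[i, j]`` is the Ricker capture likelihood of consumer i on
    resource j after thresholding; ``adjacency = likelihood > 0``.
    ``omega`` holds the relative consumption rate 1 / (number of resources)
    for consumers and 0 for plants.
    """

    pool: SpeciesPool
    likelihood: np.ndarray
    r_opt: float
    gamma: float
    link_threshold: float = 0.01
    _tl: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_species(self) -> int:
        return self.pool.n_species

    @property
    def adjacency(self) -> np.ndarray:
        return self.likelihood > 0

    @property
    def n_resources(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def omega(self) -> np.ndarray:
        nres = self.n_resources
        with np.errstate(divide="ignore"):
            w = np.where(nres > 0, 1.0 / np.maximum(nres, 1), 0.0)
        return w

    @property
    def trophic_level(self) -> np.ndarray:
        if self._tl is None:
            self._tl = trophic_levels(self.adjacency, self.pool.is_plant)
        return self._tl


def _mass_ranges(config: WebConfig) -> dict[int, tuple[float, float]]:
    return {
        PLANT: config.plant_mass_range,
        INVERTEBRATE: config.invertebrate_mass_range,
        FISH: config.fish_mass_range,
    }


def sample_body_masses(
    counts: tuple[int, int, int],
    rng: np.random.Generator,
    config: WebConfig | None = None,
) -> SpeciesPool:
    """Draw a species pool with i.i.d. uniform log10 masses per guild.

    Species are ordered plants, then invertebrates, then fish.
    """
    config = config or WebConfig()
    if len(counts) != 3 or any(int(c) != c or c < 0 for c in counts):
        raise ValueError("counts must be three non-negative integers")
    if sum(counts) <= 0:
        raise ValueError("at least one species is required")
    ranges = _mass_ranges(config)
    guilds, masses = [], []
    for g, n in zip((PLANT, INVERTEBRATE, FISH), counts):
        lo, hi = ranges[g]
        guilds.append(np.full(int(n), g))
        masses.append(rng.uniform(lo, hi, size=int(n)))
    return SpeciesPool(np.concatenate(guilds), np.concatenate(masses))


def ricker_likelihood(m_i, m_j, r_opt: float, gamma: float):
    """Capture likelihood of a consumer of mass ``m_i`` on a resource of
    mass ``m_j`` under the Ricker niche; peaks at 1 when m_i = R_opt * m_j."""
    m_i = np.asarray(m_i, dtype=float)
    m_j = np.asarray(m_j, dtype=float)
    if np.any(m_i <= 0) or np.any(m_j <= 0) or r_opt <= 0 or gamma <= 0:
        raise ValueError("masses, r_opt and gamma must be positive")
    x = m_i / (m_j * r_opt)
    out = (x * np.exp(1.0 - x)) ** gamma
    return out if out.ndim else float(out)


def build_topology(
    pool: SpeciesPool,
    r_opt: float = 100.0,
    gamma: float = 2.0,
    link_threshold: float = 0.01,
) -> FoodWeb:
    """Evaluate the Ricker likelihood for every consumer-resource pair,
    threshold it, and package the result as a :class:`FoodWeb`.

    Plants have no outgoing links and self-links are excluded.
    """
    if pool.n_species == 0:
        raise ValueError("empty species pool")
    m = pool.mass
    L = ricker_likelihood(m[:, None], m[None, :], r_opt, gamma)
    L = np.asarray(L, dtype=float)
    L[pool.is_plant, :] = 0.0           # plants do not consume
    np.fill_diagonal(L, 0.0)            # no cannibalism
    L[L <= link_threshold] = 0.0
    return FoodWeb(pool, L, r_opt=r_opt, gamma=gamma, link_threshold=link_threshold)


def trophic_levels(adjacency: np.ndarray, is_basal: np.ndarray) -> np.ndarray:
    """Prey-averaged trophic levels: TL = 1 for basal species and
    TL_i = 1 + mean(TL of resources of i) otherwise, from the linear system
    (I - W) TL = 1 where W row-normalizes the adjacency."""
    A = np.asarray(adjacency, dtype=float)
    is_basal = np.asarray(is_basal, dtype=bool)
    n = A.shape[0]
    nres = A.sum(axis=1)
    consumers = ~is_basal
    if np.any(consumers & (nres == 0)):
        bad = np.flatnonzero(consumers & (nres == 0))
        raise ValueError(f"consumers with no resources: {bad.tolist()}")
    W = np.zeros_like(A)
    rows = nres > 0
    W[rows] = A[rows] / nres[rows, None]
    W[is_basal] = 0.0
    tl = np.linalg.solve(np.eye(n) - W, np.ones(n))
    return tl


def effective_trophic_levels(web: FoodWeb, alive: np.ndarray) -> np.ndarray:
    """Trophic levels restricted to the living sub-web.

    Living consumers whose resources have all gone extinct (transient
    starvers) fall back to their full-topology trophic level.  Entries for
    dead species are NaN.
    """
    alive = np.asarray(alive, dtype=bool)
    A = web.adjacency & alive[None, :] & alive[:, None]
    is_basal = web.pool.is_plant.copy()
    nres = A.sum(axis=1)
    orphan = alive & web.pool.is_consumer & (nres == 0)
    # treat orphans (and dead species) as basal to keep the system
    # solvable, then overwrite their entries
    tl = trophic_levels(A, is_basal | orphan | ~alive)
    tl[orphan] = web.trophic_level[orphan]
    tl = np.where(alive, tl, np.nan)
    return tl


def check_viability(web: FoodWeb) -> bool:
    """True iff every plant has at least one consumer and every consumer at
    least one resource."""
    A = web.adjacency
    plants = web.pool.is_plant
    consumers = web.pool.is_consumer
    plant_eaten = A[:, plants].any(axis=0)
    consumer_fed = A[consumers].any(axis=1)
    return bool(plant_eaten.all() and consumer_fed.all())


def generate_food_web(config: WebConfig, rng: np.random.Generator) -> FoodWeb:
    """Sample pools until a viable topology appears (capped resampling)."""
    for _ in range(config.max_attempts):
        pool = sample_body_masses(config.counts, rng, config)
        web = build_topology(pool, config.r_opt, config.gamma, config.link_threshold)
        if check_viability(web):
            return web
    raise RuntimeError(
        f"no viable web in {config.max_attempts} attempts; "
        "check guild counts and mass ranges"
    )


# --- serialization -----------------------------------------------------------

def web_to_tables(web: FoodWeb) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node table (id, guild, log10 mass, TL) and edge list (consumer,
    resource, likelihood)."""
    nodes = pd.DataFrame(
        {
            "id": np.arange(web.n_species),
            "guild": [GUILD_NAMES[g] for g in web.pool.guild],
            "log10_mass": web.pool.log10_mass,
            "trophic_level": web.trophic_level,
        }
    )
    cons, res = np.nonzero(web.adjacency)
    edges = pd.DataFrame(
        {
            "consumer": cons,
            "resource": res,
            "likelihood": web.likelihood[cons, res],
        }
    )
    return nodes, edges


def web_from_tables(
    nodes: pd.DataFrame,
    edges: pd.DataFrame,
    r_opt: float = 100.0,
    gamma: float = 2.0,
    link_threshold: float = 0.01,
) -> FoodWeb:
    order = np.argsort(nodes["id"].to_numpy())
    nodes = nodes.iloc[order]
    guild = np.array([GUILD_NAMES.index(g) for g in nodes["guild"]])
    pool = SpeciesPool(guild, nodes["log10_mass"].to_numpy())
    L = np.zeros((pool.n_species, pool.n_species))
    L[edges["consumer"].to_numpy(), edges["resource"].to_numpy()] = (
        edges["likelihood"].to_numpy()
    )
    return FoodWeb(pool, L, r_opt=r_opt, gamma=gamma, link_threshold=link_threshold)


def save_web(web: FoodWeb, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    nodes, edges = web_to_tables(web)
    node_path = prefix.with_suffix(".nodes.csv")
    edge_path = prefix.with_suffix(".edges.csv")
    nodes.to_csv(node_path, index=False)
    edges.to_csv(edge_path, index=False)
    return node_path, edge_path


def load_web(prefix: str | Path, **kwargs) -> FoodWeb:
    prefix = Path(prefix)
    nodes = pd.read_csv(prefix.with_suffix(".nodes.csv"), float_precision="round_trip")
    edges = pd.read_csv(prefix.with_suffix(".edges.csv"), float_precision="round_trip")
    return web_from_tables(nodes, edges, **kwargs)
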