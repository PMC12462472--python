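"""Resolving fishery scenarios to concrete target-species sets.

Six scenarios pick the harvested species on the post-pristine web:

* ``random`` — uniform sample without replacement;
* ``price`` — the n species with the highest demand scale (price scales
  linearly with body mass, so these are the largest fish);
* ``productivity`` — the n species with the highest biomass productivity
  (energy influx minus metabolism) at the pristine end state;
* ``distanced`` — the n-subset maximizing the summed pairwise link
  distances on the undirected feeding graph;
* ``balanced`` — the n-subset maximizing the summed pairwise trophic-level
  differences (trophically-balanced harvesting);
* ``similar`` — a random focal species plus its n-1 nearest neighbours in
  trophic level (the tightest trophic band).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import networkx as nx
import numpy as np

from .config import ScenarioConfig
from .dynamics import CommunityState, EcoParams, feeding_rates
from .webs import FoodWeb, effective_trophic_levels

__all__ = [
    "SCENARIOS",
    "ScenarioSpec",
    "TargetSet",
    "species_productivity",
    "link_distance_matrix",
    "harvestable_species",
    "select_targets",
    "classify_similar_band",
]

SCENARIOS = ("random", "price", "productivity", "similar", "balanced", "distanced")

SIMILAR_BANDS = ("low", "intermediate", "high", "free")


@dataclass
class ScenarioSpec:
    name: str
    n_fisheries: int = 3
    allow_invertebrates: bool = False
    similar_band: str = "free"
    similar_mode: str = "focal"   # "focal" | "global"
    productivity_basis: str = "population"

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; one of {SCENARIOS}")
        if self.n_fisheries < 1:
            raise ValueError("need at least one fishery")
        if self.similar_band not in SIMILAR_BANDS:
            raise ValueError(f"similar_band must be one of {SIMILAR_BANDS}")

    @classmethod
    def from_config(cls, name: str, config: ScenarioConfig) -> "ScenarioSpec":
        return cls(
            name=name,
            n_fisheries=config.n_fisheries,
            allow_invertebrates=config.allow_invertebrates,
            similar_band=config.similar_band,
            similar_mode=config.similar_mode,
            productivity_basis=config.productivity_basis,
        )


@dataclass
class TargetSet:
    ids: np.ndarray
    trophic_levels: np.ndarray
    scenario: str
    link_distance_sum: float = np.nan
    optimal: bool = True

    @property
    def mean_tl(self) -> float:
        return float(np.mean(self.trophic_levels))

    @property
    def sd_tl(self) -> float:
        # population SD of the (few) targets, matching the band-width reading
        return float(np.std(self.trophic_levels))

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "ids": [int(i) for i in self.ids],
            "trophic_levels": [float(t) for t in self.trophic_levels],
            "mean_tl": self.mean_tl,
            "sd_tl": self.sd_tl,
            "link_distance_sum": float(self.link_distance_sum),
            "optimal": bool(self.optimal),
        }


def species_productivity(
    state: CommunityState, params: EcoParams, basis: str = "population"
) -> np.ndarray:
    """Productivity (energy influx minus metabolic rate) of each animal at
    a (pristine end) state; zero for plants and for extinct species.

    ``population`` (default) is the stock-level surplus
    B_i sum_k e_k F_ik - x_i B_i (mass/area/day); ``mass_specific`` is the
    per-unit-biomass surplus sum_k e_k F_ik - x_i (1/day), which tracks the
    allometry of production more directly.
    """
    B = np.where(state.alive, np.clip(state.B, 0.0, None), 0.0)
    F = feeding_rates(B, params)
    if basis == "mass_specific":
        prod = np.where(B > 0, F @ params.e_resource - params.x, 0.0)
    elif basis == "population":
        prod = B * (F @ params.e_resource) - params.x * B
    else:
        raise ValueError(f"unknown productivity basis {basis!r}")
    return np.where(params.is_plant, 0.0, prod)


def link_distance_matrix(web: FoodWeb, alive: np.ndarray | None = None) -> np.ndarray:
    """Pairwise shortest-path lengths on the undirected feeding graph of
    living species; disconnected pairs get the species count (an effective
    'farther than any path' distance)."""
    n = web.n_species
    alive = np.ones(n, dtype=bool) if alive is None else np.asarray(alive, bool)
    G = nx.Graph()
    nodes = np.flatnonzero(alive)
    G.add_nodes_from(nodes.tolist())
    cons, res = np.nonzero(web.adjacency)
    for i, j in zip(cons, res):
        if alive[i] and alive[j]:
            G.add_edge(int(i), int(j))
    dist = np.full((n, n), float(n))
    np.fill_diagonal(dist, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(G):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def harvestable_species(
    web: FoodWeb, alive: np.ndarray, allow_invertebrates: bool = False
) -> np.ndarray:
    """Living candidate targets: fish by default, optionally invertebrates."""
    mask = alive & web.pool.is_fish
    if allow_invertebrates:
        mask = alive & web.pool.is_consumer
    return np.flatnonzero(mask)


def _sum_pairwise(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.abs(v[:, None] - v[None, :]).sum() / 2.0)


def _subset_search(candidates, n, score, exhaustive_limit):
    """Maximize `score(tuple_of_ids)` over n-subsets: exhaustive when the
    candidate count allows, otherwise greedy seeding plus local swaps."""
    m = len(candidates)
    if comb(m, n) <= exhaustive_limit:
        best = max(combinations(candidates, n), key=score)
        return np.array(best), True
    # greedy: grow the subset by best marginal gain
    chosen: list = []
    rest = list(candidates)
    while len(chosen) < n:
        best_c = max(rest, key=lambda c: score(tuple(chosen) + (c,)))
        chosen.append(best_c)
        rest.remove(best_c)
    # local swap refinement
    improved = True
    while improved:
        improved = False
        current = score(tuple(chosen))
        for idx in range(n):
            for c in rest:
                trial = chosen.copy()
                swapped_out = trial[idx]
                trial[idx] = c
                if score(tuple(trial)) > current:
                    chosen = trial
                    rest.remove(c)
                    rest.append(swapped_out)
                    current = score(tuple(chosen))
                    improved = True
                    break
            if improved:
                break
    return np.array(chosen), False


def _select_balanced(cands, tl, n, exhaustive_limit):
    if n == 3:
        # sum of pairwise differences of sorted (a, b, c) is 2(c - a):
        # take the extremes, then the middle species closest to their
        # midpoint to spread the set evenly across trophic levels
        order = np.argsort(tl[cands], kind="stable")
        lo, hi = cands[order[0]], cands[order[-1]]
        mid_cands = [c for c in cands if c not in (lo, hi)]
        midpoint = (tl[lo] + tl[hi]) / 2.0
        mid = min(mid_cands, key=lambda c: (abs(tl[c] - midpoint), c))
        return np.array([lo, mid, hi]), True
    return _subset_search(
        list(cands), n, lambda s: _sum_pairwise(tl[list(s)]), exhaustive_limit
    )


def _select_similar(cands, tl, n, rng, band, mode):
    if band != "free":
        bounds = {"low": (-np.inf, 3.0), "intermediate": (3.0, 5.0),
                  "high": (5.0, np.inf)}[band]
        in_band = cands[(tl[cands] >= bounds[0]) & (tl[cands] < bounds[1])]
        focal_pool = in_band if in_band.size else cands
    else:
        focal_pool = cands
    if mode == "global":
        # the minimum-spread subset is consecutive in sorted TL order
        order = cands[np.argsort(tl[cands], kind="stable")]
        windows = [order[k : k + n] for k in range(order.size - n + 1)]
        best = min(windows, key=lambda w: np.std(tl[w]))
        return np.array(best)
    focal = int(rng.choice(focal_pool))
    others = np.array([c for c in cands if c != focal])
    # random permutation first so that exact-TL ties (e.g. herbivores all at
    # trophic level 2) are broken uniformly at random
    perm = rng.permutation(others.size)
    others = others[perm]
    order = np.argsort(np.abs(tl[others] - tl[focal]), kind="stable")
    picked = others[order[: n - 1]]
    return np.concatenate([[focal], picked])


def select_targets(
    spec: ScenarioSpec,
    web: FoodWeb,
    state: CommunityState,
    params: EcoParams,
    rng: np.random.Generator,
    tl: np.ndarray | None = None,
    exhaustive_limit: int = 5000,
) -> TargetSet:
    """Resolve a scenario to a concrete target set on the living web."""
    alive = state.alive
    cands = harvestable_species(web, alive, spec.allow_invertebrates)
    n = spec.n_fisheries
    if cands.size < n:
        raise ValueError(
            f"only {cands.size} harvestable species for {n} fisheries"
        )
    if tl is None:
        tl = effective_trophic_levels(web, alive)
    optimal = True

    if spec.name == "random":
        ids = rng.choice(cands, size=n, replace=False)
    elif spec.name == "price":
        # price scales monotonically with body mass (demand scale ~ m_i)
        order = np.argsort(web.pool.mass[cands], kind="stable")
        ids = cands[order[-n:]]
    elif spec.name == "productivity":
        prod = species_productivity(state, params, spec.productivity_basis)
        order = np.argsort(prod[cands], kind="stable")
        ids = cands[order[-n:]]
    elif spec.name == "balanced":
        ids, optimal = _select_balanced(cands, tl, n, exhaustive_limit)
    elif spec.name == "distanced":
        dist = link_distance_matrix(web, alive)

        def dscore(s):
            idx = np.array(s)
            return float(dist[np.ix_(idx, idx)].sum() / 2.0)

        ids, optimal = _subset_search(list(cands), n, dscore, exhaustive_limit)
    elif spec.name == "similar":
        ids = _select_similar(cands, tl, n, rng, spec.similar_band, spec.similar_mode)
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(spec.name)

    ids = np.asarray(sorted(int(i) for i in ids))
    dist = link_distance_matrix(web, alive)
    dsum = float(dist[np.ix_(ids, ids)].sum() / 2.0)
    return TargetSet(
        ids=ids,
        trophic_levels=tl[ids],
        scenario=spec.name,
        link_distance_sum=dsum,
        optimal=optimal,
    )


def classify_similar_band(trophic_levels: np.ndarray) -> str:
    """Band label for a Similar target set: low (< 3), intermediate
    (within [3,4] or [4,5]), high (> 5); otherwise the nearest band by
    mean trophic level."""
    tls = np.asarray(trophic_levels, dtype=float)
    if np.all(tls < 3):
        return "low"
    if np.all(tls > 5):
        return "high"
    if np.all((tls >= 3) & (tls <= 4)) or np.all((tls >= 4) & (tls <= 5)):
        return "intermediate"
    mean = tls.mean()
    if mean < 3:
        return "low"
    if mean > 5:
        return "high"
    return "intermediate"
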