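"""Shared fixtures: small deterministic webs and a kept pristine baseline.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

import fishweb as fw
from fishweb.config import SimulationConfig, reduced_config
from fishweb.dynamics import EcoParams
from fishweb.runner import run_pristine
from fishweb.webs import FoodWeb, SpeciesPool, build_topology


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Quick-integration config for unit tests (seconds per run)."""
    cfg = reduced_config(n_webs=2, master_seed=7)
    cfg.web.n_plants, cfg.web.n_invertebrates, cfg.web.n_fish = 6, 10, 8
    cfg.run.pristine_days = 1500.0
    cfg.run.harvest_days = 2500.0
    return cfg


@pytest.fixture(scope="session")
def toy_web() -> FoodWeb:
    """Hand-built 5-species web: 2 plants, 2 herbivore-ish consumers and an
    omnivore; used for exact topology / trophic-level checks."""
    pool = SpeciesPool(
        guild=np.array([0, 0, 1, 1, 2]),
        log10_mass=np.array([0.5, 1.0, 2.5, 3.0, 5.0]),
    )
    return build_topology(pool, r_opt=100.0, gamma=2.0)


@pytest.fixture(scope="session")
def kept_pristine(tiny_config):
    """A kept pristine baseline (web, params, result) found by scanning
    web seeds under the tiny config."""
    cfg = tiny_config
    for seed in range(30):
        ss = np.random.SeedSequence([cfg.master_seed, seed])
        kids = ss.spawn(4)
        web = fw.generate_food_web(cfg.web, np.random.default_rng(kids[0]))
        params = EcoParams.from_web(web, cfg.eco, np.random.default_rng(kids[1]))
        pr = run_pristine(web, params, cfg, np.random.default_rng(kids[2]))
        if pr.kept and np.sum(pr.state.alive & web.pool.is_fish) >= 5:
            return pr
    raise RuntimeError("no kept pristine baseline found in 30 seeds")
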