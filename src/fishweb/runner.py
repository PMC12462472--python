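"""Ensemble orchestration: generate web -> pristine run -> viability filter
-> scenario resolution -> harvest run -> indicators, replicated over seeds.

Seeding is hierarchical: the master seed spawns one stream per web attempt,
which spawns sub-streams for mass sampling, ecological parameter draws,
initial biomasses, and one per scenario (targets + initial vessels).  All
scenarios on a web share one pristine baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .dynamics import CommunityState, EcoParams, SimResult, simulate
from .economics import init_fleets
from .indicators import (
    INDICATOR_COLUMNS,
    biomass_change_nonharvested,
    biomass_cv,
    overall_effect,
    species_persistence,
    sustained_economics,
)
from .scenarios import SCENARIOS, ScenarioSpec, TargetSet, select_targets
from .webs import FoodWeb, effective_trophic_levels, generate_food_web

__all__ = [
    "PristineResult",
    "HarvestResult",
    "run_pristine",
    "run_harvest",
    "run_web",
    "run_ensemble",
    "summarize_ensemble",
    "fish_filter",
    "trajectory_to_frame",
    "frame_to_trajectory",
]


@dataclass
class PristineResult:
    web: FoodWeb
    params: EcoParams
    result: SimResult
    kept: bool
    fish_fraction: float
    initial_state: CommunityState

    @property
    def state(self) -> CommunityState:
        return self.result.state


@dataclass
class HarvestResult:
    scenario: str
    target_set: TargetSet | None
    result: SimResult | None
    indicators: dict
    status: str   # "completed" | "aborted" | "failed" | "timeout"


def initial_state(
    params: EcoParams, rng: np.random.Generator, biomass_init_max: float,
    nutrient_init_fraction: float,
) -> CommunityState:
    n = params.mass.size
    # uniform on (0, max]: mirror a draw on [0, max) away from exact zero
    B0 = biomass_init_max - rng.uniform(0.0, biomass_init_max, size=n)
    N0 = params.S * nutrient_init_fraction
    return CommunityState(N0.astype(float), B0, np.ones(n, dtype=bool))


def fish_filter(
    alive: np.ndarray, is_fish: np.ndarray, threshold: float = 0.75
) -> tuple[float, bool]:
    """Surviving-fish fraction and the keep/discard decision: a web is
    kept iff at least ``threshold`` of its fish remain (webs with no fish
    pass trivially)."""
    n_fish = int(np.sum(is_fish))
    if n_fish == 0:
        return 1.0, True
    frac = float(np.sum(np.asarray(alive, bool) & np.asarray(is_fish, bool)) / n_fish)
    return frac, frac >= threshold


def run_pristine(
    web: FoodWeb,
    params: EcoParams,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PristineResult:
    """Integrate the fishery-free community and apply the fish-survival
    filter (webs keeping < 75% of their fish are discarded)."""
    state0 = initial_state(
        params, rng, config.run.biomass_init_max, config.run.nutrient_init_fraction
    )
    res = simulate(
        params,
        state0.copy(),
        (0.0, config.run.pristine_days),
        fleets=None,
        run_config=config.run,
        rtol=config.eco.rtol,
        atol=config.eco.atol,
    )
    frac, kept = fish_filter(
        res.state.alive, web.pool.is_fish, config.run.fish_survival_threshold
    )
    kept = kept and res.status in ("completed", "steady")
    return PristineResult(
        web=web,
        params=params,
        result=res,
        kept=kept,
        fish_fraction=frac,
        initial_state=state0,
    )


def run_harvest(
    pristine: PristineResult,
    spec: ScenarioSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> HarvestResult:
    """Resolve targets on the pristine baseline, attach open-access fleets
    and integrate the coupled system; emit raw per-run indicators."""
    web, params = pristine.web, pristine.params
    base = pristine.state
    if config.scenario.tl_basis == "post_pristine":
        tl = effective_trophic_levels(web, base.alive)
    else:
        tl = np.where(base.alive, web.trophic_level, np.nan)
    try:
        targets = select_targets(
            spec, web, base, params, rng, tl=tl,
            exhaustive_limit=config.scenario.exhaustive_limit,
        )
    except ValueError as err:
        return HarvestResult(spec.name, None, None,
                             {"abort_reason": str(err)}, "aborted")
    fleets = init_fleets(
        targets.ids,
        web.pool.mass,
        web.pool.is_plant,
        web.pool.is_consumer,
        config.econ,
        rng,
    )
    res = simulate(
        params,
        base.copy(),
        (0.0, config.run.harvest_days),
        fleets=fleets,
        run_config=config.run,
        rtol=config.eco.rtol,
        atol=config.eco.atol,
    )
    status = res.status if res.status in ("failed", "timeout") else "completed"
    catch, revenue, n_sustained, stationary = sustained_economics(
        res.trajectory, res.fleets.active, window=config.run.equilibrium_window
    )
    ind = {
        "persistence": species_persistence(
            base.alive, res.state.alive, "post_pristine"
        ),
        "persistence_initial_denominator": species_persistence(
            base.alive, res.state.alive, "initial", n_initial=web.n_species
        ),
        "biomass_change": biomass_change_nonharvested(
            base.B, res.state.B, targets.ids
        ),
        "sustained_catch": catch,
        "sustained_revenue": revenue,
        "n_sustained": n_sustained,
        "stationary": stationary,
        "biomass_cv": biomass_cv(res.trajectory, config.run.equilibrium_window),
        "mean_tl": targets.mean_tl,
        "sd_tl": targets.sd_tl,
        "link_distance_sum": targets.link_distance_sum,
        "n_extinctions": len(res.extinctions),
        "n_exits": len(res.exits),
        "t_end": res.t_end,
    }
    return HarvestResult(spec.name, targets, res, ind, status)


def run_web(
    config: SimulationConfig,
    web_index: int,
    scenarios=SCENARIOS,
) -> tuple[PristineResult, dict[str, HarvestResult]]:
    """Run one web attempt end to end (pristine + all scenarios)."""
    ss = np.random.SeedSequence([config.master_seed, web_index])
    kids = ss.spawn(4)
    web_rng = np.random.default_rng(kids[0])
    eco_rng = np.random.default_rng(kids[1])
    init_rng = np.random.default_rng(kids[2])
    web = generate_food_web(config.web, web_rng)
    params = EcoParams.from_web(web, config.eco, eco_rng)
    pristine = run_pristine(web, params, config, init_rng)
    harvests: dict[str, HarvestResult] = {}
    if pristine.kept:
        for s_idx, name in enumerate(scenarios):
            s_rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, web_index, s_idx])
            )
            spec = ScenarioSpec.from_config(name, config.scenario)
            harvests[name] = run_harvest(pristine, spec, config, s_rng)
    return pristine, harvests


def _row(config, web_index, pristine, name, hr) -> dict:
    row = {
        "web": web_index,
        "scenario": name,
        "status": hr.status,
        "kept": pristine.kept,
        "fish_fraction": pristine.fish_fraction,
        "pristine_status": pristine.result.status,
    }
    row.update(hr.indicators)
    return row


def run_ensemble(
    config: SimulationConfig,
    scenarios=SCENARIOS,
    out_dir: str | Path | None = None,
    resume: bool = True,
    max_attempts: int | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run webs until ``config.n_webs`` kept webs have all scenarios done.

    With ``out_dir`` set, per-web manifests and rows are written as they
    complete and previously finished webs are reused on resume, so a killed
    ensemble reproduces the identical table when restarted.
    """
    max_attempts = max_attempts or 4 * config.n_webs
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "manifests").mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    kept = 0
    for web_index in range(max_attempts):
        if kept >= config.n_webs:
            break
        manifest_path = (
            out_dir / "manifests" / f"web_{web_index:05d}.json"
            if out_dir is not None
            else None
        )
        if resume and manifest_path is not None and manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            rows.extend(manifest["rows"])
            kept += int(manifest["kept"])
            continue
        pristine, harvests = run_web(config, web_index, scenarios)
        web_rows = [
            _row(config, web_index, pristine, name, hr)
            for name, hr in harvests.items()
        ]
        if not pristine.kept:
            web_rows = [
                {
                    "web": web_index,
                    "scenario": None,
                    "status": "discarded",
                    "kept": False,
                    "fish_fraction": pristine.fish_fraction,
                    "pristine_status": pristine.result.status,
                }
            ]
        if manifest_path is not None:
            manifest = {
                "web": web_index,
                "master_seed": config.master_seed,
                "kept": bool(pristine.kept),
                "fish_fraction": pristine.fish_fraction,
                "targets": {
                    name: hr.target_set.to_dict()
                    for name, hr in harvests.items()
                    if hr.target_set is not None
                },
                "rows": web_rows,
                "config": config.to_dict(),
            }
            manifest_path.write_text(json.dumps(manifest, indent=1, default=float))
        rows.extend(web_rows)
        kept += int(pristine.kept)
        if progress:
            print(
                f"web {web_index}: kept={pristine.kept} "
                f"fish={pristine.fish_fraction:.2f} total_kept={kept}",
                flush=True,
            )
    table = pd.DataFrame(rows)
    done = table[table["kept"] & (table["status"] == "completed")]
    if len(done) >= 2:
        table.loc[done.index, "overall_effect"] = overall_effect(done)
    if out_dir is not None:
        table.to_csv(out_dir / "ensemble.csv", index=False)
    return table


def summarize_ensemble(table: pd.DataFrame, n_fisheries: int = 3) -> pd.DataFrame:
    """Per-scenario fractions of runs ending with all / zero fisheries
    sustained, plus indicator means."""
    done = table[table["kept"] & (table["status"] == "completed")].copy()
    out = []
    for name, grp in done.groupby("scenario"):
        out.append(
            {
                "scenario": name,
                "n_runs": len(grp),
                "frac_all_sustained": float(
                    (grp["n_sustained"] == n_fisheries).mean()
                ),
                "frac_zero_sustained": float((grp["n_sustained"] == 0).mean()),
                "mean_n_sustained": float(grp["n_sustained"].mean()),
                **{
                    f"mean_{c}": float(grp[c].mean())
                    for c in INDICATOR_COLUMNS
                    if c in grp
                },
                "mean_mean_tl": float(grp["mean_tl"].mean()),
                "mean_sd_tl": float(grp["sd_tl"].mean()),
            }
        )
    return pd.DataFrame(out).sort_values("scenario").reset_index(drop=True)


def frame_to_trajectory(frame: pd.DataFrame):
    """Rebuild a :class:`fishweb.dynamics.Trajectory` from its long-format
    frame; exact inverse of :func:`trajectory_to_frame` (floats round-trip
    through the CSV text representation bit-identically)."""
    from .dynamics import Trajectory

    t = np.sort(frame["time"].unique())

    def block(kind):
        sub = frame[frame["kind"] == kind]
        if sub.empty:
            return np.zeros((t.size, 0))
        return (
            sub.pivot(index="time", columns="entity", values="value")
            .sort_index()
            .to_numpy()
        )

    return Trajectory(
        t,
        block("nutrient"),
        block("biomass"),
        block("vessels"),
        block("clearance"),
        block("catch"),
        block("revenue"),
        block("profit"),
    )


def trajectory_to_frame(result: SimResult) -> pd.DataFrame:
    """Long-format trajectory (time, entity id, entity kind, value)."""
    traj = result.trajectory
    frames = []
    nt = traj.t.size
    for l in range(traj.N.shape[1]):
        frames.append(
            pd.DataFrame(
                {"time": traj.t, "entity": l, "kind": "nutrient", "value": traj.N[:, l]}
            )
        )
    for i in range(traj.B.shape[1]):
        frames.append(
            pd.DataFrame(
                {"time": traj.t, "entity": i, "kind": "biomass", "value": traj.B[:, i]}
            )
        )
    if result.fleets is not None:
        for k in range(result.fleets.n):
            for kind, arr in (
                ("vessels", traj.V),
                ("clearance", traj.clearance),
                ("catch", traj.catch),
                ("revenue", traj.revenue),
                ("profit", traj.profit),
            ):
                frames.append(
                    pd.DataFrame(
                        {
                            "time": traj.t,
                            "entity": k,
                            "kind": kind,
                            "value": arr[:, k],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
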