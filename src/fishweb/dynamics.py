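"""Nutrient-plant-animal biomass dynamics with extinction events.

The community follows a two-nutrient allometric trophic-network model:

    dN_l/dt = D (S_l - N_l) - v_l * sum_plants r_i G_i B_i
    dB_i/dt = r_i G_i B_i - sum_k B_k F_ki - x_i B_i                (plants)
    dB_i/dt = B_i sum_k e_k F_ik - sum_k B_k F_ki - x_i B_i         (animals)

with Liebig growth G_i = min_l N_l / (K_il + N_l), metabolic rates
x_i = y_i m_i^-a, and a multi-resource functional response

    F_ij = omega_i b_ij B_j^(1+q)
           / (1 + c_i B_i + omega_i sum_k h_ik b_ik B_k^(1+q)) / m_i

where the capture coefficient b_ij combines allometric encounter rates with
the Ricker likelihood, and h_ik is an allometric handling time.  Species
whose biomass falls to the extinction threshold (1e-6) are set to zero and
stay extinct.  Harvested species additionally lose a fishery catch term
(see :mod:`fishweb.economics`).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .config import EcoConfig, RunConfig
from .economics import FleetSet, catch_rate, fleet_profit
from .webs import FoodWeb

__all__ = [
    "EcoParams",
    "CommunityState",
    "Trajectory",
    "SimResult",
    "growth_factor",
    "capture_coefficients",
    "handling_times",
    "feeding_rates",
    "derivatives",
    "apply_extinctions",
    "simulate",
]


@dataclass
class EcoParams:
    """Per-web realized ecological parameters (rates per day)."""

    mass: np.ndarray            # m_i
    is_plant: np.ndarray
    guild: np.ndarray
    r: np.ndarray               # intrinsic growth, 0 for animals
    x: np.ndarray               # metabolic rate
    K: np.ndarray               # (n, 2) half-saturations (plants only used)
    e_resource: np.ndarray      # assimilation efficiency by resource species
    c: np.ndarray               # consumer interference
    q: float                    # Hill exponent is 1 + q
    omega: np.ndarray
    b: np.ndarray               # capture coefficients (n, n)
    h: np.ndarray               # handling times (n, n)
    D: float
    S: np.ndarray               # (2,)
    v: np.ndarray               # (2,)
    extinction_threshold: float = 1e-6
    # precomputed functional-response kernels
    attack: np.ndarray = field(init=False)
    handling_term: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.attack = self.omega[:, None] * self.b
        self.handling_term = self.omega[:, None] * self.h * self.b

    @classmethod
    def from_web(
        cls,
        web: FoodWeb,
        config: EcoConfig,
        rng: np.random.Generator,
    ) -> "EcoParams":
        """Draw the per-web random parameters (K_il, c_i, q) and assemble
        all allometric rates for a generated topology."""
        pool = web.pool
        n = pool.n_species
        m = pool.mass
        is_plant = pool.is_plant
        r = np.where(is_plant, m ** config.growth_exponent, 0.0)
        y = np.asarray(config.metabolic_intercepts)[pool.guild]
        x = y * m ** (-config.metabolic_exponent)
        K = rng.uniform(*config.half_saturation_range, size=(n, 2))
        e_resource = np.where(is_plant, config.e_plant, config.e_animal)
        c = np.where(is_plant, 0.0, rng.uniform(*config.interference_range, size=n))
        q = float(rng.uniform(*config.hill_q_range))
        b = capture_coefficients(web, config)
        h = handling_times(web, config)
        return cls(
            mass=m,
            is_plant=is_plant,
            guild=pool.guild.copy(),
            r=r,
            x=x,
            K=K,
            e_resource=e_resource,
            c=c,
            q=q,
            omega=web.omega,
            b=b,
            h=h,
            D=config.nutrient_turnover,
            S=np.asarray(config.nutrient_supply, dtype=float),
            v=np.asarray(config.nutrient_content, dtype=float),
            extinction_threshold=config.extinction_threshold,
        )


@dataclass
class CommunityState:
    """Nutrients and species biomasses at one time point."""

    N: np.ndarray
    B: np.ndarray
    alive: np.ndarray

    def copy(self) -> "CommunityState":
        return CommunityState(self.N.copy(), self.B.copy(), self.alive.copy())


@dataclass
class Trajectory:
    """Saved samples of a run; fleet blocks are empty for pristine runs."""

    t: np.ndarray
    N: np.ndarray           # (nt, 2)
    B: np.ndarray           # (nt, n)
    V: np.ndarray           # (nt, nf)
    clearance: np.ndarray   # (nt, nf)
    catch: np.ndarray       # (nt, nf)
    revenue: np.ndarray     # (nt, nf)
    profit: np.ndarray      # (nt, nf)


@dataclass
class SimResult:
    state: CommunityState
    trajectory: Trajectory
    extinctions: list[tuple[float, int]]
    exits: list[tuple[float, int]]
    fleets: FleetSet | None
    status: str             # "completed" | "steady" | "timeout" | "failed"
    t_end: float


def growth_factor(N: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Liebig's law of the minimum: G_i = min_l N_l / (K_il + N_l)."""
    N = np.asarray(N, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(N < 0) or np.any(K < 0):
        raise ValueError("nutrients and half-saturations must be non-negative")
    sat = N / (K + N)
    return sat.min(axis=-1)


def capture_coefficients(web: FoodWeb, config: EcoConfig) -> np.ndarray:
    """Allometric capture coefficients b_ij.

    Links onto plants scale with consumer mass only (herbivore form,
    encounters are set by herbivore movement); links among animals scale
    with both masses (carnivore form).
    """
    m = web.pool.mass
    L = web.likelihood
    herb = config.b0_herbivore * m[:, None] ** config.beta_consumer * L
    carn = (
        config.b0_carnivore
        * m[:, None] ** config.beta_consumer
        * m[None, :] ** config.beta_resource
        * L
    )
    plant_resource = web.pool.is_plant[None, :]
    return np.where(plant_resource, herb, carn)


def handling_times(web: FoodWeb, config: EcoConfig) -> np.ndarray:
    """h_ij = h0 * m_i^eta_i * m_j^eta_j on links (0 elsewhere)."""
    m = web.pool.mass
    h = (
        config.h0
        * m[:, None] ** config.eta_consumer
        * m[None, :] ** config.eta_resource
    )
    return np.where(web.adjacency, h, 0.0)


def feeding_rates(B: np.ndarray, params: EcoParams) -> np.ndarray:
    """Per-unit-consumer-biomass feeding rates F_ij (1/day)."""
    B = np.asarray(B, dtype=float)
    if B.shape != params.mass.shape:
        raise ValueError("biomass vector does not match the web")
    Bq = np.clip(B, 0.0, None) ** (1.0 + params.q)
    numer = params.attack * Bq[None, :]
    denom = 1.0 + params.c * np.clip(B, 0.0, None) + params.handling_term @ Bq
    F = numer / denom[:, None] / params.mass[:, None]
    return F


def derivatives(
    state: CommunityState,
    params: EcoParams,
    fleets: FleetSet | None = None,
    V: np.ndarray | None = None,
    clearance: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dN, dB, dV, dclearance).

    Dead species and exited fleets have exactly zero derivatives.  The
    fleet blocks are empty arrays when ``fleets`` is None.
    """
    N = np.asarray(state.N, dtype=float)
    B = np.where(state.alive, np.clip(state.B, 0.0, None), 0.0)
    if N.shape != (2,) or B.shape != params.mass.shape:
        raise ValueError("state dimensions do not match the web")

    G = growth_factor(N[None, :], params.K)
    F = feeding_rates(B, params)
    predation = F.T @ B                       # loss of j to all consumers
    gains = B * (F @ params.e_resource)       # assimilated influx
    uptake = np.where(params.is_plant, params.r * G * B, 0.0)

    dN = params.D * (params.S - N) - params.v * np.sum(uptake)
    dB = np.where(
        params.is_plant,
        uptake - predation - params.x * B,
        gains - predation - params.x * B,
    )

    if fleets is not None and fleets.n > 0:
        V = np.asarray(V, dtype=float)
        clearance = np.clip(np.asarray(clearance, dtype=float), 0.0, None)
        active = fleets.active
        Bt = B[fleets.target]
        catch = np.where(
            active, catch_rate(Bt, fleets.catch_max, clearance, V), 0.0
        )
        np.subtract.at(dB, fleets.target, catch)
        pi = np.where(active, fleet_profit(catch, fleets, clearance, V), 0.0)
        dV = np.where(active, fleets.mu_vessel * pi, 0.0)
        dC = np.where(active, fleets.mu_clearance * pi, 0.0)
        # clearance is clipped at zero: no further decline once exhausted
        dC = np.where((np.asarray(clearance) <= 0.0) & (dC < 0.0), 0.0, dC)
    else:
        dV = np.zeros(0)
        dC = np.zeros(0)

    dB = np.where(state.alive, dB, 0.0)
    return dN, dB, dV, dC


def apply_extinctions(
    state: CommunityState, threshold: float
) -> np.ndarray:
    """Kill species at or below the extinction threshold (in place);
    returns the indices that just died."""
    doomed = np.flatnonzero(state.alive & (state.B <= threshold))
    state.B[doomed] = 0.0
    state.alive[doomed] = False
    return doomed


# --- integration -------------------------------------------------------------


def _pack(N, B, V, C):
    return np.concatenate([N, B, V, C])


def simulate(
    params: EcoParams,
    state0: CommunityState,
    t_span: tuple[float, float],
    fleets: FleetSet | None = None,
    run_config: RunConfig | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> SimResult:
    """Integrate the coupled system with extinction / fishery-exit events.

    Uses a stiff-capable adaptive integrator (LSODA) restarted at each
    event: extinction when any living biomass reaches the threshold from
    above, fishery exit when any active vessel density falls to its exit
    threshold.  Optionally stops early once the community is numerically
    steady (max relative derivative below ``run_config.steady_tolerance``).
    """
    run_config = run_config or RunConfig()
    rtol = 1e-8 if rtol is None else rtol
    atol = 1e-12 if atol is None else atol
    n = params.mass.size
    state = state0.copy()
    apply_extinctions(state, params.extinction_threshold)
    fleets = fleets.copy() if fleets is not None else None
    nf = fleets.n if fleets is not None else 0
    V = fleets.V0.copy() if nf else np.zeros(0)
    C = fleets.clearance0.copy() if nf else np.zeros(0)

    t0, t_end = float(t_span[0]), float(t_span[1])
    save_t = np.linspace(t0, t_end, run_config.n_save)
    saved_t: list[float] = []
    saved_y: list[np.ndarray] = []
    extinctions: list[tuple[float, int]] = []
    exits: list[tuple[float, int]] = []
    status = "completed"
    started = _time.monotonic()
    threshold = params.extinction_threshold

    def rhs(t, y):
        st = CommunityState(y[:2], y[2 : 2 + n], state.alive)
        dN, dB, dV, dC = derivatives(
            st, params, fleets, y[2 + n : 2 + n + nf], y[2 + n + nf :]
        )
        return _pack(dN, dB, dV, dC)

    def extinction_event(t, y):
        B = y[2 : 2 + n][state.alive]
        if B.size == 0:
            return 1.0
        return float(B.min() - threshold)

    extinction_event.terminal = True
    extinction_event.direction = -1

    def exit_event(t, y):
        if fleets is None or not fleets.active.any():
            return 1.0
        Vv = y[2 + n : 2 + n + nf][fleets.active]
        return float(Vv.min() - fleets.exit_threshold)

    exit_event.terminal = True
    exit_event.direction = -1

    steady_tol = run_config.steady_tolerance

    def steady_event(t, y):
        if t < t0 + run_config.steady_min_days:
            return 1.0
        dy = rhs(t, y)
        scale = np.maximum(np.abs(y), 1e-8)
        rel = np.abs(dy) / scale
        mask = np.ones_like(y, dtype=bool)
        mask[2 : 2 + n] = state.alive
        if nf:
            mask[2 + n : 2 + n + nf] = fleets.active
            mask[2 + n + nf :] = fleets.active
        return float(rel[mask].max() - steady_tol)

    steady_event.terminal = True
    steady_event.direction = -1

    events = [extinction_event, exit_event]
    if steady_tol is not None:
        events.append(steady_event)

    t_cur = t0
    y_cur = _pack(state.N, state.B, V, C)
    max_restarts = n + nf + 10

    for _ in range(max_restarts):
        t_eval = save_t[(save_t >= t_cur) & (save_t <= t_end)]
        sol = solve_ivp(
            rhs,
            (t_cur, t_end),
            y_cur,
            method="LSODA",
            events=events,
            t_eval=t_eval if t_eval.size else None,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            status = "failed"
            if sol.t.size:
                t_cur, y_cur = float(sol.t[-1]), sol.y[:, -1]
            break
        sol_t = np.asarray(sol.t)
        sol_y = np.asarray(sol.y)
        if sol_y.ndim < 2:
            sol_y = sol_y.reshape(y_cur.size, -1)
        for ts, ys in zip(sol_t, sol_y.T):
            if not saved_t or ts > saved_t[-1]:
                saved_t.append(float(ts))
                saved_y.append(ys)
        t_cur = float(sol_t[-1]) if sol_t.size else t_cur
        y_cur = sol_y[:, -1] if sol_t.size else y_cur
        if sol.status == 1:  # an event fired
            t_event = min(
                (te[0] for te in sol.t_events if te.size), default=t_cur
            )
            y_event = None
            for te, ye in zip(sol.t_events, sol.y_events):
                if te.size and te[0] == t_event:
                    y_event = ye[0]
            if y_event is not None:
                t_cur, y_cur = float(t_event), y_event
            state.N = y_cur[:2].copy()
            state.B = y_cur[2 : 2 + n].copy()
            if sol.t_events[-1].size and steady_tol is not None and len(events) == 3:
                if sol.t_events[2].size and sol.t_events[2][0] == t_event:
                    status = "steady"
                    break
            died = np.flatnonzero(
                state.alive & (state.B <= threshold * (1 + 1e-9))
            )
            for i in died:
                extinctions.append((t_cur, int(i)))
            state.B[died] = 0.0
            state.alive[died] = False
            if nf:
                Vv = y_cur[2 + n : 2 + n + nf]
                gone = np.flatnonzero(
                    fleets.active & (Vv <= fleets.exit_threshold * (1 + 1e-9))
                )
                for k in gone:
                    exits.append((t_cur, int(k)))
                fleets.active[gone] = False
            y_cur = y_cur.copy()
            y_cur[:2] = state.N
            y_cur[2 : 2 + n] = state.B
            if t_cur >= t_end:
                break
        else:
            break
        if (
            run_config.timeout_seconds is not None
            and _time.monotonic() - started > run_config.timeout_seconds
        ):
            status = "timeout"
            break
    else:
        status = "failed"

    state.N = y_cur[:2].copy()
    state.B = np.where(state.alive, y_cur[2 : 2 + n], 0.0)
    if nf:
        fleets.V_final = np.where(fleets.active, y_cur[2 + n : 2 + n + nf], 0.0)
        fleets.clearance_final = np.clip(y_cur[2 + n + nf :], 0.0, None)

    if not saved_t or saved_t[-1] < t_cur:
        saved_t.append(t_cur)
        saved_y.append(y_cur)
    Y = np.array(saved_y)
    ts = np.array(saved_t)
    traj = _build_trajectory(ts, Y, n, fleets, exits)
    return SimResult(
        state=state,
        trajectory=traj,
        extinctions=extinctions,
        exits=exits,
        fleets=fleets,
        status=status,
        t_end=t_cur,
    )


def _build_trajectory(
    ts: np.ndarray, Y: np.ndarray, n: int, fleets: FleetSet | None, exits
) -> Trajectory:
    nf = fleets.n if fleets is not None else 0
    N = Y[:, :2]
    B = Y[:, 2 : 2 + n]
    V = Y[:, 2 + n : 2 + n + nf]
    C = np.clip(Y[:, 2 + n + nf :], 0.0, None)
    catch = np.zeros((ts.size, nf))
    revenue = np.zeros((ts.size, nf))
    profit = np.zeros((ts.size, nf))
    if nf:
        exit_time = np.full(nf, np.inf)
        for t_exit, k in exits:
            exit_time[k] = min(exit_time[k], t_exit)
        live = ts[:, None] < exit_time[None, :]
        Bt = np.clip(B[:, fleets.target], 0.0, None)
        catch = np.where(
            live, catch_rate(Bt, fleets.catch_max, C, np.clip(V, 0.0, None)), 0.0
        )
        profit = np.where(
            live, fleet_profit(catch, fleets, C, np.clip(V, 0.0, None)), 0.0
        )
        from .economics import revenue_from_catch

        revenue = np.where(
            live, revenue_from_catch(catch, fleets.p_base_i, fleets.ped), 0.0
        )
    return Trajectory(ts, N, B, V, C, catch, revenue, profit)
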