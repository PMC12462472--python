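"""Ecological and economic indicators of a paired pristine/harvest run.

Five per-run indicators: species persistence, food-web biomass change of
non-harvested species, sustained total biomass catch, sustained total
revenue, and the number of sustained fisheries.  The overall effect
indicator min-max rescales each of the five across an ensemble and averages
them per run, so it is an ensemble-relative score in [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import Trajectory

__all__ = [
    "INDICATOR_COLUMNS",
    "species_persistence",
    "biomass_change_nonharvested",
    "sustained_economics",
    "biomass_cv",
    "overall_effect",
    "trim_quantiles",
]

#: the five Table-style indicators entering the overall effect score
INDICATOR_COLUMNS = [
    "persistence",
    "biomass_change",
    "sustained_catch",
    "sustained_revenue",
    "n_sustained",
]


def species_persistence(
    alive_pristine: np.ndarray,
    alive_harvest: np.ndarray,
    denominator: str = "post_pristine",
    n_initial: int | None = None,
) -> float:
    """Fraction of species that persisted after the fisheries were
    introduced.  The denominator is the post-pristine richness by default;
    the "initial" switch uses pre-pristine richness instead (sensitivity)."""
    n_harvest = int(np.sum(alive_harvest))
    if denominator == "post_pristine":
        denom = int(np.sum(alive_pristine))
    elif denominator == "initial":
        if n_initial is None:
            raise ValueError("n_initial required for the 'initial' denominator")
        denom = int(n_initial)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("persistence denominator is zero")
    return n_harvest / denom


def biomass_change_nonharvested(
    B_pristine: np.ndarray, B_harvest: np.ndarray, targets: np.ndarray
) -> float:
    """(sum B_f - sum B_p) / sum B_p over non-harvested species only."""
    mask = np.ones(np.asarray(B_pristine).size, dtype=bool)
    mask[np.asarray(targets, dtype=int)] = False
    bp = float(np.sum(np.asarray(B_pristine)[mask]))
    bf = float(np.sum(np.asarray(B_harvest)[mask]))
    if bp <= 0:
        raise ValueError("no non-harvested pristine biomass to compare against")
    return (bf - bp) / bp


def sustained_economics(
    traj: Trajectory,
    active: np.ndarray,
    window: float = 0.1,
    drift_tolerance: float = 0.01,
) -> tuple[float, float, int, bool]:
    """Equilibrium catch and revenue (per day), pooled over surviving
    fleets and averaged over the final ``window`` fraction of the run.

    Returns (catch, revenue, n_sustained, stationary) where ``stationary``
    reports whether total catch drifted less than ``drift_tolerance``
    (relative) across the window.
    """
    active = np.asarray(active, dtype=bool)
    n_sustained = int(active.sum())
    if traj.catch.size == 0 or n_sustained == 0:
        return 0.0, 0.0, n_sustained, True
    t = traj.t
    t_lo = t[-1] - window * (t[-1] - t[0])
    sel = t >= t_lo
    if sel.sum() < 2:
        sel = np.zeros_like(sel)
        sel[-1] = True
    total_catch = traj.catch[:, active].sum(axis=1)
    total_revenue = traj.revenue[:, active].sum(axis=1)
    mean_catch = float(total_catch[sel].mean())
    mean_revenue = float(total_revenue[sel].mean())
    first, last = total_catch[sel][0], total_catch[sel][-1]
    scale = max(abs(mean_catch), 1e-300)
    stationary = bool(abs(last - first) / scale < drift_tolerance)
    return mean_catch, mean_revenue, n_sustained, stationary


def biomass_cv(traj: Trajectory, window: float = 0.1) -> float:
    """Coefficient of variation of total community biomass over the final
    window (an optional stability metric)."""
    t = traj.t
    sel = t >= t[-1] - window * (t[-1] - t[0])
    total = traj.B[sel].sum(axis=1)
    mean = total.mean()
    if mean <= 0:
        return np.nan
    return float(total.std() / mean)


def overall_effect(table: pd.DataFrame, columns=INDICATOR_COLUMNS) -> pd.Series:
    """Ensemble-relative overall effect: min-max rescale each indicator
    across the rows, then average the rescaled values per row.  Indicators
    that are constant across the ensemble rescale to 0.5 so the mean stays
    defined."""
    if len(table) < 2:
        raise ValueError("overall effect needs at least two runs")
    scaled = {}
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi > lo:
            scaled[col] = (x - lo) / (hi - lo)
        else:
            scaled[col] = np.full_like(x, 0.5)
    return pd.Series(
        np.nanmean(np.column_stack(list(scaled.values())), axis=1),
        index=table.index,
        name="overall_effect",
    )


def trim_quantiles(
    table: pd.DataFrame, columns, lower: float = 0.05, upper: float = 0.95
) -> pd.DataFrame:
    """Drop rows falling in the outer quantiles of any of ``columns`` — a
    plotting/post-processing helper, not part of the indicator definitions."""
    keep = pd.Series(True, index=table.index)
    for col in columns:
        lo, hi = table[col].quantile([lower, upper])
        keep &= table[col].between(lo, hi)
    return table[keep]
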