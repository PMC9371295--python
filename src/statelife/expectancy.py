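"""Total and state-specific life expectancy at age 50.

Start-state-specific expectancies are integrals of the occupancy
probabilities over age (trapezoid rule on the solver grid, truncated at
the maximum life span of 110); they are then averaged with the baseline
start-state weights, so total LE(50) = sum_j w_j LE(50, j), and total LE
decomposes exactly into years spent with 0, 1, 2 and 3+ complications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gompertz import ModelSet, fit_model_set, profile_for
from .occupancy import OccupancyGrid, solve_occupancy
from .panel import build_analysis_episodes, compute_weights

__all__ = ["ExpectancyEstimate", "start_specific_expectancy",
           "weighted_expectancy", "expectancy_table", "estimate_expectancies",
           "deprivation_gap"]

STATE_LABELS = {1: "no_complications", 2: "one_complication",
                3: "two_complications", 4: "three_plus_complications"}


@dataclass
class ExpectancyEstimate:
    """Life expectancy at age 50 for one stratum.

    ``state_le[k]`` are expected years in state k+1; ``total_le`` is their
    sum; ``start_specific_le[j, k]`` is the expected time in state k+1 for
    an individual in state j+1 at age 50.
    """

    stratum: tuple
    total_le: float
    state_le: np.ndarray
    start_specific_le: np.ndarray
    ci: dict | None = None

    def __post_init__(self):
        assert abs(self.total_le - float(np.sum(self.state_le))) < 1e-9


def start_specific_expectancy(occupancy: OccupancyGrid,
                              rule: str = "trapezoid") -> np.ndarray:
    """LE(50, j -> k): integral of P_jk(u) du for transient states k.

    ``rule`` is "trapezoid" (default) or "left" for a left-endpoint sum;
    the grid-refinement tests bound the difference between the two.
    """
    if occupancy.ages[-1] < 110.0 - 1e-9:
        raise ValueError("occupancy grid must reach the maximum life span (110)")
    P = occupancy.P[:, :, :4]  # years in the absorbing state do not count
    if rule == "trapezoid":
        return np.trapezoid(P, occupancy.ages, axis=1)
    if rule == "left":
        dt = np.diff(occupancy.ages)
        return np.einsum("jik,i->jk", P[:, :-1, :], dt)
    raise ValueError(f"unknown integration rule {rule!r}")


def weighted_expectancy(start_specific: np.ndarray, weights: np.ndarray,
                        stratum: tuple = ()) -> ExpectancyEstimate:
    """Average the start-state-specific expectancies with baseline weights."""
    weights = np.asarray(weights, dtype=float)
    if start_specific.shape != (4, 4) or weights.shape != (4,):
        raise ValueError("start_specific must be 4x4 and weights length 4")
    state_le = weights @ start_specific
    return ExpectancyEstimate(stratum=tuple(stratum),
                              total_le=float(state_le.sum()),
                              state_le=state_le,
                              start_specific_le=start_specific)


def expectancy_table(model_set: ModelSet, weights: pd.DataFrame,
                     strata: list[tuple], grid_step_days: float = 30.0,
                     rule: str = "trapezoid") -> pd.DataFrame:
    """One expectancy row per stratum, plus least-minus-most-deprived gaps.

    ``strata`` are tuples ``(sex,)`` or ``(sex, quintile)``; ``weights``
    comes from :func:`statelife.panel.compute_weights` with matching
    stratification.
    """
    rows = []
    for stratum in strata:
        sex = stratum[0]
        q = stratum[1] if len(stratum) > 1 else None
        sel = weights[weights["sex"] == sex]
        if q is not None:
            sel = sel[sel["simd_quintile"] == q]
        if sel.empty:
            raise ValueError(f"missing weights for stratum {stratum}")
        w = sel[["w1", "w2", "w3", "w4"]].to_numpy()[0]
        occ = solve_occupancy(model_set.models, profile_for(sex, q),
                              grid_step_days=grid_step_days)
        est = weighted_expectancy(start_specific_expectancy(occ, rule), w, stratum)
        rows.append({"sex": sex, "simd_quintile": q, "total_le": est.total_le,
                     **{f"le_state{k + 1}": est.state_le[k] for k in range(4)}})
    out = pd.DataFrame(rows)
    return out


def deprivation_gap(table: pd.DataFrame, column: str = "total_le",
                    least: int = 5, most: int = 1) -> pd.DataFrame:
    """Least-minus-most-deprived gap per sex for any expectancy column."""
    rows = []
    for sex, g in table.dropna(subset=["simd_quintile"]).groupby("sex"):
        lo = g.loc[g["simd_quintile"] == most, column]
        hi = g.loc[g["simd_quintile"] == least, column]
        if len(lo) and len(hi):
            rows.append({"sex": sex, "column": column,
                         "gap": float(hi.iloc[0]) - float(lo.iloc[0])})
    return pd.DataFrame(rows)


def estimate_expectancies(cohort: pd.DataFrame, weight_sample: pd.DataFrame,
                          covariate_set: str = "set2",
                          strata: list[tuple] | None = None,
                          grid_step_days: float = 30.0,
                          slice_days: float = 30.0,
                          weights_window: tuple[float, float] = (45.0, 55.0),
                          compute_vcov: bool = False,
                          rule: str = "trapezoid"):
    """End-to-end pipeline: cohort -> episodes -> fits -> expectancy table.

    This single code path is reused verbatim by the bootstrap so replicate
    estimates and point estimates can never diverge.  Returns
    (table, model_set, weights).
    """
    build = build_analysis_episodes(cohort, slice_days=slice_days)
    model_set = fit_model_set(build.episodes, covariate_set,
                              compute_vcov=compute_vcov)
    weight_cols = ("sex",) if covariate_set == "set1" else ("sex", "simd_quintile")
    weights = compute_weights(weight_sample, weights_window, weight_cols)
    if strata is None:
        if covariate_set == "set1":
            strata = [("male",), ("female",)]
        else:
            strata = [(s, q) for s in ("male", "female") for q in (1, 2, 3, 4, 5)]
    table = expectancy_table(model_set, weights, strata, grid_step_days, rule)
    return table, model_set, weights
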