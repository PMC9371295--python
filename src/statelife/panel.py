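"""From cohort records to 30-day panels and transition-specific episodes.

States are observed per 30-day slice: the slice state is the number of
complications accrued at or before the slice start (capped at 3+), so a
complication onset becomes visible at the first slice boundary at or after
it.  Two onsets falling inside one slice surface as a two-state jump; such
individuals are excluded rather than imputing an ordering, mirroring how
registry analyses handle these rare events.  Episodes carry the age clock
with origin at age 50 and encode left truncation through ``t_entry > 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gompertz import DEATH_TRANSITION, UP_TRANSITION
from .simulate import ONSET_COLUMNS

__all__ = ["SLICE_DAYS", "slice_timeline", "find_multi_jumps",
           "build_episodes", "build_analysis_episodes", "compute_weights",
           "merge_time_updated"]

logger = logging.getLogger("statelife")

SLICE_DAYS = 30.0
DAYS_PER_YEAR = 365.25

_EPISODE_COLUMNS = ["id", "transition_id", "from_state", "t_entry", "t_exit",
                    "status", "sex", "simd_quintile"]


def _slice_width(slice_days: float) -> float:
    return slice_days / DAYS_PER_YEAR


def _onset_matrix(cohort: pd.DataFrame) -> np.ndarray:
    cols = [c for c in ONSET_COLUMNS if c in cohort.columns]
    if not cols:
        return np.full((len(cohort), 0), np.nan)
    return cohort[cols].to_numpy(dtype=float)


def _snap_onsets(cohort: pd.DataFrame, slice_days: float):
    """Snap post-entry onsets to the slice boundary where the new state is
    first observed; returns (entry_state, sorted snapped matrix, counts)."""
    h = _slice_width(slice_days)
    entry = cohort["entry_age"].to_numpy(dtype=float)
    exit_ = cohort["exit_age"].to_numpy(dtype=float)
    onsets = _onset_matrix(cohort)
    with np.errstate(invalid="ignore"):
        pre = np.nansum(onsets <= entry[:, None], axis=1).astype(int)
    entry_state = np.minimum(4, 1 + pre)
    post = np.where(np.isnan(onsets) | (onsets <= entry[:, None]), np.inf, onsets)
    k = np.ceil((post - entry[:, None]) / h - 1e-12)
    snapped = entry[:, None] + k * h
    snapped = np.where(np.isfinite(post) & (snapped < exit_[:, None] - 1e-12),
                       snapped, np.inf)
    snapped = np.where(entry_state[:, None] >= 4, np.inf, snapped)  # cap at 3+
    snapped = np.sort(snapped, axis=1)
    counts = np.isfinite(snapped).sum(axis=1)
    counts = np.minimum(counts, 4 - entry_state)  # never above state 4
    snapped = np.where(np.arange(snapped.shape[1])[None, :] < counts[:, None],
                       snapped, np.inf)
    return entry_state, snapped, counts


def slice_timeline(cohort: pd.DataFrame, slice_days: float = SLICE_DAYS) -> pd.DataFrame:
    """Expand a cohort into 30-day panel records.

    One record per individual per slice; the final slice is shortened at
    exit and carries the death flag.  Individuals whose observation is cut
    short by non-death censoring within the first 30 days are excluded
    (with a log entry): their records cover no full slice.  Early deaths
    are kept — a death is fully observed however soon it happens, and
    dropping such individuals would select on outcome and bias mortality
    downward.
    """
    h = _slice_width(slice_days)
    entry = cohort["entry_age"].to_numpy(dtype=float)
    exit_ = cohort["exit_age"].to_numpy(dtype=float)
    if np.any(exit_ <= entry):
        raise ValueError("exit_age must exceed entry_age")
    ok = (exit_ - entry > h) | (cohort["exit_reason"].to_numpy() == "death")
    if (~ok).any():
        logger.info("slice_timeline: excluded %d individuals observable <= %g days",
                    int((~ok).sum()), slice_days)
    sub = cohort.loc[ok].reset_index(drop=True)
    entry, exit_ = entry[ok], exit_[ok]
    died = (sub["exit_reason"].to_numpy() == "death")
    entry_state, snapped, _ = _snap_onsets(sub, slice_days)

    n_slices = np.ceil((exit_ - entry) / h - 1e-12).astype(int)
    idx = np.repeat(np.arange(len(sub)), n_slices)
    offs = np.arange(n_slices.sum()) - np.repeat(
        np.concatenate([[0], np.cumsum(n_slices)[:-1]]), n_slices)
    age_start = entry[idx] + offs * h
    age_end = np.minimum(age_start + h, exit_[idx])
    with np.errstate(invalid="ignore"):
        n_seen = (snapped[idx] <= age_start[:, None] + 1e-12).sum(axis=1)
    state = np.minimum(4, entry_state[idx] + n_seen)
    last = offs == (n_slices[idx] - 1)
    panel = pd.DataFrame({
        "id": sub["id"].to_numpy()[idx],
        "slice_index": offs,
        "age_start": age_start,
        "age_end": age_end,
        "state": state,
        "died_in_slice": last & died[idx],
        "sex": sub["sex"].to_numpy()[idx],
        "simd_quintile": sub["simd_quintile"].to_numpy()[idx],
    })
    return panel


def find_multi_jumps(panel: pd.DataFrame) -> set:
    """Ids whose observed state increases by two or more between consecutive
    slices (two onsets within one slice)."""
    df = panel.sort_values(["id", "slice_index"])
    jump = df.groupby("id")["state"].diff()
    if (jump < 0).any():
        raise ValueError("backward state move in panel: corrupt input")
    return set(df.loc[jump >= 2, "id"].unique())


def build_episodes(panel: pd.DataFrame) -> pd.DataFrame:
    """Transition episodes from a panel with multi-jump individuals removed.

    For each sojourn in a transient state, one episode per allowed exit
    transition: the realized exit is the event, the competing exit is
    censored at the same time.  Times are years since age 50.
    """
    if find_multi_jumps(panel):
        raise ValueError("panel contains multi-jump individuals; exclude them first")
    rows = []
    for pid, g in panel.sort_values(["id", "slice_index"]).groupby("id", sort=False):
        states = g["state"].to_numpy()
        starts = g["age_start"].to_numpy()
        died = bool(g["died_in_slice"].iloc[-1])
        exit_age = g["age_end"].iloc[-1]
        sex = g["sex"].iloc[0]
        q = g["simd_quintile"].iloc[0]
        change = np.flatnonzero(np.diff(states) != 0) + 1
        bounds = [starts[0]] + [starts[i] for i in change] + [exit_age]
        sts = [states[0]] + [states[i] for i in change]
        for j, st in enumerate(sts):
            t0, t1 = bounds[j] - 50.0, bounds[j + 1] - 50.0
            is_last = j == len(sts) - 1
            if st < 4:
                rows.append((pid, UP_TRANSITION[st], st, t0, t1,
                             int(not is_last), sex, q))
            if st <= 4:
                rows.append((pid, DEATH_TRANSITION[st], st, t0, t1,
                             int(is_last and died), sex, q))
    return pd.DataFrame(rows, columns=_EPISODE_COLUMNS)


@dataclass
class EpisodeBuild:
    episodes: pd.DataFrame
    excluded_ids: set
    log: dict


def build_analysis_episodes(cohort: pd.DataFrame,
                            slice_days: float = SLICE_DAYS) -> EpisodeBuild:
    """Cohort -> episodes in one vectorized pass (the production path).

    Equivalent to ``build_episodes(slice_timeline(cohort))`` after removing
    multi-jump individuals, but without materializing the panel; the
    equivalence is exercised by the test suite.
    """
    h = _slice_width(slice_days)
    entry = cohort["entry_age"].to_numpy(dtype=float)
    exit_ = cohort["exit_age"].to_numpy(dtype=float)
    if np.any(exit_ <= entry):
        raise ValueError("exit_age must exceed entry_age")
    # early deaths stay in: only censoring within the first slice makes an
    # individual unobservable
    observable = (exit_ - entry > h) | (cohort["exit_reason"].to_numpy() == "death")
    entry_state, snapped, counts = _snap_onsets(cohort, slice_days)

    # multi-jump: two post-entry onsets snapping to the same slice boundary
    with np.errstate(invalid="ignore"):
        same = np.isfinite(snapped[:, :-1]) & np.isfinite(snapped[:, 1:]) & (
            np.abs(np.diff(snapped, axis=1)) < h * 1e-6)
    multi = same.any(axis=1)
    ids = cohort["id"].to_numpy()
    excluded = {"short_followup": set(ids[~observable]),
                "multi_jump": set(ids[multi & observable])}
    keep = observable & ~multi

    n = int(keep.sum())
    entry, exit_ = entry[keep], exit_[keep]
    es, sn, c = entry_state[keep], snapped[keep], counts[keep]
    died = (cohort["exit_reason"].to_numpy()[keep] == "death")
    kid = ids[keep]
    sex = cohort["sex"].to_numpy()[keep]
    quint = cohort["simd_quintile"].to_numpy()[keep]

    nsoj = c + 1
    idx = np.repeat(np.arange(n), nsoj)
    soj = np.arange(nsoj.sum()) - np.repeat(
        np.concatenate([[0], np.cumsum(nsoj)[:-1]]), nsoj)
    pad = np.full((n, 1), np.inf)
    S = np.hstack([sn, pad])
    t_start = np.where(soj == 0, entry[idx], S[idx, np.maximum(soj - 1, 0)])
    t_end = np.where(soj == c[idx], exit_[idx], S[idx, soj])
    state = es[idx] + soj
    by_onset = soj < c[idx]
    by_death = (soj == c[idx]) & died[idx]

    parts = []
    up = state < 4
    tid_up = np.array([0, 1, 3, 5, 0])
    tid_dn = np.array([0, 2, 4, 6, 7])
    parts.append(pd.DataFrame({
        "id": kid[idx[up]], "transition_id": tid_up[state[up]],
        "from_state": state[up], "t_entry": t_start[up] - 50.0,
        "t_exit": t_end[up] - 50.0, "status": by_onset[up].astype(int),
        "sex": sex[idx[up]], "simd_quintile": quint[idx[up]]}))
    parts.append(pd.DataFrame({
        "id": kid[idx], "transition_id": tid_dn[state],
        "from_state": state, "t_entry": t_start - 50.0,
        "t_exit": t_end - 50.0, "status": by_death.astype(int),
        "sex": sex[idx], "simd_quintile": quint[idx]}))
    episodes = pd.concat(parts, ignore_index=True)
    episodes = episodes.sort_values(["id", "t_entry", "transition_id"],
                                    kind="stable").reset_index(drop=True)
    log = {"n_input": len(cohort),
           "n_short_followup": len(excluded["short_followup"]),
           "n_multi_jump": len(excluded["multi_jump"]),
           "n_analyzed": n,
           "events_per_transition": episodes[episodes["status"] == 1]
               .groupby("transition_id").size().to_dict()}
    logger.info("episodes: %s", log)
    return EpisodeBuild(episodes, excluded["multi_jump"], log)


def compute_weights(baseline: pd.DataFrame,
                    age_window: tuple[float, float] = (45.0, 55.0),
                    strata: tuple[str, ...] = ("sex", "simd_quintile")) -> pd.DataFrame:
    """Empirical start-state weights per stratum from a baseline table.

    The baseline table has one row per individual with an ``age`` and a
    ``state`` in 1..4; the half-open age window [45, 55) centers the
    weights at age 50.
    """
    lo, hi = age_window
    sub = baseline[(baseline["age"] >= lo) & (baseline["age"] < hi)]
    rows = []
    for key, g in sub.groupby(list(strata)):
        key = key if isinstance(key, tuple) else (key,)
        w = np.array([(g["state"] == s).sum() for s in (1, 2, 3, 4)], dtype=float)
        rows.append({**dict(zip(strata, key)),
                     **{f"w{s}": w[s - 1] / w.sum() for s in (1, 2, 3, 4)},
                     "n": int(w.sum())})
    if not rows:
        raise ValueError(f"no baseline individuals in window {age_window} "
                         f"for strata {strata}")
    out = pd.DataFrame(rows)
    if (out["n"] == 0).any():
        bad = out.loc[out["n"] == 0, list(strata)].to_dict("records")
        raise ValueError(f"empty stratum in weights computation: {bad}")
    return out


def merge_time_updated(episodes: pd.DataFrame, risk_factors: pd.DataFrame,
                       clock_origin: float = 50.0) -> pd.DataFrame:
    """Split episodes at risk-factor measurement times (piecewise-constant
    covariates for the time-updated sensitivity models).

    Measurement ages define a step function per (id, factor); each episode
    is cut at the measurement ages it spans and each segment carries the
    then-current value as an ``rf_<factor>`` column.  Only the final
    segment of an event episode keeps the event.  Centering is applied
    later, at fit time, on the analysis-table grand mean.
    """
    factors = sorted(risk_factors["factor"].unique())
    rf = {f: {pid: (g["age"].to_numpy() - clock_origin, g["value"].to_numpy())
              for pid, g in grp.sort_values("age").groupby("id")}
          for f, grp in risk_factors.groupby("factor")}
    out = []
    for row in episodes.itertuples(index=False):
        cuts = {row.t_entry, row.t_exit}
        for f in factors:
            ages, _ = rf[f].get(row.id, (np.empty(0), np.empty(0)))
            cuts.update(a for a in ages if row.t_entry < a < row.t_exit)
        bounds = sorted(cuts)
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = row._asdict()
            seg["t_entry"], seg["t_exit"] = a, b
            seg["status"] = row.status if b == row.t_exit else 0
            for f in factors:
                ages, vals = rf[f].get(row.id, (np.empty(0), np.empty(0)))
                i = np.searchsorted(ages, a + 1e-12) - 1
                seg[f"rf_{f}"] = float(vals[max(i, 0)]) if vals.size else 0.0
            out.append(seg)
    return pd.DataFrame(out)
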