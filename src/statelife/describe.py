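"""Descriptive surfaces of the cohort.

Counts and shares at study entry, the complication composition of
up-transitions, age-specific mortality rates per 1,000 person-years, and
baseline state prevalence by age band.  Displayed percentages and rates
round to one decimal; exported tables keep full precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import COMPLICATIONS, ONSET_COLUMNS
from .gompertz import UP_TRANSITION

__all__ = ["shares", "cohort_summary", "transition_table", "mortality_rates",
           "state_prevalence_by_age", "AGE_BANDS"]

AGE_BANDS = [(50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 80),
             (80, 85), (85, np.inf)]


def shares(counts) -> np.ndarray:
    """Percentages of a partition from its counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cannot form shares of an all-zero row")
    return 100.0 * counts / counts.sum()


def _median_iqr(x: pd.Series) -> tuple[float, str]:
    q1, med, q3 = np.percentile(x.dropna(), [25, 50, 75])
    return med, f"({q1:.1f} {q3:.1f})"


def entry_states(cohort: pd.DataFrame) -> np.ndarray:
    onsets = cohort[[c for c in ONSET_COLUMNS if c in cohort]].to_numpy(dtype=float)
    entry = cohort["entry_age"].to_numpy(dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        pre = np.nansum(onsets <= entry, axis=1).astype(int)
    return np.minimum(4, 1 + pre)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Study-entry characteristics: sex, deprivation, complications, states."""
    if cohort.empty:
        raise ValueError("empty cohort")
    n = len(cohort)
    rows = []

    def pct_row(label, count):
        rows.append({"label": label, "value": count,
                     "detail": f"{100.0 * count / n:.1f}%"})

    for sex in ("male", "female"):
        pct_row(sex.capitalize() + "s", int((cohort["sex"] == sex).sum()))
    med, iqr = _median_iqr(cohort["entry_age"])
    rows.append({"label": "Age (years): Median", "value": round(med, 1), "detail": iqr})
    med, iqr = _median_iqr(cohort["exit_age"] - cohort["entry_age"])
    rows.append({"label": "Follow-Up Time (years): Median", "value": round(med, 1),
                 "detail": iqr})
    entry = cohort["entry_age"].to_numpy(dtype=float)
    for comp, col in zip(COMPLICATIONS, ONSET_COLUMNS):
        if col in cohort:
            pct_row(comp, int((cohort[col] <= entry).sum()))
    states = entry_states(cohort)
    labels = ["0 Complications", "1 Complication", "2 Complications",
              "3+ Complications"]
    for s, label in enumerate(labels, start=1):
        pct_row(label, int((states == s).sum()))
    for q in (1, 2, 3, 4, 5):
        pct_row(f"Quintile {q}", int((cohort["simd_quintile"] == q).sum()))
    return pd.DataFrame(rows)


def transition_table(events: pd.DataFrame) -> pd.DataFrame:
    """Complication composition of the three up-transitions.

    ``events`` needs columns transition_id and complication (the
    complication causing each up-transition); rows are transitions 1, 3, 5
    with counts and row percentages summing to 100%.
    """
    up = events[events["transition_id"].isin(UP_TRANSITION.values())]
    if (up["complication"].fillna("") == "").any():
        raise ValueError("up-transition events must carry a complication label")
    rows = []
    for tid in sorted(UP_TRANSITION.values()):
        sub = up[up["transition_id"] == tid]
        counts = np.array([(sub["complication"] == c).sum() for c in COMPLICATIONS])
        pct = shares(counts)
        row = {"transition": tid}
        for c, k, p in zip(COMPLICATIONS, counts, pct):
            row[c] = int(k)
            row[f"{c}_pct"] = round(float(p), 1)
        row["all"] = int(counts.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def mortality_rates(mort: pd.DataFrame, min_person_years: float = 10.0) -> pd.DataFrame:
    """Deaths per 1,000 person-years from a mortality-inputs table.

    Cells with person-time below ``min_person_years`` are suppressed
    (rate set to NaN) rather than reported from unstable denominators.
    """
    out = mort.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 1000.0 * out["deaths"] / out["person_years"]
    out["rate_per_1000py"] = np.where(out["person_years"] >= min_person_years,
                                      rate, np.nan)
    return out


def state_prevalence_by_age(baseline: pd.DataFrame,
                            bands=AGE_BANDS,
                            strata: tuple[str, ...] = ()) -> pd.DataFrame:
    """Shares of states 1-4 per age band (and stratum) at study entry.

    ``baseline`` has one row per individual with ``age`` and ``state``;
    empty bands are suppressed.
    """
    keys = (baseline[list(strata)].astype(str).agg("|".join, axis=1)
            if strata else pd.Series(["all"] * len(baseline), index=baseline.index))
    rows = []
    for key in keys.unique():
        sub = baseline[keys == key]
        for lo, hi in bands:
            g = sub[(sub["age"] >= lo) & (sub["age"] < hi)]
            if g.empty:
                continue
            counts = np.array([(g["state"] == s).sum() for s in (1, 2, 3, 4)])
            row = {"age_lo": lo, "age_hi": hi, "n": int(counts.sum())}
            if strata:
                row.update(dict(zip(strata, key.split("|"))))
            for s in (1, 2, 3, 4):
                row[f"share_state{s}"] = counts[s - 1] / counts.sum()
            rows.append(row)
    return pd.DataFrame(rows)


def plot_mortality_rates(rates: pd.DataFrame, ax=None):
    """Log-scale mortality-rate curves by age group (one line per stratum)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    strata_cols = [c for c in rates.columns
                   if c not in ("age_lo", "age_hi", "deaths", "person_years",
                                "rate_per_1000py")]
    if strata_cols:
        for key, g in rates.groupby(strata_cols):
            ax.plot(g["age_lo"], g["rate_per_1000py"], marker="o",
                    label=str(key))
        ax.legend(fontsize=7)
    else:
        ax.plot(rates["age_lo"], rates["rate_per_1000py"], marker="o")
    ax.set_yscale("log")
    ax.set_xlabel("age group start")
    ax.set_ylabel("deaths per 1,000 PY")
    return ax


def plot_state_prevalence(prev: pd.DataFrame, ax=None):
    """Stacked state-prevalence shares over age bands (single stratum)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = prev["age_lo"].to_numpy()
    bottom = np.zeros(len(prev))
    for s in (1, 2, 3, 4):
        y = prev[f"share_state{s}"].to_numpy()
        ax.bar(x, y, bottom=bottom, width=4.0, label=f"state {s}")
        bottom += y
    ax.set_xlabel("age band start")
    ax.set_ylabel("share")
    ax.legend(fontsize=7)
    return ax
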