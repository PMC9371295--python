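"""Individual-level nonparametric bootstrap for expectancy uncertainty.

Individuals are resampled with replacement (all their records move
together), the full pipeline — panel, episode construction, seven
transition fits, start-state weights, occupancy, expectancy — is re-run
per replicate, and 95% intervals are formed from the replicate standard
errors (normal approximation; percentile intervals are available).  The
auxiliary baseline sample used for the weights is resampled too, so the
intervals propagate weight-estimation uncertainty as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expectancy import estimate_expectancies

__all__ = ["BootstrapResult", "bootstrap_expectancies"]

logger = logging.getLogger("statelife")


@dataclass
class BootstrapResult:
    n_reps: int
    n_failed: int
    seed: int
    point: pd.Series
    replicates: pd.DataFrame
    se: pd.Series
    ci: pd.DataFrame
    method: str

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"point": self.point, "se": self.se})
        return out.join(self.ci)


def _flatten(table: pd.DataFrame) -> pd.Series:
    """Expectancy table -> one named value per (stratum, quantity)."""
    vals = {}
    value_cols = [c for c in table.columns if c not in ("sex", "simd_quintile")]
    for _, r in table.iterrows():
        tag = r["sex"] if pd.isna(r.get("simd_quintile")) or r.get("simd_quintile") is None \
            else f"{r['sex']}_q{int(r['simd_quintile'])}"
        for c in value_cols:
            vals[f"{tag}_{c}"] = float(r[c])
    return pd.Series(vals)


def bootstrap_expectancies(cohort: pd.DataFrame, weight_sample: pd.DataFrame,
                           covariate_set: str = "set2",
                           n_reps: int = 300, seed: int = 0,
                           method: str = "normal",
                           stratified: bool = False,
                           max_failure_rate: float = 0.10,
                           estimator=None,
                           **pipeline_kwargs) -> BootstrapResult:
    """Bootstrap all total and state-specific expectancies.

    Per-replicate seeds are derived from ``seed`` and the replicate counter,
    so results do not depend on evaluation order or worker count.
    Replicates whose fits fail to converge are logged and dropped; more
    than ``max_failure_rate`` failures aborts, as the estimates are then
    unstable.

    ``estimator`` maps (cohort, weight_sample) to a named Series of
    quantities; by default it is the full expectancy pipeline.  Replicates
    run the exact same callable as the point estimate, so the two can
    never diverge.
    """
    if estimator is None:
        def estimator(c, w):
            return _flatten(estimate_expectancies(c, w, covariate_set,
                                                  **pipeline_kwargs)[0])
    point = estimator(cohort, weight_sample)
    n = len(cohort)
    m = len(weight_sample)
    strata_codes = (cohort["sex"].astype(str) + "|" +
                    cohort["simd_quintile"].astype(str)).to_numpy() if stratified else None
    reps = []
    failed = 0
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        if stratified:
            idx = np.concatenate([
                rng.choice(np.flatnonzero(strata_codes == s),
                           size=int((strata_codes == s).sum()), replace=True)
                for s in np.unique(strata_codes)])
        else:
            idx = rng.integers(0, n, n)
        widx = rng.integers(0, m, m)
        boot = cohort.iloc[idx].reset_index(drop=True)
        boot["id"] = np.arange(1, n + 1)  # resampled copies are distinct people
        wboot = weight_sample.iloc[widx].reset_index(drop=True)
        try:
            reps.append(estimator(boot, wboot))
        except (ValueError, RuntimeError, FloatingPointError) as err:
            failed += 1
            logger.warning("bootstrap replicate %d failed: %s", r, err)
    if failed > max_failure_rate * n_reps:
        raise RuntimeError(
            f"bootstrap unstable: {failed}/{n_reps} replicates failed")
    replicates = pd.DataFrame(reps)
    se = replicates.std(ddof=1)
    if method == "normal":
        ci = pd.DataFrame({"lo95": point - 1.96 * se, "hi95": point + 1.96 * se})
    elif method == "percentile":
        ci = pd.DataFrame({"lo95": replicates.quantile(0.025),
                           "hi95": replicates.quantile(0.975)})
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return BootstrapResult(n_reps=n_reps, n_failed=failed, seed=seed,
                           point=point, replicates=replicates, se=se, ci=ci,
                           method=method)
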