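"""Pooled-control equivalence QC.

A pooled control is a physical average of the individual samples, so its
region-intensity profile should match the per-region mean of the individuals.
Each pooled control's region intensities are regressed on the individual
means by ordinary least squares (pooled on y, means on x); platform accuracy
is declared when every fitted slope ("tangent") is close to 1.

The regression p-value is the test of zero slope.  Note the attenuation
caveat: noise in the individual means (the x variable) biases the slope
below 1, which bounds how close to 1 real data can sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .regions import RegionMatrix

__all__ = ["QCReport", "mean_and_se_by_region", "pooled_equivalence"]


@dataclass
class QCReport:
    per_pool: pd.DataFrame  # index pool_id; slope, intercept, r_squared, p_value
    slope_mean: float
    slope_sd: float
    slope_tolerance: float
    passed: bool

    def to_dict(self) -> dict:
        d = {pid: {k: float(v) for k, v in row.items()}
             for pid, row in self.per_pool.iterrows()}
        d["summary"] = {"slope_mean": self.slope_mean, "slope_sd": self.slope_sd,
                        "slope_tolerance": self.slope_tolerance,
                        "pass": bool(self.passed)}
        return d


def mean_and_se_by_region(matrix: RegionMatrix,
                          individual_ids: list[str]) -> pd.DataFrame:
    """Per-region arithmetic mean and standard error (SD/sqrt(n)) over the
    individual samples only."""
    if len(individual_ids) < 2:
        raise ValueError("need at least 2 individual samples")
    sub = matrix.values.loc[individual_ids]
    mean = sub.mean(axis=0)
    se = sub.std(axis=0, ddof=1) / np.sqrt(len(individual_ids))
    return pd.DataFrame({"mean": mean, "se": se})


def pooled_equivalence(matrix: RegionMatrix, pooled_ids: list[str],
                       individual_ids: list[str],
                       slope_tolerance: float = 0.1,
                       through_origin: bool = False) -> QCReport:
    """OLS of each pooled control's region intensities on the per-region
    individual means; passes when every |slope - 1| <= slope_tolerance."""
    if not pooled_ids:
        raise ValueError("need at least one pooled control")
    if len(matrix.regions) < 3:
        raise ValueError("under-determined regression: need >= 3 regions")
    x = mean_and_se_by_region(matrix, individual_ids)["mean"].to_numpy()
    rows = {}
    for pid in pooled_ids:
        y = matrix.values.loc[pid].to_numpy()
        if through_origin:
            slope = float(np.dot(x, y) / np.dot(x, x))
            intercept = 0.0
            resid = y - slope * x
            ss_tot = float(np.dot(y, y))
            r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
            # slope t-test with n-1 dof (one fitted parameter)
            n = x.size
            se = np.sqrt(np.dot(resid, resid) / (n - 1) / np.dot(x, x))
            t = slope / se if se > 0 else np.inf
            p = float(2 * scipy.stats.t.sf(abs(t), n - 1))
        else:
            fit = scipy.stats.linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
            r2, p = float(fit.rvalue ** 2), float(fit.pvalue)
        rows[pid] = {"slope": slope, "intercept": intercept,
                     "r_squared": r2, "p_value": max(p, 1e-300)}
    per_pool = pd.DataFrame.from_dict(rows, orient="index")
    slopes = per_pool["slope"]
    passed = bool((np.abs(slopes - 1.0) <= slope_tolerance).all())
    return QCReport(per_pool=per_pool,
                    slope_mean=float(slopes.mean()),
                    slope_sd=float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0,
                    slope_tolerance=slope_tolerance,
                    passed=passed)
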