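"""OLS regression of drug risk on target count, and outlier flagging."""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclasses.dataclass(slots=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    residuals: dict[str, float]
    rmse: float

    def residual(self, drug_id: str) -> float:
        return self.residuals[drug_id]


def ols_fit(
    x: Sequence[float],
    y: Sequence[float],
    labels: Sequence[str] | None = None,
) -> RegressionResult:
    """Ordinary-least-squares fit of y on x with intercept.

    r² = 1 − SS_res/SS_tot; defined as 0 when y is constant (SS_tot = 0).
    Degenerate x (all equal) is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    if labels is None:
        labels = [str(i) for i in range(len(x))]
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        logger.info("constant response: r^2 reported as 0 by convention")
        r_squared = 0.0
    else:
        r_squared = 1.0 - float(np.sum(resid**2)) / ss_tot
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        residuals={label: float(r) for label, r in zip(labels, resid)},
        rmse=math.sqrt(float(np.mean(resid**2))),
    )


def flag_outliers(result: RegressionResult, k: float = 1.0) -> frozenset[str]:
    """Drugs with residual > k × RMSE — higher-than-expected risk only
    (one-sided: negative residuals are never flagged).

    An (essentially) exact fit flags nothing: comparing float-noise residuals
    against a float-noise RMSE would otherwise flag arbitrary points.
    """
    if result.rmse <= 1e-12:
        return frozenset()
    return frozenset(
        drug_id for drug_id, r in result.residuals.items() if r > k * result.rmse
    )


def regression_report(
    drp_by_drug: Mapping[str, float],
    n_targets_by_drug: Mapping[str, int],
    k: float = 1.0,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Fit DRP ~ target count across drugs and report per-drug residuals.

    Returns the fit plus a frame (drug_id, n_targets, drp, residual, flagged).
    """
    drugs = sorted(set(drp_by_drug) & set(n_targets_by_drug))
    result = ols_fit(
        [n_targets_by_drug[d] for d in drugs],
        [drp_by_drug[d] for d in drugs],
        labels=drugs,
    )
    flagged = flag_outliers(result, k)
    frame = pd.DataFrame(
        {
            "drug_id": drugs,
            "n_targets": [n_targets_by_drug[d] for d in drugs],
            "drp": [drp_by_drug[d] for d in drugs],
            "residual": [result.residuals[d] for d in drugs],
            "flagged": [d in flagged for d in drugs],
        }
    )
    return result, frame
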