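"""Method-comparison statistics: OLS R², Bland–Altman agreement, Spearman correlation.

Used to compare BRS/BEI estimates across series variants (original vs
band-split) and across methods (sequence vs transfer function).  These are
descriptive: p-values are reported, never used as gates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "AgreementResult",
    "ols_r2",
    "bland_altman",
    "spearman_rho",
]

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    coefficients: dict[str, float]  # includes "intercept"
    r2: float
    p_values: dict[str, float]
    n: int
    n_dropped: int = 0


@dataclass
class AgreementResult:
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    proportional_bias_slope: float
    proportional_bias_p: Optional[float]
    n: int


def _complete_cases(y: np.ndarray, X: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame, int]:
    mask = np.isfinite(y) & np.all(np.isfinite(X.to_numpy()), axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropping %d observation(s) with undefined values", dropped)
    return y[mask], X.loc[mask], dropped


def ols_r2(
    response: np.ndarray | list[float],
    predictors: Mapping[str, np.ndarray] | pd.DataFrame,
) -> RegressionResult:
    """OLS of response on one or two predictor series, with intercept.

    Observations with NaN in the response or any predictor are dropped
    pairwise (logged).  A constant predictor raises, naming the offender.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors)
    if len(X) != len(y):
        raise ValueError("response and predictors must have equal length")
    y, X, dropped = _complete_cases(y, X)
    k = X.shape[1]
    if len(y) <= k + 1:
        raise ValueError(f"need more than {k + 1} complete observations, have {len(y)}")
    for name in X.columns:
        if np.ptp(X[name].to_numpy()) == 0:
            raise ValueError(f"predictor '{name}' is constant; model is singular")

    model = sm.OLS(y, sm.add_constant(X, prepend=True)).fit()
    names = ["intercept"] + list(X.columns)
    # constant response: no variance to explain, R² defined as 0
    r2 = 0.0 if np.ptp(y) == 0 else float(model.rsquared)
    return RegressionResult(
        coefficients=dict(zip(names, model.params)),
        r2=r2,
        p_values=dict(zip(names, model.pvalues)),
        n=len(y),
        n_dropped=dropped,
    )


def bland_altman(a: np.ndarray | list[float], b: np.ndarray | list[float]) -> AgreementResult:
    """Bland–Altman agreement of two paired measurements.

    Differences a−b against means (a+b)/2; limits of agreement are
    mean ± 1.96·SD.  Proportional bias is the OLS slope of the difference on
    the mean, with its t-test p-value (None when degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired values must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = a - b
    mean = (a + b) / 2.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))

    if np.ptp(mean) == 0 or np.ptp(diff) == 0:
        slope, p = 0.0, None
        if np.ptp(mean) > 0 and np.ptp(diff) == 0:
            slope = 0.0  # constant difference: exactly no proportional bias
    else:
        fit = stats.linregress(mean, diff)
        slope, p = float(fit.slope), float(fit.pvalue)
    return AgreementResult(
        mean_diff=md,
        sd_diff=sd,
        loa_lower=md - 1.96 * sd,
        loa_upper=md + 1.96 * sd,
        proportional_bias_slope=slope,
        proportional_bias_p=p,
        n=len(a),
    )


def spearman_rho(a: np.ndarray | list[float], b: np.ndarray | list[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired values must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(stats.rankdata(a)) == 0 or np.ptp(stats.rankdata(b)) == 0:
        raise ValueError("zero rank variance; Spearman correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)
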