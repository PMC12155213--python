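"""Robust outlier removal (ROUT-style, one-group location model) at Q = 2%.

Site-level HI values of all wounds in one category on one day are pooled
and screened before per-wound averaging.  The procedure follows the
published robust-regression-and-outlier-removal recipe specialized to a
single-group location fit:

* robust center = median;
* robust spread = RSDR, the 68.27th percentile of absolute residuals with
  the small-sample correction n / (n - K), K = 1 fitted parameter;
* each candidate (up to the 30% most extreme values) gets a two-sided
  t-like p-value from |residual| / RSDR with n - K degrees of freedom;
* candidates are removed outside-in under Benjamini-Hochberg-style FDR
  control at level Q.

This is an independent implementation of the published method, not the
commercial one; exact numerical agreement with the latter is not
guaranteed.  Removal is deterministic and monotone in |residual|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["OutlierResult", "rout_outliers"]

logger = logging.getLogger(__name__)

MAX_OUTLIER_FRACTION = 0.30


@dataclass
class OutlierResult:
    kept: np.ndarray
    removed: np.ndarray
    kept_mask: np.ndarray
    center: float
    spread: float
    q: float
    warning: str | None = field(default=None)


def rout_outliers(values, q: float = 0.02) -> OutlierResult:
    """Flag outliers in one pooled category-day group of HI values.

    Returns the kept/removed partition plus the robust center and spread.
    Groups of fewer than 3 values are returned untouched with a warning.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be a 1-D array")
    if not 0.0 <= q < 1.0:
        raise ValueError("Q must be in [0, 1)")
    n = x.size
    if n < 3:
        msg = f"need >= 3 values for outlier analysis, got {n}; nothing removed"
        logger.warning(msg)
        return OutlierResult(
            x.copy(), np.array([]), np.ones(n, dtype=bool),
            float(np.median(x)) if n else np.nan, np.nan, q, warning=msg,
        )
    center = float(np.median(x))
    resid = x - center
    abs_resid = np.abs(resid)
    p68 = float(np.percentile(abs_resid, 68.27))
    spread = p68 * n / (n - 1)
    if q == 0.0 or spread == 0.0:
        # Q = 0 disables removal; zero spread means >68% of values coincide
        # with the median and anything distinct would be trivially "infinite"
        # sigmas away -- treat as degenerate and keep everything unless a
        # value differs while spread is exactly 0 and q > 0.
        if spread == 0.0 and q > 0.0 and np.any(abs_resid > 0):
            mask = abs_resid == 0
            return OutlierResult(x[mask], x[~mask], mask, center, spread, q)
        return OutlierResult(x.copy(), np.array([]), np.ones(n, dtype=bool),
                             center, spread, q)
    t = abs_resid / spread
    pvals = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(-abs_resid, kind="stable")  # most extreme first
    n_candidates = max(1, int(np.floor(MAX_OUTLIER_FRACTION * n)))
    # BH outside-in: remove the i most extreme values for the largest i such
    # that the i-th most extreme candidate has p <= Q * i / n
    n_remove = 0
    for i in range(n_candidates, 0, -1):
        if pvals[order[i - 1]] <= q * i / n:
            n_remove = i
            break
    mask = np.ones(n, dtype=bool)
    mask[order[:n_remove]] = False
    if n_remove:
        logger.info("ROUT removed %d of %d values (Q=%g)", n_remove, n, q)
    return OutlierResult(x[mask], x[~mask], mask, center, spread, q)
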