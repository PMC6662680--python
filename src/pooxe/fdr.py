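"""Storey-Tibshirani q-values and QQ-plot data.

The q-value of a test is the smallest false discovery rate at which it
would be called significant. ``pi0``, the proportion of true null
hypotheses, is estimated from the flat right tail of the p-value
histogram: ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` on the
canonical grid ``lambda = 0, 0.05, ..., 0.90``, smoothed with a natural
cubic spline and read off at the largest lambda. With ``pi0 = 1`` the
q-values reduce exactly to Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import beta

__all__ = ["QValueResult", "estimate_pi0", "q_values", "qvalue", "qq_data", "add_qvalues"]

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = np.arange(0.0, 0.95, 0.05)  # 0, 0.05, ..., 0.90
MIN_PI0 = 1e-8


@dataclass
class QValueResult:
    pi0: float
    q_values: np.ndarray
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA.copy())

    @property
    def m(self) -> int:
        return len(self.q_values)


def _check_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p-values must be a non-empty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(p_values, lambda_grid: np.ndarray | None = None) -> float:
    """Spline estimate of the proportion of true nulls.

    Falls back to ``pi0 = 1`` (logged) for fewer than 100 tests, where
    the spline extrapolation is unstable.
    """
    p = _check_p(p_values)
    lam = DEFAULT_LAMBDA if lambda_grid is None else np.asarray(lambda_grid, dtype=float)
    m = p.size
    if m < 100:
        logger.info("pi0 estimation skipped for m=%d < 100; using pi0=1", m)
        return 1.0
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    spline = CubicSpline(lam, pi0_lam, bc_type="natural")
    pi0 = float(spline(lam.max()))
    if pi0 <= 0.0:
        logger.warning("pi0 estimate %.3g <= 0; clipping to %g", pi0, MIN_PI0)
        return MIN_PI0
    return min(pi0, 1.0)


def q_values(p_values, pi0: float = 1.0) -> np.ndarray:
    """Step-down q-values for given pi0, returned in the input order.

    For ordered p-values ``p_(1) <= ... <= p_(m)``:
    ``q_(m) = pi0 * p_(m)`` and
    ``q_(i) = min(pi0 * m * p_(i) / i, q_(i+1))``.
    """
    p = _check_p(p_values)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def qvalue(p_values, lambda_grid: np.ndarray | None = None) -> QValueResult:
    """Full Storey-Tibshirani path: estimate pi0, then q-values."""
    p = _check_p(p_values)
    pi0 = estimate_pi0(p, lambda_grid)
    return QValueResult(
        pi0=pi0,
        q_values=q_values(p, pi0),
        lambda_grid=(DEFAULT_LAMBDA if lambda_grid is None else np.asarray(lambda_grid)).copy(),
    )


def qq_data(p_values, band_level: float = 0.95, p_floor: float = 1e-300) -> pd.DataFrame:
    """Observed vs expected -log10 p-values with pointwise confidence band.

    Expected quantiles are the medians of the uniform order statistics;
    the pointwise band at ``band_level`` comes from the Beta(i, m-i+1)
    distribution of the i-th order statistic. Zero p-values are floored
    at ``p_floor`` before taking logs.
    """
    p = _check_p(p_values)
    if not 0.0 < band_level < 1.0:
        raise ValueError("band_level must lie in (0, 1)")
    m = p.size
    if np.any(p < p_floor):
        logger.warning("p-values below %.3g floored for the log scale", p_floor)
    p_sorted = np.sort(np.maximum(p, p_floor))
    i = np.arange(1, m + 1)
    dist = beta(i, m - i + 1)
    alpha = 1.0 - band_level
    out = pd.DataFrame(
        {
            "expected": -np.log10(dist.median()),
            "observed": -np.log10(p_sorted),
            "band_low": -np.log10(dist.ppf(1.0 - alpha / 2.0)),
            "band_high": -np.log10(np.maximum(dist.ppf(alpha / 2.0), p_floor)),
        }
    ).iloc[::-1].reset_index(drop=True)  # ascending -log10 on both axes
    out.attrs["band_level"] = band_level
    out.attrs["band_construction"] = "beta order statistics, pointwise"
    return out


def add_qvalues(table: pd.DataFrame, p_col: str = "p", q_col: str = "q") -> pd.DataFrame:
    """Fill a scan table's q-value column from its p-values.

    Rows without a finite p-value (failed fits) are excluded from the
    multiplicity count m and keep NaN q.
    """
    out = table.copy()
    ok = np.isfinite(out[p_col].to_numpy(dtype=float))
    if ok.sum() == 0:
        raise ValueError("no finite p-values to adjust")
    res = qvalue(out.loc[ok, p_col].to_numpy(dtype=float))
    out[q_col] = np.nan
    out.loc[ok, q_col] = res.q_values
    out.attrs["pi0"] = res.pi0
    return out
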