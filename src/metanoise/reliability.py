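"""Test-retest agreement statistics and split-half construction.

Two statistics quantify agreement between a test vector ``x`` and a retest
vector ``y`` of per-subject measure values: the Pearson correlation (is the
*pattern* across subjects reproduced?) and the normalized mean absolute
error

    NMAE(x, y) = mean_i |x_i - y_i|
                 / ( 1/2 mean_i |x_i - ybar| + 1/2 mean_i |y_i - xbar| ),

whose denominator — the mean absolute distance of each value to the
average of the *other* session — makes the error scale-free, so NMAE can
be compared across measures. NMAE = 1 means a subject's test value is on
average no closer to its own retest value than to the retest group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedStatisticError(ValueError):
    """Raised when a reliability statistic is undefined (constant input,
    zero denominator, too few usable pairs)."""


def split_half_interleaved(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a trial table into interleaved 'test' and 'retest' halves.

    Odd positions (1st, 3rd, ...) go to the test half, even positions to
    the retest half; sizes differ by at most one and the two halves
    partition the input in its stored order.
    """
    if len(trials) < 2:
        raise ValueError("split-half requires at least 2 trials")
    test = trials.iloc[0::2].reset_index(drop=True)
    retest = trials.iloc[1::2].reset_index(drop=True)
    return test, retest


def nmae(x, y) -> float:
    """Normalized mean absolute error between paired test/retest vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be aligned 1-d vectors of length >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite; drop missing pairs first")
    num = np.mean(np.abs(x - y))
    den = 0.5 * np.mean(np.abs(x - y.mean())) + 0.5 * np.mean(np.abs(y - x.mean()))
    if den == 0:
        raise UndefinedStatisticError(
            "NMAE undefined: all values identical across both sessions"
        )
    return float(num / den)


def pearson(x, y) -> float:
    """Sample Pearson correlation between paired test/retest vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson requires aligned 1-d vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("pearson undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ReliabilityResult:
    pearson_r: float
    nmae: float  # NaN when flagged invalid (hierarchical inputs)
    n_used: int
    n_dropped: int


def reliability(
    x_measures,
    y_measures,
    exclude_abs: float | None = None,
    hierarchical: bool = False,
) -> ReliabilityResult:
    """Pearson and NMAE reliability with missing/extreme-value policy.

    Pairs with a non-finite entry in either session are dropped, as are
    pairs where either |value| exceeds ``exclude_abs`` (used with the
    |M_ratio| > 10 rule). NMAE is reported as NaN when the inputs come
    from hierarchical estimation: the separate group priors compress each
    session around its own mean, which artificially deflates the NMAE.
    """
    x = np.asarray(x_measures, dtype=float)
    y = np.asarray(y_measures, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    if exclude_abs is not None:
        keep &= (np.abs(x) <= exclude_abs) & (np.abs(y) <= exclude_abs)
    n_used = int(keep.sum())
    if n_used < 3:
        raise UndefinedStatisticError(
            f"only {n_used} usable pairs after exclusion; need >= 3"
        )
    xr, yr = x[keep], y[keep]
    return ReliabilityResult(
        pearson_r=pearson(xr, yr),
        nmae=float("nan") if hierarchical else nmae(xr, yr),
        n_used=n_used,
        n_dropped=int(x.size - n_used),
    )
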