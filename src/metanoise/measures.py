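"""Type 1 and type 2 performance measures from confidence-rating data.

Implements the standard equal-variance signal-detection quantities (d',
criterion), the area under the type 2 ROC curve (AUROC2), the maximum-
likelihood meta-d' fit, and the metacognitive efficiency measures derived
from it: M_diff = meta-d' - d' and M_ratio = meta-d' / d', together with
the regularized M_ratio variants (exclusion, bounding, logarithm, and — in
:mod:`metanoise.hierarchical` — hierarchical group-prior estimation).

meta-d' expresses metacognitive sensitivity in type 1 units: it is the d'
that an SDT-ideal metacognitive observer would need in order to produce the
observed confidence-rating distributions conditional on stimulus and
response, holding the type 1 criterion at the same relative position
c' = c / d' as observed. It is estimated by maximizing the multinomial
likelihood of the 2 x 2 x K rating counts over meta-d' and the 2(K-1)
type 2 criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

DEFAULT_N_RATINGS = 6
MRATIO_LOWER = 0.0
MRATIO_UPPER = 1.6
MRATIO_LOG_FLOOR = 0.1
#: |M_ratio| above this is flagged as unusable in reliability analyses.
MRATIO_EXTREME = 10.0


class UndefinedMeasureError(ValueError):
    """Raised when a measure is undefined for the given data (e.g. AUROC2
    with no error trials, or meta-d' at d' = 0)."""


# ---------------------------------------------------------------------------
# rating preprocessing
# ---------------------------------------------------------------------------

def floor_negative_ratings(ratings):
    """Replace every rating below 1 by 1 (some scales use negative ratings
    to express confidence in being wrong)."""
    r = np.asarray(ratings).copy()
    r[r < 1] = 1
    return r


def discretize_confidence(confidence, k: int = DEFAULT_N_RATINGS):
    """Sort confidence values into ``k`` percentile-based rating bins (1..k).

    Bins aim for balanced counts; duplicate percentile edges are collapsed,
    so heavily tied inputs may yield fewer than ``k`` effective levels
    (ratings are renumbered consecutively from 1). The mapping is
    order-preserving: a higher confidence never receives a lower rating.
    """
    arr = np.asarray(confidence, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot discretize an empty confidence vector")
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(arr).size < 2:
        return np.ones(arr.size, dtype=int)
    try:
        codes = pd.qcut(arr, k, labels=False, duplicates="drop")
    except ValueError:
        return np.ones(arr.size, dtype=int)
    codes = np.asarray(codes, dtype=int)
    if codes.max() == 0:
        return np.ones(arr.size, dtype=int)
    return codes + 1


# ---------------------------------------------------------------------------
# contingency counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingCounts:
    """2 x 2 x K contingency counts indexed (stimulus, response, rating).

    ``counts[s, r, j]`` is the number of trials with stimulus ``s``,
    response ``r`` and rating ``j + 1``. The nR_S1 / nR_S2 vector layout
    used by classic meta-d' code is available via :meth:`nr_s1` /
    :meth:`nr_s2`.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 3 or c.shape[:2] != (2, 2) or c.shape[2] < 2:
            raise ValueError("counts must have shape (2, 2, K) with K >= 2")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_trials(cls, stimulus, response, rating, k: int | None = None) -> "RatingCounts":
        stim = np.asarray(stimulus, dtype=int)
        resp = np.asarray(response, dtype=int)
        rat = np.asarray(rating, dtype=int)
        if not (stim.shape == resp.shape == rat.shape):
            raise ValueError("stimulus, response and rating must be aligned")
        if k is None:
            k = max(int(rat.max()), 2)
        if rat.min() < 1 or rat.max() > k:
            raise ValueError(f"ratings must lie in 1..{k}")
        counts = np.zeros((2, 2, k))
        np.add.at(counts, (stim, resp, rat - 1), 1.0)
        return cls(counts)

    @property
    def n_ratings(self) -> int:
        return self.counts.shape[2]

    @property
    def n_trials(self) -> float:
        return float(self.counts.sum())

    def padded(self) -> np.ndarray:
        """Counts with 1/(2K) added to every cell.

        The convention of the original meta-d' code: keeps hit/false-alarm
        rates away from 0 and 1 so z-transforms stay finite at small counts.
        """
        return self.counts + 1.0 / (2.0 * self.n_ratings)

    def nr_s1(self) -> np.ndarray:
        """Length-2K vector for stimulus 0: (resp 0 rating K..1, resp 1 rating 1..K)."""
        return np.concatenate([self.counts[0, 0, ::-1], self.counts[0, 1, :]])

    def nr_s2(self) -> np.ndarray:
        return np.concatenate([self.counts[1, 0, ::-1], self.counts[1, 1, :]])


def tabulate_counts(trials: pd.DataFrame, k: int = DEFAULT_N_RATINGS) -> RatingCounts:
    """Build RatingCounts from a trial table that already has a ``rating``
    column (1..k)."""
    return RatingCounts.from_trials(
        trials["stimulus"], trials["choice"], trials["rating"], k=k
    )


# ---------------------------------------------------------------------------
# type 1 statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Type1Stats:
    d_prime: float
    criterion: float
    hit_rate: float
    fa_rate: float


def type1_stats(counts: RatingCounts, padding: bool = True) -> Type1Stats:
    """Equal-variance SDT d' and criterion from the collapsed choice table.

    d' = z(H) - z(F), c = -(z(H) + z(F)) / 2 with H = P(resp 1 | stim 1)
    and F = P(resp 1 | stim 0), computed from padded counts by default.
    """
    c = counts.padded() if padding else counts.counts
    table = c.sum(axis=2)  # (stimulus, response)
    hit = table[1, 1] / table[1].sum()
    fa = table[0, 1] / table[0].sum()
    zh, zf = ndtri(hit), ndtri(fa)
    return Type1Stats(
        d_prime=float(zh - zf),
        criterion=float(-(zh + zf) / 2.0),
        hit_rate=float(hit),
        fa_rate=float(fa),
    )


# ---------------------------------------------------------------------------
# AUROC2
# ---------------------------------------------------------------------------

def auroc2(correct, ratings) -> float:
    """Area under the type 2 ROC curve.

    The curve plots, for each rating threshold, the probability of a
    high-confidence report given a correct decision (type 2 hit rate)
    against the same probability given an incorrect decision (type 2 false
    alarm rate); the area is computed by trapezoidal integration over the
    thresholds between observed rating levels plus the (0,0) and (1,1)
    endpoints. Ties are handled by the cumulative construction, which makes
    the value invariant under strictly monotone relabelings of the ratings.
    """
    corr = np.asarray(correct, dtype=bool)
    rat = np.asarray(ratings)
    if corr.all() or not corr.any():
        raise UndefinedMeasureError(
            "AUROC2 requires at least one correct and one incorrect trial"
        )
    levels = np.unique(rat)
    n_c = corr.sum()
    n_i = corr.size - n_c
    # descending thresholds -> ascending FAR
    hrs = [0.0]
    fars = [0.0]
    for theta in levels[::-1][:-1]:
        hrs.append(float((rat[corr] >= theta).sum() / n_c))
        fars.append(float((rat[~corr] >= theta).sum() / n_i))
    hrs.append(1.0)
    fars.append(1.0)
    return float(np.trapezoid(hrs, fars))


# ---------------------------------------------------------------------------
# meta-d' maximum likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaDFit:
    """Result of the meta-d' maximum-likelihood fit.

    ``t2_criteria_resp0`` are the K-1 type 2 criteria below the type 1
    criterion (ascending; the outermost corresponds to the highest rating),
    ``t2_criteria_resp1`` the K-1 criteria above it (ascending).
    """

    meta_d: float
    meta_c: float
    t2_criteria_resp0: np.ndarray
    t2_criteria_resp1: np.ndarray
    log_likelihood: float
    converged: bool


def _obs_matrix(padded: np.ndarray) -> np.ndarray:
    """Arrange (2,2,K) counts as (stim, 2K) cells in ascending-criterion
    order: resp 0 ratings K..1, then resp 1 ratings 1..K."""
    k = padded.shape[2]
    obs = np.empty((2, 2 * k))
    obs[:, :k] = padded[:, 0, ::-1]
    obs[:, k:] = padded[:, 1, :]
    return obs


def _t2_negll(x: np.ndarray, cprime: float, obs: np.ndarray, k: int) -> float:
    """Negative multinomial log-likelihood of rating counts conditional on
    (stimulus, response), as a function of meta-d' and log criteria
    increments."""
    meta_d = x[0]
    meta_c = cprime * meta_d
    low = meta_c - np.cumsum(np.exp(x[1:k]))[::-1]
    high = meta_c + np.cumsum(np.exp(x[k:]))
    bounds = np.concatenate([low, [meta_c], high])

    means = np.array([-meta_d / 2.0, meta_d / 2.0])
    cd = ndtr(bounds[None, :] - means[:, None])  # (2, 2K-1)
    full = np.empty((2, 2 * k + 1))
    full[:, 0] = 0.0
    full[:, 1:-1] = cd
    full[:, -1] = 1.0
    cells = np.diff(full, axis=1)  # (2, 2K)

    denom0 = np.clip(cd[:, k - 1], 1e-12, 1.0 - 1e-12)
    cond = np.empty_like(cells)
    cond[:, :k] = cells[:, :k] / denom0[:, None]
    cond[:, k:] = cells[:, k:] / (1.0 - denom0)[:, None]
    return float(-(obs * np.log(np.clip(cond, 1e-300, None))).sum())


def _initial_point(obs: np.ndarray, d1: float, cprime: float, k: int) -> np.ndarray:
    """Starting point: meta-d' at d', criteria placed at the standard-normal
    quantiles implied by the observed pooled rating proportions."""
    meta_c = cprime * d1
    pooled = obs.sum(axis=0)
    total = pooled.sum()
    cum = np.cumsum(pooled) / total  # mass below each boundary
    base = float(np.clip(ndtr(meta_c), 1e-4, 1 - 1e-4))
    # rescale observed masses so that the response split matches Phi(meta_c)
    resp0_mass = cum[k - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        lowq = base * cum[: k - 1] / resp0_mass
        highq = base + (1 - base) * (cum[k:-1] - resp0_mass) / (1 - resp0_mass)
    q = np.clip(np.concatenate([lowq, highq]), 1e-4, 1 - 1e-4)
    bounds = ndtri(q)
    low = np.minimum(bounds[: k - 1], meta_c - 1e-3)
    high = np.maximum(bounds[k - 1:], meta_c + 1e-3)
    low.sort()
    high.sort()
    gaps_low = np.maximum(np.diff(np.concatenate([low, [meta_c]])), 1e-3)
    gaps_high = np.maximum(np.diff(np.concatenate([[meta_c], high])), 1e-3)
    return np.concatenate([[d1], np.log(gaps_low[::-1]), np.log(gaps_high)])


def fit_meta_d(counts: RatingCounts, padding: bool = True) -> MetaDFit:
    """Maximum-likelihood meta-d' under the equal-variance SDT model.

    The type 1 criterion of the model observer is held at the same
    *relative* position c' = c / d' as estimated from the (padded) type 1
    table; meta-d' and the 2(K-1) type 2 criteria are then chosen to
    maximize the multinomial log-likelihood of the observed rating counts
    conditional on each (stimulus, response) cell. Criteria are
    parameterized as ordered log-increments away from the scaled type 1
    criterion, which enforces their monotonicity by construction.

    Raises :class:`UndefinedMeasureError` when d' is numerically zero (the
    relative-criterion constraint is then undefined).
    """
    k = counts.n_ratings
    padded = counts.padded() if padding else counts.counts.astype(float)
    t1 = type1_stats(counts, padding=padding)
    if abs(t1.d_prime) < 1e-8:
        raise UndefinedMeasureError("meta-d' fit undefined at d' = 0")
    cprime = t1.criterion / t1.d_prime

    obs = _obs_matrix(padded)
    x0 = _initial_point(obs, t1.d_prime, cprime, k)
    bnds = [(-10.0, 10.0)] + [(-7.0, 3.0)] * (2 * k - 2)
    res = minimize(
        _t2_negll,
        x0,
        args=(cprime, obs, k),
        method="L-BFGS-B",
        bounds=bnds,
        options={"ftol": 1e-10, "gtol": 1e-7, "maxiter": 500},
    )

    meta_d = float(res.x[0])
    meta_c = cprime * meta_d
    low = meta_c - np.cumsum(np.exp(res.x[1:k]))[::-1]
    high = meta_c + np.cumsum(np.exp(res.x[k:]))
    return MetaDFit(
        meta_d=meta_d,
        meta_c=float(meta_c),
        t2_criteria_resp0=low,
        t2_criteria_resp1=high,
        log_likelihood=float(-res.fun),
        converged=bool(res.success and np.isfinite(res.fun)),
    )


# ---------------------------------------------------------------------------
# efficiency measures and regularization
# ---------------------------------------------------------------------------

def efficiency_measures(type1: Type1Stats, fit: MetaDFit) -> tuple[float, float]:
    """(M_diff, M_ratio) = (meta-d' - d', meta-d' / d').

    M_ratio is NaN (missing) when d' is zero; M_diff is always defined.
    """
    m_diff = fit.meta_d - type1.d_prime
    if type1.d_prime == 0:
        return float(m_diff), float("nan")
    return float(m_diff), float(fit.meta_d / type1.d_prime)


def regularize_mratio(
    m_ratio: float,
    method: str,
    lb: float | None = None,
    ub: float = MRATIO_UPPER,
) -> float:
    """Tame extreme M_ratio values.

    ``exclude``: NaN outside [lb, ub]; ``bound``: clip into [lb, ub];
    ``log``: log(max(lb, x)) with lb > 0. Defaults are the conventional
    bounds 0 and 1.6 (symmetric around a typical median of 0.8) and the
    log floor 0.1.
    """
    if lb is None:
        lb = MRATIO_LOG_FLOOR if method == "log" else MRATIO_LOWER
    if method in ("exclude", "bound") and not lb < ub:
        raise ValueError("lb must be < ub")
    x = float(m_ratio)
    if method == "exclude":
        return x if lb <= x <= ub else float("nan")
    if method == "bound":
        return min(ub, max(lb, x))
    if method == "log":
        if not lb > 0:
            raise ValueError("log regularization requires lb > 0")
        return math.log(max(lb, x))
    raise ValueError(f"unknown regularization method {method!r}")


@dataclass
class MeasureSet:
    """All type 1 / type 2 measures for one subject-session."""

    d_prime: float = float("nan")
    criterion: float = float("nan")
    auroc2: float = float("nan")
    meta_d: float = float("nan")
    m_diff: float = float("nan")
    m_ratio: float = float("nan")
    m_ratio_excl: float = float("nan")
    m_ratio_bounded: float = float("nan")
    m_ratio_log: float = float("nan")
    m_ratio_hier: float = float("nan")
    converged: bool = False

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_measures(trials: pd.DataFrame, k: int = DEFAULT_N_RATINGS) -> MeasureSet:
    """Full measure pipeline for one subject-session trial table.

    Discretizes confidence into ``k`` percentile bins, tabulates counts,
    and computes d', AUROC2, meta-d' and the efficiency measures with the
    standard regularized variants. Undefined values (AUROC2 with no errors,
    M_ratio outside the exclusion bounds) come back as NaN rather than
    raising, so cohort pipelines can apply pairwise-missing policies
    downstream. The hierarchical variant requires a cohort and is filled in
    by :func:`metanoise.hierarchical.hierarchical_mratio`.
    """
    df = trials.copy()
    df["rating"] = discretize_confidence(df["confidence"].to_numpy(), k)
    counts = tabulate_counts(df, k=max(k, int(df["rating"].max())))
    t1 = type1_stats(counts)

    out = MeasureSet(d_prime=t1.d_prime, criterion=t1.criterion)
    try:
        out.auroc2 = auroc2(df["correct"].to_numpy(), df["rating"].to_numpy())
    except UndefinedMeasureError:
        pass
    try:
        fit = fit_meta_d(counts)
    except UndefinedMeasureError:
        return out
    out.meta_d = fit.meta_d
    out.converged = fit.converged
    out.m_diff, out.m_ratio = efficiency_measures(t1, fit)
    if np.isfinite(out.m_ratio):
        out.m_ratio_excl = regularize_mratio(out.m_ratio, "exclude")
        out.m_ratio_bounded = regularize_mratio(out.m_ratio, "bound")
        out.m_ratio_log = regularize_mratio(out.m_ratio, "log")
    return out
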