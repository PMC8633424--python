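"""Simulation studies: type 1 performance dependency and test-retest
reliability of metacognitive measures.

Two designs are orchestrated here. The *dependency grid* crosses sensory
noise (sigma_s, i.e. type 1 difficulty) with metacognitive noise (sigma_m)
and summarizes every measure per cell, tracing how AUROC2, meta-d', M_diff
and the M_ratio family depend on d' at constant metacognitive noise. The
*reliability grid* crosses target accuracy with trials per session; per
cell it repeatedly simulates two-session cohorts (sigma_m uniform across
subjects, fixed within subject) and averages Pearson/NMAE reliability of
the measures across iterations.

Default grid sizes are desk-scale (minutes on one CPU); the full-scale
designs (100 sigma_s levels x 1000 subjects x 10 000 trials; 300
reliability iterations over a 25..1000 trial lattice) are available via
the ``paper_scale`` constructors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import MRATIO_EXTREME, compute_measures
from .reliability import UndefinedStatisticError, nmae, pearson
from .simulator import CohortSpec, GenerativeParams, simulate_cohort, simulate_session

_MEASURES = (
    "d_prime",
    "auroc2",
    "meta_d",
    "m_diff",
    "m_ratio",
    "m_ratio_excl",
    "m_ratio_bounded",
    "m_ratio_log",
)


@dataclass(frozen=True)
class DependencyGridSpec:
    """Grid over (sigma_s, sigma_m) for the type-1-dependency study.

    The reduced default places the 10 sigma_s levels at 1/d' for d'
    targets evenly spaced on [0.25, 4], covering the d' axis instead of
    piling points below d' = 1 as a linear sigma_s grid would.
    """

    sigma_s_grid: tuple = tuple(1.0 / np.linspace(0.25, 4.0, 10))
    sigma_m_grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    n_subjects: int = 200
    n_trials: int = 2000
    n_ratings: int = 6
    mu: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.sigma_s_grid or not self.sigma_m_grid:
            raise ValueError("grids must be non-empty")
        if any(s > 0.5 or s < 0 for s in self.sigma_m_grid):
            raise ValueError("all sigma_m must lie in [0, 0.5]")

    @classmethod
    def paper_scale(cls, seed: int | None = None) -> "DependencyGridSpec":
        """Full-scale design: 100 sigma_s levels in (0, 5], 1000 subjects,
        10 000 trials."""
        return cls(
            sigma_s_grid=tuple(np.linspace(0.05, 5.0, 100)),
            sigma_m_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
            n_subjects=1000,
            n_trials=10_000,
            seed=seed,
        )


def _asymmetric_sd(values: np.ndarray, mean: float) -> tuple[float, float]:
    """Root-mean-square deviation computed separately below and above the
    mean (the two one-sided spreads of a possibly skewed distribution)."""
    below = values[values < mean]
    above = values[values > mean]
    sd_lo = float(np.sqrt(np.mean((below - mean) ** 2))) if below.size else 0.0
    sd_hi = float(np.sqrt(np.mean((above - mean) ** 2))) if above.size else 0.0
    return sd_lo, sd_hi


def run_dependency_grid(spec: DependencyGridSpec, measures=_MEASURES) -> pd.DataFrame:
    """Simulate every (sigma_s, sigma_m) cell and summarize each measure.

    Returns a tidy table with one row per cell per measure: columns
    sigma_s, sigma_m, measure, mean, sd_lower, sd_upper, n (subjects with
    a finite value). Results are deterministic given the spec's seed.
    """
    children = iter(
        np.random.SeedSequence(spec.seed).spawn(
            len(spec.sigma_m_grid) * len(spec.sigma_s_grid)
        )
    )
    rows = []
    for sigma_m in spec.sigma_m_grid:
        for sigma_s in spec.sigma_s_grid:
            rng = np.random.default_rng(next(children))
            params = GenerativeParams(mu=spec.mu, sigma_s=sigma_s, sigma_m=sigma_m)
            values = {m: [] for m in measures}
            for _ in range(spec.n_subjects):
                trials = simulate_session(params, spec.n_trials, rng)
                ms = compute_measures(trials, k=spec.n_ratings).as_dict()
                for m in measures:
                    values[m].append(ms[m])
            for m in measures:
                v = np.asarray(values[m], dtype=float)
                v = v[np.isfinite(v)]
                mean = float(v.mean()) if v.size else float("nan")
                sd_lo, sd_hi = _asymmetric_sd(v, mean) if v.size else (0.0, 0.0)
                rows.append(
                    {
                        "sigma_s": sigma_s,
                        "sigma_m": sigma_m,
                        "measure": m,
                        "mean": mean,
                        "sd_lower": sd_lo,
                        "sd_upper": sd_hi,
                        "n": int(v.size),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReliabilityGridSpec:
    """Lattice over (target accuracy, trials per session) for the
    test-retest study; per cell, ``n_iterations`` two-session cohorts of
    ``n_subjects`` are simulated and reliability statistics averaged."""

    accuracy_grid: tuple = (0.60, 0.70, 0.80, 0.90)
    trials_grid: tuple = (100, 250, 500, 1000)
    n_subjects: int = 100
    n_iterations: int = 20
    n_ratings: int = 6
    mu: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(not 0.5 < a < 1 for a in self.accuracy_grid):
            raise ValueError("accuracies must lie strictly in (0.5, 1)")
        if not self.accuracy_grid or not self.trials_grid:
            raise ValueError("grids must be non-empty")

    @classmethod
    def paper_scale(cls, seed: int | None = None) -> "ReliabilityGridSpec":
        """Full-scale design: accuracies 55%..95%, trials 25..1000 step 25,
        300 iterations."""
        return cls(
            accuracy_grid=tuple(np.round(np.arange(0.55, 0.951, 0.05), 2)),
            trials_grid=tuple(range(25, 1001, 25)),
            n_subjects=100,
            n_iterations=300,
            seed=seed,
        )


def _session_measures(spec, accuracy, n_trials, seed, measures):
    """One iteration: simulate a two-session cohort and return per-session
    per-subject measure values as two DataFrames."""
    cohort = simulate_cohort(
        CohortSpec(
            n_subjects=spec.n_subjects,
            n_trials=n_trials,
            n_sessions=2,
            sigma_m="uniform",
            target_accuracy=accuracy,
            mu=spec.mu,
            seed=seed,
        )
    )
    per_session = []
    for sess in (0, 1):
        vals = []
        for subj in range(spec.n_subjects):
            ms = compute_measures(cohort.session(subj, sess), k=spec.n_ratings)
            vals.append({m: ms.as_dict()[m] for m in measures})
        per_session.append(pd.DataFrame(vals))
    return per_session


def run_reliability_grid(
    spec: ReliabilityGridSpec,
    measures=("m_ratio", "m_ratio_excl", "m_ratio_bounded", "m_ratio_log"),
) -> pd.DataFrame:
    """Average test-retest reliability over the (accuracy, n_trials) lattice.

    Per iteration a fresh cohort (sigma_m ~ U(0, 0.5) per subject, fixed
    across its two sessions) is simulated; Pearson r and NMAE between the
    per-session measure vectors are computed with pairwise removal of
    missing values, and — for the plain m_ratio — exclusion of
    |M_ratio| > 10 pairs. Returns a tidy table with one row per cell per
    measure: pearson (mean over iterations), pearson_sd, nmae, n_iterations.
    """
    cell_seeds = np.random.SeedSequence(spec.seed).spawn(
        len(spec.accuracy_grid) * len(spec.trials_grid)
    )
    rows = []
    idx = 0
    for accuracy in spec.accuracy_grid:
        for n_trials in spec.trials_grid:
            iter_seeds = cell_seeds[idx].spawn(spec.n_iterations)
            idx += 1
            rs = {m: [] for m in measures}
            es = {m: [] for m in measures}
            for it_seed in iter_seeds:
                test, retest = _session_measures(
                    spec, accuracy, n_trials, it_seed, measures
                )
                for m in measures:
                    x = test[m].to_numpy()
                    y = retest[m].to_numpy()
                    keep = np.isfinite(x) & np.isfinite(y)
                    if m == "m_ratio":
                        keep &= (np.abs(x) <= MRATIO_EXTREME) & (
                            np.abs(y) <= MRATIO_EXTREME
                        )
                    if keep.sum() < 3:
                        continue
                    try:
                        rs[m].append(pearson(x[keep], y[keep]))
                        es[m].append(nmae(x[keep], y[keep]))
                    except UndefinedStatisticError:
                        continue
            for m in measures:
                rows.append(
                    {
                        "accuracy": accuracy,
                        "n_trials": n_trials,
                        "measure": m,
                        "pearson": float(np.mean(rs[m])) if rs[m] else float("nan"),
                        "pearson_sd": float(np.std(rs[m])) if rs[m] else float("nan"),
                        "nmae": float(np.mean(es[m])) if es[m] else float("nan"),
                        "n_iterations": len(rs[m]),
                    }
                )
    return pd.DataFrame(rows)


def mratio_test_retest(
    accuracy: float,
    n_trials: int,
    n_subjects: int = 100,
    n_iterations: int = 20,
    seed: int | None = None,
    mu: float = 1.0,
) -> float:
    """Mean test-retest Pearson r of M_ratio for one (accuracy, trials) cell.

    Convenience wrapper around :func:`run_reliability_grid` for the plain
    M_ratio with the |M_ratio| > 10 exclusion rule.
    """
    spec = ReliabilityGridSpec(
        accuracy_grid=(accuracy,),
        trials_grid=(int(n_trials),),
        n_subjects=n_subjects,
        n_iterations=n_iterations,
        mu=mu,
        seed=seed,
    )
    table = run_reliability_grid(spec, measures=("m_ratio",))
    return float(table["pearson"].iloc[0])


@dataclass(frozen=True)
class BinnedCurve:
    """Sliding-window summary of a measure against d'."""

    bin_centers: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    counts: np.ndarray


def bin_by_dprime(
    d_prime,
    values,
    centers=None,
    halfwidth: float = 0.2,
    d_range: tuple[float, float] = (0.1, 3.1),
) -> BinnedCurve:
    """Overlapping-window means of a per-subject measure along the d' axis.

    Windows are centred at 0.3..2.9 in steps of 0.2 by default, each
    including subjects with |d' - center| <= 0.2 (adjacent windows share
    subjects); subjects outside d' in [0.1, 3.1] are discarded. SEM is the
    sample SD / sqrt(n), NaN for windows with fewer than two subjects.
    """
    d = np.asarray(d_prime, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.shape != v.shape:
        raise ValueError("d_prime and values must be aligned")
    if centers is None:
        centers = np.round(np.arange(0.3, 2.9 + 1e-9, 0.2), 10)
    centers = np.asarray(centers, dtype=float)

    ok = np.isfinite(d) & np.isfinite(v) & (d >= d_range[0]) & (d <= d_range[1])
    d, v = d[ok], v[ok]
    means = np.full(centers.size, np.nan)
    sems = np.full(centers.size, np.nan)
    counts = np.zeros(centers.size, dtype=int)
    for i, c in enumerate(centers):
        sel = np.abs(d - c) <= halfwidth + 1e-12
        counts[i] = int(sel.sum())
        if counts[i] >= 1:
            means[i] = float(v[sel].mean())
        if counts[i] >= 2:
            sems[i] = float(v[sel].std(ddof=1) / np.sqrt(counts[i]))
    return BinnedCurve(bin_centers=centers, means=means, sems=sems, counts=counts)
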