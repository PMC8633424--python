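"""Generative model of a noisy metacognitive observer.

The observer performs a binary categorization task. On each trial a stimulus
from one of two categories (labelled 0 and 1) generates a noisy percept

    percept ~ Normal(+/- mu/2, sigma_s),

where ``mu`` is the separation between the two stimulus means and ``sigma_s``
is the sensory noise standard deviation. Knowing the generative process, the
observer computes the posterior probability ``p`` that the stimulus was
category 1 (Bayes' rule reduces to a logistic in the percept), chooses
category 1 whenever ``p >= 0.5``, and forms an internal confidence

    c = |2 p - 1|  in [0, 1],

which is choice-independent (c is the same for p and 1 - p). The *reported*
confidence is a noisy version of c: a draw from a Beta distribution whose
mode is c and whose spread is governed by the metacognitive noise parameter
``sigma_m`` in (0, 0.5]. At ``sigma_m = 0.5`` the Beta becomes uniform on
[0, 1] (a metacognitively blind observer); ``sigma_m = 0`` is treated as the
noiseless limit where the report equals c exactly.

Only the ratio mu / sigma_s is identified (it equals the observer's d'), so
``mu`` defaults to 1 throughout and difficulty is manipulated via sigma_s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri


class DegenerateNoiseError(ValueError):
    """Raised when an operation requires strictly positive sensory noise."""


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters (mu, sigma_s, sigma_m) of the observer model.

    mu : separation of the two stimulus means (percept means are +/- mu/2);
        must be > 0. Defaults to 1, so that d' = mu / sigma_s = 1 / sigma_s.
    sigma_s : sensory noise SD, >= 0. Zero is the noiseless observer.
    sigma_m : metacognitive noise spread of the Beta report distribution,
        in [0, 0.5]. Zero means reported confidence equals internal
        confidence; 0.5 means reports are uniform random.
    """

    mu: float = 1.0
    sigma_s: float = 1.0
    sigma_m: float = 0.1

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")
        if not 0.0 <= self.sigma_m <= 0.5:
            raise ValueError(
                f"sigma_m must lie in [0, 0.5], got {self.sigma_m}"
            )

    @property
    def expected_accuracy(self) -> float:
        """Probability correct under the optimal sign rule, Phi(mu / (2 sigma_s))."""
        if self.sigma_s == 0:
            return 1.0
        return float(ndtr(self.mu / (2.0 * self.sigma_s)))


def choice_probability(percept, params: GenerativeParams):
    """Posterior probability of stimulus category 1 given the percept.

    p = 1 / (1 + exp(-mu * percept / sigma_s**2)); strictly increasing in
    the percept and equal to 0.5 at percept = 0.
    """
    if params.sigma_s == 0:
        raise DegenerateNoiseError(
            "choice_probability is undefined at sigma_s = 0; the noiseless "
            "observer has p in {0, 1} by the sign of the percept"
        )
    return expit(params.mu * np.asarray(percept, dtype=float) / params.sigma_s**2)


def confidence_from_p(p):
    """Choice-independent internal confidence c = |2p - 1|.

    Equals 2(p - 0.5) for p >= 0.5 and 2(0.5 - p) otherwise; symmetric
    under p -> 1 - p, 0 at guessing and 1 at certainty.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    return np.abs(2.0 * p - 1.0)


def beta_shape_params(c, sigma_m: float):
    """Shape parameters (alpha, beta) of the mode-c Beta report distribution.

    alpha = c (1/sigma_m - 2) + 1, beta = (1 - c)(1/sigma_m - 2) + 1, valid
    for sigma_m in (0, 0.5]. Both shapes are >= 1 and the distribution's
    mode (alpha - 1) / (alpha + beta - 2) equals c; at sigma_m = 0.5 the
    shapes are (1, 1), i.e. the uniform distribution.
    """
    if not 0.0 < sigma_m <= 0.5:
        raise ValueError(f"sigma_m must lie in (0, 0.5], got {sigma_m}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("c must lie in [0, 1]")
    conc = 1.0 / sigma_m - 2.0
    return c * conc + 1.0, (1.0 - c) * conc + 1.0


def sample_confidence(c, sigma_m: float, rng: np.random.Generator):
    """Draw reported confidence from Beta(mode=c, spread=sigma_m).

    sigma_m = 0 is the noiseless contract: the internal confidence is
    returned unchanged (no random numbers are consumed).
    """
    c = np.asarray(c, dtype=float)
    if sigma_m == 0:
        return c.copy()
    alpha, beta = beta_shape_params(c, sigma_m)
    return rng.beta(alpha, beta)


def sigma_for_accuracy(target_accuracy: float, mu: float = 1.0) -> float:
    """Sensory noise SD at which expected accuracy equals ``target_accuracy``.

    Inverts Phi(mu / (2 sigma_s)) = target: sigma_s = mu / (2 Phi^-1(target)).
    Only targets strictly between 0.5 and 1 are admissible (0.5 would need
    infinite noise, 1 zero noise).
    """
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError(
            f"target_accuracy must lie strictly in (0.5, 1), got {target_accuracy}"
        )
    return float(mu / (2.0 * ndtri(target_accuracy)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_session(
    params: GenerativeParams,
    n_trials: int,
    rng=None,
    stimuli: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Simulate one session and return its trial table.

    Columns: ``stimulus`` (0/1, equiprobable unless ``stimuli`` is given),
    ``percept``, ``choice`` (category 1 iff p >= 0.5), ``correct``,
    ``confidence`` (reported, in [0, 1]). The draw order is fixed
    (stimuli, then percept noise, then confidence noise) so sessions are
    reproducible from the generator state alone.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _as_rng(rng)

    if stimuli is None:
        stim = rng.integers(0, 2, size=n_trials)
    else:
        stim = np.asarray(stimuli, dtype=int)
        if stim.shape != (n_trials,) or not np.isin(stim, (0, 1)).all():
            raise ValueError("stimuli must be an (n_trials,) array of 0/1 labels")

    signs = 2.0 * stim - 1.0
    noise = rng.standard_normal(n_trials)
    percept = signs * params.mu / 2.0 + params.sigma_s * noise

    if params.sigma_s == 0:
        # Degenerate posterior: p is 0 or 1 by the sign of the percept.
        p = np.where(percept > 0, 1.0, np.where(percept < 0, 0.0, 0.5))
    else:
        p = choice_probability(percept, params)

    choice = (p >= 0.5).astype(int)  # tie at p = 0.5 resolves to category 1
    conf = sample_confidence(confidence_from_p(p), params.sigma_m, rng)

    return pd.DataFrame(
        {
            "stimulus": stim,
            "percept": percept,
            "choice": choice,
            "correct": choice == stim,
            "confidence": conf,
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated multi-subject, multi-session cohort.

    ``sigma_m`` is either a fixed value shared by all subjects or the string
    ``"uniform"``, in which case each subject's sigma_m is drawn once from
    U(0, 0.5) and shared across that subject's sessions (so that test-retest
    comparisons reflect a stable subject trait). Difficulty is set either
    directly through ``sigma_s`` or through ``target_accuracy``.
    """

    n_subjects: int
    n_trials: int
    n_sessions: int = 2
    sigma_m: float | str = "uniform"
    target_accuracy: float | None = None
    sigma_s: float | None = None
    mu: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_sessions < 1:
            raise ValueError("n_subjects, n_trials and n_sessions must be >= 1")
        if (self.target_accuracy is None) == (self.sigma_s is None):
            raise ValueError("specify exactly one of target_accuracy or sigma_s")
        if self.target_accuracy is not None and not 0.5 < self.target_accuracy < 1:
            raise ValueError("target_accuracy must lie strictly in (0.5, 1)")
        if isinstance(self.sigma_m, str) and self.sigma_m != "uniform":
            raise ValueError("sigma_m must be a number or the string 'uniform'")

    def resolved_sigma_s(self) -> float:
        if self.sigma_s is not None:
            return float(self.sigma_s)
        return sigma_for_accuracy(self.target_accuracy, self.mu)


@dataclass
class CohortData:
    """Flat trial table plus per-subject parameters for a simulated cohort.

    ``trials`` uses the Confidence-Database-style column convention extended
    with a Session column: Subj_idx, Session, Trial, Stimulus, Response,
    Correct, Confidence. ``subjects`` has one row per subject with its
    sigma_s and sigma_m.
    """

    trials: pd.DataFrame
    subjects: pd.DataFrame

    def session(self, subject: int, session: int) -> pd.DataFrame:
        """Return one subject-session as a simulator-style trial table."""
        t = self.trials
        sel = t[(t["Subj_idx"] == subject) & (t["Session"] == session)]
        return pd.DataFrame(
            {
                "stimulus": sel["Stimulus"].to_numpy(),
                "choice": sel["Response"].to_numpy(),
                "correct": sel["Correct"].to_numpy(dtype=bool),
                "confidence": sel["Confidence"].to_numpy(),
            }
        )


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate a cohort of subjects, each with ``n_sessions`` sessions.

    Per-subject random streams are spawned deterministically from the cohort
    seed, so any subject can be regenerated in isolation; a subject's
    sigma_m (when drawn) is the first draw of its own stream and is fixed
    across all of that subject's sessions.
    """
    sigma_s = spec.resolved_sigma_s()
    entropy = spec.seed
    if not isinstance(entropy, np.random.SeedSequence):
        entropy = np.random.SeedSequence(entropy)
    children = entropy.spawn(spec.n_subjects)

    frames = []
    rows = []
    for subj, child in enumerate(children):
        rng = np.random.default_rng(child)
        if spec.sigma_m == "uniform":
            sigma_m = float(rng.uniform(0.0, 0.5))
        else:
            sigma_m = float(spec.sigma_m)
        params = GenerativeParams(mu=spec.mu, sigma_s=sigma_s, sigma_m=sigma_m)
        rows.append({"Subj_idx": subj, "sigma_s": sigma_s, "sigma_m": sigma_m})
        for sess in range(spec.n_sessions):
            tt = simulate_session(params, spec.n_trials, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "Subj_idx": subj,
                        "Session": sess,
                        "Trial": np.arange(spec.n_trials),
                        "Stimulus": tt["stimulus"],
                        "Response": tt["choice"],
                        "Correct": tt["correct"].astype(int),
                        "Confidence": tt["confidence"],
                    }
                )
            )
    return CohortData(
        trials=pd.concat(frames, ignore_index=True),
        subjects=pd.DataFrame(rows),
    )
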