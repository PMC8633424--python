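"""Reading and preprocessing of trial-level confidence CSVs.

Handles datasets in the Confidence-Database column convention (one row per
trial with subject id, stimulus, response and confidence), harmonizes
rating scales (verbal labels, negative ratings, fractional/continuous
scales) to at most six discrete levels, applies the standard inclusion
policy (minimum trial count and d' threshold), and prepares the split-half
tables used by reliability and cross-validated dependency analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import (
    DEFAULT_N_RATINGS,
    RatingCounts,
    compute_measures,
    discretize_confidence,
    floor_negative_ratings,
    type1_stats,
)
from .reliability import split_half_interleaved

logger = logging.getLogger(__name__)

#: canonical column names (Confidence Database convention)
CANONICAL_COLUMNS = ("Subj_idx", "Stimulus", "Response", "Confidence")

MODALITIES = ("cognitive", "memory", "motor", "perception", "mixed", "unknown")


@dataclass
class StudyDataset:
    """One study: per-subject trial tables plus study-level metadata."""

    study_id: str
    subjects: dict
    modality: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def n_subjects(self) -> int:
        return len(self.subjects)

    def trial_counts(self) -> pd.Series:
        return pd.Series({s: len(t) for s, t in self.subjects.items()})


@dataclass(frozen=True)
class InclusionPolicy:
    """Subject inclusion rule: at least ``min_trials`` trials and
    d' > ``min_dprime`` (defaults 400 and 0.5)."""

    min_trials: int = 400
    min_dprime: float = 0.5

    def __post_init__(self) -> None:
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")


def read_trial_csv(
    path,
    column_map: dict | None = None,
    verbal_map: dict | None = None,
    study_id: str = "study",
    modality: str = "unknown",
    metadata: dict | None = None,
) -> StudyDataset:
    """Read a trial-level CSV into a StudyDataset.

    ``column_map`` maps canonical names (Subj_idx, Stimulus, Response,
    Confidence) to the file's dialect; ``verbal_map`` converts verbal
    confidence labels (e.g. {"difficult": 1, "easy": 2}) to numeric
    ratings — unmapped labels are a hard error. Stimulus and response must
    be binary (exactly two response options); their two values are mapped
    to 0/1 in sorted order. Trial order within subject is preserved.
    """
    df = pd.read_csv(path)
    colmap = {c: (column_map or {}).get(c, c) for c in CANONICAL_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    df = df.rename(columns={src: dst for dst, src in colmap.items()})

    for col in ("Stimulus", "Response"):
        values = sorted(pd.unique(df[col].dropna()))
        if set(values) <= {0, 1}:
            continue  # already canonical (one value may be unobserved)
        if len(values) != 2:
            raise ValueError(
                f"{col} must be binary (two response options); found {values}"
            )
        df[col] = df[col].map({values[0]: 0, values[1]: 1})

    if verbal_map is not None or df["Confidence"].dtype == object:
        labels = df["Confidence"]
        mapping = verbal_map or {}
        unmapped = sorted(
            set(labels.dropna().unique()) - set(mapping) - {v for v in labels.unique() if isinstance(v, (int, float))}
        )
        if unmapped:
            raise ValueError(f"unmappable verbal confidence labels: {unmapped}")
        df["Confidence"] = labels.map(lambda v: mapping.get(v, v)).astype(float)

    subjects = {}
    for subj, group in df.groupby("Subj_idx", sort=True):
        subjects[subj] = pd.DataFrame(
            {
                "stimulus": group["Stimulus"].to_numpy(dtype=int),
                "choice": group["Response"].to_numpy(dtype=int),
                "correct": (group["Stimulus"] == group["Response"]).to_numpy(),
                "confidence": group["Confidence"].to_numpy(dtype=float),
            }
        )
    return StudyDataset(
        study_id=study_id,
        subjects=subjects,
        modality=modality,
        metadata=metadata or {},
    )


def write_trial_csv(study: StudyDataset, path) -> None:
    """Write a StudyDataset back to the canonical CSV layout (round-trips
    with :func:`read_trial_csv`)."""
    frames = []
    for subj, trials in study.subjects.items():
        frames.append(
            pd.DataFrame(
                {
                    "Subj_idx": subj,
                    "Stimulus": trials["stimulus"],
                    "Response": trials["choice"],
                    "Confidence": trials["confidence"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def prepare_ratings(
    trials: pd.DataFrame, max_levels: int = DEFAULT_N_RATINGS
) -> pd.DataFrame:
    """Attach a discrete ``rating`` column (1..max_levels) to a trial table.

    Integer scales with at most ``max_levels`` levels are kept as-is after
    flooring negative ratings at 1 and renumbering levels consecutively;
    fractional/continuous scales and finer integer scales are discretized
    to ``max_levels`` percentile bins. Downstream rating counts therefore
    never exceed ``max_levels`` levels.
    """
    conf = trials["confidence"].to_numpy(dtype=float)
    out = trials.copy()
    is_integer = np.allclose(conf, np.round(conf))
    if is_integer:
        floored = floor_negative_ratings(np.round(conf).astype(int))
        levels = np.unique(floored)
        if levels.size <= max_levels:
            remap = {v: i + 1 for i, v in enumerate(levels)}
            out["rating"] = np.vectorize(remap.get)(floored)
            return out
        conf = floored.astype(float)
    out["rating"] = discretize_confidence(conf, max_levels)
    return out


def _subject_dprime(trials: pd.DataFrame, max_levels: int = DEFAULT_N_RATINGS) -> float:
    with_ratings = prepare_ratings(trials, max_levels)
    counts = RatingCounts.from_trials(
        with_ratings["stimulus"], with_ratings["choice"], with_ratings["rating"]
    )
    return type1_stats(counts).d_prime


def apply_inclusion(study: StudyDataset, policy: InclusionPolicy = InclusionPolicy()) -> StudyDataset:
    """Retain subjects meeting the trial-count and d' criteria."""
    kept = {}
    for subj, trials in study.subjects.items():
        if len(trials) < policy.min_trials:
            continue
        if not _subject_dprime(trials) > policy.min_dprime:
            continue
        kept[subj] = trials
    logger.info(
        "study %s: kept %d of %d subjects (min_trials=%d, min_dprime=%.2f)",
        study.study_id, len(kept), len(study.subjects),
        policy.min_trials, policy.min_dprime,
    )
    return StudyDataset(
        study_id=study.study_id,
        subjects=kept,
        modality=study.modality,
        metadata=dict(study.metadata),
    )


def split_half_count(n_trials: int) -> int:
    """Trials in the 'test' half of an interleaved split (odd positions)."""
    return (n_trials + 1) // 2


def assign_trial_bins(studies, bin_width: int = 200):
    """Assign each study to a split-half trial-count bin; flag outliers.

    A study's typical split-half count is the median across its subjects;
    bin b covers [(b-1) * width, b * width). Subjects whose own split-half
    count falls outside their study's bin are listed for exclusion.
    Returns (study_id -> bin number, study_id -> excluded subject ids).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    bins = {}
    exclusions = {}
    for study in studies:
        counts = {
            subj: split_half_count(len(trials))
            for subj, trials in study.subjects.items()
        }
        median = float(np.median(list(counts.values())))
        b = int(median // bin_width) + 1
        lo, hi = (b - 1) * bin_width, b * bin_width
        bins[study.study_id] = b
        exclusions[study.study_id] = [
            subj for subj, c in counts.items() if not lo <= c < hi
        ]
    return bins, exclusions


def crossvalidated_dprime_table(
    study: StudyDataset,
    policy: InclusionPolicy = InclusionPolicy(),
    k: int = DEFAULT_N_RATINGS,
    swap_halves: bool = False,
) -> pd.DataFrame:
    """Per-subject d' and metacognitive measures from disjoint halves.

    Each subject's trials are split into interleaved halves; d' is
    estimated on one half and the metacognitive measures on the other, so
    the d' entering a regression of measure-on-d' shares no measurement
    noise with the d' inside M_diff / M_ratio. ``swap_halves`` exchanges
    the roles of the two halves.
    """
    included = apply_inclusion(study, policy)
    rows = []
    for subj, trials in included.subjects.items():
        half_a, half_b = split_half_interleaved(trials)
        if swap_halves:
            half_a, half_b = half_b, half_a
        row = {"subject": subj, "d_prime_cv": _subject_dprime(half_a, k)}
        row.update(compute_measures(half_b, k=k).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
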