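"""Representational dissimilarity matrices (RDMs).

Neural RDMs are built from trial x voxel beta matrices as 1 - Pearson r
between the voxel vectors of every trial pair.  Behavioral RDMs are built
from per-trial scalar ratings as the Euclidean distance |r_i - r_j| between
the ratings of every trial pair.  RDMs are constructed separately for the
distal and imminent halves of the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateTrialError, ValidationError


@dataclass
class ROIPatternMatrix:
    """Trial x voxel beta estimates for one subject and region."""

    subject_id: int | str
    roi_name: str
    trial_ids: np.ndarray
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.trial_ids = np.asarray(self.trial_ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("pattern matrix must be 2-D (trials x voxels)")
        if len(self.trial_ids) != self.matrix.shape[0]:
            raise ValidationError(
                f"{len(self.trial_ids)} trial ids for {self.matrix.shape[0]} rows"
            )
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise ValidationError("trial ids must be unique")
        if np.isnan(self.matrix).any():
            raise ValidationError("pattern matrix contains missing values")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]

    def subset(self, trial_ids) -> "ROIPatternMatrix":
        """Row-subset to the given trial ids (kept in stored row order)."""
        wanted = set(np.asarray(trial_ids).tolist())
        mask = np.array([t in wanted for t in self.trial_ids])
        missing = wanted - set(self.trial_ids[mask].tolist())
        if missing:
            raise ValidationError(f"trials not in pattern matrix: {sorted(missing)[:5]}")
        return ROIPatternMatrix(
            subject_id=self.subject_id,
            roi_name=self.roi_name,
            trial_ids=self.trial_ids[mask],
            matrix=self.matrix[mask],
        )


@dataclass
class RDM:
    """Labelled symmetric trial-by-trial dissimilarity matrix.

    ``kind`` records the construction rule (``neural_1_minus_r`` or
    ``rating_euclidean``); ``condition`` the imminence half it belongs to;
    ``source`` the ROI name or the rating family.
    """

    labels: np.ndarray
    matrix: np.ndarray
    kind: str
    condition: str | None = None
    source: str | None = None
    subject_id: int | str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("RDM must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-10):
            raise ValidationError("RDM diagonal must be zero")
        if (self.matrix < -1e-10).any():
            raise ValidationError("RDM entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        """Vectorized strictly-lower-triangle entries (row-major order)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.matrix[i, j]


def neural_rdm(patterns: ROIPatternMatrix, condition: str | None = None) -> RDM:
    """1 - Pearson correlation between the voxel vectors of every trial pair.

    Each trial's voxel vector must have nonzero variance; a constant vector
    has no defined correlation and raises :class:`DegenerateTrialError`
    naming the offending trial.
    """
    if patterns.n_trials < 3:
        raise ValidationError("need at least 3 trials to build an RDM")
    if patterns.n_voxels < 2:
        raise ValidationError("need at least 2 voxels to correlate patterns")
    sds = patterns.matrix.std(axis=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DegenerateTrialError(
            "constant voxel vector for trial(s) "
            f"{patterns.trial_ids[bad][:5].tolist()} — correlation undefined"
        )
    r = np.corrcoef(patterns.matrix)
    mat = 1.0 - r
    mat = np.clip((mat + mat.T) / 2.0, 0.0, 2.0)  # numerical symmetry + [0, 2]
    np.fill_diagonal(mat, 0.0)
    return RDM(
        labels=patterns.trial_ids,
        matrix=mat,
        kind="neural_1_minus_r",
        condition=condition,
        source=patterns.roi_name,
        subject_id=patterns.subject_id,
    )


def rating_rdm(
    ratings,
    trial_ids,
    condition: str | None = None,
    source: str | None = None,
    subject_id=None,
) -> RDM:
    """Euclidean distance |r_i - r_j| between the ratings of every trial pair."""
    ratings = np.asarray(ratings, dtype=float)
    trial_ids = np.asarray(trial_ids)
    if ratings.ndim != 1 or len(ratings) != len(trial_ids):
        raise ValidationError("need exactly one scalar rating per trial id")
    if np.isnan(ratings).any():
        missing = trial_ids[np.isnan(ratings)]
        raise ValidationError(f"missing rating for trial(s) {missing[:5].tolist()}")
    mat = np.abs(np.subtract.outer(ratings, ratings))
    return RDM(
        labels=trial_ids,
        matrix=mat,
        kind="rating_euclidean",
        condition=condition,
        source=source,
        subject_id=subject_id,
    )


def trial_threat_ratings(
    schedule_sub: pd.DataFrame, threat_ratings: pd.DataFrame, condition: str
) -> pd.Series:
    """Map each trial of one subject's condition to its cue's threat rating.

    ``schedule_sub`` is one subject's schedule; ``threat_ratings`` holds that
    subject's six cue ratings (columns ``level, imminence, threat_rating``).
    Returns a Series indexed by ``global_trial_id``.
    """
    sub = schedule_sub.loc[schedule_sub["imminence"] == condition]
    if sub.empty:
        raise ValidationError(f"no trials in condition {condition!r}")
    lut = {
        (lv, im): r
        for lv, im, r in zip(
            threat_ratings["level"],
            threat_ratings["imminence"],
            threat_ratings["threat_rating"],
        )
    }
    values = []
    for lv, im in zip(sub["level"], sub["imminence"]):
        if (lv, im) not in lut:
            raise ValidationError(f"missing threat-cue rating for cue ({lv}, {im})")
        values.append(float(lut[(lv, im)]))
    return pd.Series(values, index=sub["global_trial_id"].to_numpy(), name="threat_rating")


def split_by_condition(schedule: pd.DataFrame, *tables: pd.DataFrame) -> dict:
    """Partition the schedule (and any trial-keyed tables) by imminence.

    Returns ``{condition: (schedule_view, *table_views)}`` where each view
    keeps only the rows whose (subject, trial) belongs to that condition.
    The two partitions are disjoint and their union is the input.
    """
    out = {}
    for condition in ("distal", "imminent"):
        sched = schedule.loc[schedule["imminence"] == condition]
        keys = set(zip(sched["subject_id"], sched["global_trial_id"]))
        views = [sched]
        for table in tables:
            mask = [
                (s, t) in keys
                for s, t in zip(table["subject_id"], table["global_trial_id"])
            ]
            views.append(table.loc[mask])
        out[condition] = tuple(views) if tables else sched
    return out
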