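"""Synthetic experiment generator.

Produces complete synthetic datasets for the helping-under-threat paradigm:
trial schedules, help/no-help decisions, shock outcomes, post-scan ratings,
and ROI voxel patterns with a *planted* representational geometry.  Every
stage is driven by a single master seed, with disjoint random streams per
subject and per stage, so a full experiment is bit-reproducible.

The generative model for the voxel patterns is deliberately simple: for
subject ``s``, region ``r``, trial ``t`` and voxel ``v``

    beta[t, v] = a * z(threat_t) * u[v] + d * z(distress_t) * w[v] + eps

where ``u`` and ``w`` are fixed random unit-norm voxel patterns drawn once
per (subject, region), ``z`` standardizes the subject's own trial-level
ratings, ``a`` and ``d`` are the subject's threat- and distress-coding
strengths in that region, and ``eps`` is i.i.d. Gaussian noise.  The
threat-coding strength of a designated target region additionally feeds a
logistic helping policy, planting the brain-behaviour link that the
similarity analysis is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITIONS, DEFAULT_ROI_LIST, DEFAULT_TARGET_ROI, TaskDesign
from .exceptions import ValidationError
from .rdm import ROIPatternMatrix

# Stage codes used to derive disjoint random streams from the master seed.
_STAGE = {
    "schedule": 0,
    "ratings": 1,
    "weights": 2,
    "patterns": 3,
    "decisions": 4,
    "outcomes": 5,
}


def _rng(seed: int, stage: str, subject_index: int = 0) -> np.random.Generator:
    """Generator for one (stage, subject) cell of the seed tree.

    ``SeedSequence`` spawn keys guarantee the streams are disjoint across
    stages and subjects while remaining a pure function of the master seed.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE[stage], subject_index))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingParams:
    """Generating equation for the post-scan ratings (9-point scales).

    Ratings are latent Gaussians -- baseline + level effect + imminence
    effect + noise -- rounded to the nearest integer and clipped to [1, 9].
    Distress ratings (one per trial clip) increase with threat level and are
    higher for imminent clips.  Felt-threat ratings (one per cue image,
    level x imminence) increase with level; the imminence increment applies
    to shock cues only by default, mirroring the manipulation-check
    structure of the task.
    """

    distress_baseline: float = 3.5
    distress_level_effects: dict[str, float] = field(
        default_factory=lambda: {"safe": 0.0, "1shock": 1.5, "2shocks": 3.0}
    )
    distress_imminence_effect: float = 1.0
    distress_noise_sd: float = 1.0
    threat_baseline: float = 2.0
    threat_level_effects: dict[str, float] = field(
        default_factory=lambda: {"safe": 0.0, "1shock": 2.5, "2shocks": 4.5}
    )
    threat_imminence_effect: float = 1.0
    threat_imminence_on_shock_only: bool = True
    threat_noise_sd: float = 1.0

    def validate(self, levels: tuple[str, ...]) -> None:
        for name, effects in (
            ("distress_level_effects", self.distress_level_effects),
            ("threat_level_effects", self.threat_level_effects),
        ):
            missing = [lv for lv in levels if lv not in effects]
            if missing:
                raise ValidationError(f"{name} missing levels: {missing}")
        if self.distress_noise_sd < 0 or self.threat_noise_sd < 0:
            raise ValidationError("rating noise SDs must be >= 0")


@dataclass(frozen=True)
class NeuralParams:
    """Cohort-level hyperparameters of the planted voxel-pattern geometry.

    ``a`` (threat-coding) and ``d`` (distress-coding) strengths are drawn
    per subject and region from truncated normals (negative draws are
    clipped to zero; the pattern geometry depends only on the magnitude of
    the coding strength, so a sign would be unidentifiable anyway).  With
    unit-norm signal patterns and ``n_voxels`` noise voxels of SD
    ``noise_sd``, the expected signal fraction of a trial pattern is roughly
    ``a^2 / (a^2 + d^2 + n_voxels * noise_sd^2)``.
    """

    rois: tuple[str, ...] = DEFAULT_ROI_LIST
    n_voxels: int = 100
    noise_sd: float = 0.15
    a_mean: float = 1.0
    a_sd: float = 0.5
    d_mean: float = 1.0
    d_sd: float = 0.5
    target_roi: str = DEFAULT_TARGET_ROI

    def validate(self) -> None:
        if self.n_voxels < 2:
            raise ValidationError("n_voxels must be >= 2")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not self.rois:
            raise ValidationError("rois must be non-empty")
        if self.target_roi not in self.rois:
            raise ValidationError(
                f"target_roi {self.target_roi!r} is not in the ROI list"
            )


@dataclass(frozen=True)
class DecisionParams:
    """Logistic helping policy on shock trials.

    P(help) = sigmoid(gamma0 + gamma1 * a_target + gamma2 * imminent).
    ``gamma1`` links the target region's threat-coding strength to helping
    propensity; ``gamma2`` is a uniform imminence effect.  Safe trials
    produce an arbitrary key press (recorded as ``safe_choice``).  The
    default intercept centres cohort-mean helping near 50 %, matching the
    task instruction to balance help and no-help choices.
    """

    gamma0: float = -2.75
    gamma1: float = 2.5
    gamma2: float = 0.5
    miss_prob: float = 0.0
    rt_mean_ms: float = 900.0
    rt_sd_ms: float = 150.0

    def validate(self) -> None:
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValidationError("miss_prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------


def generate_schedule(
    design: TaskDesign, n_subjects: int, seed: int
) -> pd.DataFrame:
    """Generate trial schedules for ``n_subjects`` subjects.

    Per run, distal and imminent trials form two contiguous blocks whose
    order is randomized independently for every run and subject; threat
    levels are balanced within each block and shuffled within it.

    Returns a table with columns ``subject_id, run, trial_index_in_run,
    global_trial_id, imminence, level, block_order``.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    rows = []
    for si in range(n_subjects):
        rng = _rng(seed, "schedule", si)
        subject_id = si + 1
        for run in range(1, design.n_runs + 1):
            first = rng.choice(["distal", "imminent"])
            order = (
                ("distal", "imminent") if first == "distal" else ("imminent", "distal")
            )
            block_order = f"{order[0]}_first"
            trial_in_run = 0
            for imminence in order:
                block_size = (
                    design.n_distal_per_run
                    if imminence == "distal"
                    else design.n_imminent_per_run
                )
                per_level = design.levels_per_block(block_size)
                levels = np.repeat(list(design.levels), per_level)
                rng.shuffle(levels)
                for level in levels:
                    trial_in_run += 1
                    rows.append(
                        (
                            subject_id,
                            run,
                            trial_in_run,
                            (run - 1) * design.trials_per_run + trial_in_run,
                            imminence,
                            level,
                            block_order,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "run",
            "trial_index_in_run",
            "global_trial_id",
            "imminence",
            "level",
            "block_order",
        ],
    )


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------


@dataclass
class RatingSet:
    """Post-scan ratings: per-trial distress and per-cue felt threat."""

    distress: pd.DataFrame  # subject_id, global_trial_id, distress_rating
    threat: pd.DataFrame  # subject_id, level, imminence, threat_rating


def _round_clip(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(latent), 1, 9).astype(int)


def generate_ratings(
    schedule: pd.DataFrame,
    rating_params: RatingParams | None = None,
    seed: int = 0,
    levels: tuple[str, ...] | None = None,
) -> RatingSet:
    """Generate distress ratings (one per trial clip) and threat-cue ratings.

    Each trial showed a unique clip of the co-participant, so every trial
    receives its own distress rating; each of the six level x imminence cue
    images receives one felt-threat rating per subject.
    """
    params = rating_params or RatingParams()
    if levels is None:
        levels = tuple(pd.unique(schedule["level"]))
    params.validate(levels)

    distress_rows = []
    threat_rows = []
    subject_ids = pd.unique(schedule["subject_id"])
    for si, subject_id in enumerate(subject_ids):
        rng = _rng(seed, "ratings", si)
        sub = schedule.loc[schedule["subject_id"] == subject_id]
        level_eff = sub["level"].map(params.distress_level_effects).to_numpy(float)
        imm = (sub["imminence"] == "imminent").to_numpy(float)
        latent = (
            params.distress_baseline
            + level_eff
            + params.distress_imminence_effect * imm
            + rng.normal(0.0, params.distress_noise_sd, len(sub))
        )
        ratings = _round_clip(latent)
        distress_rows.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "global_trial_id": sub["global_trial_id"].to_numpy(),
                    "distress_rating": ratings,
                }
            )
        )
        for level in levels:
            for condition in CONDITIONS:
                bump = params.threat_imminence_effect * (condition == "imminent")
                if params.threat_imminence_on_shock_only and level == "safe":
                    bump = 0.0
                latent_cue = (
                    params.threat_baseline
                    + params.threat_level_effects[level]
                    + bump
                    + rng.normal(0.0, params.threat_noise_sd)
                )
                threat_rows.append(
                    (subject_id, level, condition, int(_round_clip(np.array([latent_cue]))[0]))
                )
    return RatingSet(
        distress=pd.concat(distress_rows, ignore_index=True),
        threat=pd.DataFrame(
            threat_rows, columns=["subject_id", "level", "imminence", "threat_rating"]
        ),
    )


# ---------------------------------------------------------------------------
# neural patterns
# ---------------------------------------------------------------------------


def draw_coding_weights(
    params: NeuralParams, subject_ids: list[int] | np.ndarray, seed: int
) -> pd.DataFrame:
    """Draw per-(subject, region) threat (a) and distress (d) coding strengths.

    Deterministic in the master seed, so callers may draw the weights
    separately (e.g. to build the decision traits) and still obtain exactly
    the weights used inside :func:`generate_roi_patterns`.
    """
    params.validate()
    rows = []
    for si, subject_id in enumerate(subject_ids):
        rng = _rng(seed, "weights", si)
        for roi in params.rois:
            a = max(0.0, rng.normal(params.a_mean, params.a_sd))
            d = max(0.0, rng.normal(params.d_mean, params.d_sd))
            rows.append((subject_id, roi, a, d))
    return pd.DataFrame(rows, columns=["subject_id", "roi", "a", "d"])


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def trialwise_ratings(
    schedule_sub: pd.DataFrame, ratings: RatingSet, subject_id
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (threat, distress) rating vectors for one subject.

    The threat value of a trial is the subject's rating of that trial's cue
    image (its level at its imminence); the distress value is the rating of
    that trial's unique clip.
    """
    threat_sub = ratings.threat.loc[ratings.threat["subject_id"] == subject_id]
    lut = {
        (lv, im): r
        for lv, im, r in zip(
            threat_sub["level"], threat_sub["imminence"], threat_sub["threat_rating"]
        )
    }
    try:
        threat = np.array(
            [
                lut[(lv, im)]
                for lv, im in zip(schedule_sub["level"], schedule_sub["imminence"])
            ],
            dtype=float,
        )
    except KeyError as exc:
        raise ValidationError(
            f"missing threat-cue rating for subject {subject_id}: {exc.args[0]}"
        ) from exc
    distress_sub = ratings.distress.loc[ratings.distress["subject_id"] == subject_id]
    dmap = dict(
        zip(distress_sub["global_trial_id"], distress_sub["distress_rating"])
    )
    missing = [t for t in schedule_sub["global_trial_id"] if t not in dmap]
    if missing:
        raise ValidationError(
            f"missing distress ratings for subject {subject_id}, trials {missing[:5]}"
        )
    distress = np.array(
        [dmap[t] for t in schedule_sub["global_trial_id"]], dtype=float
    )
    return threat, distress


def generate_roi_patterns(
    schedule: pd.DataFrame,
    ratings: RatingSet,
    params: NeuralParams | None = None,
    seed: int = 0,
    weights: pd.DataFrame | None = None,
) -> dict[tuple[int, str], ROIPatternMatrix]:
    """Generate trial x voxel beta matrices with planted geometry.

    See the module docstring for the generative equation.  Returns a dict
    keyed by ``(subject_id, roi)``.  If ``weights`` is omitted it is drawn
    internally via :func:`draw_coding_weights` with the same seed.
    """
    params = params or NeuralParams()
    params.validate()
    subject_ids = list(pd.unique(schedule["subject_id"]))
    if weights is None:
        weights = draw_coding_weights(params, subject_ids, seed)
    wmap = {
        (s, r): (a, d)
        for s, r, a, d in zip(
            weights["subject_id"], weights["roi"], weights["a"], weights["d"]
        )
    }

    out: dict[tuple[int, str], ROIPatternMatrix] = {}
    for si, subject_id in enumerate(subject_ids):
        rng = _rng(seed, "patterns", si)
        sub = schedule.loc[schedule["subject_id"] == subject_id]
        threat, distress = trialwise_ratings(sub, ratings, subject_id)
        z_threat = _zscore(threat)
        z_distress = _zscore(distress)
        trial_ids = sub["global_trial_id"].to_numpy()
        n_trials = len(trial_ids)
        for roi in params.rois:
            u = rng.normal(size=params.n_voxels)
            u /= np.linalg.norm(u)
            w = rng.normal(size=params.n_voxels)
            w /= np.linalg.norm(w)
            if (subject_id, roi) not in wmap:
                raise ValidationError(f"weights missing for ({subject_id}, {roi})")
            a, d = wmap[(subject_id, roi)]
            noise = rng.normal(0.0, params.noise_sd, size=(n_trials, params.n_voxels))
            betas = (
                a * np.outer(z_threat, u) + d * np.outer(z_distress, w) + noise
            )
            out[(subject_id, roi)] = ROIPatternMatrix(
                subject_id=subject_id, roi_name=roi, trial_ids=trial_ids, matrix=betas
            )
    return out


# ---------------------------------------------------------------------------
# decisions and outcomes
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_decisions(
    schedule: pd.DataFrame,
    traits: pd.DataFrame,
    seed: int = 0,
    params: DecisionParams | None = None,
) -> pd.DataFrame:
    """Simulate help/no-help decisions from the logistic policy.

    ``traits`` must have one row per subject with columns ``subject_id`` and
    ``a_target`` (the subject's threat-coding strength in the target ROI).
    Safe trials yield ``safe_choice``; any trial can be ``missed`` with
    probability ``miss_prob``.
    """
    params = params or DecisionParams()
    params.validate()
    trait_map = dict(zip(traits["subject_id"], traits["a_target"]))
    rows = []
    subject_ids = pd.unique(schedule["subject_id"])
    for si, subject_id in enumerate(subject_ids):
        if subject_id not in trait_map:
            raise ValidationError(f"traits missing subject {subject_id}")
        rng = _rng(seed, "decisions", si)
        a = trait_map[subject_id]
        sub = schedule.loc[schedule["subject_id"] == subject_id]
        imm = (sub["imminence"] == "imminent").to_numpy(float)
        p_help = _sigmoid(params.gamma0 + params.gamma1 * a + params.gamma2 * imm)
        helped = rng.random(len(sub)) < p_help
        missed = rng.random(len(sub)) < params.miss_prob
        rt = rng.normal(params.rt_mean_ms, params.rt_sd_ms, len(sub)).clip(min=200.0)
        is_safe = (sub["level"] == "safe").to_numpy()
        for i, trial_id in enumerate(sub["global_trial_id"]):
            if missed[i]:
                response, rt_ms = "missed", np.nan
            elif is_safe[i]:
                response, rt_ms = "safe_choice", rt[i]
            else:
                response, rt_ms = ("help" if helped[i] else "no_help"), rt[i]
            rows.append((subject_id, trial_id, response, rt_ms))
    return pd.DataFrame(
        rows, columns=["subject_id", "global_trial_id", "response", "rt_ms"]
    )


def simulate_outcomes(
    decisions: pd.DataFrame,
    schedule: pd.DataFrame,
    design: TaskDesign,
    seed: int = 0,
) -> pd.DataFrame:
    """Resolve shock outcomes from decisions and the task contingencies.

    Help: both parties shocked with probability ``p_both_shocked_on_help``
    (otherwise neither).  No help: the co-participant is always shocked and
    the participant never.  Missed response: both shocked, on any trial.
    Safe trials with a response: nobody is shocked.
    """
    sched_key = schedule.set_index(["subject_id", "global_trial_id"])
    missing = [
        key
        for key in zip(decisions["subject_id"], decisions["global_trial_id"])
        if key not in sched_key.index
    ]
    if missing:
        raise ValidationError(f"decisions reference unscheduled trials: {missing[:5]}")
    merged = decisions.merge(
        schedule[["subject_id", "global_trial_id", "level"]],
        on=["subject_id", "global_trial_id"],
        how="left",
        validate="one_to_one",
    )
    rows = []
    subject_ids = pd.unique(merged["subject_id"])
    for si, subject_id in enumerate(subject_ids):
        rng = _rng(seed, "outcomes", si)
        sub = merged.loc[merged["subject_id"] == subject_id]
        for trial_id, response in zip(sub["global_trial_id"], sub["response"]):
            if response == "missed":
                part, copart = True, True
            elif response == "help":
                both = rng.random() < design.p_both_shocked_on_help
                part, copart = both, both
            elif response == "no_help":
                part, copart = False, True
            else:  # safe_choice
                part, copart = False, False
            rows.append((subject_id, trial_id, part, copart))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "global_trial_id",
            "participant_shocked",
            "coparticipant_shocked",
        ],
    )


# ---------------------------------------------------------------------------
# one-call experiment
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    """All tables of one synthetic cohort."""

    design: TaskDesign
    schedule: pd.DataFrame
    ratings: RatingSet
    weights: pd.DataFrame
    patterns: dict[tuple[int, str], ROIPatternMatrix]
    decisions: pd.DataFrame
    outcomes: pd.DataFrame


def simulate_experiment(
    n_subjects: int = 49,
    seed: int = 0,
    design: TaskDesign | None = None,
    rating_params: RatingParams | None = None,
    neural_params: NeuralParams | None = None,
    decision_params: DecisionParams | None = None,
) -> SimulatedExperiment:
    """Generate a full synthetic cohort (default: 49 subjects, 13 ROIs)."""
    design = design or TaskDesign()
    neural_params = neural_params or NeuralParams()
    schedule = generate_schedule(design, n_subjects, seed)
    ratings = generate_ratings(schedule, rating_params, seed, levels=design.levels)
    subject_ids = list(pd.unique(schedule["subject_id"]))
    weights = draw_coding_weights(neural_params, subject_ids, seed)
    patterns = generate_roi_patterns(schedule, ratings, neural_params, seed, weights)
    traits = (
        weights.loc[weights["roi"] == neural_params.target_roi, ["subject_id", "a"]]
        .rename(columns={"a": "a_target"})
        .reset_index(drop=True)
    )
    decisions = generate_decisions(schedule, traits, seed, decision_params)
    outcomes = simulate_outcomes(decisions, schedule, design, seed)
    return SimulatedExperiment(
        design=design,
        schedule=schedule,
        ratings=ratings,
        weights=weights,
        patterns=patterns,
        decisions=decisions,
        outcomes=outcomes,
    )
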