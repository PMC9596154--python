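"""Descriptive behavioral metrics: helping percentages and imminence preference.

Helping is only defined on responded shock trials, so safe trials and
missed responses are excluded from every denominator.  Groups with no
eligible trials yield NaN (an explicit undefined marker), never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

GROUPINGS = ("overall", "imminence", "imminence_x_level")


def _eligible(decisions: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    merged = decisions.merge(
        schedule[["subject_id", "global_trial_id", "imminence", "level"]],
        on=["subject_id", "global_trial_id"],
        how="inner",
        validate="one_to_one",
    )
    return merged.loc[
        (merged["level"] != "safe") & merged["response"].isin(["help", "no_help"])
    ]


def _pct(group: pd.DataFrame) -> float:
    n = len(group)
    if n == 0:
        return float("nan")
    return 100.0 * (group["response"] == "help").sum() / n


def helping_percentage(
    decisions: pd.DataFrame, schedule: pd.DataFrame, grouping: str = "overall"
) -> pd.DataFrame:
    """Percentage of help choices among responded shock trials, per subject.

    ``grouping`` selects the cells: ``overall`` (one row per subject),
    ``imminence`` (distal / imminent), or ``imminence_x_level``.
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"unknown grouping {grouping!r}; use one of {GROUPINGS}")
    elig = _eligible(decisions, schedule)
    subjects = pd.unique(schedule["subject_id"])

    if grouping == "overall":
        keys = ["subject_id"]
        cells = [(s,) for s in subjects]
    elif grouping == "imminence":
        keys = ["subject_id", "imminence"]
        cells = [(s, c) for s in subjects for c in ("distal", "imminent")]
    else:
        keys = ["subject_id", "imminence", "level"]
        levels = [lv for lv in pd.unique(schedule["level"]) if lv != "safe"]
        cells = [
            (s, c, lv) for s in subjects for c in ("distal", "imminent") for lv in levels
        ]

    by = keys[0] if len(keys) == 1 else keys
    grouped = {k: g for k, g in elig.groupby(by)} if len(elig) else {}
    rows = []
    for cell in cells:
        key = cell[0] if len(keys) == 1 else cell
        group = grouped.get(key, elig.iloc[0:0])
        rows.append((*cell, _pct(group), len(group)))
    return pd.DataFrame(rows, columns=[*keys, "helping_pct", "n_trials"])


def helping_summary(decisions: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Per-subject summary: overall helping %, per-imminence %, delta, class.

    ``delta_imminent_minus_distal`` is the difference of helping
    *proportions* (in percentage points), so unequal missed-response counts
    across conditions cannot bias its sign.  ``imminence_class`` is
    ``more_imminent`` / ``more_distal`` / ``equal`` by the exact sign of the
    delta (NaN deltas are classified ``equal``).
    """
    overall = helping_percentage(decisions, schedule, "overall").rename(
        columns={"helping_pct": "helping_pct_overall"}
    )
    by_imm = helping_percentage(decisions, schedule, "imminence").pivot(
        index="subject_id", columns="imminence", values="helping_pct"
    )
    out = overall[["subject_id", "helping_pct_overall"]].copy()
    out["helping_pct_distal"] = out["subject_id"].map(by_imm["distal"])
    out["helping_pct_imminent"] = out["subject_id"].map(by_imm["imminent"])
    delta = out["helping_pct_imminent"] - out["helping_pct_distal"]
    out["delta_imminent_minus_distal"] = delta
    out["imminence_class"] = np.select(
        [delta > 0, delta < 0], ["more_imminent", "more_distal"], default="equal"
    )
    return out


def classify_imminence_preference(summary: pd.DataFrame) -> pd.Series:
    """Count subjects helping more under imminent, more under distal, or equally.

    Expects one summary row per subject (as produced by
    :func:`helping_summary`); the three counts always sum to the number of
    subjects.
    """
    if summary["subject_id"].duplicated().any():
        raise ValidationError("expected exactly one summary row per subject")
    counts = summary["imminence_class"].value_counts()
    return pd.Series(
        {
            "more_imminent": int(counts.get("more_imminent", 0)),
            "more_distal": int(counts.get("more_distal", 0)),
            "equal": int(counts.get("equal", 0)),
        },
        name="n_subjects",
    )
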