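"""Second-order similarity and ROI-level inference.

The second-order similarity between a neural RDM and a behavioral (model)
RDM is Kendall's rank correlation between their vectorized lower triangles.
Tau-a is the default variant: behavioral RDMs built from 9-point ratings
are heavily tied, and tau-a is the standard recommendation when candidate
RDMs predict tied dissimilarities (tau-b is available by flag).

Per region of interest, the per-subject, per-condition similarities enter
an ordinary least squares model predicting the subject's average helping
percentage, with predictors tau_threat, tau_distress and imminence
(0 = distal, 1 = imminent).  P-values of the slope coefficients are pooled
across all regions and adjusted with the Benjamini-Hochberg false discovery
rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .behavior import helping_summary
from .exceptions import (
    CollinearityError,
    DegenerateTrialError,
    InsufficientDataError,
    LabelMismatchError,
    UndefinedStatisticError,
    ValidationError,
)
from .rdm import RDM, neural_rdm, rating_rdm, trial_threat_ratings

SLOPE_TERMS = ("tau_threat", "tau_distress", "imminence")
ALL_TERMS = ("intercept",) + SLOPE_TERMS

# ---------------------------------------------------------------------------
# Kendall's tau
# ---------------------------------------------------------------------------

_MAX_BINS = 64  # binned counting path only pays off for few distinct values


def _tie_term(x: np.ndarray) -> int:
    """Sum over tied groups of t*(t-1)/2."""
    _, counts = np.unique(x, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def _cd_sorted_numpy(xs: np.ndarray, ys: np.ndarray, k: int) -> int:
    """Concordant-minus-discordant count on y-sorted inputs (numpy path)."""
    n = len(xs)
    new_group = np.r_[True, ys[1:] != ys[:-1]]
    starts = np.flatnonzero(new_group)
    group_start = starts[np.cumsum(new_group) - 1]
    onehot = np.zeros((n, k), dtype=np.int64)
    onehot[np.arange(n), xs] = 1
    cum = np.cumsum(onehot, axis=0)
    prev = np.zeros((n, k), dtype=np.int64)
    nz = group_start > 0
    prev[nz] = cum[group_start[nz] - 1]
    ccum = np.cumsum(prev, axis=1)
    idx = np.arange(n)
    concordant = np.where(xs > 0, ccum[idx, np.maximum(xs - 1, 0)], 0)
    discordant = ccum[:, -1] - ccum[idx, xs]
    return int(concordant.sum() - discordant.sum())


try:  # optional jit of the pair-counting loop; numpy path is the fallback
    from numba import njit as _njit

    @_njit(cache=True)
    def _cd_sorted_jit(xs, ys, k):  # pragma: no cover - thin compiled loop
        n = xs.shape[0]
        counts = np.zeros(k, np.int64)
        cd = 0
        i = 0
        while i < n:
            j = i
            while j < n and ys[j] == ys[i]:
                j += 1
            for t in range(i, j):
                c = xs[t]
                less = 0
                for cc in range(c):
                    less += counts[cc]
                greater = 0
                for cc in range(c + 1, k):
                    greater += counts[cc]
                cd += less - greater
            for t in range(i, j):
                counts[xs[t]] += 1
            i = j
        return cd

    def _cd_sorted(xs: np.ndarray, ys: np.ndarray, k: int) -> int:
        return int(_cd_sorted_jit(np.ascontiguousarray(xs), np.ascontiguousarray(ys), k))

except Exception:  # pragma: no cover - numba not installed
    _cd_sorted = _cd_sorted_numpy


def _binned_conc_minus_disc(codes: np.ndarray, k: int, y: np.ndarray) -> int:
    """Concordant-minus-discordant pair count, exact for any ties.

    ``codes`` are integer bin codes of one vector (k distinct values); ``y``
    is the other vector.  O(n*k) counting: walk the elements in ascending-y
    order and, for each, count previously seen strictly-smaller-y elements
    with a smaller (concordant) or larger (discordant) code.  Elements tied
    on y contribute neither.
    """
    order = np.argsort(y, kind="stable")
    return _cd_sorted(codes[order], np.asarray(y, dtype=float)[order], k)


def kendall_tau(x, y, variant: str = "tau_a") -> float:
    """Kendall rank correlation between two equal-length vectors.

    tau_a = (C - D) / (n(n-1)/2); tau_b divides C - D by the geometric mean
    of the tie-corrected pair counts.  Under tau_b an all-tied vector has no
    defined value and raises :class:`UndefinedStatisticError`; under tau_a
    it yields 0 (no concordant or discordant pairs exist).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 2:
        raise ValidationError("need at least 2 observations")
    if variant not in ("tau_a", "tau_b"):
        raise ValidationError(f"unknown variant {variant!r}")

    n0 = n * (n - 1) // 2
    tx, ty = _tie_term(x), _tie_term(y)
    if variant == "tau_b":
        if tx == n0 or ty == n0:
            raise UndefinedStatisticError(
                "tau_b undefined: one input vector is entirely tied"
            )
        return float(scipy.stats.kendalltau(x, y, variant="b").statistic)

    if tx == n0 or ty == n0:
        return 0.0
    # bin on whichever vector has fewer distinct values
    vx, cx = np.unique(x, return_inverse=True)
    if len(vx) <= _MAX_BINS:
        cd = _binned_conc_minus_disc(cx, len(vx), y)
    else:
        vy, cy = np.unique(y, return_inverse=True)
        if len(vy) <= _MAX_BINS:
            cd = _binned_conc_minus_disc(cy, len(vy), x)
        else:
            tau_b = scipy.stats.kendalltau(x, y, variant="b").statistic
            cd = int(round(tau_b * np.sqrt(float(n0 - tx) * float(n0 - ty))))
    return cd / n0


# ---------------------------------------------------------------------------
# second-order similarity
# ---------------------------------------------------------------------------


@dataclass
class SecondOrderSimilarity:
    """Kendall tau between a neural and a behavioral RDM."""

    tau: float
    n_pairs: int
    variant: str


def _align(behavioral: RDM, labels: np.ndarray) -> np.ndarray:
    """Reorder a behavioral RDM's matrix to a neural RDM's label order."""
    pos = {lab: i for i, lab in enumerate(behavioral.labels.tolist())}
    missing = [lab for lab in labels.tolist() if lab not in pos]
    extra = [lab for lab in behavioral.labels.tolist() if lab not in set(labels.tolist())]
    if missing or extra:
        raise LabelMismatchError(
            f"RDM label mismatch; missing from behavioral: {missing[:5]}, "
            f"extra in behavioral: {extra[:5]}"
        )
    perm = np.array([pos[lab] for lab in labels.tolist()])
    return behavioral.matrix[np.ix_(perm, perm)]


def second_order_similarity(
    neural: RDM, behavioral: RDM, variant: str = "tau_a"
) -> SecondOrderSimilarity:
    """Kendall tau between the lower triangles of two label-aligned RDMs.

    Alignment is by trial id, never by position; mismatched label sets raise
    :class:`LabelMismatchError` listing the offending ids.
    """
    mat = _align(behavioral, neural.labels)
    i, j = np.tril_indices(neural.n, k=-1)
    tau = kendall_tau(neural.matrix[i, j], mat[i, j], variant=variant)
    return SecondOrderSimilarity(tau=tau, n_pairs=len(i), variant=variant)


def compute_similarity(
    patterns: dict,
    schedule: pd.DataFrame,
    distress_ratings: pd.DataFrame,
    threat_ratings: pd.DataFrame,
    roi_list=None,
    variant: str = "tau_a",
) -> pd.DataFrame:
    """Per (subject, ROI, condition) second-order similarities.

    ``patterns`` maps (subject_id, roi) to :class:`ROIPatternMatrix`.
    Returns a long table with columns ``subject_id, roi, condition,
    tau_threat, tau_distress, n_pairs``.
    """
    subject_ids = list(pd.unique(schedule["subject_id"]))
    if roi_list is None:
        roi_list = sorted({roi for _, roi in patterns})
    gaps = [
        (s, r) for s in subject_ids for r in roi_list if (s, r) not in patterns
    ]
    if gaps:
        raise ValidationError(f"missing pattern matrices for: {gaps[:10]}")

    rows = []
    for subject_id in subject_ids:
        sched_sub = schedule.loc[schedule["subject_id"] == subject_id]
        sub_trials = sched_sub["global_trial_id"].to_numpy()
        dist_sub = distress_ratings.loc[distress_ratings["subject_id"] == subject_id]
        dmap = dict(zip(dist_sub["global_trial_id"], dist_sub["distress_rating"]))
        thr_sub = threat_ratings.loc[threat_ratings["subject_id"] == subject_id]
        for condition in ("distal", "imminent"):
            pos = np.flatnonzero((sched_sub["imminence"] == condition).to_numpy())
            trial_ids = sub_trials[pos]
            threat_vals = trial_threat_ratings(sched_sub, thr_sub, condition).to_numpy()
            try:
                distress_vals = np.array([dmap[t] for t in trial_ids], dtype=float)
            except KeyError as exc:
                raise ValidationError(
                    f"missing distress rating for subject {subject_id}, "
                    f"trial {exc.args[0]}"
                ) from exc
            m = len(trial_ids)
            tri = np.tril_indices(m, k=-1)
            n0 = m * (m - 1) // 2  # lower-triangle length = number of trial pairs
            denom = n0 * (n0 - 1) // 2  # tau-a denominator over RDM entry pairs
            # behavioral lower triangles and their bin codes, shared by all ROIs
            fams = {}
            for name, vals in (("tau_threat", threat_vals), ("tau_distress", distress_vals)):
                vec = np.abs(np.subtract.outer(vals, vals))[tri]
                uniq, codes = np.unique(vec, return_inverse=True)
                fams[name] = (vec, codes.astype(np.int64), len(uniq))
            for roi in roi_list:
                pat = patterns[(subject_id, roi)]
                fast = (
                    variant == "tau_a"
                    and np.array_equal(pat.trial_ids, sub_trials)
                    and max(fams[f][2] for f in fams) <= _MAX_BINS
                )
                taus = {}
                if fast:
                    M = pat.matrix[pos]
                    sds = M.std(axis=1)
                    bad = np.flatnonzero(sds == 0)
                    if bad.size:
                        raise DegenerateTrialError(
                            "constant voxel vector for trial(s) "
                            f"{trial_ids[bad][:5].tolist()} — correlation undefined"
                        )
                    Z = M - M.mean(axis=1, keepdims=True)
                    Z /= np.linalg.norm(Z, axis=1, keepdims=True)
                    nvec = 1.0 - (Z @ Z.T)[tri]
                    order = np.argsort(nvec, kind="stable")
                    ys = nvec[order]
                    for name, (vec, codes, k) in fams.items():
                        if k == 1 or ys[0] == ys[-1]:
                            taus[name] = 0.0
                        else:
                            taus[name] = _cd_sorted(codes[order], ys, k) / denom
                else:
                    nrdm = neural_rdm(pat.subset(trial_ids), condition)
                    for name, (vec, codes, k) in fams.items():
                        brdm = rating_rdm(
                            threat_vals if name == "tau_threat" else distress_vals,
                            trial_ids,
                            condition,
                            name.removeprefix("tau_"),
                            subject_id,
                        )
                        taus[name] = second_order_similarity(nrdm, brdm, variant).tau
                rows.append(
                    (subject_id, roi, condition, taus["tau_threat"], taus["tau_distress"], n0)
                )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "roi", "condition", "tau_threat", "tau_distress", "n_pairs"],
    )


# ---------------------------------------------------------------------------
# ROI-level linear models
# ---------------------------------------------------------------------------


def fit_roi_model(
    similarity: pd.DataFrame,
    helping: pd.DataFrame,
    roi: str,
    cluster_robust: bool = False,
) -> pd.DataFrame:
    """OLS of overall helping % on similarity predictors for one ROI.

    Each subject contributes two rows (distal, imminent) sharing one
    outcome, the subject's overall helping percentage; imminence is coded
    0 = distal, 1 = imminent.  ``cluster_robust`` switches the standard
    errors to cluster-robust by subject (off by default: the published
    model treats rows as independent).
    """
    sub = similarity.loc[similarity["roi"] == roi]
    if sub.empty:
        raise ValidationError(f"no similarity rows for ROI {roi!r}")
    merged = sub.merge(
        helping[["subject_id", "helping_pct_overall"]], on="subject_id", how="inner"
    )
    if merged["helping_pct_overall"].isna().any():
        raise ValidationError("helping percentage undefined for some subjects")
    X = np.column_stack(
        [
            np.ones(len(merged)),
            merged["tau_threat"].to_numpy(float),
            merged["tau_distress"].to_numpy(float),
            (merged["condition"] == "imminent").to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError(
            f"design matrix for ROI {roi!r} is rank deficient "
            "(constant or collinear predictor)"
        )
    y = merged["helping_pct_overall"].to_numpy(float)
    model = sm.OLS(y, X)
    if cluster_robust:
        fit = model.fit(
            cov_type="cluster", cov_kwds={"groups": merged["subject_id"].to_numpy()}
        )
    else:
        fit = model.fit()
    return pd.DataFrame(
        {
            "roi": roi,
            "term": list(ALL_TERMS),
            "beta": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "n_rows": len(merged),
        }
    )


def fdr_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, significance flags); a value is flagged
    significant when its adjusted p lies strictly below ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted < alpha


def fit_all_roi_models(
    similarity: pd.DataFrame,
    helping: pd.DataFrame,
    roi_list=None,
    alpha: float = 0.05,
    fdr_pool: str = "slopes",
    cluster_robust: bool = False,
) -> pd.DataFrame:
    """One OLS model per ROI with a joint FDR correction across models.

    The FDR pool defaults to the three slope coefficients of every model
    (intercepts excluded); set ``fdr_pool='all'`` to include intercepts.
    """
    if roi_list is None:
        roi_list = list(pd.unique(similarity["roi"]))
    if fdr_pool not in ("slopes", "all"):
        raise ValidationError("fdr_pool must be 'slopes' or 'all'")
    tables = [
        fit_roi_model(similarity, helping, roi, cluster_robust) for roi in roi_list
    ]
    models = pd.concat(tables, ignore_index=True)
    in_pool = (
        models["term"].isin(SLOPE_TERMS)
        if fdr_pool == "slopes"
        else pd.Series(True, index=models.index)
    )
    adjusted, flags = fdr_adjust(models.loc[in_pool, "p"].to_numpy(), alpha)
    models["p_fdr"] = np.nan
    models.loc[in_pool, "p_fdr"] = adjusted
    models["significant"] = False
    models.loc[in_pool, "significant"] = flags
    return models


def predominance_test(similarity: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Does a region predominantly represent threat-to-self or other's distress?

    Two-sided Wilcoxon signed-rank on the per-subject tau_threat -
    tau_distress differences, per (ROI, condition), FDR-corrected across
    cells.  All-zero differences yield statistic 0 and p = 1 by convention.
    """
    rows = []
    for (roi, condition), group in similarity.groupby(["roi", "condition"]):
        diffs = (group["tau_threat"] - group["tau_distress"]).to_numpy(float)
        if len(diffs) < 5:
            raise InsufficientDataError(
                f"only {len(diffs)} paired similarities for ({roi}, {condition}); "
                "need at least 5"
            )
        mean_diff = float(diffs.mean())
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            res = scipy.stats.wilcoxon(diffs, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        direction = "threat" if mean_diff > 0 else ("distress" if mean_diff < 0 else "none")
        rows.append((roi, condition, len(diffs), mean_diff, stat, p, direction))
    out = pd.DataFrame(
        rows,
        columns=["roi", "condition", "n_subjects", "mean_tau_diff", "statistic", "p", "direction"],
    )
    adjusted, flags = fdr_adjust(out["p"].to_numpy(), alpha)
    out["p_fdr"] = adjusted
    out["significant"] = flags
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class RsaResults:
    """Outputs of the full similarity analysis."""

    similarity: pd.DataFrame
    models: pd.DataFrame
    predominance: pd.DataFrame
    helping: pd.DataFrame


def run_rsa(
    patterns: dict,
    schedule: pd.DataFrame,
    distress_ratings: pd.DataFrame,
    threat_ratings: pd.DataFrame,
    decisions: pd.DataFrame,
    roi_list=None,
    variant: str = "tau_a",
    alpha: float = 0.05,
    fdr_pool: str = "slopes",
    cluster_robust: bool = False,
    include_predominance: bool | None = None,
) -> RsaResults:
    """Run the full pipeline: similarities, per-ROI models, predominance.

    Deterministic given its inputs.  With the 13-region list this fits 13
    models and pools 39 slope p-values for the FDR step.  The predominance
    test needs at least 5 subjects; by default it is run exactly when the
    cohort is large enough (``include_predominance=None``), and an empty
    table is returned otherwise.
    """
    similarity = compute_similarity(
        patterns, schedule, distress_ratings, threat_ratings, roi_list, variant
    )
    helping = helping_summary(decisions, schedule)
    models = fit_all_roi_models(
        similarity, helping, roi_list, alpha, fdr_pool, cluster_robust
    )
    n_subjects = similarity["subject_id"].nunique()
    if include_predominance is None:
        include_predominance = n_subjects >= 5
    if include_predominance:
        predominance = predominance_test(similarity, alpha)
    else:
        predominance = pd.DataFrame(
            columns=[
                "roi",
                "condition",
                "n_subjects",
                "mean_tau_diff",
                "statistic",
                "p",
                "direction",
                "p_fdr",
                "significant",
            ]
        )
    return RsaResults(
        similarity=similarity, models=models, predominance=predominance, helping=helping
    )
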