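"""Kendall tau, second-order similarity, ROI models, FDR, predominance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import threathelp as th
from threathelp.exceptions import (
    CollinearityError,
    InsufficientDataError,
    LabelMismatchError,
    UndefinedStatisticError,
    ValidationError,
)
from threathelp.rsa import SLOPE_TERMS, fit_all_roi_models


def brute_force_tau(x, y, variant="tau_a"):
    """Exhaustive O(n^2) pair enumeration; the independent oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    conc = disc = tie_x = tie_y = 0
    for i, j in combinations(range(n), 2):
        sx, sy = np.sign(x[i] - x[j]), np.sign(y[i] - y[j])
        if sx == 0:
            tie_x += 1
        if sy == 0:
            tie_y += 1
        if sx * sy > 0:
            conc += 1
        elif sx * sy < 0:
            disc += 1
    n0 = n * (n - 1) // 2
    if variant == "tau_a":
        return (conc - disc) / n0
    return (conc - disc) / np.sqrt((n0 - tie_x) * (n0 - tie_y))


class TestKendallTau:
    def test_perfect_concordance_and_discordance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert th.kendall_tau(x, x) == 1.0
        assert th.kendall_tau(x, x, "tau_b") == 1.0
        assert th.kendall_tau(x, x[::-1]) == -1.0

    def test_hand_enumerated_example(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        # 10 pairs, 8 concordant, 2 discordant
        assert brute_force_tau(x, y) == pytest.approx(0.6)
        assert th.kendall_tau(x, y) == pytest.approx(0.6)

    def test_all_tied_input(self):
        x = np.zeros(6)
        y = np.arange(6.0)
        assert th.kendall_tau(x, y, "tau_a") == 0.0
        with pytest.raises(UndefinedStatisticError):
            th.kendall_tau(x, y, "tau_b")

    def test_input_validation(self):
        with pytest.raises(ValidationError):
            th.kendall_tau([1.0], [2.0])
        with pytest.raises(ValidationError):
            th.kendall_tau([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError):
            th.kendall_tau([1, 2, 3], [1, 2, 3], variant="tau_c")

    @given(
        n=st.integers(2, 8),
        seed=st.integers(0, 10_000),
        discrete=st.booleans(),
        variant=st.sampled_from(["tau_a", "tau_b"]),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_pair_enumeration_oracle(self, n, seed, discrete, variant):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, n).astype(float) if discrete else rng.normal(size=n)
        y = rng.integers(0, 3, n).astype(float) if discrete else rng.normal(size=n)
        n0 = n * (n - 1) // 2
        all_tied = len(np.unique(x)) == 1 or len(np.unique(y)) == 1
        if variant == "tau_b" and all_tied:
            return
        assert th.kendall_tau(x, y, variant) == pytest.approx(
            brute_force_tau(x, y, variant), abs=1e-12
        )

    def test_high_cardinality_path_agrees_with_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=120)  # 120 distinct values: scipy fallback path
        y = rng.normal(size=120)
        assert th.kendall_tau(x, y) == pytest.approx(brute_force_tau(x, y), abs=1e-9)


class TestSecondOrderSimilarity:
    def _rdms(self):
        rng = np.random.default_rng(2)
        pat = th.ROIPatternMatrix(1, "roi", np.arange(6), rng.normal(size=(6, 5)))
        neural = th.neural_rdm(pat)
        behavioral = th.rating_rdm(rng.integers(1, 10, 6), np.arange(6))
        return neural, behavioral

    def test_identical_rdms_give_tau_one(self):
        neural, _ = self._rdms()
        assert th.second_order_similarity(neural, neural).tau == pytest.approx(1.0)

    def test_constant_behavioral_rdm(self):
        neural, _ = self._rdms()
        flat = th.rating_rdm(np.full(6, 5.0), np.arange(6))
        assert th.second_order_similarity(neural, flat, "tau_a").tau == 0.0
        with pytest.raises(UndefinedStatisticError):
            th.second_order_similarity(neural, flat, "tau_b")

    def test_alignment_is_by_trial_id_not_position(self):
        neural, behavioral = self._rdms()
        perm = np.random.default_rng(3).permutation(6)
        shuffled = th.RDM(
            labels=behavioral.labels[perm],
            matrix=behavioral.matrix[np.ix_(perm, perm)],
            kind=behavioral.kind,
        )
        a = th.second_order_similarity(neural, behavioral)
        b = th.second_order_similarity(neural, shuffled)
        assert a.tau == pytest.approx(b.tau, abs=1e-12)
        assert a.n_pairs == 15  # 6 trials -> 15 lower-triangle entries

    def test_label_mismatch_lists_offenders(self):
        neural, behavioral = self._rdms()
        bad = th.RDM(
            labels=np.arange(100, 106), matrix=behavioral.matrix, kind="rating_euclidean"
        )
        with pytest.raises(LabelMismatchError, match="100"):
            th.second_order_similarity(neural, bad)

    def test_planted_threat_geometry_dominates(self, small_experiment):
        """Subjects generated with a >> d show tau_threat > tau_distress."""
        sched = th.generate_schedule(th.TaskDesign(), 1, seed=21)
        ratings = th.generate_ratings(sched, seed=21)
        params = th.NeuralParams(
            rois=("amygdala_left",), n_voxels=60, noise_sd=0.05,
            a_mean=3.0, a_sd=0.0, d_mean=0.1, d_sd=0.0,
        )
        pats = th.generate_roi_patterns(sched, ratings, params, seed=21)
        sim = th.compute_similarity(
            pats, sched, ratings.distress, ratings.threat, ["amygdala_left"]
        )
        assert (sim["tau_threat"] > sim["tau_distress"]).all()

    def test_pipeline_fast_path_equals_object_path(self, small_experiment):
        """Row-permuted patterns force per-object alignment; taus must match."""
        exp = small_experiment
        rng = np.random.default_rng(4)
        permuted = {}
        for key, pat in exp.patterns.items():
            p = rng.permutation(pat.n_trials)
            permuted[key] = th.ROIPatternMatrix(
                pat.subject_id, pat.roi_name, pat.trial_ids[p], pat.matrix[p]
            )
        rois = ["amygdala_left"]
        fast = th.compute_similarity(
            exp.patterns, exp.schedule, exp.ratings.distress, exp.ratings.threat, rois
        )
        slow = th.compute_similarity(
            permuted, exp.schedule, exp.ratings.distress, exp.ratings.threat, rois
        )
        np.testing.assert_allclose(
            fast[["tau_threat", "tau_distress"]].to_numpy(),
            slow[["tau_threat", "tau_distress"]].to_numpy(),
            atol=1e-12,
        )

    def test_permutation_destroys_similarity(self):
        """Shuffling behavioral RDM labels drives mean tau to ~0."""
        sched = th.generate_schedule(th.TaskDesign(), 1, seed=31)
        ratings = th.generate_ratings(sched, seed=31)
        params = th.NeuralParams(rois=("amygdala_left",), n_voxels=40)
        pats = th.generate_roi_patterns(sched, ratings, params, seed=31)
        cond = sched[sched.imminence == "distal"]
        trial_ids = cond["global_trial_id"].to_numpy()
        neural = th.neural_rdm(pats[(1, "amygdala_left")].subset(trial_ids))
        dist = ratings.distress.set_index("global_trial_id").loc[
            trial_ids, "distress_rating"
        ]
        behavioral = th.rating_rdm(dist.to_numpy(), trial_ids)
        rng = np.random.default_rng(5)
        taus = []
        for _ in range(200):
            perm = rng.permutation(len(trial_ids))
            shuffled = th.RDM(
                labels=behavioral.labels,
                matrix=behavioral.matrix[np.ix_(perm, perm)],
                kind="rating_euclidean",
            )
            taus.append(th.second_order_similarity(neural, shuffled).tau)
        taus = np.array(taus)
        mc_se = taus.std(ddof=1) / np.sqrt(len(taus))
        assert abs(taus.mean()) < 2 * mc_se + 1e-12


class TestRoiModels:
    def _similarity_frame(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(1, n + 1):
            for cond in ("distal", "imminent"):
                rows.append(
                    (s, "roiX", cond, rng.normal(), rng.normal(), 2556)
                )
        return pd.DataFrame(
            rows,
            columns=["subject_id", "roi", "condition", "tau_threat", "tau_distress", "n_pairs"],
        )

    def test_exact_linear_relation_recovered(self):
        sim = self._similarity_frame(seed=6)
        helping = (
            sim.groupby("subject_id")["tau_threat"].mean().rename("helping_pct_overall")
        )
        # outcome = 2 * subject-mean tau_threat; build rows accordingly
        per_subj = helping * 2.0
        sim2 = sim.copy()
        sim2["tau_threat"] = sim2["subject_id"].map(helping)  # identical across rows
        helping_df = pd.DataFrame(
            {"subject_id": per_subj.index, "helping_pct_overall": per_subj.to_numpy()}
        )
        res = th.fit_roi_model(sim2, helping_df, "roiX")
        beta = res.set_index("term")["beta"]
        assert beta["tau_threat"] == pytest.approx(2.0, abs=1e-8)
        fitted_sigma2 = res.set_index("term")["se"]["intercept"]
        assert np.isfinite(fitted_sigma2)

    def test_matches_normal_equations_on_random_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            sim = self._similarity_frame(n=15, seed=rng.integers(1 << 30))
            helping_df = pd.DataFrame(
                {
                    "subject_id": np.arange(1, 16),
                    "helping_pct_overall": rng.uniform(0, 100, 15),
                }
            )
            res = th.fit_roi_model(sim, helping_df, "roiX")
            merged = sim.merge(helping_df, on="subject_id")
            X = np.column_stack(
                [
                    np.ones(len(merged)),
                    merged["tau_threat"],
                    merged["tau_distress"],
                    (merged["condition"] == "imminent").astype(float),
                ]
            )
            y = merged["helping_pct_overall"].to_numpy()
            beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(
                res["beta"].to_numpy(), beta_ne, rtol=1e-8, atol=1e-10
            )
            # beta / se = t within numerical tolerance
            np.testing.assert_allclose(
                res["beta"] / res["se"], res["t"], rtol=1e-10
            )

    def test_constant_predictor_raises_collinearity(self):
        sim = self._similarity_frame(seed=8)
        sim["tau_distress"] = 0.5
        sim["tau_threat"] = 0.5
        helping_df = pd.DataFrame(
            {"subject_id": np.arange(1, 31), "helping_pct_overall": 50.0}
        )
        with pytest.raises(CollinearityError):
            th.fit_roi_model(sim, helping_df, "roiX")

    def test_null_cohort_betas_near_zero(self):
        """With no planted effects every slope stays within 3 SE of zero
        on average across simulations."""
        rng = np.random.default_rng(9)
        z_values = []
        for k in range(40):
            sim = self._similarity_frame(n=25, seed=rng.integers(1 << 30))
            helping_df = pd.DataFrame(
                {
                    "subject_id": np.arange(1, 26),
                    "helping_pct_overall": rng.uniform(20, 80, 25),
                }
            )
            res = th.fit_roi_model(sim, helping_df, "roiX").set_index("term")
            z_values.append(res["t"][list(SLOPE_TERMS)].to_numpy())
        mean_z = np.abs(np.mean(z_values, axis=0))
        assert (mean_z < 3 / np.sqrt(40) * 3).all()  # mean of ~N(0,1) over 40 reps

    def test_fdr_pool_counts(self, small_experiment):
        exp = small_experiment
        res = th.run_rsa(
            exp.patterns, exp.schedule, exp.ratings.distress, exp.ratings.threat,
            exp.decisions, roi_list=["amygdala_left", "insula_right"],
        )
        assert res.models["roi"].nunique() == 2
        assert res.models["p_fdr"].notna().sum() == 6  # 3 slopes x 2 models
        assert res.models.loc[res.models.term == "intercept", "p_fdr"].isna().all()

    def test_single_roi_fdr_pool(self, small_experiment):
        exp = small_experiment
        res = th.run_rsa(
            exp.patterns, exp.schedule, exp.ratings.distress, exp.ratings.threat,
            exp.decisions, roi_list=["amygdala_left"],
        )
        assert res.models["p_fdr"].notna().sum() == 3

    def test_missing_subject_roi_enumerated(self, small_experiment):
        exp = small_experiment
        patterns = dict(exp.patterns)
        patterns.pop((1, "amygdala_left"))
        with pytest.raises(ValidationError, match="amygdala_left"):
            th.compute_similarity(
                patterns, exp.schedule, exp.ratings.distress, exp.ratings.threat,
                ["amygdala_left", "insula_right"],
            )


class TestFdr:
    def test_single_p_value(self):
        adjusted, flags = th.fdr_adjust([0.04])
        assert adjusted[0] == pytest.approx(0.04)
        assert flags[0]

    def test_equal_p_values_are_fixed_point(self):
        adjusted, _ = th.fdr_adjust([0.03] * 7)
        np.testing.assert_allclose(adjusted, 0.03)

    def test_step_up_worked_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.20])
        adjusted, flags = th.fdr_adjust(p)
        # step-up: min over j>=i of m*p_(j)/j with monotonicity
        expected = [0.04, 0.04, 0.04, 0.20]
        np.testing.assert_allclose(adjusted, expected)
        assert flags.tolist() == [True, True, True, False]

    @given(
        n=st.integers(1, 20),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_up_definition(self, n, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=n), 3)
        adjusted, _ = th.fdr_adjust(p)
        order = np.argsort(p, kind="stable")
        m = len(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            expected[idx] = running
        np.testing.assert_allclose(adjusted, expected, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=15)
        perm = rng.permutation(15)
        a1, _ = th.fdr_adjust(p)
        a2, _ = th.fdr_adjust(p[perm])
        np.testing.assert_allclose(a1[perm], a2, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            th.fdr_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            th.fdr_adjust([-0.1])


class TestPredominance:
    def _sim(self, taus_t, taus_d, roi="r1", condition="distal"):
        n = len(taus_t)
        return pd.DataFrame(
            {
                "subject_id": np.arange(1, n + 1),
                "roi": roi,
                "condition": condition,
                "tau_threat": taus_t,
                "tau_distress": taus_d,
                "n_pairs": 10,
            }
        )

    def test_identical_taus_give_p_one(self):
        sim = self._sim([0.2] * 8, [0.2] * 8)
        res = th.predominance_test(sim)
        assert res["statistic"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert res["direction"].iloc[0] == "none"

    def test_threat_dominant_cohort_detected(self):
        rng = np.random.default_rng(12)
        t = 0.4 + 0.05 * rng.normal(size=20)
        d = 0.1 + 0.05 * rng.normal(size=20)
        res = th.predominance_test(self._sim(t, d))
        assert res["direction"].iloc[0] == "threat"
        assert res["significant"].iloc[0]

    def test_too_few_pairs_rejected(self):
        sim = self._sim([0.1] * 4, [0.2] * 4)
        with pytest.raises(InsufficientDataError):
            th.predominance_test(sim)

    def test_null_false_positive_rate_controlled(self):
        """Exchangeable tau_threat/tau_distress: FDR-flagged cells occur at
        most at the nominal rate (+2 Monte-Carlo SE) over 500 replicates."""
        rng = np.random.default_rng(13)
        flagged = total = 0
        for _ in range(500):
            frames = []
            for roi in ("r1", "r2"):
                for cond in ("distal", "imminent"):
                    frames.append(
                        self._sim(
                            rng.normal(0.2, 0.1, 12), rng.normal(0.2, 0.1, 12),
                            roi=roi, condition=cond,
                        )
                    )
            res = th.predominance_test(pd.concat(frames, ignore_index=True))
            flagged += int(res["significant"].sum())
            total += len(res)
        rate = flagged / total
        mc_se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 2 * mc_se

    def test_direction_matches_mean_difference_sign(self, default_cohort):
        exp = default_cohort
        sim = th.compute_similarity(
            exp.patterns, exp.schedule, exp.ratings.distress, exp.ratings.threat,
            ["amygdala_left", "vmpfc_right"],
        )
        res = th.predominance_test(sim)
        for _, row in res.iterrows():
            if row.mean_tau_diff > 0:
                assert row.direction == "threat"
            elif row.mean_tau_diff < 0:
                assert row.direction == "distress"
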