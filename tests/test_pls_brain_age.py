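"""Behavior PLS: stacking, correlations, SVD, permutation, bootstrap, summaries."""

import itertools

import numpy as np
import pytest
import scipy.stats

from neurocouple import pls_brain_age as pls
from neurocouple import gsp_coupling, synthetic_cohort
from neurocouple.gsp_coupling import CouplingProfile
from neurocouple.io_formats import SubjectRecord, ValidationError

from conftest import make_profiles, make_subjects, cohort_stack_from_cohort


def micro_stack(rng, n_ctl=4, n_ath=5, n_nodes=6):
    subjects = make_subjects(n_ctl, n_ath, rng)
    profiles = make_profiles(subjects, n_nodes, rng)
    return pls.stack_cohort(profiles, subjects), subjects, profiles


class TestStackCohort:
    def test_row_ordering_contract(self, rng):
        stack, subjects, profiles = micro_stack(rng, n_ctl=2, n_ath=2, n_nodes=5)
        assert stack.brain.shape == (8, 5)
        assert stack.row_group == ("control",) * 4 + ("athlete",) * 4
        assert stack.row_condition == ("S_C", "S_C", "S_D", "S_D") * 2
        # each subject's two rows share one age
        for sid in set(stack.subject_of_row):
            ages = {stack.age[i] for i, s in enumerate(stack.subject_of_row)
                    if s == sid}
            assert len(ages) == 1
        # rows carry the right values
        first_ctl = [s for s in subjects if s.group == "control"][0]
        assert np.array_equal(stack.brain[0], profiles[first_ctl.subject_id].s_c)
        assert np.array_equal(stack.brain[2], profiles[first_ctl.subject_id].s_d)

    def test_published_cohort_shape(self, rng):
        stack, _, _ = micro_stack(rng, n_ctl=14, n_ath=19, n_nodes=8)
        assert stack.brain.shape[0] == 66
        assert len(stack.cells) == 4

    def test_missing_profile_error(self, rng):
        subjects = make_subjects(3, 3, rng)
        profiles = make_profiles(subjects[:-1], 4, rng)
        with pytest.raises(ValidationError, match="profile"):
            pls.stack_cohort(profiles, subjects)

    def test_duplicate_subject_error(self, rng):
        subjects = make_subjects(3, 3, rng)
        profiles = make_profiles(subjects, 4, rng)
        with pytest.raises(ValidationError, match="duplicate"):
            pls.stack_cohort(profiles, subjects + [subjects[0]])


class TestBrainAgeCorrelations:
    def test_perfect_linear_cell(self, rng):
        subjects = [SubjectRecord(f"c{i}", a, "control", 0.1)
                    for i, a in enumerate([20.0, 30.0, 40.0])]
        profiles = {
            s.subject_id: CouplingProfile(("n0",), np.array([v]), np.array([1.0]))
            for s, v in zip(subjects, [1.0, 2.0, 3.0])
        }
        stack = pls.stack_cohort(profiles, subjects)
        with pytest.warns(RuntimeWarning):  # the constant S_D column
            corr = pls.brain_age_correlations(stack)
        assert corr[0, 0] == pytest.approx(1.0)
        assert corr[1, 0] == 0.0  # constant area -> 0, not NaN

    def test_matches_pearson_oracle(self, rng):
        stack, _, _ = micro_stack(rng, n_ctl=6, n_ath=6, n_nodes=7)
        corr = pls.brain_age_correlations(stack)
        for ci, (g, cond) in enumerate(stack.cells):
            idx = stack.cell_rows(g, cond)
            for j in range(7):
                r_oracle = scipy.stats.pearsonr(stack.age[idx],
                                                stack.brain[idx, j]).statistic
                assert corr[ci, j] == pytest.approx(r_oracle, abs=1e-12)

    def test_too_small_cell_error(self, rng):
        stack, _, _ = micro_stack(rng, n_ctl=2, n_ath=4, n_nodes=4)
        with pytest.raises(ValidationError, match="fewer than 3"):
            pls.brain_age_correlations(stack)


class TestPlsDecompose:
    def test_closed_form(self):
        s, v, u = pls.pls_decompose(np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert np.allclose(s, [1.0, 0.0], atol=1e-12)

    def test_four_latent_variables_for_two_groups(self, rng):
        corr = rng.standard_normal((4, 30))
        s, v, u = pls.pls_decompose(corr)
        assert len(s) == 4 and v.shape == (30, 4) and u.shape == (4, 4)

    def test_reconstruction_and_orthonormality(self, rng):
        corr = rng.standard_normal((4, 12))
        s, v, u = pls.pls_decompose(corr)
        assert np.abs(u @ np.diag(s) @ v.T - corr).max() < 1e-10
        assert np.abs(v.T @ v - np.eye(4)).max() < 1e-9
        assert np.all(np.diff(s) <= 1e-12)

    def test_sign_convention(self, rng):
        corr = rng.standard_normal((4, 12))
        _, _, u = pls.pls_decompose(corr)
        for k in range(4):
            assert u[np.argmax(np.abs(u[:, k])), k] > 0


class TestBrainScores:
    def test_identity_projection(self, rng):
        stack, _, _ = micro_stack(rng, n_ctl=3, n_ath=3, n_nodes=1)
        scores, _ = pls.brain_scores(stack, np.array([[1.0]]))
        assert np.allclose(scores[:, 0], stack.brain[:, 0])

    def test_zero_salience_degenerate(self, rng):
        stack, _, _ = micro_stack(rng, n_ctl=3, n_ath=3, n_nodes=2)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            scores, tab = pls.brain_scores(stack, np.zeros((2, 1)))
        assert not scores.any()
        assert (tab.r_score_age == 0).all()


def brute_force_perm_pvalues(stack, perms):
    """Independent oracle: plain-numpy correlations + SVD + strict counting."""
    subject_ids = list(dict.fromkeys(stack.subject_of_row))
    age_of = {s: stack.age[list(stack.subject_of_row).index(s)]
              for s in subject_ids}

    def svals(age_map):
        rows = []
        for g, cond in stack.cells:
            idx = stack.cell_rows(g, cond)
            a = np.array([age_map[stack.subject_of_row[i]] for i in idx])
            b = stack.brain[idx]
            r = [np.corrcoef(a, b[:, j])[0, 1] for j in range(b.shape[1])]
            rows.append(r)
        return np.linalg.svd(np.array(rows), compute_uv=False)

    observed = svals(age_of)
    count = np.zeros_like(observed)
    for perm in perms:
        shuffled = {subject_ids[i]: age_of[subject_ids[p]]
                    for i, p in enumerate(perm)}
        count += svals(shuffled) > observed
    return count / len(perms)


class TestPermutation:
    def test_exhaustive_micro_cohort_matches_oracle(self, rng):
        # single group of 3 subjects, all 6 age assignments enumerated
        subjects = [SubjectRecord(f"c{i}", a, "control", 0.1)
                    for i, a in enumerate([21.0, 33.0, 45.0])]
        profiles = make_profiles(subjects, 4, rng)
        stack = pls.stack_cohort(profiles, subjects)
        perms = list(itertools.permutations(range(3)))
        p, s_obs = pls.permutation_pvalues(stack, permutations=perms)
        p_oracle = brute_force_perm_pvalues(stack, perms)
        assert np.allclose(p, p_oracle, atol=1e-12)
        # with 6 permutations p is a multiple of 1/6
        assert np.allclose(np.round(p * 6), p * 6, atol=1e-12)

    def test_counting_is_strict(self, rng):
        # identity permutation never counts: singular values equal, not greater
        subjects = [SubjectRecord(f"c{i}", a, "control", 0.1)
                    for i, a in enumerate([21.0, 33.0, 45.0])]
        profiles = make_profiles(subjects, 4, rng)
        stack = pls.stack_cohort(profiles, subjects)
        p, _ = pls.permutation_pvalues(stack, permutations=[(0, 1, 2)])
        assert (p == 0).all()

    def test_invalid_n_perm(self, rng):
        stack, _, _ = micro_stack(rng)
        with pytest.raises(ValidationError):
            pls.permutation_pvalues(stack, n_perm=0)

    def test_seeded_reproducibility(self, rng):
        stack, _, _ = micro_stack(rng)
        p1, _ = pls.permutation_pvalues(stack, 200, np.random.default_rng(5))
        p2, _ = pls.permutation_pvalues(stack, 200, np.random.default_rng(5))
        assert np.array_equal(p1, p2)


class TestBootstrap:
    def test_smoke_minimum_iterations(self, rng):
        stack, _, _ = micro_stack(rng)
        corr = pls.brain_age_correlations(stack)
        s, v, u = pls.pls_decompose(corr)
        bsr, lo, hi = pls.bootstrap_ratios(stack, v, u, n_boot=2,
                                           rng=np.random.default_rng(3))
        assert bsr.shape == v.shape and np.isfinite(lo).all() and (lo <= hi).all()

    def test_n_boot_too_small(self, rng):
        stack, _, _ = micro_stack(rng)
        with pytest.raises(ValidationError):
            pls.bootstrap_ratios(stack, np.zeros((6, 4)), np.eye(4), n_boot=1)

    def test_reflection_alignment_recovers_original(self, rng):
        # inject a pure axis reflection; Procrustes alignment must undo it
        m = rng.standard_normal((4, 10))
        u, _, vt = np.linalg.svd(m, full_matrices=False)
        v = vt.T
        signs = np.diag([1.0, -1.0, -1.0, 1.0])
        u_al, v_al = pls.align_to_reference(u @ signs, v @ signs, u)
        assert np.abs(u_al - u).max() < 1e-10
        assert np.abs(v_al - v).max() < 1e-10

    def test_seeded_reproducibility(self, rng):
        stack, _, _ = micro_stack(rng)
        corr = pls.brain_age_correlations(stack)
        s, v, u = pls.pls_decompose(corr)
        out1 = pls.bootstrap_ratios(stack, v, u, 20, np.random.default_rng(9))
        out2 = pls.bootstrap_ratios(stack, v, u, 20, np.random.default_rng(9))
        for a, b in zip(out1, out2):
            assert np.array_equal(a, b)


def brute_force_network_summary(bsr, nets, threshold):
    pos, neg, counts = {}, {}, {}
    for net in set(nets):
        vals = [b for b, n in zip(bsr, nets) if n == net]
        p = [v for v in vals if v > threshold]
        m = [v for v in vals if v < -threshold]
        counts[net] = len(p) + len(m)
        if p:
            pos[net] = float(np.mean(p))
        if m:
            neg[net] = float(np.mean(m))
    return pos, neg, counts


class TestNetworkSummary:
    def test_direct_application(self):
        summ = pls.network_summary(np.array([3.0, -3.0, 1.0]),
                                   ("x", "y", "z"),
                                   {"x": "a", "y": "a", "z": "b"})
        assert summ.positive_mean == {"a": 3.0}
        assert summ.negative_mean == {"a": -3.0}
        assert summ.counts == {"a": 2, "b": 0}

    def test_value_averaging_mode(self):
        # threshold on BSR, average a companion value column (correlations)
        summ = pls.network_summary(np.array([3.0, -3.0, 1.0]),
                                   ("x", "y", "z"),
                                   {"x": "a", "y": "a", "z": "b"},
                                   values=np.array([0.8, -0.6, 0.1]))
        assert summ.positive_mean == {"a": 0.8}
        assert summ.negative_mean == {"a": -0.6}

    def test_all_below_threshold(self):
        summ = pls.network_summary(np.array([1.0, -2.0]), ("x", "y"),
                                   {"x": "a", "y": "a"})
        assert not summ.positive_mean and not summ.negative_mean
        assert summ.counts == {"a": 0}

    def test_matches_group_by_oracle(self, rng):
        n = 360
        node_ids = tuple(f"n{i}" for i in range(n))
        nets = [f"net{i % 12}" for i in range(n)]
        network_of = dict(zip(node_ids, nets))
        bsr = rng.standard_normal(n) * 2
        summ = pls.network_summary(bsr, node_ids, network_of)
        pos, neg, counts = brute_force_network_summary(bsr, nets, 2.58)
        assert summ.counts == counts
        assert summ.positive_mean == pytest.approx(pos)
        assert summ.negative_mean == pytest.approx(neg)


class TestMotionCheck:
    def test_constant_fd_degenerate(self, rng):
        stack, subjects, _ = micro_stack(rng)
        subjects = [SubjectRecord(s.subject_id, s.age_years, s.group, 0.1)
                    for s in subjects]
        scores = rng.standard_normal((stack.brain.shape[0], 2))
        with pytest.warns(RuntimeWarning):
            tab = pls.motion_check(scores, stack, subjects)
        assert (tab.r_fd == 0).all()

    def test_scores_equal_fd(self, rng):
        stack, subjects, _ = micro_stack(rng)
        fd_of = {s.subject_id: s.mean_fd_mm for s in subjects}
        scores = np.array([[fd_of[s]] for s in stack.subject_of_row])
        tab = pls.motion_check(scores, stack, subjects)
        assert np.allclose(tab.r_fd, 1.0)

    def test_fd_independent_noise_gives_small_r(self):
        # null simulation: FD is independent of the brain signal, so score-FD
        # correlations at n=33 stay modest in nearly all replicates
        hits = 0
        reps = 50
        for i, child in enumerate(np.random.SeedSequence(77).spawn(reps)):
            r = np.random.default_rng(child)
            subjects = make_subjects(14, 19, r)
            profiles = make_profiles(subjects, 12, r)
            stack = pls.stack_cohort(profiles, subjects)
            corr = pls.brain_age_correlations(stack)
            _, v, _ = pls.pls_decompose(corr)
            scores, _ = pls.brain_scores(stack, v)
            tab = pls.motion_check(scores, stack, subjects)
            if tab.r_fd.abs().max() < 0.5:
                hits += 1
        assert hits >= int(0.95 * reps)


class TestRunPls:
    def test_end_to_end_on_planted_cohort(self):
        eff = synthetic_cohort.PlantedEffect(
            target_networks=frozenset({"frontoparietal", "default"}),
            slope_sc_per_year={"athlete": 0.10, "control": 0.0})
        cfg = synthetic_cohort.SimulationConfig(
            seed=42, n_nodes=60, n_networks=12, effect=eff)
        stack, subjects, _ = cohort_stack_from_cohort(cfg)
        labels = synthetic_cohort.node_labels(cfg)
        res = pls.run_pls(stack, n_perm=200, n_boot=50, network_of=labels,
                          rng=np.random.default_rng(0), subjects=subjects)
        assert res.n_lv == 4
        assert res.perm_p[0] <= 0.05
        # top LV design salience is dominated by the athlete S_C cell
        k = res.cells.index(("athlete", "S_C"))
        assert np.argmax(np.abs(res.design_saliences[:, 0])) == k
        assert res.motion is not None and len(res.network_summaries) == 4

    def test_athlete_score_age_positive_across_replicates(self):
        # the planted athlete-only S_C slope shows up as a positive
        # score-age correlation in the athlete S_C cell
        eff = synthetic_cohort.PlantedEffect(
            target_networks=frozenset({"frontoparietal", "default"}),
            slope_sc_per_year={"athlete": 0.10, "control": 0.0})
        hits = 0
        reps = 20
        for child in np.random.SeedSequence(31).spawn(reps):
            seed = int(child.generate_state(1)[0] % (2**31))
            cfg = synthetic_cohort.SimulationConfig(
                seed=seed, n_nodes=36, n_networks=12, n_trs=60, effect=eff)
            stack, subjects, _ = cohort_stack_from_cohort(cfg)
            corr = pls.brain_age_correlations(stack)
            _, v, u = pls.pls_decompose(corr)
            scores, tab = pls.brain_scores(stack, v)
            k = stack.cells.index(("athlete", "S_C"))
            lv = int(np.argmax(np.abs(u[k])))  # LV carrying the athlete-S_C cell
            row = tab[(tab.group == "athlete") & (tab.condition == "S_C")
                      & (tab.lv == lv + 1)]
            sign = np.sign(u[k, lv])
            if float(row.r_score_age.iloc[0]) * sign > 0:
                hits += 1
        assert hits >= int(0.95 * reps)
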