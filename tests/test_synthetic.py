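import numpy as np
import pandas as pd
import pytest

from dfnc.synthetic import (
    DEFAULT_BEHAVIOR_MOMENTS,
    CohortConfig,
    MarkovModel,
    PlantedEffect,
    StateCovarianceSet,
    generate_cohort,
    make_default_states,
    simulate_behavior_table,
    simulate_state_sequence,
    simulate_subject_timecourse,
    true_state_features,
)


class TestDefaultStates:
    def test_canonical_templates_qualitative_structure(self):
        s = make_default_states(C=6, K=4, separation=0.6)
        off = ~np.eye(6, dtype=bool)
        # hyperconnected state: every off-diagonal positive
        assert (s.covariances[2][off] > 0).all()
        # first state: salience row silent, pdDMN-pvDMN and pdDMN-rECN strongest
        m1 = s.covariances[0]
        assert np.abs(m1[5, :5]).max() < 0.1
        assert m1[1, 2] == pytest.approx(m1[1, 3])
        assert m1[1, 2] > m1[0, 1]
        # isolated-dyad state: pvDMN-SN entry dominates both rows
        m4 = s.covariances[3]
        assert m4[2, 5] == np.abs(m4[2, [0, 1, 3, 4, 5]]).max()

    def test_zero_separation_gives_identity(self):
        s = make_default_states(C=2, K=1, separation=0.0)
        assert np.array_equal(s.covariances[0], np.eye(2))

    @pytest.mark.parametrize("C,K", [(6, 4), (5, 3), (8, 6), (2, 1)])
    def test_all_matrices_positive_definite_unit_diagonal(self, C, K):
        s = make_default_states(C=C, K=K, separation=0.6)
        for m in s.covariances:
            assert np.linalg.eigvalsh(m).min() > 0
            assert np.allclose(np.diag(m), 1.0)
            assert np.abs(m[~np.eye(C, dtype=bool)]).max() < 1.0

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            make_default_states(C=1, K=1)
        with pytest.raises(ValueError):
            StateCovarianceSet((np.array([[1.0, 0.5], [0.4, 1.0]]),))


class TestMarkovChain:
    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            MarkovModel(np.array([[0.5, 0.4], [0.5, 0.5]]))
        with pytest.raises(ValueError):
            MarkovModel(np.array([[1.2, -0.2], [0.0, 1.0]]))

    def test_absorbing_chain_yields_constant_sequence(self):
        model = MarkovModel(np.eye(3), initial=[0.0, 1.0, 0.0])
        seq = simulate_state_sequence(model, 50, seed=0)
        assert (seq == 1).all()

    def test_zero_self_transition_two_states_alternates(self):
        model = MarkovModel(np.array([[0.0, 1.0], [1.0, 0.0]]))
        seq = simulate_state_sequence(model, 100, seed=1)
        assert (np.diff(seq) != 0).all()

    def test_mean_run_length_matches_geometric_dwell(self):
        p = 0.9
        model = MarkovModel.uniform_sticky(3, self_transition=p)
        seq = simulate_state_sequence(model, 10**5, seed=3)
        n_runs = 1 + int((np.diff(seq) != 0).sum())
        mean_run = len(seq) / n_runs
        assert abs(mean_run - 1 / (1 - p)) / (1 / (1 - p)) < 0.05


class TestEmissions:
    def test_long_single_state_run_recovers_state_matrix(self):
        states = make_default_states()
        seq = np.full(10**5, 2)
        tc = simulate_subject_timecourse(states, seq, seed=4)
        est = np.corrcoef(tc.values, rowvar=False)
        assert np.abs(est - states.covariances[2]).max() < 0.02

    def test_same_seed_reproduces_identical_matrix(self):
        states = make_default_states()
        seq = simulate_state_sequence(MarkovModel.uniform_sticky(4), 190, seed=5)
        a = simulate_subject_timecourse(states, seq, seed=9)
        b = simulate_subject_timecourse(states, seq, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_single_timepoint(self):
        states = make_default_states()
        tc = simulate_subject_timecourse(states, np.array([0]), seed=0)
        assert tc.values.shape == (1, 6)

    def test_labels_out_of_range_rejected(self):
        states = make_default_states(C=4, K=2)
        with pytest.raises(ValueError):
            simulate_subject_timecourse(states, np.array([0, 2]), seed=0)


class TestBehaviorTable:
    def _features(self, n, rng):
        return pd.DataFrame({"f": rng.standard_normal(n)})

    def test_null_effect_has_near_zero_correlation(self, rng):
        f = self._features(10**4, rng)
        b = simulate_behavior_table(f, effects=(), seed=0)
        r = np.corrcoef(f["f"], b["YSR ADHD"])[0, 1]
        assert abs(r) < 0.03

    def test_planted_rho_recovered_at_large_n(self, rng):
        f = self._features(10**4, rng)
        eff = (PlantedEffect("f", "YSR ADHD", 0.35),)
        b = simulate_behavior_table(f, effects=eff, seed=1)
        r = np.corrcoef(f["f"], b["YSR ADHD"])[0, 1]
        assert abs(r - 0.35) < 0.03

    def test_default_moments_match_cohort_table(self, rng):
        f = self._features(10**4, rng)
        b = simulate_behavior_table(f, effects=(), seed=2)
        mean, sd = DEFAULT_BEHAVIOR_MOMENTS["YSR Attention Problems"]
        assert abs(b["YSR Attention Problems"].mean() - mean) < 0.2
        assert abs(b["YSR Attention Problems"].std() - sd) < 0.2

    def test_invalid_effects_rejected(self, rng):
        f = self._features(100, rng)
        with pytest.raises(ValueError):
            PlantedEffect("f", "YSR ADHD", 1.0)
        with pytest.raises(ValueError):
            simulate_behavior_table(
                f, effects=(PlantedEffect("missing", "YSR ADHD", 0.3),)
            )
        dup = (PlantedEffect("f", "YSR ADHD", 0.3), PlantedEffect("f", "YSR ADHD", 0.2))
        with pytest.raises(ValueError):
            simulate_behavior_table(f, effects=dup)


class TestCohort:
    def test_default_dimensions(self, small_cohort):
        cfg = small_cohort.config
        assert cfg.n_timepoints == 190 and cfg.n_components == 6
        for tc, seq in zip(small_cohort.subjects, small_cohort.true_state_sequences):
            assert tc.values.shape == (190, 6)
            assert len(seq) == 190
        assert list(small_cohort.behavior.columns[:6]) == list(
            DEFAULT_BEHAVIOR_MOMENTS
        )

    def test_full_scale_cohort_dimensions(self):
        c = generate_cohort(CohortConfig(seed=1))
        assert len(c.subjects) == 80
        assert c.behavior.shape[0] == 80

    def test_single_subject_cohort(self):
        c = generate_cohort(CohortConfig(n_subjects=1, seed=2))
        assert len(c.subjects) == 1

    def test_seed_determinism_bit_for_bit(self):
        a = generate_cohort(CohortConfig(n_subjects=4, seed=11))
        b = generate_cohort(CohortConfig(n_subjects=4, seed=11))
        assert all(
            np.array_equal(x.values, y.values)
            for x, y in zip(a.subjects, b.subjects)
        )
        pd.testing.assert_frame_equal(a.behavior, b.behavior)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_subjects=2, seed=1))
        b = generate_cohort(CohortConfig(n_subjects=2, seed=2))
        assert not np.array_equal(a.subjects[0].values, b.subjects[0].values)

    def test_single_state_segment_matches_generating_matrix(self):
        # within-state emission fidelity at the invariant's segment length
        states = make_default_states()
        seq = np.full(10**4, 1)
        tc = simulate_subject_timecourse(states, seq, seed=21)
        est = np.corrcoef(tc.values, rowvar=False)
        assert np.abs(est - states.covariances[1]).max() <= 0.05

    def test_true_feature_bookkeeping(self):
        seqs = [np.array([0, 0, 1, 1, 1, 0])]
        f = true_state_features(seqs, 2)
        assert f.loc[0, "state1_ft"] == pytest.approx(0.5)
        assert f.loc[0, "state1_mdt"] == pytest.approx(1.5)
        assert f.loc[0, "state2_mdt"] == pytest.approx(3.0)
        assert f.loc[0, "n_transitions"] == 2


class TestPlantedCorrelationRecovery:
    @pytest.mark.parametrize("rho", [0.24, 0.30, 0.35])
    def test_empirical_correlation_within_sampling_band(self, rho):
        """Planted rho is recovered within 2/sqrt(80) in >= 95% of replicates."""
        tol = 2 / np.sqrt(80)
        effects = (PlantedEffect("state3_mdt", "YSR ADHD", rho),)
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            c = generate_cohort(
                CohortConfig(n_subjects=80, effects=effects, seed=10_000 + i)
            )
            r = np.corrcoef(c.features["state3_mdt"], c.behavior["YSR ADHD"])[0, 1]
            hits += abs(r - rho) <= tol
        assert hits / n_rep >= 0.95
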