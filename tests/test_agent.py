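import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from runtumble.agent import (
    Beliefs,
    GenerativeModel,
    Strategy,
    agent_step,
    dirichlet_mean,
    expected_log_transitions,
    infer_control,
    infer_state,
    init_model,
    make_maladaptive_model,
    negative_efe,
    novelty_matrix,
    predict,
    sample_action,
    update_parameters,
)
from runtumble.environment import Action, Observation


def make_beliefs(phi_alpha, phi_s=(0.5, 0.5), prev_phi_s=None, prev_action=None):
    return Beliefs(
        phi_s=np.asarray(phi_s, dtype=float),
        phi_u=np.array([0.5, 0.5]),
        phi_alpha=np.asarray(phi_alpha, dtype=float),
        prev_phi_s=None if prev_phi_s is None else np.asarray(prev_phi_s, dtype=float),
        prev_action=prev_action,
    )


def symmetric_model(counts=1.0, rho_log=(0.0, -4.0), delta=0.1):
    alpha = np.full((2, 2, 2), counts)
    return GenerativeModel(lambda_=np.eye(2), alpha=alpha, rho_log=rho_log, delta=delta)


class TestInitModel:
    def test_likelihood_is_identity(self):
        model, _ = init_model(0)
        assert np.allclose(model.lambda_, np.eye(2), atol=1e-12)

    def test_seeded_determinism(self):
        m1, b1 = init_model(5)
        m2, b2 = init_model(5)
        assert np.array_equal(m1.alpha, m2.alpha)
        assert np.array_equal(b1.phi_alpha, b2.phi_alpha)

    def test_columns_sum_to_concentration(self):
        model, _ = init_model(3, concentration=1.7)
        assert np.allclose(model.alpha.sum(axis=1), 1.7)

    def test_initial_state_belief_uniform(self):
        _, beliefs = init_model(9)
        assert np.allclose(beliefs.phi_s, 0.5)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            init_model(0, concentration=0.0)


class TestExpectedLogTransitions:
    # oracle: the digamma recurrence psi(n+1) = psi(n) + 1/n
    @pytest.mark.parametrize(
        "column,expected",
        [
            ((1.0, 1.0), (-1.0, -1.0)),
            ((3.0, 1.0), (-1.0 / 3.0, -11.0 / 6.0)),
            ((2.0, 2.0), (-5.0 / 6.0, -5.0 / 6.0)),
        ],
    )
    def test_against_recurrence_values(self, column, expected):
        counts = np.array(column).reshape(2, 1)
        assert np.allclose(expected_log_transitions(counts)[:, 0], expected)

    def test_entries_nonpositive(self, rng):
        counts = rng.uniform(0.05, 10, size=(4, 4))
        assert np.all(expected_log_transitions(counts) <= 0)

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ValueError):
            expected_log_transitions(np.array([[1.0], [0.0]]))


class TestInferState:
    def test_unambiguous_likelihood_dominates(self):
        model, beliefs = init_model(1)
        phi_s = infer_state(Observation.POS, beliefs, model)
        assert phi_s[0] > 0.999

    def test_symmetry_gives_uniform(self):
        model = symmetric_model()
        model.lambda_ = np.full((2, 2), 0.5)
        model.log_lambda = np.log(model.lambda_)
        beliefs = make_beliefs(model.alpha.copy(), prev_phi_s=(0.5, 0.5),
                               prev_action=Action.RUN)
        assert np.allclose(infer_state(Observation.POS, beliefs, model), 0.5)

    def test_equals_normalized_likelihood_when_prior_flat(self):
        # columns (0.8, 0.2) and (0.3, 0.7); all-ones counts make the
        # transition message constant, so phi_s is the normalized row
        model = symmetric_model()
        model.lambda_ = np.array([[0.8, 0.3], [0.2, 0.7]])
        model.log_lambda = np.log(model.lambda_)
        beliefs = make_beliefs(model.alpha.copy(), prev_phi_s=(0.5, 0.5),
                               prev_action=Action.RUN)
        phi_s = infer_state(Observation.POS, beliefs, model)
        assert np.allclose(phi_s, (0.8 / 1.1, 0.3 / 1.1))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_belief_tracks_observation_with_identity_likelihood(self, seed):
        # even for extreme random counts, state inference follows the
        # unambiguous observation
        rng = np.random.default_rng(seed)
        model, beliefs = init_model(rng, concentration=0.5)
        beliefs.prev_phi_s = np.array([1.0, 0.0])
        beliefs.prev_action = Action.RUN
        obs = Observation(int(rng.integers(2)))
        phi_s = infer_state(obs, beliefs, model)
        assert phi_s[int(obs)] > 0.5
        assert phi_s.sum() == pytest.approx(1.0, abs=1e-12)


class TestPredict:
    def test_dirichlet_mean_of_column(self):
        model = symmetric_model()
        beliefs = make_beliefs(model.alpha.copy(), phi_s=(1.0, 0.0))
        beliefs.phi_alpha[Action.RUN][:, 0] = (3.0, 1.0)
        pred_s, pred_o = predict(beliefs, Action.RUN, model)
        assert np.allclose(pred_s, (0.75, 0.25))
        assert np.allclose(pred_o, pred_s)  # identity likelihood

    def test_symmetric_counts_give_uniform(self, rng):
        model = symmetric_model(counts=2.0)
        phi_s = rng.dirichlet(np.ones(2))
        beliefs = make_beliefs(model.alpha.copy(), phi_s=phi_s)
        pred_s, _ = predict(beliefs, Action.TUMBLE, model)
        assert np.allclose(pred_s, 0.5)


class TestNoveltyMatrix:
    def test_all_ones_counts(self):
        assert np.allclose(novelty_matrix(np.ones((2, 2))), 0.5)

    def test_hand_arithmetic(self):
        counts = np.array([[10.0], [10.0]])
        assert np.allclose(novelty_matrix(counts), 1.0 / 20.0)

    @given(scale=st.floats(1.5, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_homogeneity(self, scale):
        counts = np.array([[1.0, 2.0], [3.0, 0.5]])
        assert np.allclose(novelty_matrix(scale * counts), novelty_matrix(counts) / scale)

    def test_nonnegative_and_vanishing(self, rng):
        counts = rng.uniform(0.01, 5, size=(3, 3))
        w = novelty_matrix(counts)
        assert np.all(w >= 0)
        assert np.all(novelty_matrix(1e6 * counts) < 1e-5)


class TestNegativeEfe:
    def test_hand_computed_decomposition(self):
        # all-ones counts: novelty == 1/2 everywhere, predictions uniform.
        # epistemic = 1/2; instrumental = 0.5*0 + 0.5*(-4) = -2, delta = 0.1
        model = symmetric_model(counts=1.0)
        beliefs = make_beliefs(model.alpha.copy(), phi_s=(1.0, 0.0))
        assert negative_efe(beliefs, Action.RUN, model, Strategy.EPISTEMIC) == pytest.approx(0.5)
        assert negative_efe(beliefs, Action.RUN, model, Strategy.INSTRUMENTAL) == pytest.approx(-2.0)
        assert negative_efe(beliefs, Action.RUN, model, Strategy.EFE) == pytest.approx(0.3)

    def test_one_hot_prediction_picks_preferred(self):
        model = symmetric_model(counts=1.0)
        model.alpha[Action.RUN][:, :] = [[1e6, 1e6], [1e-12, 1e-12]]
        beliefs = make_beliefs(model.alpha.copy(), phi_s=(1.0, 0.0))
        # predicted obs ~ (1, 0): instrumental term ~ delta * 0
        assert negative_efe(beliefs, Action.RUN, model, Strategy.INSTRUMENTAL) == pytest.approx(
            0.0, abs=1e-5
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_efe_is_sum_of_parts(self, seed):
        rng = np.random.default_rng(seed)
        model, beliefs = init_model(rng)
        beliefs.phi_s = rng.dirichlet(np.ones(2))
        for u in (Action.RUN, Action.TUMBLE):
            total = negative_efe(beliefs, u, model, Strategy.EFE)
            parts = negative_efe(beliefs, u, model, Strategy.EPISTEMIC) + (
                model.delta * negative_efe(beliefs, u, model, Strategy.INSTRUMENTAL)
            )
            assert total == pytest.approx(parts, abs=1e-14)

    def test_random_strategy_scores_zero(self):
        model, beliefs = init_model(2)
        assert negative_efe(beliefs, Action.RUN, model, Strategy.RANDOM) == 0.0


class TestInferControl:
    def test_symmetric_model_gives_uniform(self):
        model = symmetric_model()
        beliefs = make_beliefs(model.alpha.copy(), phi_s=(0.5, 0.5))
        assert np.allclose(infer_control(beliefs, model, Strategy.EFE), 0.5)

    def test_random_strategy_uniform(self):
        model, beliefs = init_model(4)
        assert np.allclose(infer_control(beliefs, model, Strategy.RANDOM), 0.5)

    def test_softmax_of_strategy_scores(self):
        # posterior equals softmax of the per-control scores, so shifting
        # both scores by a constant cannot matter
        model, beliefs = init_model(8)
        beliefs.phi_s = np.array([0.9, 0.1])
        scores = np.array(
            [negative_efe(beliefs, Action(u), model, Strategy.EFE) for u in range(2)]
        )
        expected = np.exp(scores - scores.max())
        expected /= expected.sum()
        assert np.allclose(infer_control(beliefs, model, Strategy.EFE), expected)

    def test_efe_posterior_combines_both_strategy_scores(self):
        model, beliefs = init_model(13)
        beliefs.phi_s = np.array([0.7, 0.3])
        epi = np.array([negative_efe(beliefs, Action(u), model, Strategy.EPISTEMIC) for u in range(2)])
        ins = model.delta * np.array(
            [negative_efe(beliefs, Action(u), model, Strategy.INSTRUMENTAL) for u in range(2)]
        )
        combined = np.exp(epi + ins - (epi + ins).max())
        combined /= combined.sum()
        assert np.allclose(infer_control(beliefs, model, Strategy.EFE), combined)


class TestSampleAction:
    def test_degenerate_categoricals(self, rng):
        assert sample_action(np.array([1.0, 0.0]), rng) == Action.RUN
        assert sample_action(np.array([0.0, 1.0]), rng) == Action.TUMBLE

    def test_law_of_large_numbers(self, rng):
        draws = [sample_action(np.array([0.5, 0.5]), rng) for _ in range(10_000)]
        freq = np.mean([a == Action.RUN for a in draws])
        assert abs(freq - 0.5) < 0.02

    def test_rejects_non_simplex(self, rng):
        with pytest.raises(ValueError):
            sample_action(np.array([0.5, 0.2]), rng)


class TestUpdateParameters:
    def test_one_hot_outer_product(self):
        model = symmetric_model()
        model.xi = 0.001
        beliefs = make_beliefs(model.alpha.copy(), phi_s=(1.0, 0.0), prev_phi_s=(1.0, 0.0))
        update_parameters(beliefs, Action.RUN, model)
        expected = model.alpha.copy()
        expected[Action.RUN][0, 0] += 0.001
        assert np.allclose(beliefs.phi_alpha, expected)

    def test_uniform_beliefs_spread_update(self):
        model = symmetric_model()
        model.xi = 0.001
        beliefs = make_beliefs(model.alpha.copy(), phi_s=(0.5, 0.5), prev_phi_s=(0.5, 0.5))
        update_parameters(beliefs, Action.TUMBLE, model)
        assert np.allclose(beliefs.phi_alpha[Action.TUMBLE], 1.0 + 0.00025)
        assert np.allclose(beliefs.phi_alpha[Action.RUN], 1.0)

    def test_total_count_grows_by_xi(self, rng):
        model, beliefs = init_model(rng)
        beliefs.prev_phi_s = rng.dirichlet(np.ones(2))
        beliefs.phi_s = rng.dirichlet(np.ones(2))
        before = beliefs.phi_alpha.sum()
        update_parameters(beliefs, Action.RUN, model)
        assert beliefs.phi_alpha.sum() - before == pytest.approx(model.xi, abs=1e-15)


class TestAgentStep:
    def test_learning_flag_freezes_counts(self, rng):
        model, beliefs = init_model(6)
        before = beliefs.phi_alpha.copy()
        for _ in range(20):
            obs = Observation(int(rng.integers(2)))
            agent_step(obs, beliefs, model, Strategy.EFE, rng, learn=False)
        assert np.array_equal(beliefs.phi_alpha, before)

    def test_counts_nondecreasing_under_learning(self, rng):
        model, beliefs = init_model(6)
        prev = beliefs.phi_alpha.copy()
        for _ in range(50):
            obs = Observation(int(rng.integers(2)))
            agent_step(obs, beliefs, model, Strategy.EFE, rng, learn=True)
            assert np.all(beliefs.phi_alpha >= prev - 1e-15)
            prev = beliefs.phi_alpha.copy()

    def test_log_decomposition_identity(self, rng):
        model, beliefs = init_model(6)
        for _ in range(20):
            obs = Observation(int(rng.integers(2)))
            _, _, rec = agent_step(obs, beliefs, model, Strategy.EFE, rng, log=True)
            assert np.allclose(rec.neg_efe, rec.epistemic + rec.instrumental, atol=1e-14)

    def test_seeded_determinism(self):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            obs_rng = np.random.default_rng(7)
            model, beliefs = init_model(12)
            actions = []
            for _ in range(50):
                obs = Observation(int(obs_rng.integers(2)))
                a, _, _ = agent_step(obs, beliefs, model, Strategy.EFE, rng)
                actions.append(int(a))
            seqs.append(actions)
        assert seqs[0] == seqs[1]


class TestMaladaptiveModel:
    def test_run_in_positive_believed_worse_than_tumble(self):
        model, beliefs = make_maladaptive_model()
        run_mean = dirichlet_mean(model.alpha[Action.RUN])[Observation.POS, Observation.POS]
        tumble_mean = dirichlet_mean(model.alpha[Action.TUMBLE])[Observation.POS, Observation.POS]
        assert run_mean < tumble_mean

    def test_instrumental_prefers_tumbling_at_start(self):
        model, beliefs = make_maladaptive_model()
        beliefs.phi_s = np.array([1.0, 0.0])
        run = negative_efe(beliefs, Action.RUN, model, Strategy.INSTRUMENTAL)
        tumble = negative_efe(beliefs, Action.TUMBLE, model, Strategy.INSTRUMENTAL)
        assert tumble > run

    def test_epistemic_value_initially_equal(self):
        model, beliefs = make_maladaptive_model()
        beliefs.phi_s = np.array([1.0, 0.0])
        run = negative_efe(beliefs, Action.RUN, model, Strategy.EPISTEMIC)
        tumble = negative_efe(beliefs, Action.TUMBLE, model, Strategy.EPISTEMIC)
        assert run == pytest.approx(tumble)


class TestParameterRecovery:
    def test_random_policy_recovers_known_tensor(self):
        # abstract 2-state MDP: transitions drawn from a known tensor; an
        # elevated learning rate stands in for a long horizon
        true_T = np.array(
            [[[0.9, 0.3], [0.1, 0.7]], [[0.5, 0.6], [0.5, 0.4]]]
        )
        rng = np.random.default_rng(0)
        model, beliefs = init_model(rng, xi=1.0)
        state = 0
        kl_at = {}
        for t in range(1, 4001):
            obs = Observation(state)
            action, _, _ = agent_step(obs, beliefs, model, Strategy.RANDOM, rng)
            state = int(rng.random() < true_T[action][1, state])
            if t in (400, 4000):
                total = 0.0
                for u in range(2):
                    mean = dirichlet_mean(beliefs.phi_alpha[u])
                    for j in range(2):
                        p = true_T[u][:, j]
                        total += float(np.sum(p * np.log(p / mean[:, j])))
                kl_at[t] = total
        assert kl_at[4000] < kl_at[400]
        assert kl_at[4000] < 0.01


@given(
    counts=arrays(
        np.float64,
        (2, 2, 2),
        elements=st.floats(0.01, 20.0, allow_nan=False),
    ),
    obs=st.sampled_from([Observation.POS, Observation.NEG]),
)
@settings(max_examples=30, deadline=None)
def test_simplex_invariants(counts, obs):
    """Every simplex-typed output is non-negative and sums to one."""
    model = GenerativeModel(lambda_=np.eye(2), alpha=counts, rho_log=(0.0, -4.0))
    beliefs = make_beliefs(counts.copy(), prev_phi_s=(0.3, 0.7), prev_action=Action.RUN)
    phi_s = infer_state(obs, beliefs, model)
    phi_u = infer_control(beliefs, model, Strategy.EFE)
    pred_s, pred_o = predict(beliefs, Action.TUMBLE, model)
    for vec in (phi_s, phi_u, pred_s, pred_o):
        assert np.all(vec >= 0)
        assert abs(float(vec.sum()) - 1.0) < 1e-12
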