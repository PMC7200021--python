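"""Measurement procedures: the 'true' model oracle and all model metrics.

The learned transition model is judged against a *true* model: the same
2x2x2 tensor structure, but estimated from a long run of uniformly random
actions in the environment (approximating unlimited, behaviourally unbiased
experience). Metrics include KL model accuracy, empirical transition
histograms, per-conditional distribution change, active vs passive
counterfactual prediction error, and the post-learning chemotaxis test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .agent import (
    Beliefs,
    GenerativeModel,
    Strategy,
    StepLog,
    agent_step,
    dirichlet_mean,
)
from .environment import (
    START_DISTANCE,
    Action,
    Observation,
    WorldState,
    apply_action,
    distance_to_source,
    observe,
    reset,
)

__all__ = [
    "TrueModel",
    "TestResult",
    "run_phase",
    "estimate_true_model",
    "model_accuracy_kl",
    "transition_histogram",
    "distribution_change_kl",
    "active_passive_errors",
    "run_test_phase",
    "SUCCESS_DISPLACEMENT",
]

#: displacement toward the source (length units) that counts as chemotaxis
SUCCESS_DISPLACEMENT = 50.0


@dataclass
class TrueModel:
    """Reference transition tensor estimated under a random policy.

    ``probs[u][i, j]`` = P(next gradient state i | previous state j, action
    u), column-stochastic, estimated by Monte Carlo with add-one smoothing.
    """

    probs: np.ndarray
    n_samples: int
    seed: int

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"probs": self.probs.tolist(), "n_samples": self.n_samples, "seed": self.seed},
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "TrueModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            probs=np.asarray(payload["probs"], dtype=float),
            n_samples=int(payload["n_samples"]),
            seed=int(payload["seed"]),
        )


@dataclass
class TestResult:
    """Outcome of a post-learning chemotaxis test phase."""

    final_distance: float
    displacement_toward_source: float
    success: bool
    trajectory: np.ndarray | None = None


@dataclass
class PhaseResult:
    """What a simulated phase returns: final state, beliefs, tallies."""

    state: WorldState
    beliefs: Beliefs
    transition_counts: np.ndarray
    logs: list[StepLog] = field(default_factory=list)


def run_phase(
    model: GenerativeModel,
    beliefs: Beliefs,
    strategy: Strategy,
    n_steps: int,
    rng: np.random.Generator,
    state: WorldState | None = None,
    learn: bool = True,
    log: bool = False,
    start_distance: float = START_DISTANCE,
) -> PhaseResult:
    """Simulate ``n_steps`` of coupled agent-environment dynamics.

    A fresh world (random placement at ``start_distance``) is drawn from
    ``rng`` unless ``state`` is given. The per-step draw order is fixed:
    tumble headings are drawn by the environment update, action sampling by
    the agent, all from the single ``rng``, so runs are bit-reproducible.
    Empirical (previous state, action, next state) transitions are tallied
    into a ``[u][next, prev]`` count tensor.
    """
    if state is None:
        state = reset(rng, start_distance)
    counts = np.zeros((model.n_controls, model.n_states, model.n_states))
    logs: list[StepLog] = []
    obs = observe(state)
    for _ in range(n_steps):
        action, beliefs, record = agent_step(obs, beliefs, model, strategy, rng, learn, log)
        apply_action(state, action, rng)
        next_obs = observe(state)
        counts[action][int(next_obs), int(obs)] += 1
        if record is not None:
            logs.append(record)
        obs = next_obs
    return PhaseResult(state=state, beliefs=beliefs, transition_counts=counts, logs=logs)


def estimate_true_model(
    n_samples: int = 1_000_000,
    seed: int = 0,
    episode_length: int = 1_000,
    start_distance: float = START_DISTANCE,
) -> TrueModel:
    """Estimate the reference transition tensor under a random policy.

    Runs episodes of ``episode_length`` uniformly random actions from the
    standard placement, tallies (previous observation-state, action, next
    observation-state) transitions, adds one to every cell and normalizes
    columns.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros((2, 2, 2))
    remaining = int(n_samples)
    while remaining > 0:
        steps = min(episode_length, remaining)
        state = reset(rng, start_distance)
        obs = observe(state)
        actions = rng.integers(0, 2, size=steps)
        for a in actions:
            apply_action(state, Action(int(a)), rng)
            nxt = observe(state)
            counts[a][int(nxt), int(obs)] += 1
            obs = nxt
        remaining -= steps
    counts += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    return TrueModel(probs=probs, n_samples=int(n_samples), seed=int(seed))


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def model_accuracy_kl(learned: Beliefs | np.ndarray, true_model: TrueModel) -> float:
    """Negative model accuracy: summed KL(true || learned mean), in nats.

    The learned model is summarized by the mean of its Dirichlet posterior;
    the KL divergence is evaluated per (previous state, action) conditional
    and summed over all four.
    """
    phi_alpha = learned.phi_alpha if isinstance(learned, Beliefs) else np.asarray(learned)
    total = 0.0
    for u in range(true_model.probs.shape[0]):
        learned_mean = dirichlet_mean(phi_alpha[u])
        for j in range(true_model.probs.shape[2]):
            total += _kl(true_model.probs[u][:, j], learned_mean[:, j])
    return total


def transition_histogram(transition_counts: np.ndarray) -> np.ndarray:
    """Percentage of steps spent in each (action, next, prev) transition cell.

    Input is the ``[u][next, prev]`` count tensor tallied by
    :func:`run_phase`; output has the same shape and sums to 100.
    """
    counts = np.asarray(transition_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty transition log")
    return 100.0 * counts / total


def distribution_change_kl(initial_counts: np.ndarray, final_counts: np.ndarray) -> np.ndarray:
    """Per-conditional learning magnitude: KL(final mean || initial mean).

    Returns an ``[u, j]`` array, one value per (action, previous state)
    conditional of the transition model.
    """
    initial = np.asarray(initial_counts, dtype=float)
    final = np.asarray(final_counts, dtype=float)
    out = np.zeros((initial.shape[0], initial.shape[2]))
    for u in range(initial.shape[0]):
        init_mean = dirichlet_mean(initial[u])
        fin_mean = dirichlet_mean(final[u])
        for j in range(initial.shape[2]):
            out[u, j] = _kl(fin_mean[:, j], init_mean[:, j])
    return out


def active_passive_errors(
    model: GenerativeModel,
    beliefs: Beliefs,
    strategy: Strategy,
    true_model: TrueModel,
    n_steps: int,
    rng: np.random.Generator,
    state: WorldState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative MSE of counterfactual one-step predictions.

    At each step the current observation fixes the conditioning state (the
    likelihood is unambiguous). The *active* error compares the agent's
    predicted next-state distribution for its self-determined action with
    the true model's; the *passive* error does the same for a uniformly
    random action. The agent keeps acting and learning under its own
    strategy throughout. Returns the two cumulative series (length
    ``n_steps`` each).
    """
    if state is None:
        state = reset(rng, START_DISTANCE)
    active = np.empty(n_steps)
    passive = np.empty(n_steps)
    obs = observe(state)
    for t in range(n_steps):
        action, beliefs, _ = agent_step(obs, beliefs, model, strategy, rng, learn=True)
        s = int(obs)
        pred = dirichlet_mean(beliefs.phi_alpha[action])[:, s]
        active[t] = float(np.mean((pred - true_model.probs[action][:, s]) ** 2))
        rand_a = int(rng.integers(0, model.n_controls))
        pred_r = dirichlet_mean(beliefs.phi_alpha[rand_a])[:, s]
        passive[t] = float(np.mean((pred_r - true_model.probs[rand_a][:, s]) ** 2))
        apply_action(state, action, rng)
        obs = observe(state)
    return np.cumsum(active), np.cumsum(passive)


def run_test_phase(
    beliefs: Beliefs,
    model: GenerativeModel,
    n_steps: int,
    rng: np.random.Generator | int,
    start_distance: float = START_DISTANCE,
) -> TestResult:
    """Post-learning chemotaxis test.

    Fresh placement at ``start_distance``; the agent selects actions by
    expected free energy for ``n_steps`` with learning disabled (beliefs
    are copied, the caller's counts are never mutated). Success means
    moving strictly more than ``SUCCESS_DISPLACEMENT`` units toward the
    source.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    test_beliefs = beliefs.copy()
    result = run_phase(
        model,
        test_beliefs,
        Strategy.EFE,
        n_steps,
        rng,
        learn=False,
        start_distance=start_distance,
    )
    final_distance = distance_to_source(result.state)
    displacement = start_distance - final_distance
    return TestResult(
        final_distance=final_distance,
        displacement_toward_source=displacement,
        success=displacement > SUCCESS_DISPLACEMENT,
    )
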